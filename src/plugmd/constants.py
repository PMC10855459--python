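"""Physical constants and unit conventions.

Internal units everywhere: length nm, time ps, mass amu (g/mol),
energy kJ/mol, temperature K, charge e.  Derived force unit is
kJ/(mol*nm); with these choices velocities come out in nm/ps and
``0.5*m*v**2`` is already kJ/mol, so no mass conversion factor is needed.
"""

#: Boltzmann constant, kJ/(mol*K)
KB = 0.0083144621

#: Coulomb prefactor 1/(4*pi*eps0), kJ*nm/(mol*e^2)
COULOMB = 138.935458

#: Avogadro's number, 1/mol
AVOGADRO = 6.02214076e23

#: kcal -> kJ
KCAL_TO_KJ = 4.184

#: mass of one water molecule, amu
WATER_MOLAR_MASS = 18.0153
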