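# Methods

## Scope and model of the toolkit

`plugmd` is a desk-scale molecular dynamics toolkit built around a single
contract: a *pluggable potential model* that maps coordinates (and a
periodic box) to an energy and forces. Everything else — integrators,
hybrid ML/MM region machinery, alchemical free-energy ladders, and the
validation instruments — operates against that contract, so a classical
force field, a neural-network surrogate, or a λ-mixed Hamiltonian are
interchangeable.

Internal units are nm, ps, amu, kJ/mol and elementary charge throughout,
with k_B = 0.0083144621 kJ/(mol·K). With these units ½mv² is already
kJ/mol, and velocities come out in nm/ps.

## The plugged-model contract

A wrapped model reports

    E(x) = energy_c · λ · E_inner(coord_c · x)
    F(x) = force_c · coord_c · λ · F_inner(coord_c · x)

where `coord_c`, `force_c`, `energy_c` convert a model trained in foreign
units (say Å and kcal/mol) into the engine's convention, and λ ∈ [0, 1]
scales energies and forces linearly (default 1). Forces are the negative
gradient of the reported energy exactly when `force_c = energy_c`; the
coefficients are stored independently so that externally supplied,
not-quite-consistent models can still be driven, but the consistent
setting is what the test suite asserts (an Å/kcal harmonic model with
`coord_c = 10, energy_c = force_c = 4.184` reproduces a native nm/kJ
trajectory to 1e-10).

ML/MM regions: a *region term* presents a model with only the selected
particles' coordinates, re-indexed in ascending global order (so
per-element parameter sequences stay stable), and scatters forces back to
exactly those particles. Adaptive regions select, at a configurable
frequency (default: every evaluation), the union of centre particles and
every particle within a minimum-image distance `radius` (default
0.35 nm) of any centre, optionally closed under residue membership.
Classical intra-region interactions can be deleted by subtracting the
classical model restricted to the region — exact for additive pairwise +
bonded force fields, and verified term-by-term in the tests. Energy
conservation under *adaptive* reselection is measured but not claimed;
discontinuous selection changes inject energy in general.

## Surrogate potentials

Two potentials ship with the package; both are stand-ins with the
*shape* of production models so the validation instruments have realistic
input, not fits to any particular system.

**Flexible water** (SPC/Fw-like): harmonic O–H bonds
(r₀ = 0.1012 nm, k = 443153.38 kJ/(mol·nm²)), harmonic H–O–H angle
(θ₀ = 113.24°, k = 317.57 kJ/(mol·rad²)), Lennard-Jones on oxygen only
(ε = 0.6503 kJ/mol, σ = 0.31655 nm), charges −0.82/+0.41 e, and
shifted-force truncation of both LJ and Coulomb so energy *and* force go
to zero continuously at the cutoff. Shifted-force truncation in place of
Ewald summation is a deliberate simplification: it keeps the engine
dependency-free and is exactly what makes desk-scale NVE conservation
tests meaningful; absolute energetics and dielectric behaviour are not
production-grade and are not used as such. The default cutoff is 0.9 nm
(valid for the 256-molecule, 1.980 nm reference box); the 64-molecule
box used in the conservation analog has edge ≈ 1.247 nm, so those runs
use 0.6 nm — the engine rejects any cutoff above half the smallest box
edge rather than silently wrapping.

**Surrogate NN potential**: a Behler–Parrinello-style sum of atomic
energies. Each atom's descriptor holds 8 radial Gaussians per neighbour
element (centres 0.08 nm…cutoff, cosine switching at the 0.6 nm default
cutoff); each element has a 16-unit tanh hidden layer. Weights are drawn
once from seed 20240124 and can be saved/loaded as a versioned JSON
container. The model is permutation-, rotation- and
translation-invariant by construction and carries analytic chain-rule
gradients, verified against central finite differences (h = 1e-5 nm) to
a max relative error below 1e-4.

Neighbour search is O(N²) with vectorised cutoff masking. At the largest
in-scope system (768 atoms) a force evaluation costs ≈2.4 ms, which meets
every workload here; a cell list would only pay off well beyond these
sizes and is not implemented.

## Integrators

Velocity Verlet for NVE (time-reversible to 1e-6 nm over 2×1000 steps,
momentum-conserving to 1e-8 relative). NVT thermostats:

- **Langevin** (BAOAB splitting), `coupling` = friction γ in ps⁻¹; the
  γ → 0 limit reproduces the NVE trajectory exactly.
- **Andersen**, `coupling` = collision frequency ν; each particle is
  redrawn from the Maxwell–Boltzmann distribution with probability
  1 − exp(−ν·dt) per step. The validated reference runs quote a
  "friction coefficient" of 1 ps⁻¹ for this thermostat; collision
  frequency is the only reading that fits, and is what is implemented.
- **Nosé–Hoover**, single chain, Q = n_dof·k_B·T·τ² with
  τ = 1/`coupling`; chain length 1. Ergodicity on stiff few-particle
  systems is poor (as for any single NH chain), so unbiasedness tests use
  many independent oscillators.

All stochastic integrators take an explicit seed and produce bit-identical
energy logs for identical inputs on one platform. Positions are never
wrapped into the box (minimum-image handles periodicity), so recorded
coordinates are continuous and feed MSD analysis directly without
image-flag bookkeeping.

## Alchemical free energies

Dual-topology linear mixing without softcore:

    U(λ) = λ·U_A + (1 − λ)·(U_B1({j}) + U_B2({i}))

with disjoint groups i (solute) and j (environment) covering the system.
Endpoints are exact by construction (the λ = 0 / λ = 1 branch short-
circuits the unused term). The default schedule is the ten-state ladder
(0, 0.01, 0.03, 0.05, 0.08, 0.12, 0.2, 0.4, 0.7, 1.0), densely spaced
near the decoupled end precisely because linear scaling without softcore
degrades overlap there. The ladder driver simulates each state
independently (fresh Maxwell–Boltzmann velocities, per-state seeds
spawned from one master seed), discards a configurable burn-in fraction
(default 10%), and re-evaluates every retained frame under all K states
to build the reduced-energy matrix u[k][n] = β·U_k(x_n).

**MBAR.** Free energies solve the self-consistent equations by iteration
with Newton refinement on the K−1 free parameters (f₀ ≡ 0); convergence
is max_k |Σ_n W_nk − 1| < 1e-8. Uncertainties use the asymptotic
covariance (SVD form); no autocorrelation correction is applied by
default — decorrelation is the caller's job via the save interval, and
the tests thin harmonic-toy trajectories to ≈1 correlation time before
analysis. The overlap matrix is O_ij = Σ_n W_ni·N_j·W_nj (rows sum to 1);
identical states give O_ij = N_j/ΣN and disjoint supports give the
identity. Convention: a solvation (hydration) free energy is the
*negative* of the decoupling free energy ΔG(λ=1 → λ=0). The decoupled
solute is propagated in the same box without a restraint by default; a
centre-of-mass tether is unnecessary for the toy systems exercised here.

## Validation instruments

**NVE conservation.** `conservation_report` returns the SD of the total
energy, the per-DOF fluctuation SD/n_dof (the headline figure, quoted in
kcal/mol), and the least-squares drift. Drift *uncertainty* is subtle:
the total energy of a truncated-potential run is fast thermal
oscillation on top of a slow random walk, so the plain OLS slope SE
under-covers badly (a physically negligible drift can appear as z ≈ 5).
The reported SE is therefore the standard error of block-mean increments
(25 blocks), the appropriate inference for a random-walk-dominated
series and conservative under the increments' anticorrelation. The
companion magnitude criterion — |slope| below 1e-4 kJ/mol/ps per DOF —
is asserted separately and does not depend on this choice.

**Canonical ensemble consistency.** For two canonical runs at T₁ < T₂,
ln[P(E|β₂)/P(E|β₁)] is linear in E with slope β₁ − β₂. The recipe: bin
the *combined* min/max range of both sample sets into 30 equal bins
(combined, because the ratio needs a shared binning); compute per-
trajectory bin probabilities; drop bins with probability < 0.001 in
either set; of the survivors drop the first and last 3; fit by
unweighted least squares. The slope SE propagates the multinomial
variance of each log-ratio point rather than using residual scatter
(residuals are smooth binning curvature, not iid noise; propagated SEs
show 95% empirical ±2 SE coverage at the 8000-sample scale versus
84–88% for residual-based ones). The estimator is best-behaved at that
scale: very large samples widen the min/max range, coarsen the bins and
introduce a ≈1% systematic slope bias, which is why the calibration test
runs 300 repetitions at n = 8000 (measured mean bias −0.3%).

**RDF.** Minimum-image pair histogram normalised by the ideal-gas shell
count and frame count; same-set selections count pairs once, cross-set
selections must be disjoint. Default bin width 0.002 nm, r_max = 0.45 ×
the smallest box edge (capped at half). Peak positions are reported in
Å, the customary unit of liquid-structure tables, with parabolic sub-bin
refinement. Cross-checked against MDAnalysis `InterRDF` on identical
frames.

**MSD / diffusion.** Multi-origin MSD via the FFT autocorrelation
identity (equal to the O(T²) windowed oracle to 1e-10); D = slope/6 with
the fit window defaulting to lags in [10%, 50%] of the maximum. Because
MSD values at different lags share origins, the naive OLS slope SE is
dishonestly small; the reported SE is the spread of independent
per-walker slope fits. A log-log exponent far from 1 flags non-diffusive
(e.g. ballistic) input. Finite-size extrapolation fits D = D_∞ + b/L and
returns the intercept; on the five published periodic-box water values —
D for 256–2048 molecules plus the 4096-molecule value, with box edges
density-scaled from the 19.80 Å reference box (L ∝ N^{1/3}; the original
report does not print the larger edges, so this scaling is an assumption
of this package) — it reproduces the published infinite-box value
0.686×10⁻⁵ cm²/s to within 0.002.

## Synthetic fixtures: what they do and do not show

Fixture generators are first-class, seed-deterministic code:
jittered-lattice water boxes (guaranteed packing at liquid density;
random molecular orientations), harmonic toys, ideal-gas frames,
Brownian walks with known D, and Gamma(n_dof/2, k_B·T) canonical energy
samples — the exact potential-energy law of a harmonic system, which
makes the ensemble-consistency oracle exact rather than approximate.
Passing tests demonstrate that the *instruments and estimators* are
correct (conservation statistics, slope recovery, MBAR against analytic
partition-function ratios, Einstein-relation round trips). They do not
demonstrate that any surrogate potential reproduces real water:
structural/transport numbers from the surrogates are validation analogs,
not predictions, and no claim is made about agreement with experimental
water properties.

## Problem sizes and numerical choices

The conservation analog runs 64 water molecules (192 atoms, n_dof = 576)
for 10 ps at dt = 0.2 fs after 1 ps of Langevin equilibration at 300 K —
a scaled-down analog of the 256-molecule, 2 ns reference experiment,
chosen as the smallest system that keeps the cutoff physics
representative while the whole battery stays interactive. Alchemy tests
use 1–2-particle harmonic systems where every answer is known in closed
form. Degenerate inputs fail loudly: too-dense packing, cutoff beyond
half the box, non-finite energies during integration (with the step
index), empty adaptive centres, fewer than two usable histogram bins,
and MBAR non-convergence (with the final residual) all raise typed
errors.

## Known limitations

- No Ewald/PME, no constraints, no barostat, orthorhombic boxes only;
  absolute solvation energetics with the surrogate water are not
  meaningful.
- Single-chain Nosé–Hoover; no chains > 1, no massive thermostatting.
- MBAR assumes decorrelated samples as given; subsample via the save
  interval.
- Adaptive-region energy conservation is not guaranteed (and not
  claimed); reselection discontinuities are inherent to the scheme.
- The O(N²) neighbour search is intentional for desk scale and will not
  scale to 10⁵-atom systems.
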