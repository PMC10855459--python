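"""Flexible three-site water force field (SPC/Fw-style surrogate).

Harmonic O-H bonds and H-O-H angle, Lennard-Jones on oxygen only, and
point-charge electrostatics, with shifted-force truncation of both
nonbonded terms so that energy and forces are continuous at the cutoff --
the property that makes desk-scale NVE conservation tests meaningful
without Ewald summation.
"""

from __future__ import annotations

import numpy as np

from ..constants import COULOMB
from ..system import ParticleSystem, minimum_image
from .base import PotentialModel

__all__ = ["FlexibleWaterPotential", "WaterParameters"]


class WaterParameters:
    """SPC/Fw-like parameter set, internal units (nm, kJ/mol, rad, e)."""

    r0_oh = 0.1012                   # nm
    k_oh = 443153.38                 # kJ/(mol nm^2)
    theta0 = np.deg2rad(113.24)      # rad
    k_hoh = 317.5657                 # kJ/(mol rad^2)
    epsilon_oo = 0.650300            # kJ/mol
    sigma_oo = 0.3165492             # nm
    q_o = -0.82                      # e
    q_h = 0.41                       # e


class FlexibleWaterPotential(PotentialModel):
    """Flexible water model over a fixed topology of whole molecules.

    Parameters
    ----------
    element_types, residue_index
        Per-particle topology; each residue must contain one O and two H.
    cutoff
        Nonbonded cutoff in nm (shifted-force LJ and Coulomb).
    """

    def __init__(self, element_types: list[str], residue_index: np.ndarray,
                 cutoff: float = 0.9, params: WaterParameters | None = None):
        self.params = params or WaterParameters()
        self.cutoff = float(cutoff)
        self.element_types = list(element_types)
        self.residue_index = np.asarray(residue_index, dtype=int)
        n = len(self.element_types)
        if len(self.residue_index) != n:
            raise ValueError("topology length mismatch")
        self._n = n

        bonds, angles = [], []
        for res in np.unique(self.residue_index):
            idx = np.flatnonzero(self.residue_index == res)
            os = [i for i in idx if self.element_types[i] == "O"]
            hs = [i for i in idx if self.element_types[i] == "H"]
            if len(os) != 1 or len(hs) != 2:
                raise ValueError(f"residue {res} is not a water (O + 2H)")
            bonds += [(os[0], hs[0]), (os[0], hs[1])]
            angles.append((hs[0], os[0], hs[1]))
        self.bonds = np.array(bonds, dtype=int)
        self.angles = np.array(angles, dtype=int)

        p = self.params
        self.charges = np.where(np.array(self.element_types) == "O", p.q_o, p.q_h)

        # intermolecular pairs only; intramolecular nonbonded fully excluded
        ii, jj = np.triu_indices(n, k=1)
        inter = self.residue_index[ii] != self.residue_index[jj]
        self.pair_i, self.pair_j = ii[inter], jj[inter]
        is_o = np.array(self.element_types) == "O"
        self.pair_lj = is_o[self.pair_i] & is_o[self.pair_j]
        self.pair_qq = self.charges[self.pair_i] * self.charges[self.pair_j]

    @classmethod
    def for_system(cls, system: ParticleSystem, cutoff: float = 0.9,
                   **kw) -> "FlexibleWaterPotential":
        return cls(system.element_types, system.residue_index, cutoff=cutoff, **kw)

    @property
    def n_expected_particles(self) -> int:
        return self._n

    # -- energy terms ------------------------------------------------------

    def _bond_energy_forces(self, pos, box, forces):
        p = self.params
        d = pos[self.bonds[:, 1]] - pos[self.bonds[:, 0]]
        if box is not None:
            d = minimum_image(d, box)
        r = np.linalg.norm(d, axis=1)
        dr = r - p.r0_oh
        energy = 0.5 * p.k_oh * np.sum(dr**2)
        fvec = (-p.k_oh * dr / r)[:, None] * d
        np.add.at(forces, self.bonds[:, 1], fvec)
        np.add.at(forces, self.bonds[:, 0], -fvec)
        return energy

    def _angle_energy_forces(self, pos, box, forces):
        p = self.params
        i, j, k = self.angles.T  # H, O, H
        u = pos[i] - pos[j]
        v = pos[k] - pos[j]
        if box is not None:
            u = minimum_image(u, box)
            v = minimum_image(v, box)
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.clip(1.0 - cos**2, 1e-12, None))
        de = p.k_hoh * (theta - p.theta0)
        energy = 0.5 * p.k_hoh * np.sum((theta - p.theta0) ** 2)
        fi = (de / (nu * sin))[:, None] * (vh - cos[:, None] * uh)
        fk = (de / (nv * sin))[:, None] * (uh - cos[:, None] * vh)
        np.add.at(forces, i, fi)
        np.add.at(forces, k, fk)
        np.add.at(forces, j, -(fi + fk))
        return energy

    def _nonbonded_energy_forces(self, pos, box, forces):
        p = self.params
        rc = self.cutoff
        d = pos[self.pair_i] - pos[self.pair_j]
        if box is not None:
            d = minimum_image(d, box)
        r2 = np.sum(d * d, axis=1)
        mask = r2 < rc * rc
        if not np.any(mask):
            return 0.0
        d = d[mask]
        r = np.sqrt(r2[mask])
        pi, pj = self.pair_i[mask], self.pair_j[mask]

        # shifted-force Coulomb: V = f q q (1/r - 1/rc + (r - rc)/rc^2)
        qq = COULOMB * self.pair_qq[mask]
        energy = float(np.sum(qq * (1.0 / r - 1.0 / rc + (r - rc) / rc**2)))
        fmag = qq * (1.0 / r**2 - 1.0 / rc**2)  # along +d

        lj = self.pair_lj[mask]
        if np.any(lj):
            rl = r[lj]
            s6 = (p.sigma_oo / rl) ** 6
            s6c = (p.sigma_oo / rc) ** 6
            v = 4 * p.epsilon_oo * (s6**2 - s6)
            vc = 4 * p.epsilon_oo * (s6c**2 - s6c)
            dvc = -(24 * p.epsilon_oo / rc) * (2 * s6c**2 - s6c)  # V'(rc)
            energy += float(np.sum(v - vc - (rl - rc) * dvc))
            fmag_lj = (24 * p.epsilon_oo / rl) * (2 * s6**2 - s6) + dvc
            fmag[lj] += fmag_lj

        fvec = (fmag / r)[:, None] * d
        n = len(forces)
        for dim in range(3):  # bincount scatter: much faster than add.at here
            forces[:, dim] += (np.bincount(pi, weights=fvec[:, dim], minlength=n)
                               - np.bincount(pj, weights=fvec[:, dim], minlength=n))
        return energy

    def energy_components(self, positions, box=None) -> dict[str, float]:
        """Per-term energies (kJ/mol) at lambda = 1, for diagnostics."""
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        f = np.zeros_like(pos)
        return {
            "bond": float(self._bond_energy_forces(pos, box, f)),
            "angle": float(self._angle_energy_forces(pos, box, f)),
            "nonbonded": float(self._nonbonded_energy_forces(pos, box, f)),
        }

    def _compute(self, pos, box):
        forces = np.zeros_like(pos)
        energy = self._bond_energy_forces(pos, box, forces)
        energy += self._angle_energy_forces(pos, box, forces)
        energy += self._nonbonded_energy_forces(pos, box, forces)
        return energy, forces

    # -- region support ----------------------------------------------------

    def subset(self, indices: np.ndarray) -> "FlexibleWaterPotential":
        """Model restricted to the interactions fully inside ``indices``.

        Bonded terms and nonbonded pairs with any atom outside the subset
        are dropped; the returned model acts on re-indexed coordinates in
        ascending global order.  Used to delete classical intra-region
        interactions in hybrid ML/MM setups.
        """
        indices = np.asarray(sorted(set(np.asarray(indices, dtype=int).tolist())))
        remap = -np.ones(self._n, dtype=int)
        remap[indices] = np.arange(len(indices))
        inside = np.zeros(self._n, dtype=bool)
        inside[indices] = True

        sub = object.__new__(FlexibleWaterPotential)
        sub.params = self.params
        sub.cutoff = self.cutoff
        sub.lambda_scale = 1.0
        sub.element_types = [self.element_types[i] for i in indices]
        sub.residue_index = self.residue_index[indices]
        sub._n = len(indices)

        keep_b = inside[self.bonds].all(axis=1)
        sub.bonds = remap[self.bonds[keep_b]]
        keep_a = inside[self.angles].all(axis=1)
        sub.angles = remap[self.angles[keep_a]]
        sub.charges = self.charges[indices]
        keep_p = inside[self.pair_i] & inside[self.pair_j]
        sub.pair_i = remap[self.pair_i[keep_p]]
        sub.pair_j = remap[self.pair_j[keep_p]]
        sub.pair_lj = self.pair_lj[keep_p]
        sub.pair_qq = self.pair_qq[keep_p]
        return sub
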