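"""Small closed-form potentials used for oracles, toys and alchemy tests."""

from __future__ import annotations

import numpy as np

from ..system import minimum_image
from .base import PotentialModel

__all__ = ["ZeroPotential", "HarmonicWellPotential", "LennardJonesPotential"]


class ZeroPotential(PotentialModel):
    """Ideal gas: zero energy and forces."""

    def _compute(self, pos, box):
        return 0.0, np.zeros_like(pos)


class HarmonicWellPotential(PotentialModel):
    """Independent isotropic springs tying each particle to a fixed centre.

    E = sum_i 0.5 * k_i * |r_i - c_i|^2 with k in kJ/(mol nm^2).  ``k`` may
    be a scalar or per-particle array; ``centers`` defaults to the origin.
    """

    def __init__(self, k: float | np.ndarray, centers: np.ndarray | None = None):
        self.k = np.asarray(k, dtype=float)
        self.centers = None if centers is None else np.asarray(centers, float)

    def _compute(self, pos, box):
        d = pos if self.centers is None else pos - self.centers
        k = self.k if self.k.ndim == 0 else self.k[:, None]
        energy = float(0.5 * np.sum(k * d * d))
        return energy, -k * d


class LennardJonesPotential(PotentialModel):
    """Single-type Lennard-Jones fluid with optional shifted-force cutoff.

    With ``shifted=True`` the pair energy is
    ``V(r) - V(rc) - (r - rc) V'(rc)`` so both energy and force vanish
    continuously at the cutoff; ``sf_offset(r)`` reports the constant-and-
    linear correction separately so that bare-potential identities (e.g.
    V(sigma) = 0) remain checkable.
    """

    def __init__(self, epsilon: float, sigma: float, cutoff: float,
                 shifted: bool = True):
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.cutoff = float(cutoff)
        self.shifted = bool(shifted)

    def _vp(self, r):
        s6 = (self.sigma / r) ** 6
        v = 4 * self.epsilon * (s6**2 - s6)
        dv = -(24 * self.epsilon / r) * (2 * s6**2 - s6)
        return v, dv

    def sf_offset(self, r: float) -> float:
        """Shifted-force correction -V(rc) - (r - rc) V'(rc) at distance r."""
        vc, dvc = self._vp(self.cutoff)
        return -vc - (r - self.cutoff) * dvc

    def _compute(self, pos, box):
        n = len(pos)
        ii, jj = np.triu_indices(n, k=1)
        d = pos[ii] - pos[jj]
        if box is not None:
            d = minimum_image(d, box)
        r = np.linalg.norm(d, axis=1)
        mask = r < self.cutoff
        ii, jj, d, r = ii[mask], jj[mask], d[mask], r[mask]
        forces = np.zeros_like(pos)
        if len(r) == 0:
            return 0.0, forces
        v, dv = self._vp(r)
        if self.shifted:
            vc, dvc = self._vp(self.cutoff)
            energy = float(np.sum(v - vc - (r - self.cutoff) * dvc))
            fmag = -dv + dvc
        else:
            energy = float(np.sum(v))
            fmag = -dv
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, ii, fvec)
        np.add.at(forces, jj, -fvec)
        return energy, forces
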