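"""Seeded feed-forward neural-network potential with radial descriptors.

A deliberately small Behler-Parrinello-style model: per-atom radial
symmetry-function descriptors (Gaussian centres with cosine cutoff
switching, resolved by neighbour element) feed one tanh hidden layer per
element, and the system energy is the sum of atomic energies,
U_sys = sum_i U_i.  The weights are random but fixed by a seed, giving a
smooth, permutation/rotation/translation-invariant many-body surface with
analytic gradients -- the shape of a trained ML potential without the
training.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..system import minimum_image
from .base import PotentialModel

__all__ = ["SurrogateNNPotential"]

WEIGHTS_FORMAT_VERSION = 1
DEFAULT_WEIGHT_SEED = 20240124


class SurrogateNNPotential(PotentialModel):
    """Sum-of-atomic-energies NN potential over fixed element types.

    Parameters
    ----------
    element_types
        Element symbol per particle (fixed topology).
    cutoff
        Descriptor cutoff, nm; cosine switching to zero at the cutoff.
    n_centers, n_hidden
        Radial Gaussians per neighbour element and hidden-layer width.
    seed
        Seed for the fixed random network weights.
    energy_scale
        kJ/mol scale of atomic energy contributions.
    """

    def __init__(self, element_types: list[str], cutoff: float = 0.6,
                 n_centers: int = 8, n_hidden: int = 16,
                 seed: int = DEFAULT_WEIGHT_SEED, energy_scale: float = 5.0,
                 weights: dict | None = None):
        self.element_types = list(element_types)
        self.cutoff = float(cutoff)
        self.n_centers = int(n_centers)
        self.n_hidden = int(n_hidden)
        self.energy_scale = float(energy_scale)
        self.elements = sorted(set(self.element_types))
        self._elem_class = np.array([self.elements.index(e)
                                     for e in self.element_types])
        self._n = len(self.element_types)
        ii, jj = np.triu_indices(self._n, k=1)
        self._pair_i, self._pair_j = ii, jj

        self.centers = np.linspace(0.08, self.cutoff, self.n_centers)
        width = self.centers[1] - self.centers[0] if self.n_centers > 1 else 0.1
        self.eta = 1.0 / (2.0 * width**2)

        self.weights = weights if weights is not None else self._init_weights(seed)

    @property
    def n_expected_particles(self) -> int:
        return self._n

    def _init_weights(self, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        d_in = len(self.elements) * self.n_centers
        w = {}
        for elem in self.elements:
            w[elem] = {
                "W1": rng.normal(0, 1.0 / np.sqrt(d_in), (self.n_hidden, d_in)),
                "b1": rng.normal(0, 0.1, self.n_hidden),
                "W2": rng.normal(0, 1.0 / np.sqrt(self.n_hidden), self.n_hidden),
                "b2": float(rng.normal(0, 0.1)),
            }
        return w

    # -- weight container (versioned, portable JSON) -----------------------

    def save_weights(self, path: str | Path) -> None:
        payload = {"format_version": WEIGHTS_FORMAT_VERSION,
                   "elements": self.elements,
                   "n_centers": self.n_centers, "n_hidden": self.n_hidden,
                   "cutoff": self.cutoff, "energy_scale": self.energy_scale,
                   "weights": {e: {k: np.asarray(v).tolist()
                                   for k, v in w.items()}
                               for e, w in self.weights.items()}}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_weights_file(cls, path: str | Path,
                          element_types: list[str]) -> "SurrogateNNPotential":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != WEIGHTS_FORMAT_VERSION:
            raise ValueError("unsupported weights file version")
        weights = {e: {k: np.asarray(v, dtype=float) for k, v in w.items()}
                   for e, w in payload["weights"].items()}
        return cls(element_types, cutoff=payload["cutoff"],
                   n_centers=payload["n_centers"], n_hidden=payload["n_hidden"],
                   energy_scale=payload["energy_scale"], weights=weights)

    # -- descriptors and network -------------------------------------------

    def _pair_terms(self, pos, box):
        d = pos[self._pair_i] - pos[self._pair_j]
        if box is not None:
            d = minimum_image(d, box)
        r2 = np.sum(d * d, axis=1)
        mask = r2 < self.cutoff**2
        return self._pair_i[mask], self._pair_j[mask], d[mask], np.sqrt(r2[mask])

    def _radial_basis(self, r):
        """g_m(r) = exp(-eta (r-mu_m)^2) fc(r) and its derivative, (P, M)."""
        rc = self.cutoff
        fc = 0.5 * (1.0 + np.cos(np.pi * r / rc))
        dfc = -0.5 * np.pi / rc * np.sin(np.pi * r / rc)
        diff = r[:, None] - self.centers[None, :]
        gauss = np.exp(-self.eta * diff**2)
        g = gauss * fc[:, None]
        dg = gauss * (dfc[:, None] - 2.0 * self.eta * diff * fc[:, None])
        return g, dg

    def _descriptors(self, pi, pj, r):
        n_s, m = len(self.elements), self.n_centers
        g, dg = self._radial_basis(r)
        desc = np.zeros((self._n, n_s, m))
        ci, cj = self._elem_class[pi], self._elem_class[pj]
        for s in range(n_s):
            sel = cj == s
            for col in range(m):
                desc[:, s, col] += np.bincount(pi[sel], weights=g[sel, col],
                                               minlength=self._n)
            sel = ci == s
            for col in range(m):
                desc[:, s, col] += np.bincount(pj[sel], weights=g[sel, col],
                                               minlength=self._n)
        return desc.reshape(self._n, n_s * m), g, dg

    def _network(self, desc):
        """Atomic energies and dU_i/dG_i for all atoms, vectorized by element."""
        energies = np.zeros(self._n)
        grad = np.zeros_like(desc)
        for s, elem in enumerate(self.elements):
            idx = np.flatnonzero(self._elem_class == s)
            if len(idx) == 0:
                continue
            w = self.weights[elem]
            h = np.tanh(desc[idx] @ w["W1"].T + w["b1"])
            energies[idx] = self.energy_scale * (h @ w["W2"] + w["b2"])
            # dU/dG = W1^T (W2 * (1 - h^2))
            grad[idx] = self.energy_scale * ((w["W2"] * (1 - h**2)) @ w["W1"])
        return energies, grad

    def atomic_energies(self, positions, box=None) -> np.ndarray:
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        pi, pj, _, r = self._pair_terms(pos, box)
        desc, _, _ = self._descriptors(pi, pj, r)
        energies, _ = self._network(desc)
        return energies

    def _compute(self, pos, box):
        n_s, m = len(self.elements), self.n_centers
        pi, pj, d, r = self._pair_terms(pos, box)
        desc, _, dg = self._descriptors(pi, pj, r)
        energies, grad = self._network(desc)
        grad3 = grad.reshape(self._n, n_s, m)

        forces = np.zeros_like(pos)
        if len(r):
            ci, cj = self._elem_class[pi], self._elem_class[pj]
            # dU/dr for pair (i,j): descriptor channels of i indexed by j's
            # element and vice versa
            coeff = grad3[pi, cj] + grad3[pj, ci]          # (P, M)
            dudr = np.sum(coeff * dg, axis=1)              # (P,)
            fvec = (-dudr / r)[:, None] * d                # force on i
            for dim in range(3):
                forces[:, dim] += (
                    np.bincount(pi, weights=fvec[:, dim], minlength=self._n)
                    - np.bincount(pj, weights=fvec[:, dim], minlength=self._n))
        return float(np.sum(energies)), forces
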