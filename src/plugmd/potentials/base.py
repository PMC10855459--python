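"""The pluggable potential-model contract.

Every potential exposes ``evaluate(positions, box) -> (energy, forces)`` in
kJ/mol and kJ/(mol*nm), scaled linearly by ``lambda_scale``.  Concrete
models implement ``_compute``; the base class applies the lambda scaling so
alchemical machinery can dial any model between 0 and 1 uniformly.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

__all__ = ["PotentialModel", "CutoffError"]


class CutoffError(ValueError):
    """Interaction cutoff exceeds half the smallest box edge."""


class PotentialModel(ABC):
    """Energy/force evaluator contract.

    Attributes
    ----------
    lambda_scale
        Dimensionless multiplier in [0, 1] applied to energies and forces.
    cutoff
        Largest interaction range in nm, or ``None`` for models without a
        distance cutoff.  Checked against half the smallest box edge.
    """

    lambda_scale: float = 1.0
    cutoff: float | None = None

    @abstractmethod
    def _compute(self, positions: np.ndarray, box: np.ndarray | None
                 ) -> tuple[float, np.ndarray]:
        """Raw energy (kJ/mol) and forces (kJ/(mol*nm)) at lambda = 1."""

    def check_box(self, box: np.ndarray | None) -> None:
        if self.cutoff is not None and box is not None and np.any(np.asarray(box) > 0):
            if self.cutoff > 0.5 * float(np.min(box)):
                raise CutoffError(
                    f"cutoff {self.cutoff} nm exceeds half the smallest box "
                    f"edge ({0.5 * float(np.min(box)):.4f} nm)")

    def evaluate(self, positions: np.ndarray, box: np.ndarray | None = None
                 ) -> tuple[float, np.ndarray]:
        """Energy and forces, scaled by ``lambda_scale``."""
        self.check_box(box)
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        energy, forces = self._compute(positions, box)
        lam = float(self.lambda_scale)
        if lam == 1.0:
            return float(energy), forces
        return lam * float(energy), lam * forces

    @property
    def n_expected_particles(self) -> int | None:
        """Particle count the model was parameterised for (None = any)."""
        return None
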