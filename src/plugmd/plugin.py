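"""Pluggable-model user contract: unit transforms, lambda scaling, and
fixed or adaptive ML regions combinable with a classical force field.

The central object is :class:`PluggedModel`, which wraps any
:class:`~plugmd.potentials.base.PotentialModel` trained in foreign units
and exposes it in the engine's nm / kJ/mol convention:

    reported energy = energy_c * lambda * E_inner(coord_c * x)
    reported forces = force_c * coord_c * lambda * F_inner

Chain-rule consistency of forces with the reported energy holds when
``force_coefficient == energy_coefficient``; the coefficients are kept
independent so partially inconsistent external models can still be driven.

Region terms restrict a model to a subset of particles (the ML region of a
hybrid ML/MM scheme): the model sees only the selected coordinates,
re-indexed in ascending global order, and its forces scatter back to those
particles only.  Adaptive regions reselect around centre particles by a
minimum-image distance criterion with optional residue closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .potentials.base import PotentialModel
from .system import ParticleSystem, minimum_image

__all__ = [
    "PluggedModel", "RegionSpec", "CompositeForceField",
    "FullSystemTerm", "RegionTerm", "AdaptiveRegionTerm", "ExclusionTerm",
    "TypeMapError", "set_unit_transform", "create_full_system_force",
    "add_particles_to_region", "select_adaptive_region",
    "apply_region_exclusions",
]


class TypeMapError(ValueError):
    """Topology does not match what the model was parameterised for."""


class PluggedModel(PotentialModel):
    """A potential model wrapped with unit-transform coefficients and a
    lambda scale factor (default 1.0)."""

    def __init__(self, inner: PotentialModel, lambda_scale: float = 1.0,
                 coord_coefficient: float = 1.0,
                 force_coefficient: float = 1.0,
                 energy_coefficient: float = 1.0):
        if not 0.0 <= lambda_scale <= 1.0:
            raise ValueError("lambda_scale must lie in [0, 1]")
        self.inner = inner
        self.lambda_scale = float(lambda_scale)
        set_unit_transform(self, coord_coefficient, force_coefficient,
                           energy_coefficient)

    @property
    def cutoff(self):
        c = self.inner.cutoff
        # inner cutoff is in inner length units: convert back to nm
        return None if c is None else c / self.coord_coefficient

    @cutoff.setter
    def cutoff(self, value):  # pragma: no cover - base-class default assign
        pass

    @property
    def n_expected_particles(self):
        return self.inner.n_expected_particles

    def _compute(self, pos, box):
        cc = self.coord_coefficient
        inner_box = None if box is None else np.asarray(box) * cc
        e, f = self.inner.evaluate(pos * cc, inner_box)
        return self.energy_coefficient * e, self.force_coefficient * cc * f


def set_unit_transform(model: PluggedModel, coord_coefficient: float,
                       force_coefficient: float, energy_coefficient: float
                       ) -> PluggedModel:
    """Set the three unit-conversion coefficients on a plugged model."""
    for name, value in [("coord", coord_coefficient),
                        ("force", force_coefficient),
                        ("energy", energy_coefficient)]:
        if not value > 0:
            raise ValueError(f"{name} coefficient must be positive")
    model.coord_coefficient = float(coord_coefficient)
    model.force_coefficient = float(force_coefficient)
    model.energy_coefficient = float(energy_coefficient)
    return model


@dataclass
class RegionSpec:
    """Configuration of the ML region of a hybrid simulation."""
    mode: str = "full"  # full | fixed | adaptive
    fixed_particles: tuple[int, ...] = ()
    center_particles: tuple[int, ...] = ()
    radius: float = 0.35
    extend_residues: bool = True
    update_every: int = 1

    def __post_init__(self):
        if self.mode not in ("full", "fixed", "adaptive"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        for group in (self.fixed_particles, self.center_particles):
            if len(set(group)) != len(group) or any(i < 0 for i in group):
                raise ValueError("particle indices must be unique and >= 0")
        if self.mode == "adaptive" and self.radius <= 0:
            raise ValueError("adaptive mode requires radius > 0")


class FullSystemTerm(PotentialModel):
    """A force-field term whose scope is every particle in the system."""

    def __init__(self, model: PotentialModel, n_particles: int):
        self.model = model
        self.n_particles = int(n_particles)

    @property
    def cutoff(self):
        return self.model.cutoff

    @cutoff.setter
    def cutoff(self, value):  # pragma: no cover
        pass

    def _compute(self, pos, box):
        if len(pos) != self.n_particles:
            raise TypeMapError(f"expected {self.n_particles} particles, "
                               f"got {len(pos)}")
        return self.model.evaluate(pos, box)


def create_full_system_force(model: PotentialModel,
                             topology: ParticleSystem) -> FullSystemTerm:
    """Wrap a model as a simulation-ready whole-system force term."""
    n = topology.n_particles
    expected = model.n_expected_particles
    if expected is not None and expected != n:
        raise TypeMapError(
            f"model is parameterised for {expected} particles but the "
            f"topology has {n}")
    return FullSystemTerm(model, n)


class RegionTerm(PotentialModel):
    """A model evaluated on a fixed particle subset with force scatter.

    The inner model sees the selected particles' coordinates re-indexed in
    ascending global order; every particle outside the region receives
    exactly zero force from this term.
    """

    def __init__(self, model: PotentialModel, particles: Sequence[int],
                 n_total: int, sign: float = 1.0):
        particles = np.asarray(sorted(set(int(i) for i in particles)))
        if len(particles) == 0:
            raise ValueError("region must contain at least one particle")
        if particles[0] < 0 or particles[-1] >= n_total:
            raise IndexError("region particle index out of range")
        self.model = model
        self.particles = particles
        self.n_total = int(n_total)
        self.sign = float(sign)

    @property
    def cutoff(self):
        return self.model.cutoff

    @cutoff.setter
    def cutoff(self, value):  # pragma: no cover
        pass

    def _compute(self, pos, box):
        e, f_sub = self.model.evaluate(pos[self.particles], box)
        forces = np.zeros_like(pos)
        forces[self.particles] = f_sub
        return self.sign * e, self.sign * forces


def add_particles_to_region(model: PotentialModel, particles: Sequence[int],
                            topology: ParticleSystem) -> RegionTerm:
    """Scope a model to an explicit particle set of the full topology."""
    return RegionTerm(model, particles, topology.n_particles)


def select_adaptive_region(positions: np.ndarray, box: np.ndarray | None,
                           centers: Sequence[int], radius: float,
                           extend_residues: bool = True,
                           residue_index: np.ndarray | None = None
                           ) -> np.ndarray:
    """Select the ML region around centre particles.

    Returns the sorted union of the centres and every particle whose
    minimum-image distance to any centre is <= ``radius`` (nm), closed
    under residue membership when ``extend_residues``.
    """
    centers = np.asarray(list(centers), dtype=int)
    if len(centers) == 0:
        raise ValueError("centers must be non-empty")
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    delta = pos[None, :, :] - pos[centers][:, None, :]   # (C, N, 3)
    if box is not None and np.all(np.asarray(box) > 0):
        delta = minimum_image(delta, np.asarray(box))
    within = np.any(np.sum(delta**2, axis=2) <= radius**2, axis=0)
    within[centers] = True
    if extend_residues:
        if residue_index is None:
            raise ValueError("extend_residues requires residue_index")
        residue_index = np.asarray(residue_index)
        hit = np.unique(residue_index[within])
        within |= np.isin(residue_index, hit)
    return np.flatnonzero(within)


class AdaptiveRegionTerm(PotentialModel):
    """A region term whose particle set is reselected during simulation.

    ``model_factory`` maps the selected global indices to a potential for
    that subset (models are topology-bound).  Selection is refreshed every
    ``update_every`` evaluations; per-evaluation by default.
    """

    def __init__(self, model_factory: Callable[[np.ndarray], PotentialModel],
                 spec: RegionSpec, topology: ParticleSystem):
        if spec.mode != "adaptive":
            raise ValueError("AdaptiveRegionTerm requires an adaptive spec")
        if len(spec.center_particles) == 0:
            raise ValueError("centers must be non-empty")
        self.model_factory = model_factory
        self.spec = spec
        self.residue_index = topology.residue_index.copy()
        self.n_total = topology.n_particles
        self._calls = 0
        self._term: RegionTerm | None = None
        self.current_selection: np.ndarray | None = None

    def _compute(self, pos, box):
        if self._term is None or self._calls % self.spec.update_every == 0:
            sel = select_adaptive_region(
                pos, box, self.spec.center_particles, self.spec.radius,
                self.spec.extend_residues, self.residue_index)
            self.current_selection = sel
            self._term = RegionTerm(self.model_factory(sel), sel, self.n_total)
        self._calls += 1
        return self._term.evaluate(pos, box)


class ExclusionTerm(PotentialModel):
    """A classical term with its intra-region interactions removed.

    Implemented by subtracting the classical model restricted to the
    region, so cross-boundary interactions are untouched by construction.
    """

    def __init__(self, full_term: FullSystemTerm, region: Sequence[int]):
        model = full_term.model
        if not hasattr(model, "subset"):
            raise TypeError("classical model does not support region "
                            "exclusions (no .subset method)")
        self.full_term = full_term
        self.region = np.asarray(sorted(set(int(i) for i in region)))
        self._intra = RegionTerm(model.subset(self.region), self.region,
                                 full_term.n_particles, sign=-1.0)

    @property
    def cutoff(self):
        return self.full_term.cutoff

    @cutoff.setter
    def cutoff(self, value):  # pragma: no cover
        pass

    def _compute(self, pos, box):
        e1, f1 = self.full_term.evaluate(pos, box)
        e2, f2 = self._intra.evaluate(pos, box)
        return e1 + e2, f1 + f2


@dataclass
class CompositeForceField(PotentialModel):
    """Ordered sum of force terms spanning classical and plugged models."""

    terms: list[PotentialModel] = field(default_factory=list)

    def add(self, term: PotentialModel) -> "CompositeForceField":
        self.terms.append(term)
        return self

    def _compute(self, pos, box):
        energy = 0.0
        forces = np.zeros_like(pos)
        for term in self.terms:
            e, f = term.evaluate(pos, box)
            energy += e
            forces += f
        return energy, forces


def apply_region_exclusions(forcefield: CompositeForceField,
                            region: Sequence[int],
                            policy: str = "drop_intra"
                            ) -> CompositeForceField:
    """Drop classical interactions fully inside the ML region.

    With ``policy='drop_intra'`` every full-system classical term (a term
    whose model exposes ``subset``) has its intra-region contribution
    removed; any other policy, or an empty region, returns the composite
    unchanged.
    """
    if policy not in ("drop_intra", "keep_all"):
        raise ValueError(f"unknown exclusion policy {policy!r}")
    region = list(region)
    if policy == "keep_all" or len(region) == 0:
        return forcefield
    new_terms: list[PotentialModel] = []
    for term in forcefield.terms:
        if isinstance(term, FullSystemTerm) and hasattr(term.model, "subset"):
            new_terms.append(ExclusionTerm(term, region))
        else:
            new_terms.append(term)
    return CompositeForceField(new_terms)
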