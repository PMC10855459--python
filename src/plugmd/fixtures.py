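"""Seed-deterministic synthetic fixtures.

These presets generate, at run time, the small systems and sample sets
that the validation instruments are exercised on: surrogate water boxes,
harmonic toys, ideal-gas frames, Brownian trajectories and
Gamma-distributed canonical energy samples (the exact potential-energy law
of a harmonic system, E ~ Gamma(n_dof/2, k_B T)).
"""

from __future__ import annotations

import numpy as np

from .constants import KB
from .integrators import Trajectory, integrate_nvt, maxwell_boltzmann_velocities
from .potentials.water import FlexibleWaterPotential
from .system import ParticleSystem, build_water_box

__all__ = [
    "water_box", "equilibrated_water_box", "harmonic_toy_system",
    "ideal_gas_frames", "brownian_trajectory", "gamma_energy_samples",
]


def water_box(n_molecules: int = 64, box_edge: float | None = None,
              density: float | None = None, seed: int = 1) -> ParticleSystem:
    """Surrogate water box; defaults to liquid density when no size given."""
    if box_edge is None and density is None:
        density = 0.987
    return build_water_box(n_molecules, box_edge=box_edge, density=density,
                           seed=seed)


def equilibrated_water_box(n_molecules: int = 64, seed: int = 1,
                           T: float = 300.0, equil_ps: float = 1.0,
                           dt: float = 2e-4, cutoff: float = 0.6,
                           ) -> tuple[ParticleSystem, FlexibleWaterPotential]:
    """Water box relaxed by a short Langevin run at temperature T.

    Returns the equilibrated system together with the potential used, so
    callers continue with a consistent model.
    """
    system = water_box(n_molecules, seed=seed)
    model = FlexibleWaterPotential.for_system(system, cutoff=cutoff)
    rng = np.random.default_rng(seed)
    system.velocities = maxwell_boltzmann_velocities(system.masses, T, rng)
    n_steps = max(1, int(round(equil_ps / dt)))
    integrate_nvt(system, model, dt, n_steps, thermostat="langevin", T=T,
                  coupling=5.0, seed=seed, save_every=n_steps,
                  record_every=n_steps)
    return system, model


def harmonic_toy_system(n_particles: int = 1, mass: float = 18.0,
                        T: float | None = None, seed: int = 0
                        ) -> ParticleSystem:
    """Particles at the origin of harmonic wells, optionally thermalised."""
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_particles, 3))
    masses = np.full(n_particles, mass)
    vel = (maxwell_boltzmann_velocities(masses, T, rng, remove_com=False)
           if T else np.zeros_like(pos))
    return ParticleSystem(pos, vel, masses, ["Ar"] * n_particles,
                          np.arange(n_particles), ["TOY"] * n_particles,
                          box=np.zeros(3))


def ideal_gas_frames(n_frames: int = 500, n_particles: int = 100,
                     box_edge: float = 2.0, seed: int = 0) -> Trajectory:
    """Uncorrelated uniform-random configurations (ideal gas, g(r) = 1)."""
    rng = np.random.default_rng(seed)
    traj = Trajectory(box=np.full(3, float(box_edge)),
                      element_types=["Ar"] * n_particles)
    for f in range(n_frames):
        traj.append(float(f), rng.uniform(0, box_edge, size=(n_particles, 3)))
    return traj


def brownian_trajectory(n_steps: int = 2000, dt: float = 1.0,
                        D: float = 0.005, n_particles: int = 50,
                        seed: int = 0) -> Trajectory:
    """Random walk with per-dimension step variance 2 D dt (D in nm^2/ps)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2 * D * dt),
                       size=(n_steps, n_particles, 3))
    pos = np.concatenate([np.zeros((1, n_particles, 3)),
                          np.cumsum(steps, axis=0)])
    traj = Trajectory(box=np.full(3, 1e6),
                      element_types=["Ar"] * n_particles)
    for f in range(n_steps + 1):
        traj.append(f * dt, pos[f])
    return traj


def gamma_energy_samples(n_samples: int, n_dof: int, T: float,
                         seed: int = 0) -> np.ndarray:
    """Canonical potential-energy samples of a harmonic system, kJ/mol."""
    rng = np.random.default_rng(seed)
    return rng.gamma(shape=n_dof / 2.0, scale=KB * T, size=n_samples)
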