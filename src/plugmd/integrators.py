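"""NVE and thermostatted NVT integrators.

All integrators use velocity-Verlet cores with a 0.2 fs-scale time step in
mind, mutate the passed :class:`~plugmd.system.ParticleSystem` in place and
return a trajectory plus an energy log.  Positions are never wrapped back
into the box -- periodicity is handled by minimum-image in the potentials
-- so the recorded coordinates are continuous (unwrapped) and can be fed
directly to mean-squared-displacement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .potentials.base import PotentialModel
from .system import ParticleSystem

__all__ = [
    "EnergyRecord", "Trajectory", "IntegrationBlowUp",
    "maxwell_boltzmann_velocities", "integrate_nve", "integrate_nvt",
    "THERMOSTATS",
]

THERMOSTATS = ("andersen", "langevin", "nose_hoover")


class IntegrationBlowUp(RuntimeError):
    """Non-finite energy encountered during integration."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"non-finite energy at step {step}")


@dataclass
class EnergyRecord:
    """One row of the energy log (kJ/mol, K)."""
    step: int
    time_ps: float
    potential: float
    kinetic: float
    total: float
    temperature: float


@dataclass
class Trajectory:
    """Ordered frames of (time, positions) in a constant box."""
    times: list[float] = field(default_factory=list)
    frames: list[np.ndarray] = field(default_factory=list)
    box: np.ndarray | None = None
    element_types: list[str] | None = None
    save_interval_ps: float | None = None

    def append(self, time: float, positions: np.ndarray) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("trajectory times must increase monotonically")
        if self.frames and positions.shape != self.frames[0].shape:
            raise ValueError("frame particle count changed")
        self.times.append(float(time))
        self.frames.append(np.array(positions, dtype=float))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinates."""
        return np.stack(self.frames)


def maxwell_boltzmann_velocities(masses: np.ndarray, T: float,
                                 rng: np.random.Generator,
                                 remove_com: bool = True) -> np.ndarray:
    """Draw velocities (nm/ps) from the Maxwell-Boltzmann distribution."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * T / masses)
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    if remove_com:
        v -= np.sum(masses[:, None] * v, axis=0) / np.sum(masses)
    return v


def _box_or_none(system: ParticleSystem):
    return system.box if np.all(system.box > 0) else None


def _record(records, step, t, pot, kin, n_dof):
    total = pot + kin
    if not np.isfinite(total):
        raise IntegrationBlowUp(step)
    records.append(EnergyRecord(step, t, pot, kin, total,
                                2.0 * kin / (n_dof * KB)))


def integrate_nve(system: ParticleSystem, model: PotentialModel, dt: float,
                  n_steps: int, save_every: int = 100,
                  record_every: int = 1, time_offset: float = 0.0,
                  ) -> tuple[Trajectory, list[EnergyRecord]]:
    """Velocity-Verlet microcanonical propagation.

    ``dt`` in ps; deterministic given inputs.  Energies are logged every
    ``record_every`` steps and frames saved every ``save_every`` steps
    (step 0 included in both).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    box = _box_or_none(system)
    n_dof = system.n_dof()
    inv_m = 1.0 / system.masses[:, None]
    traj = Trajectory(box=None if box is None else box.copy(),
                      element_types=list(system.element_types),
                      save_interval_ps=save_every * dt)
    records: list[EnergyRecord] = []

    pot, forces = model.evaluate(system.positions, box)
    _record(records, 0, time_offset, pot, system.kinetic_energy(), n_dof)
    traj.append(time_offset if time_offset else 0.0, system.positions)
    v, x = system.velocities, system.positions
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * forces * inv_m
        x += dt * v
        pot, forces = model.evaluate(x, box)
        v += 0.5 * dt * forces * inv_m
        if step % record_every == 0 or step == n_steps:
            _record(records, step, time_offset + step * dt, pot,
                    system.kinetic_energy(), n_dof)
        if step % save_every == 0:
            traj.append(time_offset + step * dt, x)
    return traj, records


def integrate_nvt(system: ParticleSystem, model: PotentialModel, dt: float,
                  n_steps: int, thermostat: str = "langevin",
                  T: float = 300.0, coupling: float = 1.0,
                  seed: int = 0, save_every: int = 100,
                  record_every: int = 1, time_offset: float = 0.0,
                  ) -> tuple[Trajectory, list[EnergyRecord]]:
    """Thermostatted (canonical) propagation.

    Parameters
    ----------
    thermostat
        ``langevin`` (BAOAB), ``andersen`` (collision frequency =
        ``coupling``) or ``nose_hoover`` (single chain, time constant
        ``1/coupling``).
    coupling
        ps^-1; friction (Langevin), collision rate (Andersen) or inverse
        time constant (Nose-Hoover).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T <= 0 or coupling < 0:
        raise ValueError("T must be positive and coupling non-negative")
    if thermostat not in THERMOSTATS:
        raise ValueError(f"unknown thermostat {thermostat!r}; "
                         f"choose from {THERMOSTATS}")
    rng = np.random.default_rng(seed)
    box = _box_or_none(system)
    n_dof = system.n_dof()
    m = system.masses[:, None]
    inv_m = 1.0 / m
    traj = Trajectory(box=None if box is None else box.copy(),
                      element_types=list(system.element_types),
                      save_interval_ps=save_every * dt)
    records: list[EnergyRecord] = []

    # thermostat-specific precomputation
    if thermostat == "langevin":
        c1 = np.exp(-coupling * dt)
        c2 = np.sqrt(KB * T * (1.0 - c1**2)) / np.sqrt(system.masses)[:, None]
    elif thermostat == "andersen":
        p_collide = 1.0 - np.exp(-coupling * dt)
        sigma_v = np.sqrt(KB * T / system.masses)[:, None]
    else:  # nose_hoover
        tau = 1.0 / coupling
        Q = n_dof * KB * T * tau**2
        v_xi = 0.0

    pot, forces = model.evaluate(system.positions, box)
    _record(records, 0, time_offset, pot, system.kinetic_energy(), n_dof)
    traj.append(time_offset if time_offset else 0.0, system.positions)
    v, x = system.velocities, system.positions

    def nh_half():
        nonlocal v_xi
        ke = 0.5 * np.sum(m * v * v)
        v_xi += 0.25 * dt * (2.0 * ke - n_dof * KB * T) / Q
        scale = np.exp(-0.5 * dt * v_xi)
        v[:] *= scale
        ke *= scale**2
        v_xi += 0.25 * dt * (2.0 * ke - n_dof * KB * T) / Q

    for step in range(1, n_steps + 1):
        if thermostat == "langevin":
            v += 0.5 * dt * forces * inv_m
            x += 0.5 * dt * v
            v *= c1
            v += c2 * rng.standard_normal(v.shape)
            x += 0.5 * dt * v
            pot, forces = model.evaluate(x, box)
            v += 0.5 * dt * forces * inv_m
        elif thermostat == "andersen":
            v += 0.5 * dt * forces * inv_m
            x += dt * v
            pot, forces = model.evaluate(x, box)
            v += 0.5 * dt * forces * inv_m
            hit = rng.random(len(v)) < p_collide
            if np.any(hit):
                v[hit] = sigma_v[hit] * rng.standard_normal((int(hit.sum()), 3))
        else:  # nose_hoover
            nh_half()
            v += 0.5 * dt * forces * inv_m
            x += dt * v
            pot, forces = model.evaluate(x, box)
            v += 0.5 * dt * forces * inv_m
            nh_half()
        if step % record_every == 0 or step == n_steps:
            _record(records, step, time_offset + step * dt, pot,
                    system.kinetic_energy(), n_dof)
        if step % save_every == 0:
            traj.append(time_offset + step * dt, x)
    return traj, records
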