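"""Particle systems, periodic geometry and water-box construction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, KB, WATER_MOLAR_MASS

__all__ = [
    "ParticleSystem",
    "PackingError",
    "minimum_image",
    "build_water_box",
    "WATER_GEOMETRY",
]

#: Equilibrium geometry of the flexible water monomer used by the box builder
#: (bond length nm, bond angle rad).  Matches the SPC/Fw-style surrogate
#: force field defaults.
WATER_GEOMETRY = {"r_oh": 0.1012, "theta_hoh": np.deg2rad(113.24)}

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
                  "P": 30.974, "Zn": 65.38, "Na": 22.990, "Cl": 35.45, "Ar": 39.948}


class PackingError(RuntimeError):
    """Raised when a requested box cannot be packed at the target density."""


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s).

    Parameters
    ----------
    delta
        Displacement(s), shape (..., 3), nm.
    box
        Orthorhombic box edge lengths, shape (3,), nm.

    Returns
    -------
    Wrapped displacement(s) with every component in [-edge/2, edge/2).
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.floor(delta / box + 0.5)


@dataclass
class ParticleSystem:
    """State of an N-particle system in an orthorhombic periodic box.

    positions/velocities are (N, 3) arrays in nm and nm/ps, masses amu,
    ``residue_index`` partitions particles into contiguous groups (one group
    per molecule for water boxes).
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    element_types: list[str]
    residue_index: np.ndarray
    residue_name: list[str]
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if n < 1:
            raise ValueError("system must contain at least one particle")
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(n)
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        self.residue_index = np.asarray(self.residue_index, dtype=int).reshape(n)
        self.element_types = list(self.element_types)
        self.residue_name = list(self.residue_name)
        if len(self.element_types) != n or len(self.residue_name) != n:
            raise ValueError("per-particle metadata length mismatch")
        self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def n_dof(self, remove_com: bool = False) -> int:
        """Degrees of freedom: 3N, minus 3 when COM motion is projected out."""
        return 3 * self.n_particles - (3 if remove_com else 0)

    def kinetic_energy(self) -> float:
        """kJ/mol."""
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))

    def temperature(self, n_dof: int | None = None) -> float:
        """Instantaneous kinetic temperature, K."""
        if n_dof is None:
            n_dof = self.n_dof()
        return 2.0 * self.kinetic_energy() / (n_dof * KB)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            list(self.element_types), self.residue_index.copy(),
            list(self.residue_name), self.box.copy())


def _water_template() -> np.ndarray:
    """One water molecule (O, H, H) centred on the oxygen, nm."""
    r = WATER_GEOMETRY["r_oh"]
    th = WATER_GEOMETRY["theta_hoh"]
    h1 = np.array([r * np.sin(th / 2), r * np.cos(th / 2), 0.0])
    h2 = np.array([-r * np.sin(th / 2), r * np.cos(th / 2), 0.0])
    return np.vstack([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_water_box(
    n_molecules: int,
    box_edge: float | None = None,
    density: float | None = None,
    seed: int = 0,
    jitter: float = 0.01,
    min_oo_distance: float = 0.24,
) -> ParticleSystem:
    """Build a periodic box of rigid-geometry water molecules.

    Molecules are placed on a perturbed simple-cubic lattice (jitter in nm)
    with random orientations; this guarantees packing success at liquid
    density.  Exactly one of ``box_edge`` (nm) or ``density`` (g/mL) must be
    given.  Deterministic for fixed ``seed``.

    Raises
    ------
    PackingError
        If the requested density leaves lattice sites closer than the
        ``min_oo_distance`` contact limit.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if (box_edge is None) == (density is None):
        raise ValueError("give exactly one of box_edge or density")
    if box_edge is None:
        # edge [cm] from mass/density, then cm -> nm
        volume_cm3 = n_molecules * WATER_MOLAR_MASS / (AVOGADRO * density)
        box_edge = volume_cm3 ** (1.0 / 3.0) * 1e7
    box = np.full(3, float(box_edge))

    n_cells = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = box_edge / n_cells
    if spacing - 2 * jitter < min_oo_distance:
        raise PackingError(
            f"lattice spacing {spacing:.3f} nm (jitter {jitter}) violates the "
            f"{min_oo_distance} nm O-O contact limit; density too high")

    rng = np.random.default_rng(seed)
    template = _water_template()
    sites = [(i, j, k) for i in range(n_cells) for j in range(n_cells)
             for k in range(n_cells)][:n_molecules]

    positions = np.empty((3 * n_molecules, 3))
    for m, (i, j, k) in enumerate(sites):
        centre = (np.array([i, j, k]) + 0.5) * spacing
        centre += rng.uniform(-jitter, jitter, size=3)
        rot = _random_rotation(rng)
        positions[3 * m:3 * m + 3] = centre + template @ rot.T

    elements = ["O", "H", "H"] * n_molecules
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    residue_index = np.repeat(np.arange(n_molecules), 3)
    return ParticleSystem(
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=masses,
        element_types=elements,
        residue_index=residue_index,
        residue_name=["HOH"] * (3 * n_molecules),
        box=box,
    )
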