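"""Minimal PDB topology reader (ATOM/HETATM records only).

Coordinates are converted from Angstrom to nm; residue indices are
renumbered contiguously from 0 in order of first appearance (chain +
residue sequence number).  CONECT and other record types are ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from ..system import ELEMENT_MASSES, ParticleSystem

__all__ = ["read_minimal_pdb", "PDBParseError"]


class PDBParseError(ValueError):
    pass


def _infer_element(atom_name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().capitalize()
    name = atom_name.strip()
    warnings.warn(f"element column empty; inferring from atom name {name!r}")
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ELEMENT_MASSES:
        return stripped[:2].capitalize()
    if stripped and stripped[0].upper() in ELEMENT_MASSES:
        return stripped[0].upper()
    raise PDBParseError(f"cannot infer element for atom {name!r}")


def read_minimal_pdb(path) -> ParticleSystem:
    positions, elements, res_names = [], [], []
    res_keys: list = []
    res_index = []
    for line in Path(path).read_text().splitlines():
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        x = float(line[30:38]) * 0.1
        y = float(line[38:46]) * 0.1
        z = float(line[46:54]) * 0.1
        atom_name = line[12:16]
        res_name = line[17:20].strip() or "UNK"
        chain = line[21:22]
        res_seq = line[22:26].strip()
        element_field = line[76:78] if len(line) >= 78 else ""
        elem = _infer_element(atom_name, element_field)
        key = (chain, res_seq, res_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        positions.append([x, y, z])
        elements.append(elem)
        res_names.append(res_name)
        res_index.append(len(res_keys) - 1)
    if not positions:
        raise PDBParseError("no ATOM/HETATM records found")
    positions = np.asarray(positions)
    masses = np.array([ELEMENT_MASSES.get(e, 12.0) for e in elements])
    return ParticleSystem(
        positions=positions, velocities=np.zeros_like(positions),
        masses=masses, element_types=elements,
        residue_index=np.asarray(res_index), residue_name=res_names,
        box=np.zeros(3))
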