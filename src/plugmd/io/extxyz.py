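"""Extended-XYZ trajectory reading and writing.

Frames carry ``Lattice="ax 0 0 0 by 0 0 0 cz"`` (orthorhombic, nm) and
``Properties=species:S:1:pos:R:3`` plus a ``Time=`` key in ps.  Round
trips preserve coordinates to better than 1e-8 nm.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from ..integrators import Trajectory

__all__ = ["write_extxyz", "read_extxyz", "ExtXYZParseError"]


class ExtXYZParseError(ValueError):
    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


def write_extxyz(trajectory: Trajectory, path) -> None:
    box = trajectory.box
    elements = trajectory.element_types
    with open(path, "w") as fh:
        for time, frame in zip(trajectory.times, trajectory.frames):
            n = len(frame)
            fh.write(f"{n}\n")
            lat = ""
            if box is not None:
                lat = (f'Lattice="{box[0]:.10g} 0 0 0 {box[1]:.10g} 0 '
                       f'0 0 {box[2]:.10g}" ')
            fh.write(f'{lat}Properties=species:S:1:pos:R:3 Time={time:.10g}\n')
            for i in range(n):
                sp = elements[i] if elements else "X"
                fh.write(f"{sp} {frame[i, 0]:.10f} {frame[i, 1]:.10f} "
                         f"{frame[i, 2]:.10f}\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([0-9eE.+-]+)")


def read_extxyz(path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    traj = Trajectory()
    elements: list[str] | None = None
    ln = 0
    frame_index = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ExtXYZParseError(ln + 1, "expected an atom count")
        if ln + 1 >= len(lines):
            raise ExtXYZParseError(ln + 2, "missing comment line")
        comment = lines[ln + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise ExtXYZParseError(ln + 2, "missing Lattice= specification")
        cell = np.array([float(x) for x in m.group(1).split()])
        if len(cell) != 9:
            raise ExtXYZParseError(ln + 2, "Lattice must have 9 components")
        box = cell.reshape(3, 3).diagonal().copy()
        if "Properties=" not in comment:
            raise ExtXYZParseError(ln + 2, "missing Properties= specification")
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(frame_index)

        frame = np.empty((n, 3))
        species = []
        for i in range(n):
            row = ln + 2 + i
            if row >= len(lines):
                raise ExtXYZParseError(row + 1, "truncated frame")
            parts = lines[row].split()
            if len(parts) < 4:
                raise ExtXYZParseError(row + 1, "expected species + 3 coords")
            species.append(parts[0])
            frame[i] = [float(x) for x in parts[1:4]]
        if elements is None:
            elements = species
            traj.element_types = elements
            traj.box = box
        traj.append(time, frame)
        ln += 2 + n
        frame_index += 1
    return traj
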