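"""CSV energy logs with the canonical header
``step,time_ps,potential_kjmol,kinetic_kjmol,total_kjmol,temperature_K``."""

from __future__ import annotations

import pandas as pd

from ..integrators import EnergyRecord

__all__ = ["write_energy_log", "read_energy_log", "records_to_frame"]

COLUMNS = ["step", "time_ps", "potential_kjmol", "kinetic_kjmol",
           "total_kjmol", "temperature_K"]


def records_to_frame(records: list[EnergyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.step, r.time_ps, r.potential, r.kinetic, r.total, r.temperature)
         for r in records], columns=COLUMNS)


def write_energy_log(records: list[EnergyRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_energy_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"energy log missing columns: {sorted(missing)}")
    return df
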