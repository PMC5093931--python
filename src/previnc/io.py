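"""Delimited-text serialization for schedules, trajectories and tables.

All interchange formats are plain CSV: hazard schedules with columns
``age,i,r,f,m``; trajectories additionally ``S,C,p,M``; grouped rate
tables with ``age_low,age_high,rate,se,count,denominator`` (open-ended
top band written as ``age_high=plus``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .hazards import HazardSchedule, StateTrajectory, csmr_from_trajectory
from .preprocess import GroupedRateTable

__all__ = [
    "read_hazard_schedule",
    "write_hazard_schedule",
    "write_trajectory",
    "read_grouped_table",
    "write_grouped_table",
]


def write_hazard_schedule(hazards: HazardSchedule, path: str | Path) -> None:
    hazards.to_frame().to_csv(path, index=False)


def read_hazard_schedule(path: str | Path) -> HazardSchedule:
    return HazardSchedule.from_frame(pd.read_csv(path))


def write_trajectory(
    traj: StateTrajectory, hazards: HazardSchedule, path: str | Path
) -> None:
    df = traj.to_frame(hazards)
    df["M"] = csmr_from_trajectory(traj, hazards)
    df.to_csv(path, index=False)


def read_grouped_table(path: str | Path) -> GroupedRateTable:
    return GroupedRateTable.from_csv(path)


def write_grouped_table(table: GroupedRateTable, path: str | Path) -> None:
    table.to_csv(path)
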