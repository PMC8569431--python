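"""Tidy table readers/writers for the pipeline's on-disk interfaces.

All tables are tab-separated with a header row, UTF-8, '.' decimal point
and empty string as the NA marker, so outputs are locale-independent and
diffable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_tsv",
    "read_tsv",
    "trajectories_to_frame",
    "events_to_frame",
    "read_growth_assay",
]


def write_tsv(frame: pd.DataFrame, path, *, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, na_rep="")
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def trajectories_to_frame(trajectories: dict) -> pd.DataFrame:
    """Long-format sample table for a set of culture trajectories."""
    parts = [t.to_frame() for t in trajectories.values()]
    if not parts:
        return pd.DataFrame(
            columns=["culture_id", "cycle", "time_min", "od830", "temperature_C", "event"]
        )
    return pd.concat(parts, ignore_index=True)


def events_to_frame(trajectories: dict) -> pd.DataFrame:
    """Switch and transfer events of a set of trajectories, one row each."""
    rows = []
    for cid, traj in trajectories.items():
        rows.extend(
            {"culture_id": cid, "time_min": t, "event": "switch"} for t in traj.switch_events
        )
        rows.extend(
            {"culture_id": cid, "time_min": t, "event": "transfer"} for t in traj.transfer_events
        )
    return pd.DataFrame(rows, columns=["culture_id", "time_min", "event"]).sort_values(
        ["culture_id", "time_min"], ignore_index=True
    )


def read_growth_assay(path) -> pd.DataFrame:
    """Read a tidy growth-assay table or a wide one (time + OD per replicate).

    Tidy input needs columns ``strain_id, replicate, time_min, od830``;
    wide input needs ``time_min`` plus one OD column per replicate named
    ``<strain_id>.<replicate>``.
    """
    df = read_tsv(path)
    if {"strain_id", "replicate", "time_min", "od830"}.issubset(df.columns):
        return df
    if "time_min" not in df.columns:
        raise ValueError("growth assay table needs a time_min column")
    long_rows = []
    for col in df.columns:
        if col == "time_min":
            continue
        strain, _, rep = col.rpartition(".")
        if not strain:
            strain, rep = col, "1"
        long_rows.append(
            pd.DataFrame(
                {
                    "strain_id": strain,
                    "replicate": int(rep),
                    "time_min": df["time_min"],
                    "od830": df[col],
                }
            )
        )
    return pd.concat(long_rows, ignore_index=True)
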