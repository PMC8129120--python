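"""CSV serialization of the pipeline's exchange tables.

All tables are UTF-8 CSV with a header row.  Missing intensities for absent
spines are written as empty fields and read back as NaN.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SPINE_COLUMNS = [
    "mouse_id",
    "condition",
    "dendrite_id",
    "spine_id",
    "timepoint",
    "spine_sep",
    "spine_dsred",
    "shaft_sep",
    "shaft_dsred",
    "present",
]

PERF_COLUMNS = ["mouse_id", "condition", "session", "trial", "fall_speed"]


def write_spine_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=SPINE_COLUMNS)


def read_spine_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "mouse_id": str,
            "condition": str,
            "dendrite_id": str,
            "spine_id": str,
            "timepoint": str,
        },
    )
    missing = set(SPINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spine table missing columns: {sorted(missing)}")
    if df["present"].dtype != bool:
        df["present"] = (
            df["present"].astype(str).str.strip().str.lower().isin(["true", "1"])
        )
    return df


def write_performance_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=PERF_COLUMNS)


def read_performance_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mouse_id": str, "condition": str})
    missing = set(PERF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"performance table missing columns: {sorted(missing)}")
    return df
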