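"""Long-format network-measure tables (MeasureTable).

One row per observation: subject, condition, band, measure ("T" or "E"),
value. Values must be strictly positive to enter the log-normal model.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

COLUMNS = ["subject", "condition", "band", "measure", "value"]


def validate_measure_table(
    table: pd.DataFrame, require_positive: bool = True
) -> pd.DataFrame:
    """Check the MeasureTable contract; returns the table (copy, typed)."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measure table missing columns: {missing}")
    out = table[COLUMNS].copy()
    out["value"] = out["value"].astype(float)
    if out["value"].isna().any():
        bad = out.index[out["value"].isna()].tolist()
        raise ValueError(f"non-finite measure values at rows {bad}")
    if require_positive and (out["value"] <= 0).any():
        bad = out.index[out["value"] <= 0].tolist()
        raise ValueError(
            f"non-positive values at rows {bad}: the log-normal likelihood "
            "requires strictly positive measures"
        )
    return out


def write_measure_table(path: str | Path, table: pd.DataFrame) -> None:
    table[COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_measure_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_measure_table(table, require_positive=False)
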