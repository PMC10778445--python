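"""CSV input/output.

Two input schemas, both headered UTF-8 CSV with '.' decimals:

* trials — one row per platform reading:
  ``dog_id, timepoint, trial_index, wb_lf, wb_rf, wb_lh, wb_rh``
* anchors — one row per dog:
  ``dog_id, anchor_t0, anchor_d15`` (verbal labels or codes 1-5)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

TRIALS_COLUMNS = [
    "dog_id",
    "timepoint",
    "trial_index",
    "wb_lf",
    "wb_rf",
    "wb_lh",
    "wb_rh",
]
ANCHORS_COLUMNS = ["dog_id", "anchor_t0", "anchor_d15"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} CSV missing columns: {', '.join(missing)}")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read and type-check a trials CSV (per-row range checks happen at
    aggregation time, where violations can name the trial)."""
    df = pd.read_csv(path, dtype={"dog_id": str, "timepoint": str})
    _require_columns(df, TRIALS_COLUMNS, "trials")
    try:
        df["trial_index"] = df["trial_index"].astype(int)
        for col in ("wb_lf", "wb_rf", "wb_lh", "wb_rh"):
            df[col] = df[col].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"trials CSV has non-numeric values: {exc}") from exc
    return df[TRIALS_COLUMNS]


def read_anchors_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dog_id": str})
    _require_columns(df, ANCHORS_COLUMNS, "anchors")
    return df[ANCHORS_COLUMNS]


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials[TRIALS_COLUMNS].to_csv(path, index=False)


def write_anchors_csv(anchors: pd.DataFrame, path: str | Path) -> None:
    anchors[ANCHORS_COLUMNS].to_csv(path, index=False)
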