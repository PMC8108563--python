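"""Trial-level CSV I/O and the results-report writer.

The trial CSV schema (UTF-8, header row) is::

    subject_id, group, age, sex, block, display_id, target_id,
    target_angle_deg, distractor1_angle_deg, distractor2_angle_deg,
    response_angle_deg, error_deg, delay_index, identification_correct

Angles are wrapped to (-180, 180] on read; mandatory fields that fail to
parse are reported with their row numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_angle

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "write_report",
           "validate_report"]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "block",
    "display_id",
    "target_id",
    "target_angle_deg",
    "distractor1_angle_deg",
    "distractor2_angle_deg",
    "response_angle_deg",
    "error_deg",
    "delay_index",
    "identification_correct",
]

_ANGLE_COLUMNS = [
    "target_angle_deg",
    "distractor1_angle_deg",
    "distractor2_angle_deg",
    "response_angle_deg",
    "error_deg",
]

_INT_COLUMNS = ["block", "display_id", "target_id", "delay_index"]


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-level CSV.

    Raises ``ValueError`` naming any missing column, and listing the row
    numbers (1-based, excluding the header) of rows with missing or
    unparseable mandatory values.  An empty file with a header yields an
    empty frame.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        return df[TRIAL_COLUMNS]

    bad_rows = set()
    for col in _ANGLE_COLUMNS + _INT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows.update((np.flatnonzero(coerced.isna()) + 1).tolist())
        df[col] = coerced
    for col in ("subject_id", "group"):
        bad_rows.update((np.flatnonzero(df[col].isna()) + 1).tolist())
    if bad_rows:
        rows = ", ".join(str(r) for r in sorted(bad_rows)[:20])
        raise ValueError(f"{path}: unparseable or missing values in row(s): {rows}")

    for col in _ANGLE_COLUMNS:
        df[col] = wrap_angle(df[col].to_numpy(dtype=float))
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(int)
    df["identification_correct"] = (
        df["identification_correct"].astype(str).str.lower().isin(("true", "1", "1.0"))
    )
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write trials in the documented column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trials table missing column(s): {', '.join(missing)}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


REPORT_REQUIRED_KEYS = ("seed", "settings", "cutoff", "group_fits",
                        "model_comparison", "permutation", "glm")


def validate_report(report: dict) -> None:
    """Structural check of a results report before serialization."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing section(s): {', '.join(missing)}")
    cutoff = report["cutoff"]
    if "rule" not in cutoff or "cutoff_deg" not in cutoff:
        raise ValueError("report cutoff section must record rule and cutoff_deg")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_report(report: dict, path) -> None:
    """Serialize a validated results report to JSON (sorted keys, so equal
    reports are byte-identical)."""
    validate_report(report)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_NumpyEncoder,
                  allow_nan=True)
        fh.write("\n")
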