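"""Session metadata and long-format feature tables.

A SessionTable records which sessions exist for which subject and which
inter-session interval each session belongs to (closed vocabulary:
baseline, same_day, 2wk, 4wk, 6wk — interval membership is assigned by
study design, never inferred from timestamps). A FeatureTable holds the
six spectral features per subject-session in long format, which joins
directly into the n-subjects x k-visits matrices reliability analysis
needs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "INTERVAL_LABELS",
    "validate_session_table",
    "read_session_table",
    "write_session_table",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
]

FEATURE_NAMES = ("rbp_delta", "rbp_theta", "rbp_alpha", "rbp_beta", "rbp_gamma", "ipf")
INTERVAL_LABELS = ("baseline", "same_day", "2wk", "4wk", "6wk")

_SESSION_COLS = ["subject_id", "session_id", "session_datetime", "interval_label"]
_FEATURE_COLS = ["subject_id", "session_id", "feature_name", "value"]

IPF_RANGE = (5.0, 14.0)


def validate_session_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_SESSION_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"session table missing columns: {sorted(missing)}")
    df = df[_SESSION_COLS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["session_id"] = df["session_id"].astype(str)
    bad = set(df["interval_label"]) - set(INTERVAL_LABELS)
    if bad:
        raise ValidationError(
            f"interval labels outside vocabulary {INTERVAL_LABELS}: {sorted(bad)}"
        )
    if df.duplicated(["subject_id", "session_id"]).any():
        dupes = df[df.duplicated(["subject_id", "session_id"], keep=False)]
        raise ValidationError(
            "duplicate (subject_id, session_id) rows: "
            + ", ".join(map(str, dupes[["subject_id", "session_id"]].values.tolist()))
        )
    return df


def read_session_table(path: str | Path) -> pd.DataFrame:
    return validate_session_table(pd.read_csv(path))


def write_session_table(df: pd.DataFrame, path: str | Path) -> Path:
    df = validate_session_table(df)
    df = df.sort_values(["subject_id", "session_id"], kind="stable")
    df.to_csv(path, index=False)
    return Path(path)


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format feature-table invariants.

    Relative band powers must lie in [0, 1], the individual peak frequency
    inside its 5-14 Hz search window, and each (subject, session, feature)
    may appear only once.
    """
    missing = set(_FEATURE_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    df = df[_FEATURE_COLS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["session_id"] = df["session_id"].astype(str)
    bad_names = set(df["feature_name"]) - set(FEATURE_NAMES)
    if bad_names:
        raise ValidationError(f"unknown feature names: {sorted(bad_names)}")
    values = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("feature values must be finite")
    is_rbp = df["feature_name"].str.startswith("rbp_").to_numpy()
    rbp = values[is_rbp]
    if rbp.size and (rbp.min() < 0.0 or rbp.max() > 1.0):
        raise ValidationError("relative band power values must lie in [0, 1]")
    ipf = values[~is_rbp]
    if ipf.size and (ipf.min() < IPF_RANGE[0] or ipf.max() > IPF_RANGE[1]):
        raise ValidationError(f"ipf values must lie in {IPF_RANGE} Hz")
    if df.duplicated(["subject_id", "session_id", "feature_name"]).any():
        raise ValidationError("duplicate (subject, session, feature) rows")
    return df


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so write -> read -> write is bit-identical
    return validate_feature_table(pd.read_csv(path, float_precision="round_trip"))


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated feature table as CSV in deterministic row order."""
    df = validate_feature_table(df)
    order = {name: i for i, name in enumerate(FEATURE_NAMES)}
    df = df.assign(_ord=df["feature_name"].map(order)).sort_values(
        ["subject_id", "session_id", "_ord"], kind="stable"
    )
    df = df.drop(columns="_ord")
    # repr-precision floats so that read -> write round-trips bit-identically
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)
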