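"""Intraclass correlation ICC(A,1): estimation, confidence intervals and
reliability classification for test-retest designs.

Model
-----
Each measurement is y_ij = mu + r_i + c_j + e_ij for subject i = 1..n and
visit j = 1..k, with subjects and visits both random (two-way random
effects). Reliability of a *single* measurement under *absolute agreement*
is

    ICC(A,1) = sigma2_r / (sigma2_r + sigma2_c + sigma2_e),

estimated from the two-way ANOVA mean squares (McGraw & Wong single-rater
absolute-agreement form)

    ICC(A,1) = (BMS - EMS) / (BMS + (k-1) EMS + (k/n)(RMS - EMS))

where BMS, RMS and EMS are the between-subject, between-visit and residual
mean squares. Confidence intervals use the McGraw-Wong F-based
approximation with a Satterthwaite denominator df. Estimates can be
negative in finite samples; they are reported as computed and classify as
"poor". Classification bands: poor < 0.5 <= moderate < 0.75 <= good
< 0.9 <= excellent <= 1.

``formula="as-printed"`` switches the denominator's (k-1)EMS term to
(k+1)EMS, a variant kept only for auditing against sources that print it;
it does not correspond to the two-way ANOVA expectations.

The object interface follows the fitted-model convention:
``ICCReliability(values).fit()`` returns an :class:`ICCResults` carrying
the estimate, mean squares, interval and class, with a ``summary()``
table; :func:`reliability_table` maps the fit over every feature x
interval cell of a study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InsufficientDataError, ValidationError
from .tables import (
    FEATURE_NAMES,
    INTERVAL_LABELS,
    validate_feature_table,
    validate_session_table,
)

__all__ = [
    "MeanSquares",
    "ICCResults",
    "ICCReliability",
    "anova_mean_squares",
    "icc_a1",
    "icc_confidence_interval",
    "classify_reliability",
    "pair_sessions",
    "reliability_table",
]

_CLASS_EDGES = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


@dataclass(frozen=True)
class MeanSquares:
    """Two-way (subjects x visits, no replication) ANOVA mean squares."""

    bms: float  # between-subject, df n-1
    rms: float  # between-visit, df k-1
    ems: float  # residual, df (n-1)(k-1)
    wms: float  # within-subject, df n(k-1)
    n: int
    k: int
    degenerate: bool = False

    @property
    def df_subjects(self) -> int:
        return self.n - 1

    @property
    def df_visits(self) -> int:
        return self.k - 1

    @property
    def df_residual(self) -> int:
        return (self.n - 1) * (self.k - 1)


def _as_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("paired measurements must be an n x k matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"need n >= 2 subjects and k >= 2 visits, got {n} x {k}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("paired measurements must be complete and finite")
    return values


def anova_mean_squares(values: np.ndarray) -> MeanSquares:
    """Two-way decomposition of an n x k matrix without replication.

    Satisfies (n-1)BMS + (k-1)RMS + (n-1)(k-1)EMS = total sum of squares.
    A matrix with zero total variance returns all-zero mean squares
    flagged degenerate.
    """
    X = _as_matrix(values)
    n, k = X.shape
    grand = X.mean()
    ss_total = ((X - grand) ** 2).sum()
    ss_subjects = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_visits = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_resid = ss_total - ss_subjects - ss_visits
    bms = ss_subjects / (n - 1)
    rms = ss_visits / (k - 1)
    ems = max(ss_resid, 0.0) / ((n - 1) * (k - 1))
    wms = (ss_visits + max(ss_resid, 0.0)) / (n * (k - 1))
    degenerate = ss_total <= 0.0
    return MeanSquares(bms, rms, ems, wms, n, k, degenerate)


def icc_a1(ms: MeanSquares, formula: str = "mcgraw-wong") -> float:
    """Single-measure absolute-agreement ICC from the mean squares.

    ``formula="mcgraw-wong"`` (default) is the standard A,1 estimator;
    ``"as-printed"`` replaces (k-1)EMS with (k+1)EMS for auditing only.
    Returns NaN when the denominator is zero (flagged degenerate input).
    """
    n, k = ms.n, ms.k
    if formula == "mcgraw-wong":
        coef = k - 1
    elif formula == "as-printed":
        coef = k + 1
    else:
        raise ValidationError(f"unknown ICC formula variant: {formula!r}")
    denom = ms.bms + coef * ms.ems + (k / n) * (ms.rms - ms.ems)
    if denom == 0.0:
        return float("nan")
    return (ms.bms - ms.ems) / denom


def icc_confidence_interval(
    ms: MeanSquares, level: float = 0.95
) -> tuple[float, float]:
    """McGraw-Wong F-based interval for ICC(A,1).

    Uses the Satterthwaite degrees of freedom for the denominator mean
    square. Degenerate (zero-variance) input yields the uninformative
    interval (-1, 1).
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must lie in (0, 1)")
    if ms.degenerate:
        return (-1.0, 1.0)
    n, k = ms.n, ms.k
    est = icc_a1(ms)
    if not np.isfinite(est):
        return (-1.0, 1.0)
    alpha = 1.0 - level
    a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
    b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est)) if est < 1.0 else np.inf
    if not np.isfinite(a):
        return (1.0, 1.0)
    num = (a * ms.rms + b * ms.ems) ** 2
    den = (a * ms.rms) ** 2 / (k - 1.0) + (b * ms.ems) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    common = k * ms.rms + (k * n - k - n) * ms.ems
    lower = n * (ms.bms - f_l * ms.ems) / (f_l * common + n * ms.bms)
    upper = n * (f_u * ms.bms - ms.ems) / (common + n * f_u * ms.bms)
    # guard floating noise: the interval must bracket the estimate
    lower = min(lower, est)
    upper = min(max(upper, est), 1.0)
    return (float(lower), float(upper))


def classify_reliability(estimate: float) -> str:
    """Map an ICC estimate to poor / moderate / good / excellent.

    Thresholds 0.5, 0.75 and 0.9 are left-closed: 0.5 is moderate, 0.75
    good, 0.9 excellent. Estimates above 1 are invalid; negatives are
    poor.
    """
    if not np.isfinite(estimate):
        return "poor"
    if estimate > 1.0:
        raise ValidationError("ICC estimate cannot exceed 1")
    for edge, name in _CLASS_EDGES:
        if estimate < edge:
            return name
    return "excellent"


@dataclass
class ICCResults:
    """Fitted ICC(A,1) for one n x k measurement matrix."""

    estimate: float
    ci_low: float
    ci_high: float
    mean_squares: MeanSquares
    level: float
    feature_name: str | None = None
    interval_label: str | None = None
    formula: str = "mcgraw-wong"

    @property
    def n(self) -> int:
        return self.mean_squares.n

    @property
    def k(self) -> int:
        return self.mean_squares.k

    @property
    def reliability_class(self) -> str:
        return classify_reliability(self.estimate)

    def summary(self) -> str:
        ms = self.mean_squares
        lines = [
            "ICC(A,1) reliability — two-way random effects, absolute agreement, single measure",
            "=" * 78,
        ]
        if self.feature_name or self.interval_label:
            lines.append(
                f"feature: {self.feature_name or '-'}    interval: {self.interval_label or '-'}"
            )
        lines += [
            f"subjects (n): {ms.n}    visits (k): {ms.k}",
            f"ICC estimate: {self.estimate: .4f}   ({self.reliability_class})",
            f"{self.level:.0%} CI: [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            "-" * 78,
            f"mean squares   BMS {ms.bms:.6g} (df {ms.df_subjects})   "
            f"RMS {ms.rms:.6g} (df {ms.df_visits})   "
            f"EMS {ms.ems:.6g} (df {ms.df_residual})",
        ]
        if ms.degenerate:
            lines.append("note: zero total variance — estimate undefined")
        return "\n".join(lines)


class ICCReliability:
    """ICC(A,1) model for an n-subjects x k-visits measurement matrix.

    Parameters
    ----------
    values : array-like, shape (n, k)
        Complete paired measurements, one row per subject.
    subject_ids : sequence of str, optional
    feature_name, interval_label : str, optional
        Carried through to the results for labelling.
    """

    def __init__(
        self,
        values,
        subject_ids=None,
        feature_name: str | None = None,
        interval_label: str | None = None,
    ) -> None:
        self.values = _as_matrix(values)
        n = self.values.shape[0]
        if subject_ids is not None and len(subject_ids) != n:
            raise ValidationError("one subject_id per row required")
        self.subject_ids = tuple(subject_ids) if subject_ids is not None else None
        self.feature_name = feature_name
        self.interval_label = interval_label

    @classmethod
    def from_feature_table(
        cls,
        features: pd.DataFrame,
        sessions: pd.DataFrame,
        feature_name: str,
        interval_label: str,
    ) -> "ICCReliability":
        """Build the model from long-format feature and session tables."""
        paired = pair_sessions(features, sessions, interval_label)
        if feature_name not in paired:
            raise InsufficientDataError(
                f"feature {feature_name!r} absent for interval {interval_label!r}"
            )
        values, subject_ids = paired[feature_name]
        return cls(values, subject_ids, feature_name, interval_label)

    def fit(self, level: float = 0.95, formula: str = "mcgraw-wong") -> ICCResults:
        ms = anova_mean_squares(self.values)
        estimate = icc_a1(ms, formula=formula)
        ci_low, ci_high = icc_confidence_interval(ms, level=level)
        return ICCResults(
            estimate=float(estimate),
            ci_low=ci_low,
            ci_high=ci_high,
            mean_squares=ms,
            level=level,
            feature_name=self.feature_name,
            interval_label=self.interval_label,
            formula=formula,
        )


def pair_sessions(
    features: pd.DataFrame,
    sessions: pd.DataFrame,
    interval_label: str,
) -> dict[str, tuple[np.ndarray, tuple[str, ...]]]:
    """Assemble complete n x 2 matrices for one inter-session interval.

    A subject contributes the pair (baseline visit, interval visit); for
    ``interval_label="baseline"`` the subject's baseline is paired with
    itself only if two baseline sessions exist (not the designed case).
    Subjects lacking either visit are dropped (listwise completion).
    Returns {feature_name: (values, subject_ids)}.
    """
    features = validate_feature_table(features)
    sessions = validate_session_table(sessions)
    if interval_label not in INTERVAL_LABELS:
        raise ValidationError(f"unknown interval label {interval_label!r}")
    merged = features.merge(sessions, on=["subject_id", "session_id"], how="inner")
    out: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
    for feature_name, grp in merged.groupby("feature_name", sort=False):
        rows = []
        ids = []
        for subject_id, sub in grp.groupby("subject_id", sort=True):
            if interval_label == "baseline":
                # only meaningful when a subject has two baseline sessions
                base = sub[sub["interval_label"] == "baseline"].sort_values("session_id")
                if len(base) == 2:
                    rows.append(base["value"].tolist())
                    ids.append(subject_id)
                continue
            first = sub[sub["interval_label"] == "baseline"]
            second = sub[sub["interval_label"] == interval_label]
            if len(first) == 1 and len(second) == 1:
                rows.append([first["value"].iloc[0], second["value"].iloc[0]])
                ids.append(subject_id)
        if len(rows) >= 2:
            out[str(feature_name)] = (np.array(rows, dtype=float), tuple(ids))
    if not out:
        raise InsufficientDataError(
            f"fewer than 2 subjects with complete (baseline, {interval_label}) pairs"
        )
    return out


def reliability_table(
    features: pd.DataFrame,
    sessions: pd.DataFrame,
    intervals: tuple[str, ...] = ("same_day", "2wk", "4wk", "6wk"),
    level: float = 0.95,
    formula: str = "mcgraw-wong",
) -> pd.DataFrame:
    """ICC(A,1) per feature x interval, long-format result table.

    Columns: feature, interval, estimate, ci_low, ci_high, n, k, class.
    Cells with fewer than 2 complete subjects are reported with NaN
    estimate and the reason. Raises InsufficientDataError when no cell is
    computable.
    """
    rows = []
    any_ok = False
    for interval in intervals:
        try:
            paired = pair_sessions(features, sessions, interval)
        except InsufficientDataError as exc:
            for feature_name in FEATURE_NAMES:
                rows.append(
                    dict(feature=feature_name, interval=interval, estimate=np.nan,
                         ci_low=np.nan, ci_high=np.nan, n=0, k=2,
                         reliability_class="", reason=str(exc))
                )
            continue
        for feature_name in FEATURE_NAMES:
            if feature_name not in paired:
                rows.append(
                    dict(feature=feature_name, interval=interval, estimate=np.nan,
                         ci_low=np.nan, ci_high=np.nan, n=0, k=2,
                         reliability_class="", reason="no complete pairs")
                )
                continue
            values, ids = paired[feature_name]
            res = ICCReliability(values, ids, feature_name, interval).fit(
                level=level, formula=formula
            )
            any_ok = True
            rows.append(
                dict(feature=feature_name, interval=interval,
                     estimate=res.estimate, ci_low=res.ci_low, ci_high=res.ci_high,
                     n=res.n, k=res.k, reliability_class=res.reliability_class,
                     reason="")
            )
    if not any_ok:
        raise InsufficientDataError("no feature x interval cell had enough data")
    return pd.DataFrame(rows)
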