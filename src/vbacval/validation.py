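"""External-validation statistics: decile calibration, Hosmer-Lemeshow
goodness of fit, and ROC/AUC discrimination.

Calibration follows the fixed-probability-decile procedure: predicted VBAC
probabilities (in percent) are binned into ten fixed ranges 0-10, 11-20, ...,
91-100, and the observed VBAC proportion is tabulated per bin with a binomial
confidence interval.  The bins are fixed probability ranges, *not*
equal-count deciles; an equal-count grouping is available for the
Hosmer-Lemeshow statistic, whose classic form uses it.

Discrimination is summarised by the ROC curve (sensitivity vs
1-specificity, positive class = VBAC, "predict VBAC when score >=
threshold") and its trapezoidal AUC, with a DeLong (default) or
Hanley-McNeil confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, DomainError
from .grobman import ScoreResult

__all__ = [
    "DECILE_LABELS",
    "PrevalenceResult",
    "CalibrationTable",
    "HLResult",
    "RocResult",
    "prevalence",
    "decile_bin",
    "decile_bins",
    "calibration_table",
    "hosmer_lemeshow",
    "roc_curve",
    "auc_with_ci",
    "predicted_summary",
]

DECILE_LABELS = (
    "0-10", "11-20", "21-30", "31-40", "41-50",
    "51-60", "61-70", "71-80", "81-90", "91-100",
)


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------

def _as_probabilities(scores) -> np.ndarray:
    """Accept ScoreResult sequences or raw probability arrays in (0,1)."""
    if len(scores) and isinstance(scores[0], ScoreResult):
        p = np.array([s.probability for s in scores], dtype=float)
    else:
        p = np.asarray(scores, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p >= 1) or not np.all(np.isfinite(p))):
        raise DomainError("predicted probabilities must lie in the open (0, 1)")
    return p


def _as_outcome_flags(outcomes) -> np.ndarray:
    """Coerce 'VBAC'/'ERCS' labels or 0/1 flags to a boolean success array."""
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "US":
        return arr == "VBAC"
    return arr.astype(bool)


# ---------------------------------------------------------------------------
# prevalence and summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceResult:
    percent: float
    numerator: int
    denominator: int


def prevalence(cohort: Cohort) -> PrevalenceResult:
    """Overall VBAC proportion of a cohort, in percent with exact fraction."""
    if len(cohort) == 0:
        raise DomainError("prevalence of an empty cohort is undefined")
    n_vbac = sum(1 for r in cohort.records if r.outcome == "VBAC")
    return PrevalenceResult(100.0 * n_vbac / len(cohort), n_vbac, len(cohort))


def predicted_summary(scores) -> tuple[float, float]:
    """Mean and sample SD of predicted probability, on the percent scale.

    A single score has no sample SD: returns ``(mean, nan)`` with a warning.
    """
    p = _as_probabilities(scores)
    if p.size == 0:
        raise DomainError("predicted_summary of an empty score list")
    pct = 100.0 * p
    if p.size == 1:
        warnings.warn("sample SD undefined for a single score", stacklevel=2)
        return float(pct[0]), float("nan")
    return float(pct.mean()), float(pct.std(ddof=1))


# ---------------------------------------------------------------------------
# decile binning and the calibration table
# ---------------------------------------------------------------------------

def decile_bin(probability_percent: float) -> int:
    """Fixed-decile bin index 1..10 of a probability in percent.

    Bin 1 covers [0, 10]; bin k>=2 covers (10(k-1), 10k], so a predicted
    10.0% falls in "0-10" and 10.0001% in "11-20" (the printed labels are
    read as half-open intervals on the continuous scale).
    """
    p = float(probability_percent)
    if not (0.0 <= p <= 100.0) or not np.isfinite(p):
        raise DomainError(f"probability percent {p!r} outside [0, 100]")
    if p <= 10.0:
        return 1
    return int(np.ceil(p / 10.0 - 1e-12))


def decile_bins(probability_percent) -> np.ndarray:
    """Vectorised :func:`decile_bin`."""
    p = np.asarray(probability_percent, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 100) or not np.all(np.isfinite(p))):
        raise DomainError("probability percent outside [0, 100]")
    bins = np.ceil(p / 10.0 - 1e-12).astype(int)
    return np.clip(bins, 1, 10)


def _wald_ci(successes: int, n: int, level: float) -> tuple[float, float]:
    # deliberately unclipped: mirrors out-of-range printed intervals
    p = successes / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


@dataclass
class CalibrationTable:
    """Per-decile calibration rows plus totals (the shape of a fixed-decile
    predicted-vs-observed table)."""

    rows: pd.DataFrame           # bin, label, n, attended_vb, observed, ci, mean_predicted
    total_n: int
    total_vbac: int
    ci_method: str

    def validate(self) -> None:
        r = self.rows
        if int(r["n"].sum()) != self.total_n:
            raise DomainError("calibration table: bin sizes do not sum to cohort size")
        if int(r["attended_vb"].sum()) != self.total_vbac:
            raise DomainError("calibration table: VBAC counts do not sum to total")
        if np.any(r["attended_vb"] > r["n"]) or np.any(r["attended_vb"] < 0):
            raise DomainError("calibration table: counts out of range")


def calibration_table(
    scores,
    outcomes,
    ci_method: Literal["wilson", "wald"] = "wilson",
    level: float = 0.95,
) -> CalibrationTable:
    """Fixed-decile calibration table of observed VBAC proportion.

    Empty bins are reported with ``n = 0`` and NaN observed probability / CI
    (printed as NA).  Wilson intervals are the default; Wald intervals are
    unbounded and may exceed [0, 100].
    """
    p = _as_probabilities(scores)
    y = _as_outcome_flags(outcomes)
    if p.shape != y.shape:
        raise DomainError(f"scores ({p.size}) and outcomes ({y.size}) differ in length")
    if ci_method not in ("wilson", "wald"):
        raise DomainError(f"unknown ci_method {ci_method!r}")
    bins = decile_bins(100.0 * p)
    rows = []
    for b in range(1, 11):
        mask = bins == b
        n = int(mask.sum())
        k = int(y[mask].sum())
        if n == 0:
            obs = lo = hi = mean_pred = float("nan")
        else:
            obs = 100.0 * k / n
            mean_pred = float(100.0 * p[mask].mean())
            if ci_method == "wilson":
                lo_, hi_ = proportion_confint(k, n, alpha=1 - level, method="wilson")
            else:
                lo_, hi_ = _wald_ci(k, n, level)
            lo, hi = 100.0 * lo_, 100.0 * hi_
        rows.append(
            {
                "bin": b,
                "label": DECILE_LABELS[b - 1],
                "n": n,
                "attended_vb": k,
                "observed_probability": obs,
                "ci_low": lo,
                "ci_high": hi,
                "mean_predicted": mean_pred,
            }
        )
    table = CalibrationTable(
        rows=pd.DataFrame(rows),
        total_n=int(p.size),
        total_vbac=int(y.sum()),
        ci_method=ci_method,
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow
# ---------------------------------------------------------------------------

@dataclass
class HLResult:
    """Hosmer-Lemeshow grouped chi-square for calibration.

    ``df_policy='development'`` uses G-2 degrees of freedom (the SPSS /
    model-development convention); ``'validation'`` uses G, the reference
    distribution appropriate when the predicted probabilities are fixed
    externally rather than fitted to the data at hand.
    """

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame          # per non-empty group: n, observed, expected, contribution
    binning: str
    df_policy: str


def hosmer_lemeshow(
    scores,
    outcomes,
    binning: Literal["fixed_deciles", "equal_size"] = "fixed_deciles",
    df_policy: Literal["development", "validation"] = "development",
    groups: int = 10,
) -> HLResult:
    """Hosmer-Lemeshow statistic over probability groups.

    statistic = sum_g (O_g - E_g)^2 / (E_g (1 - E_g/n_g)) over non-empty
    groups, with O_g the observed successes and E_g the sum of predicted
    probabilities in group g.  ``fixed_deciles`` groups on the same fixed
    0-10, ..., 91-100 ranges as the calibration table; ``equal_size`` uses
    equal-count quantile groups (the classic form).
    """
    p = _as_probabilities(scores)
    y = _as_outcome_flags(outcomes).astype(float)
    if p.shape != y.shape:
        raise DomainError("scores and outcomes differ in length")
    if binning == "fixed_deciles":
        g = decile_bins(100.0 * p)
    elif binning == "equal_size":
        edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)))
        g = np.searchsorted(edges[1:-1], p, side="left")
    else:
        raise DomainError(f"unknown binning {binning!r}")
    labels = np.unique(g)
    if labels.size < 2:
        raise DomainError("Hosmer-Lemeshow needs at least 2 non-empty groups")

    rows = []
    stat = 0.0
    for lab in labels:
        mask = g == lab
        n_g = int(mask.sum())
        o_g = float(y[mask].sum())
        e_g = float(p[mask].sum())
        denom = e_g * (1.0 - e_g / n_g)
        if denom <= 0.0:
            # degenerate variance: all-0 or all-1 predictions in the group
            if np.isclose(o_g, e_g):
                contrib = 0.0
            else:
                raise DomainError(
                    f"degenerate H-L group (E={e_g}, n={n_g}) with O != E"
                )
        else:
            contrib = (o_g - e_g) ** 2 / denom
        stat += contrib
        rows.append(
            {"group": int(lab), "n": n_g, "observed": o_g, "expected": e_g,
             "contribution": contrib}
        )
    if df_policy not in ("development", "validation"):
        raise DomainError(f"unknown df_policy {df_policy!r}")
    n_groups = len(labels)
    df = n_groups - 2 if df_policy == "development" else n_groups
    if df == 0:
        # chi-square with 0 df is a point mass at zero
        p_value = 1.0 if np.isclose(stat, 0.0) else 0.0
    else:
        p_value = float(chi2.sf(stat, df))
    return HLResult(
        statistic=float(stat),
        df=int(df),
        p_value=p_value,
        table=pd.DataFrame(rows),
        binning=binning,
        df_policy=df_policy,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC points (1-specificity, sensitivity), trapezoidal AUC and CI."""

    points: np.ndarray           # (k, 2) array, (0,0) ... (1,1)
    thresholds: np.ndarray       # score threshold per interior point
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None
    # raw data retained for variance estimation
    _scores: np.ndarray = field(default=None, repr=False)
    _labels: np.ndarray = field(default=None, repr=False)


def roc_curve(scores, outcomes) -> RocResult:
    """ROC over all distinct score thresholds; positive class is VBAC.

    A woman is predicted VBAC when her score is >= the threshold; ties are
    grouped so each distinct score contributes one point.  Requires both
    outcome classes.
    """
    if len(scores) and isinstance(scores[0], ScoreResult):
        s = np.array([x.probability for x in scores], dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
    y = _as_outcome_flags(outcomes)
    if s.shape != y.shape:
        raise DomainError("scores and outcomes differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0:
        raise DomainError("ROC undefined: no VBAC (positive) outcomes present")
    if n_neg == 0:
        raise DomainError("ROC undefined: no ERCS (negative) outcomes present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y_sorted.size - 1]  # last index of each tie group
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(~y_sorted)[idx]
    sens = tps / n_pos
    fpr = fps / n_neg
    points = np.vstack([[0.0, 0.0], np.column_stack([fpr, sens])])
    thresholds = s_sorted[idx]
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocResult(
        points=points,
        thresholds=thresholds,
        auc=auc,
        _scores=s,
        _labels=y,
    )


def _delong_variance(s: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC via structural components (ties -> 1/2)."""
    pos = s[y]
    neg = s[~y]
    m, n = pos.size, neg.size
    # psi(x, y) = 1 if x > y, 1/2 if x == y, 0 if x < y
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # per-positive components
    v01 = cmp.mean(axis=0)   # per-negative components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
    ) / (m * n)


def auc_with_ci(
    roc: RocResult,
    method: Literal["delong", "hanley_mcneil"] = "delong",
    level: float = 0.95,
) -> RocResult:
    """Attach a confidence interval to a ROC result's AUC.

    The variance is DeLong's (default) or Hanley-McNeil's; the interval is
    clipped to [0, 1].  With fewer than 2 observations in either class the
    CI is undefined and flagged as ``None`` bounds.
    """
    s, y = roc._scores, roc._labels
    if s is None or y is None:
        raise DomainError("RocResult lacks the raw scores needed for a CI")
    m = int(y.sum())
    n = int(y.size - m)
    if m < 2 or n < 2:
        warnings.warn("CI undefined with < 2 observations in a class", stacklevel=2)
        return RocResult(
            points=roc.points, thresholds=roc.thresholds, auc=roc.auc,
            ci_low=None, ci_high=None, method=method, _scores=s, _labels=y,
        )
    if method == "delong":
        var = _delong_variance(s, y)
    elif method == "hanley_mcneil":
        var = _hanley_mcneil_variance(roc.auc, m, n)
    else:
        raise DomainError(f"unknown AUC CI method {method!r}")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        points=roc.points,
        thresholds=roc.thresholds,
        auc=roc.auc,
        ci_low=float(np.clip(roc.auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(roc.auc + half, 0.0, 1.0)),
        method=method,
        _scores=s,
        _labels=y,
    )
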