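"""Bivariate cohort-description statistics: chi-square contingency tests,
Mann-Whitney U with mean ranks, the pooled two-sample t-test, and the
per-variable association report (outcome VBAC vs ERCS).

The chi-square is the uncorrected Pearson statistic even for 2x2 tables (no
Yates continuity correction), which is the form the printed registry
statistics follow.  Mann-Whitney p-values use the normal approximation with
tie correction and no continuity correction (the large-sample / SPSS form);
an exact enumeration is available for small samples as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANTENATAL, INTRAPARTUM, Cohort, DomainError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "RankTestResult",
    "TTestResult",
    "chi_square",
    "mann_whitney",
    "two_sample_t",
    "cohort_association_report",
    "station_group",
    "effacement_group",
    "dilation_group",
    "DEFAULT_TEST_ASSIGNMENT",
]


@dataclass
class ContingencyTable:
    """Predictor-category x outcome counts (columns VBAC, ERCS)."""

    row_labels: Sequence[str]
    counts: np.ndarray
    col_labels: Sequence[str] = ("VBAC", "ERCS")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise DomainError("contingency counts must be 2-dimensional")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise DomainError("contingency table needs at least 2 rows and 2 columns")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise DomainError("contingency counts must be non-negative integers")
        if len(self.row_labels) != self.counts.shape[0]:
            raise DomainError("row label count does not match table")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    small_cells: int  # expected counts below 5


@dataclass
class RankTestResult:
    u_statistic: float      # U of the first group
    mean_rank_a: float
    mean_rank_b: float
    n_a: int
    n_b: int
    p_value: float


@dataclass
class TTestResult:
    statistic: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Uncorrected Pearson chi-square on a contingency table.

    Returns the expected counts so callers can flag small-cell tables
    (expected < 5), where the chi-square approximation weakens.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DomainError("chi-square undefined with a zero marginal total")
    statistic, p_value, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        expected=expected,
        small_cells=int(np.sum(expected < 5)),
    )


def mann_whitney(
    group_a,
    group_b,
    method: Literal["asymptotic", "exact"] = "asymptotic",
) -> RankTestResult:
    """Mann-Whitney U with midrank ties and per-group mean ranks.

    ``U`` is reported for the first group (U_A + U_B = n_A * n_B without
    ties).  The asymptotic p-value is the tie-corrected normal approximation
    without continuity correction; ``method='exact'`` enumerates the null
    distribution (small samples, no ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("Mann-Whitney requires two non-empty groups")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    ranks = stats.rankdata(np.concatenate([a, b]))
    return RankTestResult(
        u_statistic=float(res.statistic),
        mean_rank_a=float(ranks[: a.size].mean()),
        mean_rank_b=float(ranks[a.size:].mean()),
        n_a=int(a.size),
        n_b=int(b.size),
        p_value=float(res.pvalue),
    )


def two_sample_t(group_a, group_b) -> TTestResult:
    """Pooled-variance (equal-variance) two-sample t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("t-test requires n >= 2 in each group")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        raise DomainError("t-test undefined with zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic),
        df=int(a.size + b.size - 2),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=sd_a,
        sd_b=sd_b,
    )


# ---------------------------------------------------------------------------
# reporting-time grouping of the admission examination
# ---------------------------------------------------------------------------

def station_group(station: float) -> str:
    """Fetal head station grouped as reported: -3 / -2 / -1 and 0 / +1 and +2.

    Stations below -3 are folded into the "-3" group and +3 into
    "+1 and +2" so the partition covers the full recordable range.
    """
    s = float(station)
    if s <= -3:
        return "-3"
    if s == -2:
        return "-2"
    if s in (-1, 0):
        return "-1 and 0"
    return "+1 and +2"


def effacement_group(effacement: float) -> str:
    """Cervical effacement grouped as 0-30% / 40-50% / 60-70% / >=80%."""
    e = float(effacement)
    if e < 40:
        return "0-30%"
    if e < 60:
        return "40-50%"
    if e < 80:
        return "60-70%"
    return "80% or more"


def dilation_group(dilation: float) -> str:
    """Cervical dilation grouped as closed / 1-2 / 3-4 / >=5 cm."""
    d = float(dilation)
    if d < 1:
        return "closed"
    if d < 3:
        return "1-2"
    if d < 5:
        return "3-4"
    return "5 or more"


_STATION_ORDER = ("-3", "-2", "-1 and 0", "+1 and +2")
_EFFACEMENT_ORDER = ("0-30%", "40-50%", "60-70%", "80% or more")
_DILATION_ORDER = ("closed", "1-2", "3-4", "5 or more")
_HTN_ORDER = ("none", "preeclampsia", "chronic")
_HISTORY_ORDER = ("no history of VB", "history of VB before CS", "history of VBAC")

#: per-variable default test, following the registry-report conventions
#: (age is rank-tested antenatally but t-tested intrapartum)
DEFAULT_TEST_ASSIGNMENT: Mapping[str, Mapping[str, str]] = {
    ANTENATAL: {
        "age": "mann_whitney",
        "bmi": "mann_whitney",
        "htn_disorders": "chi_square",
        "vaginal_birth_history": "chi_square",
    },
    INTRAPARTUM: {
        "age": "t_test",
        "bmi": "mann_whitney",
        "gestational_age": "mann_whitney",
        "previous_vb": "chi_square",
        "previous_vbac": "chi_square",
        "induction": "chi_square",
        "station": "chi_square",
        "effacement": "chi_square",
        "dilation": "chi_square",
        "htn_disorders": "chi_square",
    },
}


def _history_category(record) -> str:
    if record.prior_vbac:
        return "history of VBAC"
    if record.prior_vaginal_delivery:
        return "history of VB before CS"
    return "no history of VB"


def _continuous_rows(name, test_name, a, b, result) -> list[dict]:
    if test_name == "t_test":
        detail_a = f"{result.mean_a:.2f} ({result.sd_a:.2f})"
        detail_b = f"{result.mean_b:.2f} ({result.sd_b:.2f})"
        stat_label = f"t = {result.statistic:.3f}"
    else:
        detail_a = f"mean rank {result.mean_rank_a:.2f}"
        detail_b = f"mean rank {result.mean_rank_b:.2f}"
        stat_label = f"U = {result.u_statistic:.1f}"
    return [
        {
            "variable": name,
            "category": "",
            "vbac": f"n={len(a)}, {detail_a}",
            "ercs": f"n={len(b)}, {detail_b}",
            "test": test_name,
            "statistic": stat_label,
            "p_value": result.p_value,
        }
    ]


def _categorical_rows(name, order, cat_vbac, cat_ercs) -> tuple[list[dict], ContingencyTable | None]:
    rows = []
    labels, counts = [], []
    n_vbac = len(cat_vbac)
    n_ercs = len(cat_ercs)
    for level in order:
        kv = int(np.sum(np.asarray(cat_vbac) == level))
        ke = int(np.sum(np.asarray(cat_ercs) == level))
        if kv + ke == 0:
            warnings.warn(f"{name}: empty category {level!r} dropped", stacklevel=3)
            continue
        labels.append(level)
        counts.append([kv, ke])
        rows.append(
            {
                "variable": name,
                "category": level,
                "vbac": f"{kv} ({100.0 * kv / n_vbac:.1f}%)" if n_vbac else "0",
                "ercs": f"{ke} ({100.0 * ke / n_ercs:.1f}%)" if n_ercs else "0",
                "test": "chi_square",
                "statistic": "",
                "p_value": np.nan,
            }
        )
    table = None
    if len(labels) >= 2:
        table = ContingencyTable(labels, np.asarray(counts))
    return rows, table


def cohort_association_report(
    cohort: Cohort,
    test_assignment: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variable VBAC-vs-ERCS association table for a cohort.

    Continuous variables are compared by Mann-Whitney (or t-test, per the
    assignment), categorical variables by Pearson chi-square with per-cell
    counts and column percentages (within outcome group).  Station,
    effacement and dilation are grouped into their reporting bins here;
    records keep the raw values.
    """
    if len(cohort) == 0:
        raise DomainError("association report of an empty cohort")
    assign = dict(DEFAULT_TEST_ASSIGNMENT[cohort.variant])
    if test_assignment:
        assign.update(test_assignment)

    recs = cohort.records
    vbac = [r for r in recs if r.outcome == "VBAC"]
    ercs = [r for r in recs if r.outcome == "ERCS"]
    rows: list[dict] = []

    def continuous(name, attr):
        a = [getattr(r, attr) for r in vbac]
        b = [getattr(r, attr) for r in ercs]
        test = assign[name]
        if test == "t_test":
            result = two_sample_t(a, b)
        else:
            result = mann_whitney(a, b)
        rows.extend(_continuous_rows(name, test, a, b, result))

    def categorical(name, order, value_fn):
        cat_v = [value_fn(r) for r in vbac]
        cat_e = [value_fn(r) for r in ercs]
        cat_rows, table = _categorical_rows(name, order, cat_v, cat_e)
        if table is not None:
            result = chi_square(table)
            cat_rows[0]["statistic"] = f"X2 = {result.statistic:.3f}"
            cat_rows[0]["p_value"] = result.p_value
        rows.extend(cat_rows)

    bmi_attr = "bmi_booking" if cohort.variant == ANTENATAL else "bmi_last_visit"
    continuous("age", "age")
    assign.setdefault("bmi", "mann_whitney")
    continuous("bmi", bmi_attr)
    if cohort.variant == ANTENATAL:
        categorical("htn_disorders", _HTN_ORDER, lambda r: r.htn_status or "none")
        categorical("vaginal_birth_history", _HISTORY_ORDER, _history_category)
    else:
        continuous("gestational_age", "gestational_age")
        categorical(
            "previous_vb", ("yes", "no"),
            lambda r: "yes" if (r.prior_vaginal_delivery and not r.prior_vbac) else "no",
        )
        categorical("previous_vbac", ("yes", "no"), lambda r: "yes" if r.prior_vbac else "no")
        categorical("induction", ("yes", "no"), lambda r: "yes" if r.induction else "no")
        categorical("station", _STATION_ORDER, lambda r: station_group(r.station))
        categorical("effacement", _EFFACEMENT_ORDER, lambda r: effacement_group(r.effacement))
        categorical("dilation", _DILATION_ORDER, lambda r: dilation_group(r.dilation))
        categorical("htn_disorders", _HTN_ORDER, lambda r: r.htn_status or "none")
    return pd.DataFrame(rows)
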