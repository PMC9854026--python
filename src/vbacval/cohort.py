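"""Patient records, cohorts, delimited-text I/O and complete-case filtering.

A cohort is an ordered collection of one record variant:

* :class:`AntenatalRecord` — the five predictors known at the booking visit
  (age, booking BMI, prior vaginal delivery, prior VBAC, recurring caesarean
  indication) plus the delivery outcome.
* :class:`IntrapartumRecord` — the antenatal predictors plus the admission
  findings (BMI at the last antenatal visit, gestational age, hypertensive
  disease, cervical effacement/dilation, fetal head station, induction).

Records may carry missing fields (``None``); :func:`complete_case_filter`
restricts a cohort to records with every model-required field present, which
is the inclusion rule applied before scoring and validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "ANTENATAL",
    "INTRAPARTUM",
    "HTN_LEVELS",
    "OUTCOMES",
    "AntenatalRecord",
    "IntrapartumRecord",
    "Cohort",
    "CohortError",
    "ConfigurationError",
    "CohortReadError",
    "DomainError",
    "RecordValidationError",
    "ScoringError",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
    "ANTENATAL_REQUIRED",
    "INTRAPARTUM_REQUIRED",
    "ANTENATAL_COLUMNS",
    "INTRAPARTUM_COLUMNS",
]

ANTENATAL = "antenatal"
INTRAPARTUM = "intrapartum"

OUTCOMES = ("VBAC", "ERCS")
HTN_LEVELS = ("none", "preeclampsia", "chronic")

#: tokens read as a missing value (empty cell is canonical on write)
MISSING_TOKENS = {"", "na", "nan", "none", "null"}

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f"}


class CohortError(Exception):
    """Base class for all cohort-layer errors."""


class ConfigurationError(CohortError):
    """Bad configuration: unknown variant, missing mandatory column, ..."""


class RecordValidationError(CohortError):
    """A record field violates its domain invariant."""


class ScoringError(CohortError):
    """A model-required field is missing at scoring time."""


class DomainError(CohortError):
    """A statistical operation was asked of degenerate input."""


class CohortReadError(CohortError):
    """One or more rows of a cohort file failed to parse or validate.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based data-row numbers (header excluded) with their failure reason.
    """

    def __init__(self, path, row_errors: list[tuple[int, str]]):
        self.path = str(path)
        self.row_errors = row_errors
        lines = "; ".join(f"row {r}: {m}" for r, m in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{self.path}: {len(row_errors)} invalid row(s): {lines}{more}")


def _check_range(name: str, value, lo, hi):
    if value is None:
        return
    if not (lo <= value <= hi):
        raise RecordValidationError(f"{name}={value!r} outside [{lo}, {hi}]")


def _check_level(name: str, value, levels):
    if value is not None and value not in levels:
        raise RecordValidationError(f"{name}={value!r} not one of {levels}")


@dataclass(kw_only=True)
class AntenatalRecord:
    """One pregnancy's antenatal predictors and delivery outcome.

    Any field may be ``None`` (missing in the registry extract); present
    values are validated against clinical plausibility ranges.  The two
    vaginal-birth-history flags are deliberately independent: a prior VBAC is
    itself a vaginal delivery, so ``prior_vbac=True`` normally accompanies
    ``prior_vaginal_delivery=True``, but the scoring equations carry the two
    as separate indicator terms and this type does not conflate them.
    ``htn_status`` is descriptive at the antenatal stage (it is not a term of
    the antenatal equation).
    """

    age: float | None = None               # years, [15, 55]
    bmi_booking: float | None = None       # kg/m^2 at booking, [12, 60]
    prior_vaginal_delivery: bool | None = None
    prior_vbac: bool | None = None
    recurring_indication: bool | None = None
    htn_status: str | None = None          # none | preeclampsia | chronic
    outcome: str | None = None             # VBAC | ERCS

    def __post_init__(self):
        _check_range("age", self.age, 15, 55)
        _check_range("bmi_booking", self.bmi_booking, 12, 60)
        _check_level("htn_status", self.htn_status, HTN_LEVELS)
        _check_level("outcome", self.outcome, OUTCOMES)

    @property
    def variant(self) -> str:
        return ANTENATAL

    def missing_fields(self, required: Sequence[str]) -> list[str]:
        return [f for f in required if getattr(self, f) is None]


@dataclass(kw_only=True)
class IntrapartumRecord(AntenatalRecord):
    """Antenatal predictors plus the admission examination.

    ``bmi_last_visit`` (not ``bmi_booking``) is the BMI term of the
    intrapartum equation; ``htn_flag`` is the scored any-hypertensive-disease
    indicator.  Cohort inclusion is term-only, so ``gestational_age`` must be
    at least 37 completed weeks.
    """

    bmi_last_visit: float | None = None    # kg/m^2 at last antenatal visit
    gestational_age: float | None = None   # completed weeks, >= 37
    htn_flag: bool | None = None           # any hypertensive disease (scored)
    effacement: float | None = None        # percent, [0, 100]
    dilation: float | None = None          # cm, [0, 10]
    station: int | None = None             # [-5, +3]
    induction: bool | None = None

    def __post_init__(self):
        super().__post_init__()
        _check_range("bmi_last_visit", self.bmi_last_visit, 12, 60)
        _check_range("gestational_age", self.gestational_age, 37, 45)
        _check_range("effacement", self.effacement, 0, 100)
        _check_range("dilation", self.dilation, 0, 10)
        _check_range("station", self.station, -5, 3)

    @property
    def variant(self) -> str:
        return INTRAPARTUM


#: model-required fields per variant (complete-case rule)
ANTENATAL_REQUIRED = (
    "age",
    "bmi_booking",
    "prior_vaginal_delivery",
    "prior_vbac",
    "recurring_indication",
    "outcome",
)
INTRAPARTUM_REQUIRED = (
    "age",
    "bmi_last_visit",
    "prior_vaginal_delivery",
    "prior_vbac",
    "recurring_indication",
    "gestational_age",
    "htn_flag",
    "effacement",
    "dilation",
    "station",
    "induction",
    "outcome",
)

#: canonical on-disk column order per variant
ANTENATAL_COLUMNS = (
    "age",
    "bmi_booking",
    "prior_vaginal_delivery",
    "prior_vbac",
    "recurring_indication",
    "htn_status",
    "outcome",
)
INTRAPARTUM_COLUMNS = (
    "age",
    "bmi_booking",
    "bmi_last_visit",
    "gestational_age",
    "prior_vaginal_delivery",
    "prior_vbac",
    "recurring_indication",
    "htn_status",
    "htn_flag",
    "effacement",
    "dilation",
    "station",
    "induction",
    "outcome",
)

_RECORD_CLS = {ANTENATAL: AntenatalRecord, INTRAPARTUM: IntrapartumRecord}
_COLUMNS = {ANTENATAL: ANTENATAL_COLUMNS, INTRAPARTUM: INTRAPARTUM_COLUMNS}
REQUIRED_FIELDS = {ANTENATAL: ANTENATAL_REQUIRED, INTRAPARTUM: INTRAPARTUM_REQUIRED}

_BOOL_FIELDS = {
    "prior_vaginal_delivery",
    "prior_vbac",
    "recurring_indication",
    "htn_flag",
    "induction",
}
_INT_FIELDS = {"station"}
_CATEGORY_FIELDS = {"htn_status": HTN_LEVELS, "outcome": OUTCOMES}


@dataclass
class Cohort:
    """An ordered, single-variant collection of patient records."""

    records: list
    variant: str
    label: str = ""

    def __post_init__(self):
        if self.variant not in _RECORD_CLS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        cls = _RECORD_CLS[self.variant]
        for i, r in enumerate(self.records):
            # an IntrapartumRecord is-an AntenatalRecord; require exact variant
            if r.variant != self.variant:
                raise ConfigurationError(
                    f"record {i} has variant {r.variant!r}, cohort is {self.variant!r}"
                )
            if not isinstance(r, cls):
                raise ConfigurationError(f"record {i} is not a {cls.__name__}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cohort)
            and self.variant == other.variant
            and self.records == other.records
        )

    def outcomes(self) -> list[str]:
        return [r.outcome for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        cols = _COLUMNS[self.variant]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=list(cols)
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_cell(field_name: str, raw: str):
    """Parse one CSV cell to the field's python type; '' / 'NA' -> None."""
    token = raw.strip()
    # category levels win over missing tokens ("none" is a valid htn_status)
    if field_name in _CATEGORY_FIELDS:
        norm = token.lower() if field_name == "htn_status" else token.upper()
        if norm in _CATEGORY_FIELDS[field_name]:
            return norm
    if token.lower() in MISSING_TOKENS:
        return None
    if field_name in _BOOL_FIELDS:
        low = token.lower()
        if low in _TRUE_TOKENS:
            return True
        if low in _FALSE_TOKENS:
            return False
        raise ValueError(f"{field_name}: {raw!r} is not a recognised boolean")
    if field_name in _INT_FIELDS:
        value = int(token)  # rejects '1.5' stations
        return value
    if field_name in _CATEGORY_FIELDS:
        raise ValueError(
            f"{field_name}: {raw!r} not one of {_CATEGORY_FIELDS[field_name]}"
        )
    value = float(token)
    if not math.isfinite(value):
        raise ValueError(f"{field_name}: {raw!r} is not finite")
    return value


def _format_cell(field_name: str, value) -> str:
    if value is None:
        return ""
    if field_name in _BOOL_FIELDS:
        return "1" if value else "0"
    if field_name in _INT_FIELDS:
        return str(int(value))
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def read_cohort(
    path,
    variant: str,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> Cohort:
    """Read a delimited-text cohort file.

    Parameters
    ----------
    path : path-like
        CSV file (RFC-4180, UTF-8) with a header row.
    variant : {'antenatal', 'intrapartum'}
        Record variant to parse rows into.
    column_map : mapping, optional
        ``canonical_field -> file_column`` overrides for non-canonical
        headers.  The BMI binding is explicit per variant: the antenatal
        variant reads ``bmi_booking``, the intrapartum variant
        ``bmi_last_visit``; there is no silent fallback between the two.

    Raises
    ------
    ConfigurationError
        If a mandatory (model-required) column is absent from the file.
    CohortReadError
        Listing every row whose cells fail to parse or whose record violates
        a domain invariant; nothing is silently dropped.
    """
    if variant not in _RECORD_CLS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    fields = _COLUMNS[variant]
    bound = {f: column_map.get(f, f) for f in fields}
    required = REQUIRED_FIELDS[variant]
    missing_cols = [bound[f] for f in required if bound[f] not in frame.columns]
    if missing_cols:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing_cols} for the "
            f"{variant} model (use column_map to bind non-canonical headers)"
        )

    cls = _RECORD_CLS[variant]
    records: list = []
    row_errors: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        kwargs = {}
        errs = []
        for f in fields:
            col = bound[f]
            if col not in frame.columns:
                kwargs[f] = None  # optional descriptive column absent
                continue
            try:
                kwargs[f] = _parse_cell(f, str(row[col]))
            except (ValueError, TypeError) as exc:
                errs.append(str(exc))
        if not errs:
            try:
                records.append(cls(**kwargs))
            except RecordValidationError as exc:
                errs.append(str(exc))
        if errs:
            row_errors.append((i, "; ".join(errs)))
    if row_errors:
        raise CohortReadError(path, row_errors)
    return Cohort(records, variant, label=label or path.stem)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as canonical-header CSV (booleans 0/1, missing empty)."""
    path = Path(path)
    cols = _COLUMNS[cohort.variant]
    rows = [{c: _format_cell(c, getattr(r, c)) for c in cols} for r in cohort.records]
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, index=False)


def complete_case_filter(cohort: Cohort) -> tuple[Cohort, int]:
    """Restrict to records with every model-required field present.

    Returns the filtered cohort and the number of dropped records.  Emits a
    warning when nothing survives; downstream statistics refuse to run on an
    empty cohort.
    """
    required = REQUIRED_FIELDS[cohort.variant]
    kept = [r for r in cohort.records if not r.missing_fields(required)]
    dropped = len(cohort.records) - len(kept)
    if not kept:
        warnings.warn(
            f"complete-case filter removed all {dropped} records "
            f"({cohort.label or cohort.variant})",
            stacklevel=2,
        )
    return Cohort(kept, cohort.variant, label=cohort.label), dropped
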