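"""The Grobman VBAC-success nomograms: fixed-coefficient linear predictors
and the logistic transform.

Two published models are carried as data, not arithmetic:

* **antenatal** — five predictors available at the booking visit::

      w = 3.766 - 0.039*age - 0.060*BMI(booking)
          + 0.888*I(prior vaginal delivery) + 1.003*I(prior VBAC)
          - 0.632*I(recurring caesarean indication)

* **intrapartum** — the antenatal terms (re-weighted) plus the admission
  findings::

      w = 7.059 - 0.037*age - 0.044*BMI(last visit)
          + 0.955*I(prior VD) + 0.851*I(prior VBAC) - 0.655*I(recurring)
          - 0.109*GA - 0.499*I(hypertensive disease)
          + 0.044*effacement(%) + 0.109*dilation(cm) + 0.082*station
          - 0.452*I(induction)

The predicted probability of a successful VBAC is ``exp(w)/(1+exp(w))``.
Note that effacement enters on the raw 0-100 percent scale, so its term
alone spans 0 to 4.4 on the log-odds scale; this follows the published
equation literally and is the single largest lever of the intrapartum score.
The original model's race term is omitted entirely (no placeholder).

Coefficients live in a :class:`CoefficientSet` registry so both models share
one evaluation engine and tests (and the synthetic-cohort calibration
machinery) can inject perturbed sets.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy.special import expit

from .cohort import (
    ANTENATAL,
    INTRAPARTUM,
    AntenatalRecord,
    Cohort,
    ConfigurationError,
    DomainError,
    IntrapartumRecord,
    ScoringError,
)

__all__ = [
    "CoefficientSet",
    "ScoreResult",
    "ANTENATAL_COEFFICIENTS",
    "INTRAPARTUM_COEFFICIENTS",
    "get_coefficients",
    "antenatal_linear_predictor",
    "intrapartum_linear_predictor",
    "linear_predictor",
    "linear_predictor_frame",
    "predicted_probability",
    "score_record",
    "score_cohort",
    "coefficients_to_json",
]


@dataclass(frozen=True)
class CoefficientSet:
    """A named, immutable set of log-odds coefficients for one model."""

    model: str
    intercept: float
    coefficients: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "coefficients", MappingProxyType(dict(self.coefficients)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
        }


ANTENATAL_COEFFICIENTS = CoefficientSet(
    model=ANTENATAL,
    intercept=3.766,
    coefficients={
        "age": -0.039,
        "bmi": -0.060,
        "prior_vaginal_delivery": 0.888,
        "prior_vbac": 1.003,
        "recurring_indication": -0.632,
    },
)

INTRAPARTUM_COEFFICIENTS = CoefficientSet(
    model=INTRAPARTUM,
    intercept=7.059,
    coefficients={
        "age": -0.037,
        "bmi": -0.044,
        "prior_vaginal_delivery": 0.955,
        "prior_vbac": 0.851,
        "recurring_indication": -0.655,
        "gestational_age": -0.109,
        "hypertension": -0.499,
        "effacement": 0.044,
        "dilation": 0.109,
        "station": 0.082,
        "induction": -0.452,
    },
)

_REGISTRY = {ANTENATAL: ANTENATAL_COEFFICIENTS, INTRAPARTUM: INTRAPARTUM_COEFFICIENTS}

#: coefficient term -> record attribute, per model (BMI binding is explicit)
_TERM_ATTR = {
    ANTENATAL: {
        "age": "age",
        "bmi": "bmi_booking",
        "prior_vaginal_delivery": "prior_vaginal_delivery",
        "prior_vbac": "prior_vbac",
        "recurring_indication": "recurring_indication",
    },
    INTRAPARTUM: {
        "age": "age",
        "bmi": "bmi_last_visit",
        "prior_vaginal_delivery": "prior_vaginal_delivery",
        "prior_vbac": "prior_vbac",
        "recurring_indication": "recurring_indication",
        "gestational_age": "gestational_age",
        "hypertension": "htn_flag",
        "effacement": "effacement",
        "dilation": "dilation",
        "station": "station",
        "induction": "induction",
    },
}


def get_coefficients(model: str) -> CoefficientSet:
    try:
        return _REGISTRY[model]
    except KeyError:
        raise ConfigurationError(f"unknown model {model!r}") from None


def coefficients_to_json(model: str | None = None) -> str:
    """Export the coefficient registry (or one model) as JSON."""
    if model is not None:
        return json.dumps(get_coefficients(model).to_dict(), indent=2)
    return json.dumps({m: c.to_dict() for m, c in _REGISTRY.items()}, indent=2)


@dataclass(frozen=True)
class ScoreResult:
    """One woman's linear predictor ``w`` and predicted VBAC probability."""

    linear_predictor: float
    probability: float
    probability_percent: float
    model: str


def linear_predictor(record, model: str, coefficients: CoefficientSet | None = None) -> float:
    """Evaluate the model's linear predictor ``w`` on one record.

    Raises :class:`ScoringError` naming the first missing required field.
    """
    coeffs = coefficients if coefficients is not None else get_coefficients(model)
    attrs = _TERM_ATTR[model]
    w = coeffs.intercept
    for term, beta in coeffs.coefficients.items():
        value = getattr(record, attrs[term])
        if value is None:
            raise ScoringError(
                f"{model} model: required field {attrs[term]!r} is missing"
            )
        w += beta * float(value)
    return w


def antenatal_linear_predictor(record: AntenatalRecord) -> float:
    return linear_predictor(record, ANTENATAL)


def intrapartum_linear_predictor(record: IntrapartumRecord) -> float:
    return linear_predictor(record, INTRAPARTUM)


def linear_predictor_frame(
    frame, model: str, coefficients: CoefficientSet | None = None
) -> np.ndarray:
    """Vectorised ``w`` over a DataFrame of canonical record columns."""
    coeffs = coefficients if coefficients is not None else get_coefficients(model)
    attrs = _TERM_ATTR[model]
    w = np.full(len(frame), coeffs.intercept, dtype=float)
    for term, beta in coeffs.coefficients.items():
        w += beta * frame[attrs[term]].to_numpy(dtype=float)
    return w


def predicted_probability(w: float) -> float:
    """Logistic transform ``exp(w)/(1+exp(w))``, stable for large ``|w|``."""
    if not math.isfinite(w):
        raise DomainError(f"linear predictor must be finite, got {w!r}")
    p = float(expit(w))
    # keep the open interval even when expit saturates in float64
    return min(max(p, np.finfo(float).tiny), 1.0 - np.finfo(float).epsneg)


def score_record(record, model: str, coefficients: CoefficientSet | None = None) -> ScoreResult:
    w = linear_predictor(record, model, coefficients)
    p = predicted_probability(w)
    return ScoreResult(
        linear_predictor=w,
        probability=p,
        probability_percent=100.0 * p,
        model=model,
    )


def score_cohort(
    cohort: Cohort, model: str, coefficients: CoefficientSet | None = None
) -> list[ScoreResult]:
    """Score every record of a cohort, order preserved.

    The cohort's variant must match the requested model (the two record
    variants carry different BMI fields; there is no silent crossover).
    """
    get_coefficients(model)  # validate model name early
    if cohort.variant != model:
        raise ConfigurationError(
            f"cohort variant {cohort.variant!r} does not match model {model!r}"
        )
    if len(cohort) == 0:
        warnings.warn("scoring an empty cohort", stacklevel=2)
    return [score_record(r, model, coefficients) for r in cohort.records]
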