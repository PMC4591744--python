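"""Published creatinine-based eGFR equations and fitted spline-model evaluation.

Comparator equations
--------------------
* CKD-EPI creatinine (2009): a two-slope power law in Scr/κ with sex-specific
  knot κ (0.7 mg/dL women, 0.9 mg/dL men), an exponential age decay and
  female/black multipliers.  Some reprints give the below-knot exponent α a
  positive sign, which would make eGFR *rise* with creatinine below the knot;
  the standard form uses α = −0.329 (women) / −0.411 (men) and is the default
  here.  ``strict_printed=True`` evaluates the positive-α variant for audit.
* Japanese eGFR equation: 194 · Scr^−1.094 · Age^−0.287 (× 0.739 if female).
* Japanese HbA1c-adjusted equation: the same power law divided by
  (0.428 + 0.0085 · HbA1c), reflecting glycaemia-driven hyperfiltration.

Fitted models
-------------
:class:`SplineEquationModel` holds the coefficients of a log-scale two-slope
creatinine spline regression, with sex-specific knots and optional additive
covariates (BMI, HbA1c, UACR on the natural scale):

    ln eGFR = b0 + b_lo·min(ln(Scr/κ_sex), 0) + b_hi·max(ln(Scr/κ_sex), 0)
              + b_age·Age + b_fem·[female] + Σ_c b_c·c

The min/max split makes the prediction continuous in Scr at the knot.

All outputs are mL/min/1.73 m²; no body-surface-area re-normalization is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .cohort import PatientRecord
from .errors import EvaluationError, ValidationError

__all__ = [
    "ckd_epi",
    "japanese_1",
    "japanese_2",
    "SplineEquationModel",
    "evaluate_spline_model",
]

#: Sex-specific creatinine knots (mg/dL) of the fitted spline models.
SPLINE_KNOT_FEMALE = 0.7
SPLINE_KNOT_MALE = 0.8

_ALLOWED_COVARIATES = ("bmi", "hba1c", "uacr")


def _check_domain(age: float, scr: float) -> None:
    if scr <= 0 or not math.isfinite(scr):
        raise EvaluationError(f"serum creatinine must be > 0 mg/dL, got {scr}")
    if age < 18 or not math.isfinite(age):
        raise EvaluationError(f"age must be >= 18 years, got {age}")


def ckd_epi(
    sex: str,
    age: float,
    scr: float,
    black: bool = False,
    strict_printed: bool = False,
) -> float:
    """CKD-EPI creatinine eGFR (mL/min/1.73 m²).

    141 × min(Scr/κ, 1)^α × max(Scr/κ, 1)^−1.209 × 0.993^Age
        × 1.018 (if female) × 1.159 (if black)

    with κ = 0.7 / 0.9 and α = −0.329 / −0.411 for women / men.
    ``strict_printed`` flips α to the positive-sign variant found in some
    reprints (audit only; not monotonically decreasing in creatinine).
    """
    _check_domain(age, scr)
    female = _is_female(sex)
    kappa = 0.7 if female else 0.9
    alpha = (0.329 if female else 0.411) if strict_printed else (-0.329 if female else -0.411)
    ratio = scr / kappa
    gfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age
    if female:
        gfr *= 1.018
    if black:
        gfr *= 1.159
    return gfr


def japanese_1(sex: str, age: float, scr: float) -> float:
    """Japanese creatinine eGFR: 194 · Scr^−1.094 · Age^−0.287 (× 0.739 if female)."""
    _check_domain(age, scr)
    gfr = 194.0 * scr ** -1.094 * age ** -0.287
    if _is_female(sex):
        gfr *= 0.739
    return gfr


def japanese_2(sex: str, age: float, scr: float, hba1c: float) -> float:
    """HbA1c-adjusted Japanese eGFR: japanese_1 / (0.428 + 0.0085 · HbA1c)."""
    if hba1c <= 0 or not math.isfinite(hba1c):
        raise EvaluationError(f"HbA1c must be > 0 %, got {hba1c}")
    return japanese_1(sex, age, scr) / (0.428 + 0.0085 * hba1c)


def _is_female(sex: str) -> bool:
    if sex in ("female", "f", "F"):
        return True
    if sex in ("male", "m", "M"):
        return False
    raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")


@dataclass(frozen=True)
class SplineEquationModel:
    """Coefficients of a log-scale two-slope creatinine spline eGFR equation.

    ``intercept`` is ln(mL/min/1.73 m²); ``slope_below``/``slope_above`` act
    on ln(Scr/κ_sex) below/above the sex knot; ``age_coef`` per year;
    ``female_coef`` is the additive log-scale female term;
    ``covariate_coefs`` maps a subset of {bmi, hba1c, uacr} to additive
    per-natural-unit coefficients.
    """

    intercept: float
    slope_below: float
    slope_above: float
    age_coef: float
    female_coef: float
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)
    knot_female: float = SPLINE_KNOT_FEMALE
    knot_male: float = SPLINE_KNOT_MALE

    def __post_init__(self) -> None:
        if self.knot_female <= 0 or self.knot_male <= 0:
            raise ValidationError("knots must be positive creatinine values (mg/dL)")
        bad = set(self.covariate_coefs) - set(_ALLOWED_COVARIATES)
        if bad:
            raise ValidationError(f"unknown covariates {sorted(bad)}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.covariate_coefs)

    def knot(self, sex: str) -> float:
        return self.knot_female if _is_female(sex) else self.knot_male

    def log_egfr(
        self,
        sex: str,
        age: float,
        scr: float,
        covariate_values: Optional[Mapping[str, float]] = None,
    ) -> float:
        _check_domain(age, scr)
        z = math.log(scr / self.knot(sex))
        val = (
            self.intercept
            + self.slope_below * min(z, 0.0)
            + self.slope_above * max(z, 0.0)
            + self.age_coef * age
            + (self.female_coef if _is_female(sex) else 0.0)
        )
        for name, coef in self.covariate_coefs.items():
            if covariate_values is None or covariate_values.get(name) is None:
                raise EvaluationError(f"model requires covariate {name!r}")
            val += coef * covariate_values[name]
        return val

    def predict(self, record: PatientRecord) -> float:
        """Predicted eGFR for one record (mL/min/1.73 m²)."""
        values = {name: record.get(name) for name in self.covariate_coefs}
        return math.exp(self.log_egfr(record.sex, record.age, record.scr, values))


def evaluate_spline_model(model: SplineEquationModel, record: PatientRecord) -> float:
    """Evaluate a fitted spline equation on a patient record."""
    return model.predict(record)
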