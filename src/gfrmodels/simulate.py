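"""Synthetic diabetic cohort generation with a known ground-truth GFR model.

No patient-level data are distributed with this package, so development and
validation code is exercised on simulated cohorts whose marginals emulate a
hospital type 2 diabetes population: mean age about 60 y, mean BMI 25 kg/m²,
median creatinine 0.8 mg/dL, median HbA1c 8.5 %, heavily right-skewed
albuminuria (median UACR 42.6 mg/g with IQR 219 mg/g), 54.3 % male, and a
mean standard GFR near 81 mL/min/1.73 m².

Distribution families (the summary statistics alone do not pin them down):

* age, BMI — truncated normals (age >= 18 y, BMI > 0);
* Scr, UACR, HbA1c — log-normal, the usual family for right-skewed labs;
  log-normal parameters are matched to the reported median and IQR through
  sigma = asinh(IQR / (2 median)) / z_0.75.

The standard GFR of each record is a configurable ground-truth model
evaluated on the covariates times multiplicative log-normal noise:
sGFR = truth(record) · exp(eps), eps ~ N(0, noise_sigma²).  With
noise_sigma = 0 the reference GFR is exactly the truth model's prediction,
which makes fitting stages exactly recoverable.

Covariates are independent by default; an optional Gaussian copula
correlation matrix couples (sex, age, bmi, scr, hba1c, uacr) while leaving
every marginal unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, PatientRecord
from .equations import SplineEquationModel
from .errors import ConfigurationError, EvaluationError, ValidationError

__all__ = [
    "CohortSimConfig",
    "DEFAULT_TRUTH_MODEL",
    "lognormal_sigma_from_median_iqr",
    "generate_cohort",
    "summarize_cohort",
]

_Z75 = stats.norm.ppf(0.75)  # 0.6744897501960817

#: Order of variables in the optional Gaussian-copula correlation matrix.
COPULA_VARIABLES = ("sex", "age", "bmi", "scr", "hba1c", "uacr")


def lognormal_sigma_from_median_iqr(median: float, iqr: float) -> float:
    """Log-scale sigma of a log-normal with the given median and IQR.

    For X log-normal with median m, Q3 - Q1 = 2 m sinh(z_0.75 sigma), so
    sigma = asinh(IQR / (2 m)) / z_0.75.
    """
    if median <= 0 or iqr <= 0:
        raise ValidationError("median and IQR must be positive")
    return math.asinh(iqr / (2.0 * median)) / _Z75


#: Default generating mechanism: a two-slope creatinine spline with
#: CKD-EPI-like slopes, intercept placed so a typical subject (male, 60 y,
#: Scr 0.8 mg/dL) lands near the population mean sGFR of ~81 mL/min/1.73 m².
DEFAULT_TRUTH_MODEL = SplineEquationModel(
    intercept=4.81,
    slope_below=-0.35,
    slope_above=-1.2,
    age_coef=math.log(0.993),
    female_coef=math.log(1.018),
)


@dataclass(frozen=True)
class CohortSimConfig:
    """Simulation parameters; defaults emulate the reference diabetic cohort."""

    n: int = 414
    male_fraction: float = 0.543
    age_mean: float = 59.8  # years
    age_sd: float = 13.1
    bmi_mean: float = 25.0  # kg/m²
    bmi_sd: float = 3.5
    scr_log_median: float = math.log(0.8)  # log mg/dL; median 0.8, IQR 0.6
    scr_log_sigma: float = lognormal_sigma_from_median_iqr(0.8, 0.6)
    hba1c_median: float = 8.5  # percent; IQR 3.4
    hba1c_iqr: float = 3.4
    uacr_log_median: float = math.log(42.6)  # log mg/g; median 42.6, IQR 219.0
    uacr_log_sigma: float = lognormal_sigma_from_median_iqr(42.6, 219.0)
    noise_sigma: float = 0.2  # SD of log-scale GFR noise
    truth: object = DEFAULT_TRUTH_MODEL
    seed: int = 0
    correlation: Optional[np.ndarray] = None  # 6x6 over COPULA_VARIABLES
    id_prefix: str = "sim"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        for name in ("age_sd", "bmi_sd", "scr_log_sigma", "hba1c_median",
                     "hba1c_iqr", "uacr_log_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(COPULA_VARIABLES)
            if corr.shape != (k, k) or not np.allclose(corr, corr.T):
                raise ConfigurationError(f"correlation must be a symmetric {k}x{k} matrix")


def _copula_uniforms(config: CohortSimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n, 6) uniforms, coupled through a Gaussian copula when configured."""
    k = len(COPULA_VARIABLES)
    if config.correlation is None:
        return rng.uniform(size=(config.n, k))
    corr = np.asarray(config.correlation, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("correlation matrix is not positive definite") from exc
    z = rng.standard_normal((config.n, k)) @ chol.T
    return stats.norm.cdf(z)


def generate_cohort(config: CohortSimConfig) -> Cohort:
    """Draw a synthetic cohort; deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    u = _copula_uniforms(config, rng)

    sex = np.where(u[:, 0] < config.male_fraction, "male", "female")
    a_age = (18.0 - config.age_mean) / config.age_sd
    age = stats.truncnorm.ppf(u[:, 1], a=a_age, b=np.inf,
                              loc=config.age_mean, scale=config.age_sd)
    a_bmi = (0.0 - config.bmi_mean) / config.bmi_sd
    bmi = stats.truncnorm.ppf(u[:, 2], a=a_bmi, b=np.inf,
                              loc=config.bmi_mean, scale=config.bmi_sd)
    scr = np.exp(config.scr_log_median
                 + config.scr_log_sigma * stats.norm.ppf(u[:, 3]))
    hba1c_sigma = lognormal_sigma_from_median_iqr(config.hba1c_median, config.hba1c_iqr)
    hba1c = np.exp(math.log(config.hba1c_median)
                   + hba1c_sigma * stats.norm.ppf(u[:, 4]))
    uacr = np.exp(config.uacr_log_median
                  + config.uacr_log_sigma * stats.norm.ppf(u[:, 5]))

    noise = (rng.normal(0.0, config.noise_sigma, size=config.n)
             if config.noise_sigma > 0 else np.zeros(config.n))

    width = max(5, len(str(config.n)))
    records = []
    for i in range(config.n):
        rec = PatientRecord(
            id=f"{config.id_prefix}-{i:0{width}d}",
            sex=str(sex[i]),
            age=float(age[i]),
            scr=float(scr[i]),
            bmi=float(bmi[i]),
            hba1c=float(hba1c[i]),
            uacr=float(uacr[i]),
        )
        try:
            truth_gfr = config.truth.predict(rec)
        except EvaluationError as exc:
            raise ConfigurationError(
                f"truth model needs a field the generator does not produce: {exc}"
            ) from exc
        records.append(replace(rec, sgfr=float(truth_gfr * math.exp(noise[i]))))
    return Cohort(records=records)


# Table-style category bins: left-closed, right-open.
_BINS = {
    "bmi": ((-np.inf, 20, 25, 30, np.inf), ("<20", "20-25", "25-30", ">30")),
    "hba1c": ((-np.inf, 6, 8, np.inf), ("<6", "6-8", ">8")),
    "uacr": ((-np.inf, 30, 300, np.inf), ("<30", "30-300", ">300")),
    "sgfr": ((-np.inf, 15, 30, 60, 90, np.inf), ("<15", "15-29", "30-59", "60-90", ">90")),
}


def _mean_sd(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": 0.0 if values.size == 1 else float(np.std(values, ddof=1)),
        "n": int(values.size),
    }


def _median_iqr(values: np.ndarray) -> dict:
    q1, q2, q3 = np.percentile(values, [25, 50, 75])  # type-7 quantiles
    return {"median": float(q2), "iqr": float(q3 - q1), "n": int(values.size)}


def _bin_percentages(values: np.ndarray, field_name: str) -> dict:
    edges, labels = _BINS[field_name]
    counts = np.histogram(values, bins=np.asarray(edges))[0]
    return {
        label: {"count": int(c), "percent": float(100.0 * c / values.size)}
        for label, c in zip(labels, counts)
    }


def summarize_cohort(cohort: Cohort) -> dict:
    """Cohort characteristics table: mean ± SD for roughly symmetric variables
    (age, BMI, sGFR), median (IQR) for skewed labs (Scr, HbA1c, UACR),
    male/female percentages, and clinical category bins."""
    if len(cohort) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    recs = cohort.records
    out: dict = {"n": len(recs)}
    males = sum(1 for r in recs if r.sex == "male")
    out["male_percent"] = 100.0 * males / len(recs)
    out["female_percent"] = 100.0 - out["male_percent"]
    out["age"] = _mean_sd(np.array([r.age for r in recs]))

    def _present(name: str) -> np.ndarray:
        return np.array([r.get(name) for r in recs if r.get(name) is not None])

    for name, kind in (("bmi", "mean"), ("sgfr", "mean"),
                       ("scr", "median"), ("hba1c", "median"), ("uacr", "median")):
        vals = _present(name) if name != "scr" else np.array([r.scr for r in recs])
        if vals.size == 0:
            continue
        out[name] = _mean_sd(vals) if kind == "mean" else _median_iqr(vals)
        if name in _BINS:
            out[name]["bins"] = _bin_percentages(vals, name)
    return out
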