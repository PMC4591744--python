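"""Validation metrics for GFR-estimating models.

The standard clinical yardsticks are used throughout:

* **bias** — median of the per-patient difference between estimated and
  reference GFR (default sign convention eGFR − sGFR, so an equation that
  underestimates has negative bias);
* **precision** — interquartile range of those differences;
* **P30 accuracy** — percentage of estimates within ±30 % of the reference
  (boundary inclusive).

95 % confidence intervals come from a percentile bootstrap over patients
(2000 resamples by default).  Two models on the same patients are compared
with the Wilcoxon signed-rank test on absolute errors (exact null for small
n, normal approximation with continuity correction otherwise) and the
McNemar test on the paired within-30 % indicators (exact binomial for few
discordant pairs, chi-square with continuity correction otherwise).
Quantiles use linear interpolation between order statistics (type 7), the
default of the major statistics environments; reported IQRs depend on this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .cohort import Cohort, PatientRecord
from .errors import EvaluationError, InsufficientDataError, ValidationError

__all__ = [
    "PairedPredictions",
    "MetricReport",
    "TestResult",
    "paired_predictions",
    "bias",
    "precision_iqr",
    "p30_accuracy",
    "bootstrap_ci",
    "compare_bias_wilcoxon",
    "compare_accuracy_mcnemar",
    "compare_cohorts",
    "table3_report",
]

#: n (non-zero pairs / discordant pairs) at or below which exact tests run.
EXACT_TEST_MAX_N = 25

# Variables reported mean ± SD and compared by t test; the rest are skewed
# and compared by Mann-Whitney.
_NORMAL_SCALE_VARIABLES = {"age", "bmi", "sgfr", "weight", "height", "bsa"}


@dataclass(frozen=True)
class PairedPredictions:
    """Reference sGFR plus one eGFR vector per model, all paired by record."""

    sgfr: np.ndarray
    egfr: Mapping[str, np.ndarray]
    sign_convention: str = "egfr_minus_sgfr"  # or "sgfr_minus_egfr"

    def __post_init__(self) -> None:
        n = len(self.sgfr)
        if n == 0 or not self.egfr:
            raise ValidationError("need at least one record and one model")
        if np.any(self.sgfr <= 0):
            raise ValidationError("all reference sGFR values must be > 0")
        for name, vals in self.egfr.items():
            if len(vals) != n:
                raise ValidationError(f"model {name!r} predictions not paired (length)")
        if self.sign_convention not in ("egfr_minus_sgfr", "sgfr_minus_egfr"):
            raise ValidationError(f"unknown sign convention {self.sign_convention!r}")

    @property
    def n(self) -> int:
        return len(self.sgfr)

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(self.egfr)

    def differences(self, model: str) -> np.ndarray:
        """Signed per-record differences under the configured convention."""
        d = self._egfr_of(model) - self.sgfr
        return d if self.sign_convention == "egfr_minus_sgfr" else -d

    def within_p30(self, model: str) -> np.ndarray:
        """Boolean indicator |eGFR − sGFR| / sGFR <= 0.30 (boundary within)."""
        return np.abs(self._egfr_of(model) - self.sgfr) / self.sgfr <= 0.30

    def _egfr_of(self, model: str) -> np.ndarray:
        if model not in self.egfr:
            raise KeyError(f"no predictions for model {model!r}")
        return np.asarray(self.egfr[model], dtype=float)


def paired_predictions(
    records: Union[Cohort, Sequence[PatientRecord]],
    models: Mapping[str, Union[Callable[[PatientRecord], float], Sequence[float]]],
    sign_convention: str = "egfr_minus_sgfr",
) -> PairedPredictions:
    """Evaluate models on records with measured sGFR.

    ``models`` maps a name to either a callable ``record -> eGFR`` or a
    precomputed prediction sequence paired with the records.
    """
    recs = list(records.records) if isinstance(records, Cohort) else list(records)
    missing = [r.id for r in recs if r.sgfr is None]
    if missing:
        raise ValidationError(f"records lacking sgfr: {missing[:5]}")
    sgfr = np.array([r.sgfr for r in recs], dtype=float)
    egfr: dict[str, np.ndarray] = {}
    for name, model in models.items():
        if callable(model):
            egfr[name] = np.array([float(model(r)) for r in recs])
        else:
            egfr[name] = np.asarray(model, dtype=float)
    return PairedPredictions(sgfr=sgfr, egfr=egfr, sign_convention=sign_convention)


def bias(paired: PairedPredictions, model: str) -> float:
    """Median signed difference (mL/min/1.73 m²)."""
    return float(np.median(paired.differences(model)))


def precision_iqr(paired: PairedPredictions, model: str) -> float:
    """IQR (Q3 − Q1, type-7 quantiles) of the signed differences."""
    d = paired.differences(model)
    if len(d) < 2:
        raise InsufficientDataError("IQR needs at least 2 records")
    q1, q3 = np.percentile(d, [25, 75])
    return float(q3 - q1)


def p30_accuracy(paired: PairedPredictions, model: str) -> float:
    """Percentage of estimates within ±30 % of the reference GFR."""
    return float(100.0 * np.mean(paired.within_p30(model)))


_METRICS: dict[str, Callable[[PairedPredictions, str], float]] = {
    "bias": bias,
    "precision": precision_iqr,
    "p30": p30_accuracy,
}


def bootstrap_ci(
    metric: Union[str, Callable[[PairedPredictions, str], float]],
    paired: PairedPredictions,
    model: str,
    reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-method 95 % CI (2.5th/97.5th percentiles over ``reps``
    resamples of records with replacement).  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = paired.n
    idx = rng.integers(0, n, size=(reps, n))
    name = metric if isinstance(metric, str) else None
    if name == "bias":
        d = paired.differences(model)
        vals = np.median(d[idx], axis=1)
    elif name == "precision":
        d = paired.differences(model)
        q1, q3 = np.percentile(d[idx], [25, 75], axis=1)
        vals = q3 - q1
    elif name == "p30":
        w = paired.within_p30(model).astype(float)
        vals = 100.0 * w[idx].mean(axis=1)
    else:
        fn = _METRICS[metric] if isinstance(metric, str) else metric
        vals = np.empty(reps)
        for r in range(reps):
            sub = PairedPredictions(
                sgfr=paired.sgfr[idx[r]],
                egfr={model: paired._egfr_of(model)[idx[r]]},
                sign_convention=paired.sign_convention,
            )
            vals[r] = fn(sub, model)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a paired significance test."""

    p_value: float
    statistic: float
    method: str
    degenerate: bool = False


def compare_bias_wilcoxon(paired: PairedPredictions, model_a: str, model_b: str) -> TestResult:
    """Wilcoxon signed-rank test on paired |error| magnitudes of two models.

    Zero within-pair differences are dropped (Wilcoxon convention).  Exact
    null enumeration for up to 25 non-zero pairs without ties; otherwise the
    normal approximation with continuity correction.  All-zero differences
    yield p = 1 with the degenerate flag set.
    """
    err_a = np.abs(paired._egfr_of(model_a) - paired.sgfr)
    err_b = np.abs(paired._egfr_of(model_b) - paired.sgfr)
    d = err_a - err_b
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return TestResult(1.0, 0.0, "wilcoxon-degenerate", degenerate=True)
    ranks = stats.rankdata(np.abs(nonzero))
    has_ties = len(np.unique(ranks)) < len(ranks)
    method = "exact" if (len(nonzero) <= EXACT_TEST_MAX_N and not has_ties) else "approx"
    res = stats.wilcoxon(err_a, err_b, zero_method="wilcox",
                         correction=True, method=method)
    return TestResult(float(res.pvalue), float(res.statistic), f"wilcoxon-{method}")


def compare_accuracy_mcnemar(paired: PairedPredictions, model_a: str, model_b: str) -> TestResult:
    """McNemar test on the paired within-30 % indicators.

    b = records where only model A is within 30 %, c = only model B.  Exact
    two-sided binomial p = min(1, 2·P(X <= min(b,c))) with X ~ Bin(b+c, ½)
    for b + c <= 25; chi-square with continuity correction above.
    """
    in_a = paired.within_p30(model_a)
    in_b = paired.within_p30(model_b)
    b = int(np.sum(in_a & ~in_b))
    c = int(np.sum(~in_a & in_b))
    n_disc = b + c
    if n_disc == 0:
        return TestResult(1.0, 0.0, "mcnemar-degenerate", degenerate=True)
    if n_disc <= EXACT_TEST_MAX_N:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5))
        return TestResult(float(p), float(min(b, c)), "mcnemar-exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / n_disc
    p = stats.chi2.sf(chi2, df=1)
    return TestResult(float(p), float(chi2), "mcnemar-chi2")


def compare_cohorts(
    cohort_a: Union[Cohort, Sequence[PatientRecord]],
    cohort_b: Union[Cohort, Sequence[PatientRecord]],
    variable: str,
) -> TestResult:
    """Two-sample comparison of one variable between independent cohorts.

    Roughly symmetric variables (age, BMI, sGFR) use the independent-samples
    t test; skewed labs (Scr, HbA1c, UACR) use the Mann-Whitney test (exact
    for small samples).
    """
    def _values(data) -> np.ndarray:
        recs = data.records if isinstance(data, Cohort) else data
        vals = [r.get(variable) for r in recs]
        vals = [v for v in vals if v is not None]
        if not vals:
            raise InsufficientDataError(f"no {variable!r} values in cohort")
        return np.asarray(vals, dtype=float)

    a, b = _values(cohort_a), _values(cohort_b)
    if variable in _NORMAL_SCALE_VARIABLES:
        res = stats.ttest_ind(a, b)
        return TestResult(float(res.pvalue), float(res.statistic), "t-test")
    method = "exact" if max(len(a), len(b)) <= EXACT_TEST_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.pvalue), float(res.statistic), f"mann-whitney-{method}")


@dataclass(frozen=True)
class MetricReport:
    """Bias / precision / P30 with bootstrap CIs for one model on one set."""

    model: str
    n: int
    bias: float
    bias_ci: tuple[float, float]
    precision: float
    precision_ci: tuple[float, float]
    accuracy_p30: float
    accuracy_p30_ci: tuple[float, float]
    p_bias_vs_reference: Optional[float] = None
    p_accuracy_vs_reference: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_p30 <= 100.0:
            raise ValidationError("accuracy_p30 must lie in [0, 100]")
        if self.precision < 0:
            raise ValidationError("precision must be >= 0")


def table3_report(
    paired: PairedPredictions,
    models: Optional[Sequence[str]] = None,
    reference: Optional[str] = None,
    reps: int = 2000,
    seed: int = 0,
) -> list[MetricReport]:
    """Per-model bias/precision/P30 with bootstrap CIs, plus Wilcoxon and
    McNemar p-values against a designated reference model (the reference's
    own p-values are reported as 1)."""
    names = list(models) if models is not None else list(paired.models)
    reports = []
    for k, name in enumerate(names):
        p_w = p_m = None
        if reference is not None:
            if name == reference:
                p_w = p_m = 1.0
            else:
                p_w = compare_bias_wilcoxon(paired, name, reference).p_value
                p_m = compare_accuracy_mcnemar(paired, name, reference).p_value
        reports.append(MetricReport(
            model=name,
            n=paired.n,
            bias=bias(paired, name),
            bias_ci=bootstrap_ci("bias", paired, name, reps, seed + k),
            precision=precision_iqr(paired, name),
            precision_ci=bootstrap_ci("precision", paired, name, reps, seed + k),
            accuracy_p30=p30_accuracy(paired, name),
            accuracy_p30_ci=bootstrap_ci("p30", paired, name, reps, seed + k),
            p_bias_vs_reference=p_w,
            p_accuracy_vs_reference=p_m,
        ))
    return reports


def report_to_rows(reports: Sequence[MetricReport]) -> list[dict]:
    """Flatten reports for delimited-text output."""
    rows = []
    for r in reports:
        rows.append({
            "model": r.model,
            "n": r.n,
            "bias": r.bias,
            "bias_ci_low": r.bias_ci[0],
            "bias_ci_high": r.bias_ci[1],
            "precision": r.precision,
            "precision_ci_low": r.precision_ci[0],
            "precision_ci_high": r.precision_ci[1],
            "accuracy_p30": r.accuracy_p30,
            "accuracy_p30_ci_low": r.accuracy_p30_ci[0],
            "accuracy_p30_ci_high": r.accuracy_p30_ci[1],
            "p_bias_vs_reference": r.p_bias_vs_reference,
            "p_accuracy_vs_reference": r.p_accuracy_vs_reference,
        })
    return rows
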