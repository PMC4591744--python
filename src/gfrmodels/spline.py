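"""Development of new eGFR regression equations.

The estimating equations regress ln(sGFR) on a two-slope linear spline in
ln(serum creatinine) with sex-specific knots (0.7 mg/dL women, 0.8 mg/dL
men), age, a female indicator, and optional natural-scale covariates (BMI,
HbA1c, UACR).  Eight standard variable sets are defined, every one
containing age, sex and creatinine:

    eq1: —            eq2: HbA1c        eq3: BMI          eq4: UACR
    eq5: HbA1c+BMI    eq6: HbA1c+UACR   eq7: BMI+UACR     eq8: all three

Plain ordinary least squares is used — no selection or shrinkage; all named
covariates enter and stay.  A nonparametric smoothing diagnostic (penalized
regression B-splines of ln sGFR on ln Scr, per sex) is provided to justify
the two-slope shape visually; it is not part of the prediction path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import BSpline

from .cohort import Cohort, PatientRecord
from .equations import SPLINE_KNOT_FEMALE, SPLINE_KNOT_MALE, SplineEquationModel
from .errors import CollinearityError, InsufficientDataError, ValidationError

__all__ = [
    "VARIABLE_SETS",
    "VariableSet",
    "FitDiagnostics",
    "fit_spline_equation",
    "fit_all_equations",
    "smoothing_spline_diagnostic",
]

#: The eight standard variable sets (covariates beyond age/sex/creatinine).
VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "eq1": (),
    "eq2": ("hba1c",),
    "eq3": ("bmi",),
    "eq4": ("uacr",),
    "eq5": ("hba1c", "bmi"),
    "eq6": ("hba1c", "uacr"),
    "eq7": ("bmi", "uacr"),
    "eq8": ("hba1c", "uacr", "bmi"),
}


@dataclass(frozen=True)
class VariableSet:
    """A named covariate set; ``name`` must be one of eq1..eq8."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in VARIABLE_SETS:
            raise ValidationError(
                f"unknown variable set {self.name!r}; expected one of {sorted(VARIABLE_SETS)}"
            )

    @property
    def covariates(self) -> tuple[str, ...]:
        return VARIABLE_SETS[self.name]


@dataclass(frozen=True)
class FitDiagnostics:
    n_used: int
    residual_sd: float  # log scale
    r_squared: float
    coefficient_se: Mapping[str, float]


def _records_of(data: Union[Cohort, Sequence[PatientRecord]],
                pool_internal: bool = False) -> list[PatientRecord]:
    """Development records of a cohort (optionally pooled with internal),
    or a plain record sequence passed through."""
    if isinstance(data, Cohort):
        recs = data.subset("development")
        if pool_internal:
            recs = recs + data.subset("internal")
        if not recs:  # unlabelled cohort: use everything
            recs = list(data.records)
        return recs
    return list(data)


def _design(records: Sequence[PatientRecord], covariates: Sequence[str],
            knot_female: float, knot_male: float):
    names = ["intercept", "log_scr_below", "log_scr_above", "age", "female"]
    names += list(covariates)
    rows, y = [], []
    for rec in records:
        if rec.sgfr is None:
            raise ValidationError(f"record {rec.id!r} lacks sgfr; cannot fit")
        kappa = knot_female if rec.female else knot_male
        z = np.log(rec.scr / kappa)
        row = [1.0, min(z, 0.0), max(z, 0.0), rec.age, 1.0 if rec.female else 0.0]
        for cov in covariates:
            val = rec.get(cov)
            if val is None:
                raise ValidationError(f"record {rec.id!r} lacks covariate {cov!r}")
            row.append(val)
        rows.append(row)
        y.append(np.log(rec.sgfr))
    return np.asarray(rows), np.asarray(y), names


def fit_spline_equation(
    data: Union[Cohort, Sequence[PatientRecord]],
    vset: Union[VariableSet, str] = "eq1",
    knot_female: float = SPLINE_KNOT_FEMALE,
    knot_male: float = SPLINE_KNOT_MALE,
    pool_internal: bool = False,
) -> tuple[SplineEquationModel, FitDiagnostics]:
    """OLS fit of ln(sGFR) on the two-slope creatinine spline design.

    Raises :class:`CollinearityError` when the design is rank deficient
    (e.g. a single-sex sample makes the female column constant, or constant
    creatinine kills both spline columns).
    """
    if isinstance(vset, str):
        vset = VariableSet(vset)
    if knot_female <= 0 or knot_male <= 0:
        raise ValidationError("knots must be positive (mg/dL)")
    records = _records_of(data, pool_internal)
    X, y, names = _design(records, vset.covariates, knot_female, knot_male)
    n, p = X.shape
    if n < p + 1:
        raise InsufficientDataError(
            f"need more than {p} records to fit {p} coefficients, have {n}"
        )
    if np.linalg.matrix_rank(X) < p:
        degenerate = [nm for j, nm in enumerate(names)
                      if j > 0 and np.ptp(X[:, j]) == 0]
        raise CollinearityError(
            "rank-deficient design"
            + (f"; constant columns: {degenerate}" if degenerate else "")
        )
    res = sm.OLS(y, X).fit()
    coefs = dict(zip(names, res.params))
    model = SplineEquationModel(
        intercept=float(coefs["intercept"]),
        slope_below=float(coefs["log_scr_below"]),
        slope_above=float(coefs["log_scr_above"]),
        age_coef=float(coefs["age"]),
        female_coef=float(coefs["female"]),
        covariate_coefs={c: float(coefs[c]) for c in vset.covariates},
        knot_female=knot_female,
        knot_male=knot_male,
    )
    diag = FitDiagnostics(
        n_used=n,
        residual_sd=float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0,
        r_squared=float(res.rsquared),
        coefficient_se=dict(zip(names, map(float, res.bse))),
    )
    return model, diag


def fit_all_equations(
    data: Union[Cohort, Sequence[PatientRecord]],
    knot_female: float = SPLINE_KNOT_FEMALE,
    knot_male: float = SPLINE_KNOT_MALE,
    pool_internal: bool = False,
    warn=None,
) -> dict[str, tuple[SplineEquationModel, FitDiagnostics]]:
    """Fit every standard variable set whose covariates the data carry.

    Sets needing an absent covariate are skipped (reported through ``warn``,
    a callable taking a message, when given).
    """
    records = _records_of(data, pool_internal)
    if not records:
        raise InsufficientDataError("no records to fit")
    available = {c for c in ("bmi", "hba1c", "uacr")
                 if all(r.get(c) is not None for r in records)}
    out = {}
    for name, covs in VARIABLE_SETS.items():
        missing = set(covs) - available
        if missing:
            if warn is not None:
                warn(f"skipping {name}: covariate(s) {sorted(missing)} absent")
            continue
        out[name] = fit_spline_equation(records, name, knot_female, knot_male)
    return out


@dataclass(frozen=True)
class SmoothCurve:
    """A fitted per-sex smooth of ln(sGFR) vs ln(Scr), evaluable on a grid."""

    spline: BSpline
    df: int
    gcv: float
    x_min: float
    x_max: float

    def __call__(self, log_scr_grid) -> np.ndarray:
        x = np.clip(np.asarray(log_scr_grid, dtype=float), self.x_min, self.x_max)
        return self.spline(x)


def _fit_bspline(x: np.ndarray, y: np.ndarray, df: int) -> tuple[BSpline, float]:
    # cubic regression B-splines, interior knots at quantiles; GCV score
    k = 3
    n_interior = max(df - (k + 1), 0)
    lo, hi = x.min(), x.max()
    pad = max(1e-9, 1e-9 * (hi - lo))
    if n_interior > 0:
        qs = np.linspace(0, 100, n_interior + 2)[1:-1]
        interior = np.percentile(x, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[lo - pad] * (k + 1), interior, [hi + pad] * (k + 1)])
    B = BSpline.design_matrix(x, t, k).toarray()
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    n, p = B.shape
    gcv = (resid @ resid / n) / (1.0 - min(p, n - 1) / n) ** 2
    return BSpline(t, coef, k), float(gcv)


def smoothing_spline_diagnostic(
    data: Union[Cohort, Sequence[PatientRecord]],
    df_grid: Sequence[int] = (4, 5, 6, 8, 10),
    min_per_sex: int = 20,
) -> dict[str, SmoothCurve]:
    """Per-sex nonparametric smooth of ln(sGFR) on ln(Scr).

    For each sex the basis dimension is chosen from ``df_grid`` by
    generalized cross-validation.  The curves are a shape diagnostic used to
    justify the two-slope linear approximation; they never enter prediction.
    """
    records = [r for r in _records_of(data) if r.sgfr is not None]
    out: dict[str, SmoothCurve] = {}
    for sex in ("female", "male"):
        sub = [r for r in records if r.sex == sex]
        if len(sub) < min_per_sex:
            raise InsufficientDataError(
                f"need >= {min_per_sex} {sex} records with sGFR, have {len(sub)}"
            )
        x = np.log([r.scr for r in sub])
        y = np.log([r.sgfr for r in sub])
        best: Optional[SmoothCurve] = None
        for df in df_grid:
            if df < 4 or df >= len(sub):
                continue
            spl, gcv = _fit_bspline(x, y, df)
            if best is None or gcv < best.gcv:
                best = SmoothCurve(spl, df, gcv, float(x.min()), float(x.max()))
        if best is None:
            raise ValidationError(f"df_grid {df_grid} has no feasible entry")
        out[sex] = best
    return out
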