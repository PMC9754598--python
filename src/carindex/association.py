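"""Bivariate association and z-standardized polynomial regression.

Associations between city characteristics and the CRI are assessed with
Pearson's correlation when both variables are plausibly Gaussian
(Shapiro-Wilk at a configurable alpha) and Spearman's rank correlation
otherwise.  The regression models are ordinary least squares of CRI on a
z-transformed exposure (one of the ICE variants), optionally with its
square (degree 2, testing a convex/U-shaped relationship), plus raw-scale
demographic covariates chosen from a confounder DAG.

Raw (non-orthogonal) polynomial terms are used on the z-scored exposure so
the linear and quadratic coefficients are separately interpretable, and
two-sided p-values come from the t distribution with residual degrees of
freedom.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .demography import COVARIATE_LABELS, ICE_VARIANTS, CovariateSet, ICEProfile
from .errors import (
    CollinearityError,
    DegenerateVariableError,
    InsufficientDataError,
    InvalidInputError,
    InvalidLabelError,
)

#: Variables treated as Gaussian a priori in the bivariate screen (so
#: tested with Pearson's r); everything else defaults to the data-driven
#: Shapiro-Wilk choice.  Override per study via StudyConfig.
GAUSSIAN_ASSUMED = ("prop_65plus", "property_rate", "ice_income", "ice_education")


@dataclass(frozen=True)
class CityRecord:
    """One analysis row: a city's CRI, ICE profile, and covariates."""

    city: str
    cri: float
    ice: ICEProfile
    covariates: CovariateSet

    def __post_init__(self):
        if not -1.0 <= self.cri <= 1.0:
            raise InvalidInputError(f"{self.city}: CRI {self.cri} outside [-1, 1]")
        if all(v is None for v in self.ice.as_dict().values()):
            raise InvalidInputError(f"{self.city}: no ICE value present")

    def as_dict(self) -> dict:
        row: dict = {"city": self.city, "cri": self.cri}
        row.update(self.ice.as_dict())
        row.update(self.covariates.as_dict())
        return row


def records_frame(records: Sequence[CityRecord]) -> pd.DataFrame:
    """City-by-variable DataFrame (index: city), missing values as NaN."""
    df = pd.DataFrame([r.as_dict() for r in records]).set_index("city")
    return df.astype(float)


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int

    def __post_init__(self):
        if self.method not in ("pearson", "spearman"):
            raise InvalidInputError(f"unknown method {self.method!r}")
        if abs(self.coefficient) > 1 + 1e-12:
            raise InvalidInputError(f"|coefficient| {self.coefficient} > 1")
        if self.n < 3:
            raise InsufficientDataError(f"n = {self.n} < 3")


@dataclass(frozen=True)
class ModelSpec:
    """One regression model: exposure, polynomial degree, adjustment set."""

    exposure: str
    degree: int = 2
    adjust: tuple[str, ...] = ()
    name: str | None = None

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise InvalidInputError(f"degree must be 1 or 2, got {self.degree}")
        if self.exposure not in ICE_VARIANTS:
            raise InvalidLabelError(f"unknown exposure {self.exposure!r}")
        object.__setattr__(self, "adjust", tuple(self.adjust))
        for label in self.adjust:
            if label not in COVARIATE_LABELS:
                raise InvalidLabelError(f"unknown covariate {label!r}")

    @property
    def label(self) -> str:
        return self.name or self.exposure


#: Default adjustment sets: Model 1 (income ICE) adjusts for age >=65 and
#: non-Hispanic-White shares; Model 2 (education ICE) additionally for the
#: >$100k income share; Models 3-4 (combined race+income ICEs) for age >=65
#: only, race and income being part of the exposure itself.
DEFAULT_MODELS = (
    ModelSpec("ice_income", 2, ("prop_65plus", "prop_nh_white"), name="Model 1"),
    ModelSpec(
        "ice_education", 2, ("prop_65plus", "prop_nh_white", "prop_income_gt100k"),
        name="Model 2",
    ),
    ModelSpec("ice_wb_income", 2, ("prop_65plus",), name="Model 3"),
    ModelSpec("ice_wpc_income", 2, ("prop_65plus",), name="Model 4"),
)


@dataclass(frozen=True)
class FitResult:
    """Coefficient table and per-city residual information for one model.

    ``coefficients`` is indexed by term (``const``, the exposure label,
    ``<exposure>^2`` when degree 2, then covariates) with columns
    ``coef``, ``se``, ``p_value``, plus 95% CI bounds.
    """

    spec: ModelSpec
    coefficients: pd.DataFrame
    adjusted_r2: float
    n: int
    residuals: pd.Series
    fitted: pd.Series
    exposure_z: pd.Series

    def __post_init__(self):
        expected = 1 + self.spec.degree + len(self.spec.adjust)
        if len(self.coefficients) != expected:
            raise InvalidInputError(
                f"{len(self.coefficients)} coefficient rows, expected {expected}"
            )
        if self.adjusted_r2 > 1 + 1e-12:
            raise InvalidInputError(f"adjusted R^2 {self.adjusted_r2} > 1")

    @property
    def quad_term(self) -> str:
        return f"{self.spec.exposure}^2"

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "coef"])


def standardize(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """z-transformation: mean 0, unit sample SD (divisor n-1).

    Missing entries (NaN) are ignored for the mean/SD and preserved in the
    output.  A variable with zero spread cannot be standardized.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(f"need >= 2 non-missing values, got {n}")
    mean = arr[mask].mean()
    sd = arr[mask].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateVariableError("zero spread: cannot z-standardize")
    out = np.full_like(arr, np.nan)
    out[mask] = (arr[mask] - mean) / sd
    return out


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("x and y must be the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def choose_method(x, y, alpha: float = 0.05) -> str:
    """Pick Pearson vs Spearman from per-variable Shapiro-Wilk normality.

    Pearson only when both variables pass Shapiro-Wilk at ``alpha``;
    any failure, tie-degenerate input, or sample too small for the test
    falls back conservatively to Spearman.
    """
    x, y = _complete_pairs(x, y)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(x)}")
    for arr in (x, y):
        if np.ptp(arr) == 0:
            return "spearman"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = stats.shapiro(arr).pvalue
        except Exception:
            return "spearman"
        if not np.isfinite(p) or p < alpha:
            return "spearman"
    return "pearson"


def bivariate(x, y, method: str | None = None, alpha: float = 0.05) -> CorrelationResult:
    """Correlation between two variables after pairwise deletion.

    ``method`` may be forced; by default it is chosen per
    :func:`choose_method`.
    """
    xc, yc = _complete_pairs(x, y)
    if len(xc) < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {len(xc)}")
    if method is None:
        method = choose_method(xc, yc, alpha=alpha)
    if method == "pearson":
        res = stats.pearsonr(xc, yc)
    elif method == "spearman":
        res = stats.spearmanr(xc, yc)
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    coef = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(p):  # degenerate (e.g. constant) input
        p = 1.0
    return CorrelationResult(method=method, coefficient=coef, p_value=p, n=len(xc))


def _design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    cols = ["cri", spec.exposure, *spec.adjust]
    data = df[cols].dropna()
    n_params = 1 + spec.degree + len(spec.adjust)
    if len(data) < n_params + 2:
        raise InsufficientDataError(
            f"{len(data)} complete cases for {n_params} parameters "
            f"(need >= {n_params + 2})"
        )
    z = standardize(data[spec.exposure].to_numpy())
    design = pd.DataFrame({"const": 1.0, spec.exposure: z}, index=data.index)
    if spec.degree == 2:
        design[f"{spec.exposure}^2"] = z**2
    for label in spec.adjust:
        design[label] = data[label]
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name columns loading on the null space
        _, sv, vt = np.linalg.svd(design.to_numpy())
        bad = np.abs(vt[rank:]).sum(axis=0) > 1e-8
        offenders = [c for c, b in zip(design.columns, bad) if b]
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {design.shape[1]})", columns=offenders
        )
    return design, data["cri"]


def fit_model(records: Sequence[CityRecord] | pd.DataFrame, spec: ModelSpec) -> FitResult:
    """OLS of CRI on the z-scored exposure (+ square) and raw covariates.

    Complete-case per model: rows missing the exposure or any covariate in
    this model's adjustment set are dropped, and the exposure is z-scored
    within the retained rows.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    design, y = _design(df, spec)
    model = sm.OLS(y, design)
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)
    coefficients = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "p_value": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )
    return FitResult(
        spec=spec,
        coefficients=coefficients,
        adjusted_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        residuals=pd.Series(fit.resid, index=design.index, name="residual"),
        fitted=pd.Series(fit.fittedvalues, index=design.index, name="fitted"),
        exposure_z=design[spec.exposure],
    )


@dataclass(frozen=True)
class DiagnosticsBundle:
    """Residual diagnostics for heteroscedasticity/normality/curvature checks.

    ``resid_fitted`` holds (fitted, residual) pairs for a residuals-vs-
    fitted plot; ``qq`` holds (theoretical, ordered-residual) quantile
    pairs for a normal probability plot; the curvature indicator is the
    slope (with p-value) of residuals regressed on squared fitted values
    — significant curvature suggests a missing quadratic term.
    """

    resid_fitted: pd.DataFrame
    qq: pd.DataFrame
    curvature_slope: float
    curvature_p: float


def diagnostics(fit: FitResult) -> DiagnosticsBundle:
    """Residual diagnostics for one fitted model."""
    resid = fit.residuals
    if len(resid) < 5:
        raise InsufficientDataError("need >= 5 residuals for diagnostics")
    resid_fitted = pd.DataFrame({"fitted": fit.fitted, "residual": resid})
    (osm, osr), _ = stats.probplot(resid.to_numpy(), dist="norm")
    qq = pd.DataFrame({"theoretical": osm, "ordered_residual": osr})
    curv_design = sm.add_constant(pd.DataFrame({"fitted_sq": fit.fitted**2}))
    curv = sm.OLS(resid, curv_design).fit()
    return DiagnosticsBundle(
        resid_fitted=resid_fitted,
        qq=qq,
        curvature_slope=float(curv.params["fitted_sq"]),
        curvature_p=float(curv.pvalues["fitted_sq"]),
    )


def partial_residuals(fit: FitResult, exposure: str | None = None) -> pd.DataFrame:
    """Partial residuals for the exposure: residual + exposure contribution.

    Each city's partial residual adds back the fitted linear (and, for
    degree-2 models, quadratic) exposure terms, isolating the exposure-CRI
    relationship net of covariates.  Returns columns ``z`` and
    ``partial_residual`` indexed by city.
    """
    if exposure is None:
        exposure = fit.spec.exposure
    if exposure != fit.spec.exposure:
        raise InvalidLabelError(
            f"exposure {exposure!r} not in this fit (has {fit.spec.exposure!r})"
        )
    z = fit.exposure_z
    contribution = fit.coef(exposure) * z
    if fit.spec.degree == 2:
        contribution = contribution + fit.coef(fit.quad_term) * z**2
    return pd.DataFrame({"z": z, "partial_residual": fit.residuals + contribution})
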