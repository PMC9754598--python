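"""Correlation-method choice, z-scored polynomial OLS, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from carindex import (
    CityRecord,
    ModelSpec,
    bivariate,
    choose_method,
    diagnostics,
    fit_model,
    partial_residuals,
    standardize,
)
from carindex.association import records_frame
from carindex.demography import CovariateSet, ICEProfile
from carindex.errors import (
    CollinearityError,
    DegenerateVariableError,
    InsufficientDataError,
    InvalidLabelError,
)


def _records(x, cri, **covariates):
    """CityRecords with ice_wb_income = x and given covariate vectors."""
    n = len(x)
    cov_rows = [
        {k: (v[i] if np.ndim(v) else v) for k, v in covariates.items()} for i in range(n)
    ]
    return [
        CityRecord(
            city=f"c{i}",
            cri=float(cri[i]),
            ice=ICEProfile(ice_wb_income=float(np.clip(x[i], -1, 1))),
            covariates=CovariateSet(**cov_rows[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# standardize


def test_standardize_basic():
    np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])


def test_standardize_idempotent():
    z = standardize(np.arange(10.0))
    np.testing.assert_allclose(standardize(z), z, atol=1e-12)


def test_standardize_preserves_missing():
    out = standardize([1.0, np.nan, 3.0])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], [-np.sqrt(0.5), np.sqrt(0.5)])


def test_standardize_degenerate():
    with pytest.raises(DegenerateVariableError):
        standardize([2.0, 2.0, 2.0])
    with pytest.raises(InsufficientDataError):
        standardize([1.0])


# ---------------------------------------------------------------------------
# method choice and bivariate


def test_choose_method_gaussian_vs_skewed():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    assert choose_method(x, y) == "pearson"
    assert choose_method(np.exp(3 * x), y) == "spearman"


def test_choose_method_pathological_small_sample():
    assert choose_method([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == "spearman"


def test_bivariate_monotone():
    x = np.arange(10.0)
    up = bivariate(x, np.exp(x), method="spearman")
    assert up.coefficient == pytest.approx(1.0)
    down = bivariate(x, -(x**3), method="spearman")
    assert down.coefficient == pytest.approx(-1.0)
    with pytest.raises(InsufficientDataError):
        bivariate([1, 2], [1, 2])


def test_bivariate_pairwise_deletion():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [1.0, np.nan, 3.0, 4.0, 5.0]
    res = bivariate(x, y, method="pearson")
    assert res.n == 3


def test_bivariate_null_calibrated():
    """Independent permutations rarely reach p < 0.05."""
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        y = rng.normal(size=50)
        x = rng.permutation(y)
        if bivariate(x, y, method="spearman").p_value > 0.05:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    base = bivariate(x, y, method="spearman")
    warped = bivariate(np.exp(x), np.arctan(y), method="spearman")
    assert warped.coefficient == pytest.approx(base.coefficient, abs=1e-12)
    assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# model fitting


def test_noiseless_quadratic_recovered_exactly():
    x = np.linspace(-0.2, 0.2, 40)
    z = standardize(x)
    cri = 0.5 * z**2 - 0.6
    fit = fit_model(_records(x, cri), ModelSpec("ice_wb_income", 2))
    assert fit.coef("ice_wb_income^2") == pytest.approx(0.5, abs=1e-8)
    assert fit.coef("ice_wb_income") == pytest.approx(0.0, abs=1e-8)
    assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-8)
    assert fit.coefficients.shape[0] == 3


def test_noiseless_linear_recovered_exactly():
    x = np.linspace(-0.2, 0.2, 25)
    cri = 0.3 * standardize(x) + 0.1
    fit = fit_model(_records(x, cri), ModelSpec("ice_wb_income", 1))
    assert fit.coef("const") == pytest.approx(0.1, abs=1e-10)
    assert fit.coef("ice_wb_income") == pytest.approx(0.3, abs=1e-10)


def test_degree1_matches_independent_lstsq():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.1, 30)
    cri = np.clip(0.2 * x / x.std(ddof=1) + rng.normal(0, 0.05, 30), -1, 1)
    fit = fit_model(_records(x, cri), ModelSpec("ice_wb_income", 1))
    z = standardize(x)
    design = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(design, cri, rcond=None)
    np.testing.assert_allclose(
        fit.coefficients["coef"].to_numpy(), beta, atol=1e-10
    )


def test_coefficients_invariant_to_affine_exposure_transform():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.05, 40)
    cri = np.clip(-0.4 + 0.3 * standardize(x) + 0.2 * standardize(x) ** 2
                  + rng.normal(0, 0.05, 40), -1, 1)
    spec = ModelSpec("ice_wb_income", 2)
    base = fit_model(_records(x, cri), spec)
    moved = fit_model(_records(5 * x + 0.01, cri), spec)
    np.testing.assert_allclose(
        base.coefficients["coef"], moved.coefficients["coef"], atol=1e-10
    )


def test_residuals_orthogonal_to_design(small_cohort):
    from carindex.demography import compute_covariates, ice_profile

    records = [
        CityRecord(c.name, c.truth["cri"], ice_profile(c.bundle),
                   compute_covariates(c.bundle.age, c.bundle.income, c.bundle.race,
                                      c.bundle.crime))
        for c in small_cohort.cities
    ]
    fit = fit_model(records, ModelSpec("ice_wb_income", 2, ("prop_65plus",)))
    resid = fit.residuals.to_numpy()
    z = fit.exposure_z.to_numpy()
    df = records_frame(records).loc[fit.residuals.index]
    for column in (np.ones_like(z), z, z**2, df["prop_65plus"].to_numpy()):
        assert abs(resid @ column) < 1e-8


def test_adjustment_covariate_in_table():
    rng = np.random.default_rng(6)
    n = 40
    x = rng.normal(0, 0.1, n)
    age = rng.uniform(0.1, 0.3, n)
    cri = np.clip(-0.4 + 0.5 * age + 0.2 * standardize(x), -1, 1)
    fit = fit_model(
        _records(x, cri, prop_65plus=age), ModelSpec("ice_wb_income", 1, ("prop_65plus",))
    )
    assert fit.coef("prop_65plus") == pytest.approx(0.5, abs=1e-8)
    assert list(fit.coefficients.index) == ["const", "ice_wb_income", "prop_65plus"]


def test_collinear_design_names_offenders():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.1, 30)
    age = rng.uniform(0.1, 0.3, 30)
    rich = 0.5 * age + 0.1  # exact affine duplicate of the age covariate
    cri = np.clip(0.2 * standardize(x), -1, 1)
    with pytest.raises(CollinearityError) as excinfo:
        fit_model(
            _records(x, cri, prop_65plus=age, prop_income_gt100k=rich),
            ModelSpec("ice_wb_income", 1, ("prop_65plus", "prop_income_gt100k")),
        )
    assert set(excinfo.value.columns) >= {"prop_65plus", "prop_income_gt100k"}


def test_too_few_complete_cases():
    x = np.array([0.1, 0.2, 0.3, 0.4])
    with pytest.raises(InsufficientDataError):
        fit_model(_records(x, 0.1 * x), ModelSpec("ice_wb_income", 2))


# ---------------------------------------------------------------------------
# diagnostics and partial residuals


def test_diagnostics_noiseless_fit_has_zero_residuals():
    x = np.linspace(-0.2, 0.2, 20)
    z = standardize(x)
    fit = fit_model(_records(x, 0.4 * z**2 - 0.5), ModelSpec("ice_wb_income", 2))
    bundle = diagnostics(fit)
    assert np.abs(bundle.resid_fitted["residual"]).max() < 1e-10
    assert len(bundle.qq) == 20


def test_curvature_detected_when_quadratic_omitted():
    rng = np.random.default_rng(8)
    detected = 0
    n_rep = 40
    for _ in range(n_rep):
        x = rng.uniform(-0.2, 0.2, 50)
        z = (x - x.mean()) / x.std(ddof=1)
        # centered outcome: the fitted-squared statistic targets pure
        # curvature rather than leaking the linear term via the intercept
        cri = np.clip(-0.25 + 0.25 * z + 0.25 * z**2 + rng.normal(0, 0.05, 50), -1, 1)
        fit = fit_model(_records(x, cri), ModelSpec("ice_wb_income", 1))
        if diagnostics(fit).curvature_p < 0.05:
            detected += 1
    assert detected >= 0.9 * n_rep


def test_partial_residuals_no_covariates_equal_cri_minus_intercept():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 0.1, 30)
    cri = np.clip(-0.3 + 0.2 * standardize(x) + rng.normal(0, 0.05, 30), -1, 1)
    fit = fit_model(_records(x, cri), ModelSpec("ice_wb_income", 2))
    pr = partial_residuals(fit)
    np.testing.assert_allclose(
        pr["partial_residual"].to_numpy(), cri - fit.coef("const"), atol=1e-10
    )


def test_partial_residuals_on_noiseless_parabola():
    x = np.linspace(-0.2, 0.2, 20)
    z = standardize(x)
    fit = fit_model(_records(x, 0.4 * z**2 - 0.5), ModelSpec("ice_wb_income", 2))
    pr = partial_residuals(fit)
    expected = fit.coef("ice_wb_income") * pr["z"] + fit.coef("ice_wb_income^2") * pr["z"] ** 2
    np.testing.assert_allclose(pr["partial_residual"], expected, atol=1e-10)
    with pytest.raises(InvalidLabelError):
        partial_residuals(fit, "ice_income")


# ---------------------------------------------------------------------------
# parameter recovery across a (beta1, beta2) grid


@pytest.mark.parametrize(("beta1", "beta2"), [(0.3, 0.0), (0.0, 0.3)])
def test_ci_coverage_of_planted_coefficients(beta1, beta2):
    """95% CIs cover planted link coefficients at close-to-nominal rates."""
    from carindex import CohortSpec, generate_cohort
    from carindex.demography import compute_covariates, ice_profile
    from carindex.synthetic_data import LinkBlock

    n_rep = 150
    covered1 = covered2 = 0
    spec_model = ModelSpec("ice_wb_income", 2)
    for rep in range(n_rep):
        cohort = generate_cohort(
            CohortSpec(n_cities=50, seed=10_000 + rep,
                       link=LinkBlock(beta1=beta1, beta2=beta2))
        )
        records = [
            CityRecord(c.name, c.truth["cri"], ice_profile(c.bundle),
                       compute_covariates(c.bundle.age, c.bundle.income,
                                          c.bundle.race, c.bundle.crime))
            for c in cohort.cities
        ]
        fit = fit_model(records, spec_model)
        lo1, hi1 = fit.coefficients.loc["ice_wb_income", ["ci_low", "ci_high"]]
        lo2, hi2 = fit.coefficients.loc["ice_wb_income^2", ["ci_low", "ci_high"]]
        covered1 += lo1 <= beta1 <= hi1
        covered2 += lo2 <= beta2 <= hi2
    assert covered1 / n_rep >= 0.90
    assert covered2 / n_rep >= 0.90
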