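"""ICE variants, covariates, and crime rates from count tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carindex import (
    AgeTable,
    CrimeCounts,
    DemographicBundle,
    EducationTable,
    IncomeTable,
    RaceTable,
    TenureTable,
    compute_covariates,
    compute_ice,
    crime_rate,
    ice_profile,
    ice_variant,
)
from carindex.demography import (
    ICE_VARIANTS,
    load_demographics,
    write_table_csv,
)
from carindex.errors import (
    DegeneratePopulationError,
    InconsistentCountsError,
    MissingDataError,
)


@pytest.mark.parametrize(
    ("a", "p", "t", "expected"),
    [(100, 0, 100, 1.0), (0, 100, 100, -1.0), (30, 10, 100, 0.2), (0, 0, 50, 0.0)],
)
def test_compute_ice(a, p, t, expected):
    assert compute_ice(a, p, t) == pytest.approx(expected)


def test_compute_ice_errors():
    with pytest.raises(DegeneratePopulationError):
        compute_ice(0, 0, 0)
    with pytest.raises(InconsistentCountsError):
        compute_ice(60, 50, 100)


def _income(cells):
    return IncomeTable(cells=cells, total_households=sum(cells.values()))


def _bundle(**kwargs):
    return DemographicBundle(city="X", **kwargs)


def test_ice_income_symmetry():
    # 25% of households over $100k and 25% under $25k cancel exactly
    income = _income({
        ("under_25k", "white_nh"): 100, ("under_25k", "black"): 100,
        ("from_25k_to_100k", "other"): 400,
        ("over_100k", "white_nh"): 150, ("over_100k", "black"): 50,
    })
    assert ice_variant(_bundle(income=income), "ice_income") == pytest.approx(0.0)


def test_ice_wpc_income_example():
    income = _income({
        ("over_100k", "white_nh"): 200,
        ("under_25k", "white_nh"): 100, ("under_25k", "black"): 150,
        ("under_25k", "other"): 50,
        ("from_25k_to_100k", "other"): 500,
    })
    # deprived = all <$25k (300) minus white NH <$25k (100) = 200
    assert ice_variant(_bundle(income=income), "ice_wpc_income") == pytest.approx(0.0)


def test_ice_wb_homeownership_example():
    tenure = TenureTable(
        cells={
            ("owner", "white_nh"): 400, ("owner", "black"): 100,
            ("renter", "black"): 100, ("renter", "white_nh"): 150,
            ("renter", "other"): 250,
        },
        total_occupied_units=1000,
    )
    assert ice_variant(_bundle(tenure=tenure), "ice_wb_homeownership") == pytest.approx(0.3)


def test_wb_equals_wpc_when_other_deprived_strata_empty():
    income = _income({
        ("over_100k", "white_nh"): 200,
        ("under_25k", "black"): 150,
        ("from_25k_to_100k", "white_nh"): 650,
    })
    bundle = _bundle(income=income)
    assert ice_variant(bundle, "ice_wb_income") == ice_variant(bundle, "ice_wpc_income")


def test_missing_table_signals_missing():
    bundle = _bundle(race=RaceTable(10, 5, 5, 20))
    with pytest.raises(MissingDataError):
        ice_variant(bundle, "ice_income")
    profile = ice_profile(bundle)
    assert profile.ice_income is None
    assert profile.ice_race_wb == pytest.approx(0.25)


@st.composite
def income_tables(draw):
    counts = draw(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=9, max_size=9)
    )
    if sum(counts) == 0:
        counts[0] = 1
    keys = [(b, s) for b in ("under_25k", "from_25k_to_100k", "over_100k")
            for s in ("white_nh", "black", "other")]
    return _income(dict(zip(keys, counts)))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(income_tables())
def test_income_ice_variants_bounded(income):
    bundle = _bundle(income=income)
    for variant in ("ice_income", "ice_wb_income", "ice_wpc_income"):
        assert -1.0 <= ice_variant(bundle, variant) <= 1.0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(income_tables(), st.integers(min_value=2, max_value=20))
def test_ice_invariant_under_uniform_scaling(income, k):
    bundle = _bundle(income=income)
    scaled = _bundle(income=_income({key: k * n for key, n in income.cells.items()}))
    for variant in ("ice_income", "ice_wb_income", "ice_wpc_income"):
        assert ice_variant(scaled, variant) == pytest.approx(
            ice_variant(bundle, variant), abs=1e-12
        )


def test_moving_one_unit_shifts_ice_by_2_over_t():
    base = {("under_25k", "black"): 50, ("over_100k", "white_nh"): 30,
            ("from_25k_to_100k", "other"): 120}
    shifted = {("under_25k", "black"): 49, ("over_100k", "white_nh"): 31,
               ("from_25k_to_100k", "other"): 120}
    t = 200
    before = ice_variant(_bundle(income=_income(base)), "ice_wb_income")
    after = ice_variant(_bundle(income=_income(shifted)), "ice_wb_income")
    assert after - before == pytest.approx(2 / t, abs=1e-12)


def test_ice_variant_matches_manual_extraction(small_cohort):
    """Every variant equals (A - P)/T with cells pulled out by hand."""
    for city in small_cohort.cities:
        b = city.bundle
        inc, ten = b.income.cells, b.tenure.cells
        under = sum(n for (br, _), n in inc.items() if br == "under_25k")
        over = sum(n for (br, _), n in inc.items() if br == "over_100k")
        renters = sum(n for (t, _), n in ten.items() if t == "renter")
        manual = {
            "ice_income": (over - under) / b.income.total_households,
            "ice_education": (b.education.college_4plus - b.education.less_than_hs)
            / b.education.total_adults25,
            "ice_race_wb": (b.race.white_nh - b.race.black_nh) / b.race.total_population,
            "ice_wb_income": (inc[("over_100k", "white_nh")] - inc[("under_25k", "black")])
            / b.income.total_households,
            "ice_wpc_income": (
                inc[("over_100k", "white_nh")] - (under - inc[("under_25k", "white_nh")])
            ) / b.income.total_households,
            "ice_wb_homeownership": (
                ten[("owner", "white_nh")] - ten[("renter", "black")]
            ) / b.tenure.total_occupied_units,
            "ice_wpc_homeownership": (
                ten[("owner", "white_nh")] - (renters - ten[("renter", "white_nh")])
            ) / b.tenure.total_occupied_units,
        }
        for variant in ICE_VARIANTS:
            assert ice_variant(b, variant) == pytest.approx(manual[variant], abs=1e-15)


def test_compute_covariates():
    age = AgeTable(under_18=180, from_18_to_64=600, age_65_plus=220, total_population=1000)
    income = _income({("under_25k", "black"): 200, ("over_100k", "white_nh"): 300,
                      ("from_25k_to_100k", "other"): 500})
    race = RaceTable(white_nh=1000, black_nh=0, other=0, total_population=1000)
    crime = CrimeCounts(violent_count=100, property_count=50, population=50_000, year=2016)
    cov = compute_covariates(age, income, race, crime)
    assert cov.prop_under18 == pytest.approx(0.18)
    assert cov.prop_65plus == pytest.approx(0.22)
    assert cov.prop_income_lt25k == pytest.approx(0.2)
    assert cov.prop_income_gt100k == pytest.approx(0.3)
    assert cov.prop_nh_white == 1.0
    assert cov.violent_rate == pytest.approx(200.0)
    assert cov.property_rate == pytest.approx(100.0)


def test_covariates_without_crime():
    age = AgeTable(100, 800, 100, 1000)
    cov = compute_covariates(age, None, None, None)
    assert cov.violent_rate is None and cov.property_rate is None
    assert cov.prop_under18 == pytest.approx(0.1)
    assert cov.prop_income_lt25k is None


def test_crime_rate():
    assert crime_rate(100, 50_000) == pytest.approx(200.0)
    assert crime_rate(0, 1000) == 0.0
    with pytest.raises(DegeneratePopulationError):
        crime_rate(1, 0)


def test_table_invariants_enforced():
    with pytest.raises(InconsistentCountsError):
        RaceTable(white_nh=10, black_nh=10, other=10, total_population=40)
    with pytest.raises(DegeneratePopulationError):
        CrimeCounts(violent_count=1, property_count=1, population=0, year=2016)


def test_table_csv_round_trip(tmp_path):
    income_cells = {"cityA": {"under_25k:black": 10, "over_100k:white_nh": 20,
                              "from_25k_to_100k:other": 70}}
    write_table_csv(tmp_path / "income.csv", "income", income_cells)
    (tmp_path / "crime.csv").write_text(
        "city,year,violent_count,property_count,population\ncityA,2016,12,30,40000\n"
    )
    bundles = load_demographics(
        income_path=tmp_path / "income.csv", crime_path=tmp_path / "crime.csv"
    )
    bundle = bundles["cityA"]
    assert bundle.income.total_households == 100
    assert ice_variant(bundle, "ice_wb_income") == pytest.approx(0.1)
    assert bundle.crime.violent_count == 12
    assert bundle.education is None
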