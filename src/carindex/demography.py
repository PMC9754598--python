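"""Demographic count tables, the seven ICE variants, and covariates.

The Index of Concentration at the Extremes (ICE; Massey) measures how far
a population is concentrated into a privileged extreme versus a deprived
extreme::

    ICE = (A - P) / T

where ``A`` counts members of the privileged group, ``P`` the deprived
group, and ``T`` the relevant denominator population.  ICE ranges from -1
(everyone deprived) to +1 (everyone privileged).

Seven variants are computed from census-style count tables (ACS table
structures B19001, B15002, B03002, S2502, S0101):

========================  =============================================  ==================
variant                   A - P                                          T
========================  =============================================  ==================
ice_income                >$100k households - <$25k households           total households
ice_education             >=4yr college adults - <HS adults              adults >= 25
ice_race_wb               white NH persons - Black NH persons            total population
ice_wb_income             white NH >$100k - Black alone <$25k            total households
ice_wpc_income            white NH >$100k - (all <$25k - white NH <$25k) total households
ice_wb_homeownership      white NH owner units - Black renter units      occupied units
ice_wpc_homeownership     white NH owner - (all renter - white NH renter) occupied units
========================  =============================================  ==================

Denominators deliberately differ across variants (households, adults >=25,
persons, occupied housing units) and match each source table's universe.
The "wpc" (white vs. people of color) variants define the deprived count
as the total deprived minus the white-non-Hispanic deprived.

Missing tables propagate as ``None`` (never zero): a city missing a table
is excluded only from analyses that need that variant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    DegeneratePopulationError,
    InconsistentCountsError,
    InvalidInputError,
    InvalidLabelError,
    MissingDataError,
)

INCOME_BRACKETS = ("under_25k", "from_25k_to_100k", "over_100k")
RACE_STRATA = ("white_nh", "black", "other")
TENURES = ("owner", "renter")

ICE_VARIANTS = (
    "ice_income",
    "ice_education",
    "ice_race_wb",
    "ice_wb_income",
    "ice_wpc_income",
    "ice_wb_homeownership",
    "ice_wpc_homeownership",
)

COVARIATE_LABELS = (
    "prop_under18",
    "prop_65plus",
    "prop_income_lt25k",
    "prop_income_gt100k",
    "prop_nh_white",
    "violent_rate",
    "property_rate",
)


def _check_counts(counts: Iterable[int], total: int, what: str) -> None:
    counts = list(counts)
    if any(c < 0 for c in counts):
        raise InvalidInputError(f"{what}: negative cell count")
    if total < 0:
        raise InvalidInputError(f"{what}: negative total")
    if sum(counts) != total:
        raise InconsistentCountsError(
            f"{what}: cells sum to {sum(counts)} but total is {total}"
        )


@dataclass(frozen=True)
class IncomeTable:
    """Household counts by income bracket x race stratum (B19001 shape).

    Brackets are collapsed to the three bins the analysis uses
    (<$25k, $25k-$100k, >$100k); finer bins should be aggregated at
    ingest with :func:`coarsen_income_bins`.
    """

    cells: Mapping[tuple[str, str], int]
    total_households: int

    def __post_init__(self):
        for key in self.cells:
            bracket, stratum = key
            if bracket not in INCOME_BRACKETS or stratum not in RACE_STRATA:
                raise InvalidLabelError(f"unknown income cell {key!r}")
        _check_counts(self.cells.values(), self.total_households, "income table")

    def bracket_total(self, bracket: str) -> int:
        return sum(n for (b, _), n in self.cells.items() if b == bracket)

    def cell(self, bracket: str, stratum: str) -> int:
        return self.cells.get((bracket, stratum), 0)


@dataclass(frozen=True)
class EducationTable:
    """Adults >=25 by attainment (B15002 shape, collapsed to three levels)."""

    less_than_hs: int
    hs_to_some_college: int
    college_4plus: int
    total_adults25: int

    def __post_init__(self):
        _check_counts(
            (self.less_than_hs, self.hs_to_some_college, self.college_4plus),
            self.total_adults25,
            "education table",
        )


@dataclass(frozen=True)
class RaceTable:
    """Persons by race/ethnicity (B03002 shape, collapsed)."""

    white_nh: int
    black_nh: int
    other: int
    total_population: int

    def __post_init__(self):
        _check_counts(
            (self.white_nh, self.black_nh, self.other), self.total_population, "race table"
        )


@dataclass(frozen=True)
class TenureTable:
    """Occupied housing units by tenure x race stratum (S2502 shape)."""

    cells: Mapping[tuple[str, str], int]
    total_occupied_units: int

    def __post_init__(self):
        for key in self.cells:
            tenure, stratum = key
            if tenure not in TENURES or stratum not in RACE_STRATA:
                raise InvalidLabelError(f"unknown tenure cell {key!r}")
        _check_counts(self.cells.values(), self.total_occupied_units, "tenure table")

    def cell(self, tenure: str, stratum: str) -> int:
        return self.cells.get((tenure, stratum), 0)

    def tenure_total(self, tenure: str) -> int:
        return sum(n for (t, _), n in self.cells.items() if t == tenure)


@dataclass(frozen=True)
class AgeTable:
    """Persons by age band (S0101 shape, collapsed to three bands)."""

    under_18: int
    from_18_to_64: int
    age_65_plus: int
    total_population: int

    def __post_init__(self):
        _check_counts(
            (self.under_18, self.from_18_to_64, self.age_65_plus),
            self.total_population,
            "age table",
        )


@dataclass(frozen=True)
class CrimeCounts:
    """Annual violent and property crime event counts (UCR definitions).

    Violent crime: murder/manslaughter, rape, robbery, aggravated assault.
    Property crime: burglary, larceny-theft, motor vehicle theft, arson.
    """

    violent_count: int
    property_count: int
    population: int
    year: int

    def __post_init__(self):
        if self.violent_count < 0 or self.property_count < 0:
            raise InvalidInputError("negative crime count")
        if self.population <= 0:
            raise DegeneratePopulationError("crime population must be positive")


@dataclass(frozen=True)
class DemographicBundle:
    """All count tables for one city; any table may be absent (None)."""

    city: str
    income: IncomeTable | None = None
    education: EducationTable | None = None
    race: RaceTable | None = None
    tenure: TenureTable | None = None
    age: AgeTable | None = None
    crime: CrimeCounts | None = None


@dataclass(frozen=True)
class ICEProfile:
    """The seven ICE values for one city; missing variants are None."""

    ice_income: float | None = None
    ice_education: float | None = None
    ice_race_wb: float | None = None
    ice_wb_income: float | None = None
    ice_wpc_income: float | None = None
    ice_wb_homeownership: float | None = None
    ice_wpc_homeownership: float | None = None

    def __post_init__(self):
        for name in ICE_VARIANTS:
            value = getattr(self, name)
            if value is not None and not -1.0 <= value <= 1.0:
                raise InvalidInputError(f"{name} = {value} outside [-1, 1]")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in ICE_VARIANTS}


@dataclass(frozen=True)
class CovariateSet:
    """Demographic proportions and crime rates entering the models."""

    prop_under18: float | None = None
    prop_65plus: float | None = None
    prop_income_lt25k: float | None = None
    prop_income_gt100k: float | None = None
    prop_nh_white: float | None = None
    violent_rate: float | None = None
    property_rate: float | None = None

    def __post_init__(self):
        for name in COVARIATE_LABELS[:5]:
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise InvalidInputError(f"{name} = {value} outside [0, 1]")
        for name in ("violent_rate", "property_rate"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InvalidInputError(f"{name} = {value} negative")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in COVARIATE_LABELS}


# ---------------------------------------------------------------------------
# core operations


def compute_ice(privileged: int, deprived: int, total: int) -> float:
    """The Massey index (A - P) / T for one privileged/deprived split."""
    if total <= 0:
        raise DegeneratePopulationError("ICE denominator must be positive")
    if privileged < 0 or deprived < 0:
        raise InvalidInputError("ICE counts must be non-negative")
    if privileged + deprived > total:
        raise InconsistentCountsError(
            f"A + P = {privileged + deprived} exceeds T = {total}"
        )
    return (privileged - deprived) / total


def _ice_cells(bundle: DemographicBundle, variant: str) -> tuple[int, int, int]:
    """Map a variant label to its (A, P, T) cells, or raise MissingDataError."""
    def need(table, name):
        if table is None:
            raise MissingDataError(f"{bundle.city}: {name} table required for {variant}")
        return table

    if variant == "ice_income":
        t = need(bundle.income, "income")
        return t.bracket_total("over_100k"), t.bracket_total("under_25k"), t.total_households
    if variant == "ice_education":
        t = need(bundle.education, "education")
        return t.college_4plus, t.less_than_hs, t.total_adults25
    if variant == "ice_race_wb":
        t = need(bundle.race, "race")
        return t.white_nh, t.black_nh, t.total_population
    if variant == "ice_wb_income":
        t = need(bundle.income, "income")
        return t.cell("over_100k", "white_nh"), t.cell("under_25k", "black"), t.total_households
    if variant == "ice_wpc_income":
        t = need(bundle.income, "income")
        deprived = t.bracket_total("under_25k") - t.cell("under_25k", "white_nh")
        return t.cell("over_100k", "white_nh"), deprived, t.total_households
    if variant == "ice_wb_homeownership":
        t = need(bundle.tenure, "tenure")
        return t.cell("owner", "white_nh"), t.cell("renter", "black"), t.total_occupied_units
    if variant == "ice_wpc_homeownership":
        t = need(bundle.tenure, "tenure")
        deprived = t.tenure_total("renter") - t.cell("renter", "white_nh")
        return t.cell("owner", "white_nh"), deprived, t.total_occupied_units
    raise InvalidLabelError(f"unknown ICE variant {variant!r}")


def ice_variant(bundle: DemographicBundle, variant: str) -> float:
    """Compute one named ICE variant from a city's table bundle.

    Raises :class:`MissingDataError` when the required table is absent;
    use :func:`ice_profile` to record missing variants as ``None``.
    """
    a, p, t = _ice_cells(bundle, variant)
    return compute_ice(a, p, t)


def ice_profile(bundle: DemographicBundle) -> ICEProfile:
    """All seven ICE variants; absent tables yield missing (None) values."""
    values: dict[str, float | None] = {}
    for variant in ICE_VARIANTS:
        try:
            values[variant] = ice_variant(bundle, variant)
        except MissingDataError:
            values[variant] = None
    return ICEProfile(**values)


def crime_rate(count: int, population: int) -> float:
    """Events per 100,000 persons."""
    if population <= 0:
        raise DegeneratePopulationError("crime-rate population must be positive")
    if count < 0:
        raise InvalidInputError("crime count must be non-negative")
    return 100_000.0 * count / population


def compute_covariates(
    age: AgeTable | None,
    income: IncomeTable | None,
    race: RaceTable | None,
    crime: CrimeCounts | None = None,
) -> CovariateSet:
    """Model covariates: age/income/race proportions plus crime rates.

    Proportions are cell count over table total.  An absent table yields
    missing covariates for that table only; absent crime counts yield
    missing rates (a city lacking crime data is excluded only from
    crime-dependent analyses).
    """
    kwargs: dict[str, float | None] = {}
    if age is not None:
        kwargs["prop_under18"] = age.under_18 / age.total_population
        kwargs["prop_65plus"] = age.age_65_plus / age.total_population
    if income is not None:
        kwargs["prop_income_lt25k"] = income.bracket_total("under_25k") / income.total_households
        kwargs["prop_income_gt100k"] = income.bracket_total("over_100k") / income.total_households
    if race is not None:
        kwargs["prop_nh_white"] = race.white_nh / race.total_population
    if crime is not None:
        kwargs["violent_rate"] = crime_rate(crime.violent_count, crime.population)
        kwargs["property_rate"] = crime_rate(crime.property_count, crime.population)
    return CovariateSet(**kwargs)


def coarsen_income_bins(
    fine_counts: Mapping[str, int], bin_map: Mapping[str, str]
) -> dict[str, int]:
    """Aggregate finer income bins (e.g. the 16 B19001 bins) to the three
    analysis brackets using an explicit fine-bin -> bracket mapping."""
    out = {bracket: 0 for bracket in INCOME_BRACKETS}
    for bin_name, count in fine_counts.items():
        bracket = bin_map.get(bin_name)
        if bracket not in INCOME_BRACKETS:
            raise InvalidLabelError(f"fine bin {bin_name!r} maps to unknown bracket {bracket!r}")
        if count < 0:
            raise InvalidInputError(f"negative count in bin {bin_name!r}")
        out[bracket] += count
    return out


# ---------------------------------------------------------------------------
# CSV ingest (one file per table family, header: city,cell,count)

#: Controlled vocabulary for the ``cell`` column, per table family.
CELL_VOCABULARY = {
    "income": tuple(f"{b}:{s}" for b in INCOME_BRACKETS for s in RACE_STRATA),
    "education": ("less_than_hs", "hs_to_some_college", "college_4plus"),
    "race": ("white_nh", "black_nh", "other"),
    "tenure": tuple(f"{t}:{s}" for t in TENURES for s in RACE_STRATA),
    "age": ("under_18", "from_18_to_64", "age_65_plus"),
}


def _read_cells(path: Path, family: str) -> dict[str, dict[str, int]]:
    vocab = set(CELL_VOCABULARY[family])
    per_city: dict[str, dict[str, int]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"city", "cell", "count"} - set(reader.fieldnames or ())
        if missing:
            raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            cell = row["cell"].strip()
            if cell not in vocab:
                raise InvalidInputError(f"{path}, row {lineno}: unknown {family} cell {cell!r}")
            try:
                count = int(row["count"])
            except ValueError as exc:
                raise InvalidInputError(f"{path}, row {lineno}: bad count {row['count']!r}") from exc
            cells = per_city.setdefault(row["city"].strip(), {})
            if cell in cells:
                raise InvalidInputError(f"{path}, row {lineno}: duplicate cell {cell!r}")
            cells[cell] = count
    return per_city


def _split_key(cell: str) -> tuple[str, str]:
    left, right = cell.split(":")
    return left, right


def load_demographics(
    income_path: str | Path | None = None,
    education_path: str | Path | None = None,
    race_path: str | Path | None = None,
    tenure_path: str | Path | None = None,
    age_path: str | Path | None = None,
    crime_path: str | Path | None = None,
) -> dict[str, DemographicBundle]:
    """Load all table-family CSVs and join them by city.

    Any file may be omitted; cities missing from a file simply lack that
    table.  Crime CSVs have the header
    ``city,year,violent_count,property_count,population``.
    """
    income = _read_cells(Path(income_path), "income") if income_path else {}
    education = _read_cells(Path(education_path), "education") if education_path else {}
    race = _read_cells(Path(race_path), "race") if race_path else {}
    tenure = _read_cells(Path(tenure_path), "tenure") if tenure_path else {}
    age = _read_cells(Path(age_path), "age") if age_path else {}
    crime: dict[str, CrimeCounts] = {}
    if crime_path:
        with open(crime_path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                crime[row["city"].strip()] = CrimeCounts(
                    violent_count=int(row["violent_count"]),
                    property_count=int(row["property_count"]),
                    population=int(row["population"]),
                    year=int(row["year"]),
                )

    cities = sorted(
        set(income) | set(education) | set(race) | set(tenure) | set(age) | set(crime)
    )
    bundles: dict[str, DemographicBundle] = {}
    for city in cities:
        inc = edu = rac = ten = ag = None
        if city in income:
            cells = {_split_key(c): n for c, n in income[city].items()}
            inc = IncomeTable(cells=cells, total_households=sum(cells.values()))
        if city in education:
            e = education[city]
            edu = EducationTable(
                less_than_hs=e.get("less_than_hs", 0),
                hs_to_some_college=e.get("hs_to_some_college", 0),
                college_4plus=e.get("college_4plus", 0),
                total_adults25=sum(e.values()),
            )
        if city in race:
            r = race[city]
            rac = RaceTable(
                white_nh=r.get("white_nh", 0),
                black_nh=r.get("black_nh", 0),
                other=r.get("other", 0),
                total_population=sum(r.values()),
            )
        if city in tenure:
            cells = {_split_key(c): n for c, n in tenure[city].items()}
            ten = TenureTable(cells=cells, total_occupied_units=sum(cells.values()))
        if city in age:
            a = age[city]
            ag = AgeTable(
                under_18=a.get("under_18", 0),
                from_18_to_64=a.get("from_18_to_64", 0),
                age_65_plus=a.get("age_65_plus", 0),
                total_population=sum(a.values()),
            )
        bundles[city] = DemographicBundle(
            city=city, income=inc, education=edu, race=rac, tenure=ten, age=ag,
            crime=crime.get(city),
        )
    return bundles


def write_table_csv(
    path: str | Path, family: str, per_city_cells: Mapping[str, Mapping[str, int]]
) -> None:
    """Write one table-family CSV in the ``city,cell,count`` ingest format."""
    vocab = CELL_VOCABULARY[family]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["city", "cell", "count"])
        for city in sorted(per_city_cells):
            cells = per_city_cells[city]
            for cell in vocab:
                if cell in cells:
                    writer.writerow([city, cell, cells[cell]])
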