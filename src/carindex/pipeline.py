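"""Study orchestration: ingest -> CRI -> ICE/covariates -> models -> report.

``run_study`` reproduces the shape of a city-level budget-equity study:
a per-city table (CRI, seven ICE variants, covariates, crime rates), a
summary stratified at the cohort median CRI, a bivariate correlation
table, adjusted polynomial model fits with residual diagnostics, and a
JSON report with provenance.  Everything is deterministic given the
inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, budget_ledger, demography
from .association import (
    DEFAULT_MODELS,
    CityRecord,
    FitResult,
    GAUSSIAN_ASSUMED,
    ModelSpec,
    bivariate,
    diagnostics,
    fit_model,
    partial_residuals,
    records_frame,
)
from .budget_ledger import CategoryLexicon, adjust_inflation, budgets_by_city, compute_cri
from .demography import COVARIATE_LABELS, ICE_VARIANTS, compute_covariates, ice_profile
from .errors import InsufficientDataError, InvalidInputError, MissingDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Paths, inflation factors, model specs, and options for one study run."""

    ledger_path: str | Path
    income_path: str | Path | None = None
    education_path: str | Path | None = None
    race_path: str | Path | None = None
    tenure_path: str | Path | None = None
    age_path: str | Path | None = None
    crime_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    #: (city, source fiscal year) -> inflation factor into the study year.
    inflation: Mapping[tuple[str, int], float] = field(default_factory=dict)
    study_year: int | None = None
    models: tuple[ModelSpec, ...] = DEFAULT_MODELS
    alpha: float = 0.05
    #: variables assumed Gaussian a priori (tested with Pearson's r).
    gaussian_assumed: tuple[str, ...] = GAUSSIAN_ASSUMED
    #: quantile interpolation rule for IQRs (numpy method name).
    quantile_method: str = "linear"
    out_dir: str | Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        base = Path(path).parent
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in (
            "ledger_path", "income_path", "education_path", "race_path",
            "tenure_path", "age_path", "crime_path", "lexicon_path", "out_dir",
        ):
            if kwargs.get(key):
                p = Path(kwargs[key])
                kwargs[key] = p if p.is_absolute() else base / p
        if "inflation" in kwargs:
            kwargs["inflation"] = {
                (str(e["city"]), int(e["fiscal_year"])): float(e["factor"])
                for e in kwargs["inflation"]
            }
        if "models" in kwargs:
            kwargs["models"] = tuple(
                ModelSpec(
                    exposure=m["exposure"],
                    degree=int(m.get("degree", 2)),
                    adjust=tuple(m.get("adjust", ())),
                    name=m.get("name"),
                )
                for m in kwargs["models"]
            )
        if "gaussian_assumed" in kwargs:
            kwargs["gaussian_assumed"] = tuple(kwargs["gaussian_assumed"])
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the analytic configuration for provenance.

        The output directory does not affect results and is excluded.
        """
        payload = {
            k: str(v) if not isinstance(v, (int, float, type(None))) else v
            for k, v in sorted(self.__dict__.items())
            if k != "out_dir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    per_city: pd.DataFrame
    summary: pd.DataFrame
    bivariate: pd.DataFrame
    fits: tuple[FitResult, ...]
    model_table: pd.DataFrame
    diagnostics: Mapping[str, association.DiagnosticsBundle]
    partial_residuals: Mapping[str, pd.DataFrame]
    provenance: dict


# ---------------------------------------------------------------------------
# record assembly


def build_records(
    budgets: Mapping[str, budget_ledger.ClassifiedBudget],
    bundles: Mapping[str, demography.DemographicBundle],
) -> list[CityRecord]:
    """Join classified budgets with demographic bundles into analysis rows.

    Cities present in only one of the two sources are dropped with a log
    message; within a retained city, missing tables simply yield missing
    ICE values/covariates.
    """
    records = []
    for city in sorted(budgets):
        if city not in bundles:
            logger.warning("%s: no demographic tables; city dropped", city)
            continue
        bundle = bundles[city]
        cri = compute_cri(budgets[city])
        covariates = compute_covariates(
            bundle.age, bundle.income, bundle.race, bundle.crime
        )
        records.append(
            CityRecord(
                city=city, cri=cri.value, ice=ice_profile(bundle), covariates=covariates
            )
        )
    for city in sorted(set(bundles) - set(budgets)):
        logger.warning("%s: no budget ledger; city dropped", city)
    return records


# ---------------------------------------------------------------------------
# stratified summary (median-CRI split)

_SUMMARY_STATS = ("mean", "sd", "median", "min", "max")


def summarize_cohort(
    records: Sequence[CityRecord] | pd.DataFrame, quantile_method: str = "linear"
) -> pd.DataFrame:
    """Summary statistics stratified at the cohort median CRI.

    Cities at or below the median CRI form the first stratum, cities
    above it the second ("equal or below" keeps ties and, for odd n, the
    median city).  Returns one row per (variable, statistic) with columns
    for each stratum and for all cities; per-variable n uses pairwise
    (non-missing) counts.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if len(df) < 2:
        raise InsufficientDataError(f"need >= 2 cities, got {len(df)}")
    median_cri = float(df["cri"].median())
    low = df[df["cri"] <= median_cri]
    high = df[df["cri"] > median_cri]
    if high.empty:
        warnings.warn("all cities at or below the median CRI; upper stratum empty")
    strata = {
        f"cri_le_median (n={len(low)})": low,
        f"cri_gt_median (n={len(high)})": high,
        f"all (n={len(df)})": df,
    }
    rows = []
    for variable in df.columns:
        for stat in _SUMMARY_STATS:
            row: dict = {"variable": variable, "statistic": stat}
            for label, stratum in strata.items():
                values = stratum[variable].dropna()
                if values.empty:
                    row[label] = np.nan
                elif stat == "mean":
                    row[label] = values.mean()
                elif stat == "sd":
                    row[label] = values.std(ddof=1)
                elif stat == "median":
                    row[label] = values.median()
                elif stat == "min":
                    row[label] = values.min()
                else:
                    row[label] = values.max()
            rows.append(row)
    return pd.DataFrame(rows).set_index(["variable", "statistic"])


def iqr(values, quantile_method: str = "linear") -> tuple[float, float]:
    """(Q25, Q75) with a configurable interpolation rule."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("no non-missing values")
    q25, q75 = np.quantile(arr, [0.25, 0.75], method=quantile_method)
    return float(q25), float(q75)


# ---------------------------------------------------------------------------
# study tables


def bivariate_table(
    df: pd.DataFrame, alpha: float = 0.05, gaussian_assumed: Sequence[str] = GAUSSIAN_ASSUMED
) -> pd.DataFrame:
    """Correlation of every covariate and ICE variant with the CRI.

    Variables in ``gaussian_assumed`` are tested with Pearson's r;
    everything else uses the Shapiro-Wilk-driven method choice.  Cities
    missing a variable are deleted pairwise, so each row reports its own n.
    """
    rows = []
    for variable in (*COVARIATE_LABELS, *ICE_VARIANTS):
        if variable not in df.columns:
            continue
        method = "pearson" if variable in gaussian_assumed else None
        try:
            res = bivariate(df[variable], df["cri"], method=method, alpha=alpha)
        except InsufficientDataError as exc:
            logger.warning("bivariate %s skipped: %s", variable, exc)
            continue
        rows.append(
            {
                "variable": variable,
                "method": res.method,
                "coefficient": res.coefficient,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def model_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Stacked coefficient table across models (one row per term)."""
    frames = []
    for fit in fits:
        frame = fit.coefficients.copy()
        frame.insert(0, "model", fit.spec.label)
        frame.insert(1, "term", frame.index)
        frame["adjusted_r2"] = fit.adjusted_r2
        frame["n"] = fit.n
        frames.append(frame.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# orchestration


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full pipeline and (optionally) write all outputs.

    Unreadable inputs abort the run with a file-level error before any
    output is written; a model whose exposure is entirely missing is
    skipped with a logged reason rather than failing the study.
    """
    lexicon = (
        CategoryLexicon.from_yaml(config.lexicon_path)
        if config.lexicon_path
        else CategoryLexicon.default()
    )
    items = budget_ledger.read_ledger(config.ledger_path)
    budgets = budgets_by_city(items, lexicon)
    for (city, year), factor in config.inflation.items():
        if city in budgets and budgets[city].fiscal_year == year:
            budgets[city] = adjust_inflation(budgets[city], factor, config.study_year)
            logger.info("%s: FY%d amounts inflated by %s", city, year, factor)
    bundles = demography.load_demographics(
        income_path=config.income_path,
        education_path=config.education_path,
        race_path=config.race_path,
        tenure_path=config.tenure_path,
        age_path=config.age_path,
        crime_path=config.crime_path,
    )
    records = build_records(budgets, bundles)
    if len(records) < 2:
        raise InsufficientDataError(f"only {len(records)} analyzable cities")
    if len(records) < 30:
        warnings.warn(f"only {len(records)} cities; model estimates will be unstable")
    df = records_frame(records)

    summary = summarize_cohort(df, quantile_method=config.quantile_method)
    biv = bivariate_table(df, alpha=config.alpha, gaussian_assumed=config.gaussian_assumed)

    fits: list[FitResult] = []
    diag: dict[str, association.DiagnosticsBundle] = {}
    presid: dict[str, pd.DataFrame] = {}
    for spec in config.models:
        if spec.exposure not in df.columns or df[spec.exposure].isna().all():
            logger.warning("%s skipped: exposure %s all-missing", spec.label, spec.exposure)
            continue
        try:
            fit = fit_model(df, spec)
        except InsufficientDataError as exc:
            logger.warning("%s skipped: %s", spec.label, exc)
            continue
        fits.append(fit)
        diag[spec.label] = diagnostics(fit)
        presid[spec.label] = partial_residuals(fit)

    q25, q75 = iqr(df["cri"], config.quantile_method)
    provenance = {
        "config_digest": config.digest(),
        "package_version": _version(),
        "n_cities": len(records),
        "cri_median": float(df["cri"].median()),
        "cri_iqr": [q25, q75],
    }
    report = StudyReport(
        per_city=df,
        summary=summary,
        bivariate=biv,
        fits=tuple(fits),
        model_table=model_table(fits) if fits else pd.DataFrame(),
        diagnostics=diag,
        partial_residuals=presid,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(report, budgets, config.out_dir)
    return report


def _version() -> str:
    try:
        return metadata.version("carindex")
    except metadata.PackageNotFoundError:
        return "unknown"


def write_report(
    report: StudyReport,
    budgets: Mapping[str, budget_ledger.ClassifiedBudget],
    out_dir: str | Path,
) -> None:
    """Write all study outputs: CSV tables, diagnostics, and report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_city.to_csv(out / "per_city.csv")
    report.summary.to_csv(out / "summary.csv")
    report.bivariate.to_csv(out / "bivariate.csv")
    report.model_table.to_csv(out / "models.csv", index=False)
    budget_ledger.write_classification_csv(budgets.values(), out / "classification.csv")
    budget_ledger.write_cri_report(budgets, out / "cri.json")
    for label, bundle in report.diagnostics.items():
        slug = label.lower().replace(" ", "_")
        bundle.resid_fitted.to_csv(out / f"diagnostics_{slug}_resid_fitted.csv")
        bundle.qq.to_csv(out / f"diagnostics_{slug}_qq.csv", index=False)
    for label, frame in report.partial_residuals.items():
        slug = label.lower().replace(" ", "_")
        frame.to_csv(out / f"partial_residuals_{slug}.csv")

    payload = {
        "provenance": report.provenance,
        "per_city": json.loads(report.per_city.reset_index().to_json(orient="records")),
        "bivariate": json.loads(report.bivariate.reset_index().to_json(orient="records")),
        "models": json.loads(report.model_table.to_json(orient="records")),
        "curvature": {
            label: {"slope": b.curvature_slope, "p_value": b.curvature_p}
            for label, b in report.diagnostics.items()
        },
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
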