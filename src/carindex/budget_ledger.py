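"""Municipal budget ledgers, department classification, and the CRI.

The Carceral Resource Index (CRI) contrasts a city's appropriations for
carceral systems (police, corrections, courts, prosecution and public
defense, sheriffs, probation) with its appropriations for health (public
health, human services, parks and public spaces) and social support
(housing, neighborhood development, employment, community engagement,
arts and culture)::

    CRI = ((health + support) - carceral) / total_budget

The index lives in [-1, 1]: -1 is total fiscal prioritization of carceral
systems to the exclusion of health and support; +1 is the reverse.  A
handful of departments that sit between the carceral and health/support
systems (medical examiners, environmental protection, child and family
services, education) are excluded from all three numerator categories but
— like every unmatched "other" department — still count toward the total
budget in the denominator.

Amounts are carried as exact :class:`decimal.Decimal` values from ingest
through aggregation; division happens in floating point only inside
:func:`compute_cri`.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from decimal import Decimal, InvalidOperation
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DegenerateBudgetError, InvalidInputError

#: Numerator / exclusion categories, in canonical order.
CATEGORIES = ("carceral", "health", "support", "excluded")
#: All category labels a line can receive ("other" = unmatched).
ALL_CATEGORIES = CATEGORIES + ("other",)

_WS = re.compile(r"\s+")


def _normalize(name: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class LineItem:
    """One departmental appropriation line in an adopted city budget."""

    city: str
    fiscal_year: int
    department: str
    amount: Decimal
    category_override: str | None = None

    def __post_init__(self):
        if not _normalize(self.department):
            raise InvalidInputError("department name is empty")
        amount = self.amount
        if not isinstance(amount, Decimal):
            try:
                amount = Decimal(str(amount))
            except InvalidOperation as exc:
                raise InvalidInputError(f"bad amount {self.amount!r}") from exc
            object.__setattr__(self, "amount", amount)
        if amount < 0:
            raise InvalidInputError(f"negative amount {amount} for {self.department!r}")
        if self.category_override is not None and self.category_override not in ALL_CATEGORIES:
            raise InvalidInputError(
                f"unknown category override {self.category_override!r}; "
                f"expected one of {ALL_CATEGORIES}"
            )


class CategoryLexicon:
    """Ordered pattern → category mapping for department classification.

    Matching is case-insensitive substring matching against the
    whitespace-normalized name, longest pattern first; ties are broken by
    the order patterns appear in the lexicon.  This reproduces a hand-coded
    classification deterministically; ambiguous departments can always be
    resolved with a per-line ``category_override``.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        patterns: list[tuple[str, str]] = []
        seen: dict[str, str] = {}
        for category, pats in mapping.items():
            if category not in CATEGORIES:
                raise InvalidInputError(
                    f"unknown lexicon category {category!r}; expected one of {CATEGORIES}"
                )
            for pat in pats:
                norm = _normalize(pat)
                if not norm:
                    raise InvalidInputError("empty lexicon pattern")
                if norm in seen and seen[norm] != category:
                    raise InvalidInputError(
                        f"pattern {norm!r} mapped to both {seen[norm]!r} and {category!r}"
                    )
                if norm not in seen:
                    seen[norm] = category
                    patterns.append((norm, category))
        # longest first; ties keep lexicon order (sort is stable)
        self._patterns = sorted(patterns, key=lambda pc: -len(pc[0]))

    @property
    def patterns(self) -> list[tuple[str, str]]:
        return list(self._patterns)

    def classify(self, name: str) -> str:
        return classify_department(name, self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CategoryLexicon":
        """The packaged default lexicon (police/corrections/... lists)."""
        text = resources.files("carindex.data").joinpath("default_lexicon.yaml").read_text("utf-8")
        return cls(yaml.safe_load(text))


def classify_department(name: str, lexicon: CategoryLexicon) -> str:
    """Assign a department name to a spending category.

    Returns the category of the first matching lexicon pattern (longest
    pattern first); unmatched names return ``"other"`` and count toward
    the total budget only.
    """
    norm = _normalize(name)
    if not norm:
        raise InvalidInputError("department name is empty")
    for pattern, category in lexicon.patterns:
        if pattern in norm:
            return category
    return "other"


@dataclass(frozen=True)
class ClassifiedBudget:
    """A city-year ledger with per-line categories and category subtotals."""

    city: str
    fiscal_year: int
    lines: tuple[tuple[LineItem, str], ...]
    subtotals: Mapping[str, Decimal]
    total: Decimal

    def __post_init__(self):
        if self.total <= 0:
            raise DegenerateBudgetError(f"non-positive total budget for {self.city!r}")
        if sum(self.subtotals.values()) != self.total:
            raise InvalidInputError("subtotals do not sum to total")

    @property
    def carceral(self) -> Decimal:
        return self.subtotals["carceral"]

    @property
    def health(self) -> Decimal:
        return self.subtotals["health"]

    @property
    def support(self) -> Decimal:
        return self.subtotals["support"]

    @property
    def excluded(self) -> Decimal:
        return self.subtotals["excluded"]

    @property
    def other(self) -> Decimal:
        return self.subtotals["other"]


@dataclass(frozen=True)
class CRIResult:
    """The CRI value for one city-year plus the amounts it derives from."""

    value: float
    carceral: float
    health: float
    support: float
    total: float

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise InvalidInputError(f"CRI {self.value} outside [-1, 1]")

    def as_dict(self) -> dict:
        return {
            "cri": self.value,
            "carceral": self.carceral,
            "health": self.health,
            "support": self.support,
            "total": self.total,
        }


def aggregate_budget(
    items: Sequence[LineItem], lexicon: CategoryLexicon | None = None
) -> ClassifiedBudget:
    """Classify every line of a single city-year ledger and sum by category.

    A ``category_override`` on a line wins over the lexicon.  All items
    must share one city and fiscal year and sum to a positive total.
    """
    if lexicon is None:
        lexicon = CategoryLexicon.default()
    items = list(items)
    if not items:
        raise InvalidInputError("empty ledger")
    cities = {it.city for it in items}
    years = {it.fiscal_year for it in items}
    if len(cities) > 1 or len(years) > 1:
        raise InvalidInputError(
            f"ledger mixes cities {sorted(cities)} / fiscal years {sorted(years)}"
        )
    subtotals = {cat: Decimal(0) for cat in ALL_CATEGORIES}
    lines = []
    for item in items:
        category = item.category_override or classify_department(item.department, lexicon)
        subtotals[category] += item.amount
        lines.append((item, category))
    total = sum(subtotals.values())
    if total <= 0:
        raise DegenerateBudgetError(
            f"ledger for {items[0].city!r} FY{items[0].fiscal_year} has zero total"
        )
    return ClassifiedBudget(
        city=items[0].city,
        fiscal_year=items[0].fiscal_year,
        lines=tuple(lines),
        subtotals=subtotals,
        total=total,
    )


def adjust_inflation(
    budget: ClassifiedBudget, factor: float | Decimal, target_year: int | None = None
) -> ClassifiedBudget:
    """Rescale all currency fields into target-year dollars.

    Used when a city's adopted budget is only available for an adjacent
    fiscal year.  The CRI is a ratio, so it is invariant under this
    operation; only the dollar amounts and the fiscal-year label change.
    The factor's provenance (CPI series, base year) is the caller's
    responsibility and should be recorded in study configuration.
    """
    factor = Decimal(str(factor))
    if factor <= 0:
        raise InvalidInputError(f"inflation factor must be positive, got {factor}")
    year = target_year if target_year is not None else budget.fiscal_year
    lines = tuple(
        (replace(item, fiscal_year=year, amount=item.amount * factor), cat)
        for item, cat in budget.lines
    )
    subtotals = {cat: amt * factor for cat, amt in budget.subtotals.items()}
    return ClassifiedBudget(
        city=budget.city,
        fiscal_year=year,
        lines=lines,
        subtotals=subtotals,
        total=budget.total * factor,
    )


def compute_cri(budget: ClassifiedBudget) -> CRIResult:
    """Compute the Carceral Resource Index for one classified budget."""
    if budget.total <= 0:
        raise DegenerateBudgetError("total budget must be positive")
    numerator = budget.health + budget.support - budget.carceral
    value = float(numerator) / float(budget.total)
    return CRIResult(
        value=value,
        carceral=float(budget.carceral),
        health=float(budget.health),
        support=float(budget.support),
        total=float(budget.total),
    )


# ---------------------------------------------------------------------------
# ingest / export

LEDGER_COLUMNS = ("city", "fiscal_year", "department", "amount")


def read_ledger(path: str | Path) -> list[LineItem]:
    """Read a ledger CSV (``city,fiscal_year,department,amount[,category_override]``).

    Amounts must be plain numbers without currency symbols or thousands
    separators; they are parsed as exact decimals.
    """
    path = Path(path)
    items: list[LineItem] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(LEDGER_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise InvalidInputError(f"{path}: missing ledger columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                override = (row.get("category_override") or "").strip() or None
                items.append(
                    LineItem(
                        city=row["city"].strip(),
                        fiscal_year=int(row["fiscal_year"]),
                        department=row["department"],
                        amount=Decimal(row["amount"]),
                        category_override=override,
                    )
                )
            except (InvalidOperation, ValueError, InvalidInputError) as exc:
                raise InvalidInputError(f"{path}, row {lineno}: {exc}") from exc
    return items


def budgets_by_city(
    items: Iterable[LineItem], lexicon: CategoryLexicon | None = None
) -> dict[str, ClassifiedBudget]:
    """Group a multi-city ledger by city and aggregate each one.

    Each city must appear with a single fiscal year.
    """
    grouped: dict[str, list[LineItem]] = {}
    for item in items:
        grouped.setdefault(item.city, []).append(item)
    return {city: aggregate_budget(city_items, lexicon) for city, city_items in grouped.items()}


def write_classification_csv(budgets: Iterable[ClassifiedBudget], path: str | Path) -> None:
    """Write the per-line classification audit trail."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["city", "fiscal_year", "department", "amount", "category"])
        for budget in budgets:
            for item, category in budget.lines:
                writer.writerow(
                    [item.city, item.fiscal_year, item.department, str(item.amount), category]
                )


def write_cri_report(budgets: Mapping[str, ClassifiedBudget], path: str | Path) -> dict:
    """Write a JSON CRI report (one entry per city) and return it."""
    report = {city: compute_cri(budget).as_dict() for city, budget in sorted(budgets.items())}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
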