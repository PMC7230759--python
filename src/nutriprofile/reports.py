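"""Comparison statistics: per-category healthier proportions, sales-weighted
proportions, pairwise Cohen's kappa with interpretation bands, and the
health-symbol vs rating-scheme conflict scenarios."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import RATING_MODELS, ClassificationMatrix
from .errors import InputError, UndefinedProportionError
from .supply import FoodProduct

logger = logging.getLogger(__name__)

#: Agreement bands on the kappa value.  The printed ranges leave kappa <= 0
#: and 1.0 unnamed; they fold into the adjacent outer bands and the raw
#: value is always reported alongside the label.
KAPPA_BANDS = (
    (0.20, "none-to-slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "near perfect"),
)


@dataclass
class ProportionResult:
    category: str
    model: str
    n: int
    n_healthier: int

    @property
    def proportion(self) -> float:
        return self.n_healthier / self.n


@dataclass
class SalesWeightedResult:
    category: str
    model: str
    n_included: int
    n_excluded: int  # products lacking sales, excluded from both sums
    total_sales: float
    healthier_sales: float

    @property
    def proportion(self) -> float:
        return self.healthier_sales / self.total_sales


@dataclass
class KappaResult:
    kappa: float
    degenerate: bool  # both raters constant: chance agreement is total

    @property
    def band(self) -> str:
        return band_label(self.kappa)


@dataclass
class ScenarioReport:
    """Cross-tab of symbol eligibility x green rating.

    A: green rating + symbol; B: green, no symbol; C: non-green + symbol
    (the conflicting case); D: non-green, no symbol.
    """

    symbol_model: str
    rating_model: str
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        n = self.n
        return {k: 100.0 * v / n if n else 0.0 for k, v in self.counts.items()}

    @property
    def conflict_pct(self) -> float:
        """Percentage of all products in scenario C (symbol but non-green)."""
        return self.percentages["C"]


def proportion_healthier(
    matrix: ClassificationMatrix, category: str, model: str
) -> ProportionResult:
    """Share of products in one category that one model calls healthier."""
    try:
        flags = matrix.flags(model, category)
    except InputError as exc:
        raise UndefinedProportionError(str(exc)) from exc
    return ProportionResult(
        category=category, model=model, n=len(flags), n_healthier=int(flags.sum())
    )


def sales_weighted_proportion(
    matrix: ClassificationMatrix,
    products: list[FoodProduct],
    category: str,
    model: str,
) -> SalesWeightedResult:
    """Sales-weighted healthier share: healthier sales / total sales.

    Products without recorded sales are excluded from both sums (and
    counted); sales units are unitless relative weights.
    """
    flags = matrix.flags(model, category)
    sales = {
        p.id: p.sales_units
        for p in products
        if p.category == category and p.id in flags.index
    }
    included = {pid: s for pid, s in sales.items() if s is not None}
    n_excluded = len(sales) - len(included)
    if n_excluded:
        logger.info(
            "%s/%s: %d products lack sales and are excluded", category, model, n_excluded
        )
    total = float(sum(included.values()))
    if total <= 0:
        raise UndefinedProportionError(
            f"no positive sales recorded in category {category!r}"
        )
    healthier = float(sum(s for pid, s in included.items() if flags.loc[pid]))
    return SalesWeightedResult(
        category=category,
        model=model,
        n_included=len(included),
        n_excluded=n_excluded,
        total_sales=total,
        healthier_sales=healthier,
    )


def cohens_kappa(flags_x, flags_y) -> KappaResult:
    """Cohen's kappa between two binary verdict vectors.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginals.  When both raters are
    constant p_e = 1 and the statistic is 0/0; the convention here returns
    0 with the degenerate flag set (agreement indistinguishable from
    chance under zero variation).
    """
    x = np.asarray(flags_x, dtype=bool)
    y = np.asarray(flags_y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("flag vectors must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise InputError("kappa needs at least two rated items")
    p_o = float(np.mean(x == y))
    px, py = float(np.mean(x)), float(np.mean(y))
    p_e = px * py + (1 - px) * (1 - py)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(kappa=0.0, degenerate=True)
    return KappaResult(kappa=(p_o - p_e) / (1 - p_e), degenerate=False)


def band_label(kappa: float) -> str:
    """Map a kappa value onto its agreement band label."""
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise InputError(f"kappa outside [-1, 1]: {kappa}")
    for upper, label in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return KAPPA_BANDS[-1][1]


def scenario_table(
    matrix: ClassificationMatrix, symbol_model: str, rating_model: str
) -> ScenarioReport:
    """Cross-tab symbol eligibility against a green rating (scenarios A-D)."""
    if rating_model not in RATING_MODELS:
        raise InputError(
            f"{rating_model!r} exposes no green rating; use one of {RATING_MODELS}"
        )
    symbol = matrix.flags(symbol_model)
    green = matrix.flags(rating_model).reindex(symbol.index)
    counts = {
        "A": int((green & symbol).sum()),
        "B": int((green & ~symbol).sum()),
        "C": int((~green & symbol).sum()),
        "D": int((~green & ~symbol).sum()),
    }
    return ScenarioReport(
        symbol_model=symbol_model, rating_model=rating_model, counts=counts
    )


def proportion_report(
    matrix: ClassificationMatrix, products: list[FoodProduct] | None = None
) -> pd.DataFrame:
    """Per (category, model) table of n, healthier counts and proportions,
    with sales-weighted columns when any product in the category has sales."""
    rows = []
    for category in matrix.categories():
        for model in matrix.models:
            prop = proportion_healthier(matrix, category, model)
            row = {
                "category": category,
                "model": model,
                "n": prop.n,
                "n_healthier": prop.n_healthier,
                "proportion": prop.proportion,
            }
            if products is not None and any(
                p.sales_units is not None for p in products if p.category == category
            ):
                sw = sales_weighted_proportion(matrix, products, category, model)
                row.update(
                    {
                        "total_sales": sw.total_sales,
                        "healthier_sales": sw.healthier_sales,
                        "sw_proportion": sw.proportion,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)


def kappa_report(
    matrix: ClassificationMatrix, reference: str, models: list[str] | None = None
) -> pd.DataFrame:
    """Per-category kappa of every model against a reference model."""
    models = [m for m in (models or matrix.models) if m != reference]
    rows = []
    for category in matrix.categories():
        ref = matrix.flags(reference, category)
        if len(ref) < 2:
            logger.info("category %s has < 2 products; kappa skipped", category)
            continue
        for model in models:
            other = matrix.flags(model, category).reindex(ref.index)
            k = cohens_kappa(ref.to_numpy(), other.to_numpy())
            rows.append(
                {
                    "category": category,
                    "reference": reference,
                    "model": model,
                    "kappa": k.kappa,
                    "band": k.band,
                    "degenerate": k.degenerate,
                }
            )
    return pd.DataFrame(rows)
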