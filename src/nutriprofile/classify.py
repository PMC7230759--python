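"""Running all profiling models over a supply and collecting verdicts.

The harmonised "healthier" flag per model follows the published comparison
convention: Nutri-Score grade A/B, HSR >= 3.5 stars, traffic light with no
red light, symbol schemes when the symbol may be carried, Ofcom/WHOE when
marketing to children is permitted, FSANZ when health claims are permitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import scores, thresholds
from .categories import resolve_category
from .config import config_version
from .errors import InputError, NutriProfileError
from .supply import FoodProduct

logger = logging.getLogger(__name__)

#: All ten model identifiers, in report order.
ALL_MODELS = (
    "nutriscore",
    "hsr",
    "traffic_light",
    "protective_food",
    "keyhole",
    "choices",
    "finnish_heart",
    "whoe",
    "ofcom",
    "fsanz",
)

#: Interpretive rating models that expose a "green" notion for scenario
#: cross-tabs (green = the model's harmonised healthier flag).
RATING_MODELS = ("nutriscore", "hsr", "traffic_light")


@dataclass
class ModelVerdict:
    model: str
    healthier: bool
    raw: str
    version: str
    detail: object = None


def classify_product(product: FoodProduct, model: str) -> ModelVerdict:
    """Classify one product under one model."""
    panel = product.panel
    if model in ("nutriscore", "ofcom", "fsanz", "hsr"):
        category = resolve_category(product, model)
        fn = getattr(scores, model)
        bd = fn(panel, category)
        return ModelVerdict(model, bd.healthier, bd.raw, bd.version, bd)
    if model == "traffic_light":
        tl = thresholds.traffic_light(panel)
        return ModelVerdict(model, tl.healthier, tl.raw, tl.version, tl)
    if model == "protective_food":
        el = thresholds.protective_food(panel, product.category)
        return ModelVerdict(model, el.eligible, el.raw, el.version, el)
    if model in ("keyhole", "choices", "finnish_heart", "whoe"):
        el = thresholds.symbol_scheme(panel, product.category, model)
        return ModelVerdict(model, el.eligible, el.raw, el.version, el)
    raise InputError(f"unknown model {model!r}")


@dataclass
class ClassificationMatrix:
    """Products x models verdicts in long form, plus config versions."""

    table: pd.DataFrame  # columns: product_id, category, model, healthier, raw
    versions: dict[str, str]

    @property
    def models(self) -> list[str]:
        return list(self.table["model"].unique())

    def healthier_matrix(self) -> pd.DataFrame:
        """Wide boolean matrix: rows = product ids, columns = models."""
        if self.table.empty:
            return pd.DataFrame()
        return self.table.pivot(index="product_id", columns="model", values="healthier")

    def flags(self, model: str, category: str | None = None) -> pd.Series:
        """Healthier flags for one model (optionally one category),
        indexed by product id."""
        t = self.table[self.table["model"] == model]
        if category is not None:
            t = t[t["category"] == category]
        if t.empty:
            raise InputError(
                f"no classifications for model {model!r}"
                + (f" in category {category!r}" if category else "")
            )
        return t.set_index("product_id")["healthier"].astype(bool)

    def categories(self) -> list[str]:
        return sorted(self.table["category"].unique())


def classify_all(
    products: list[FoodProduct], models: tuple[str, ...] | list[str] = ALL_MODELS
) -> ClassificationMatrix:
    """Classify every product under every requested model.

    Deterministic; any model failing on any product aborts with the
    product id and cause.
    """
    for m in models:
        if m not in ALL_MODELS:
            raise InputError(f"unknown model {m!r}; known: {', '.join(ALL_MODELS)}")
    rows = []
    for product in products:
        for model in models:
            try:
                verdict = classify_product(product, model)
            except NutriProfileError as exc:
                raise type(exc)(
                    f"model {model!r} failed on product {product.id!r}: {exc}"
                ) from exc
            rows.append(
                {
                    "product_id": product.id,
                    "category": product.category,
                    "model": model,
                    "healthier": verdict.healthier,
                    "raw": verdict.raw,
                }
            )
    table = pd.DataFrame(
        rows, columns=["product_id", "category", "model", "healthier", "raw"]
    )
    versions = {m: config_version(m) for m in models}
    for model in models:
        n = int(table[table["model"] == model]["healthier"].sum()) if rows else 0
        logger.info("model %s (%s): %d healthier products", model, versions[model], n)
    return ClassificationMatrix(table=table, versions=versions)
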