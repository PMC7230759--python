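"""Resolution of leaf food categories into each model's internal category.

The four point-scoring models group foods coarsely (Ofcom: food/drink;
FSANZ: three NPSC categories; Nutri-Score adds cheese and added fats; HSR
adds dairy categories).  The mapping is config data; the only conditional
rule is the FSANZ cheese split on declared calcium.
"""

from __future__ import annotations

import logging

from .config import load_config
from .errors import ConfigError
from .supply import FoodProduct, LEAF_CATEGORIES

logger = logging.getLogger(__name__)

CategoryMapping = dict  # model -> {leaf code or "default" -> internal category}


def load_category_mapping() -> CategoryMapping:
    return load_config("category_mapping")["models"]


def resolve_category(
    product: FoodProduct, model: str, mapping: CategoryMapping | None = None
) -> str:
    """Return the model-internal category for one product.

    Pure function of (leaf code, panel, config).  The FSANZ cheese entry
    routes high-calcium cheese to the oils/cheese NPSC category; cheese
    without a calcium declaration falls back to the general-food category
    with a logged warning.
    """
    mapping = mapping if mapping is not None else load_category_mapping()
    try:
        model_map = mapping[model]
    except KeyError as exc:
        raise ConfigError(f"no category mapping for model {model!r}") from exc
    if product.category not in LEAF_CATEGORIES:
        raise ConfigError(f"unmapped leaf category {product.category!r}")

    entry = model_map.get(product.category, model_map.get("default"))
    if entry is None:
        raise ConfigError(
            f"model {model!r} maps neither {product.category!r} nor a default"
        )
    if isinstance(entry, dict):  # conditional entry (FSANZ cheese/calcium)
        limit = float(entry["calcium_at_least"])
        calcium = product.panel.calcium
        if calcium is None:
            logger.warning(
                "product %s: no calcium declaration; falling back to %s",
                product.id,
                entry["else"],
            )
            return str(entry["else"])
        return str(entry["then"] if calcium >= limit else entry["else"])
    return str(entry)
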