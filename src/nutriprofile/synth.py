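"""Seeded generator of synthetic food-supply tables.

Stands in for an undeposited national branded-food composition survey:
category-typical nutrient panels drawn from truncated normals (or uniforms)
with hard bounds that respect the panel invariants, plus heavy-tailed
(log-normal) 12-month sales that can be biased so that market leaders are
systematically more or less healthy than the category average.

The healthiness index used for the sales bias is the negated Ofcom score —
a continuous, category-agnostic nutrient-quality measure — standardised
within category.  With bias ``b < 0`` expected log-sales fall with
healthiness, so sales-weighting lowers the healthier share (the pattern
reported for breakfast cereals); ``b > 0`` raises it (the cheese pattern).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy import stats

from .categories import resolve_category
from .config import load_config
from .errors import InputError
from .scores import ofcom
from .supply import LEAF_CATEGORIES, FoodProduct, NutrientPanel

logger = logging.getLogger(__name__)

KJ_PER_G_FAT = 37.0


@dataclass
class SupplySpec:
    """Per-category generation parameters plus the mandatory seed."""

    categories: dict[str, dict]
    sales: dict
    seed: int
    version: str = "1.0"

    def validate(self) -> "SupplySpec":
        for cat, block in self.categories.items():
            if cat not in LEAF_CATEGORIES:
                raise InputError(f"spec category {cat!r} is not a leaf category")
            if int(block.get("n", 0)) < 0:
                raise InputError(f"{cat}: negative product count")
            needed = {"total_fat", "sat_fat", "total_sugars", "salt", "protein"}
            if not block.get("energy_from_fat"):
                needed.add("energy")
            missing = needed - set(block.get("nutrients", {}))
            if missing:
                raise InputError(f"{cat}: missing nutrient dists {sorted(missing)}")
            for name, dist in block["nutrients"].items():
                lo, hi = _dist_bounds(dist)
                if lo > hi or lo < 0:
                    raise InputError(f"{cat}.{name}: infeasible bounds [{lo}, {hi}]")
        return self


def _dist_bounds(dist: dict) -> tuple[float, float]:
    if "uniform" in dist:
        return float(dist["uniform"][0]), float(dist["uniform"][1])
    return float(dist["lo"]), float(dist["hi"])


def _draw(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    """Draw n values from a bounded distribution spec."""
    if "uniform" in dist:
        lo, hi = (float(v) for v in dist["uniform"])
        return rng.uniform(lo, hi, size=n)
    mean, sd = float(dist["mean"]), float(dist["sd"])
    lo, hi = float(dist["lo"]), float(dist["hi"])
    if sd <= 0 or hi == lo:
        return np.full(n, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def default_spec(seed: int) -> SupplySpec:
    """The shipped default market specification with the given seed."""
    cfg = copy.deepcopy(load_config("supply_spec"))
    return SupplySpec(
        categories=cfg["categories"],
        sales=cfg["sales"],
        seed=int(seed),
        version=str(cfg.get("version", "1.0")),
    ).validate()


def load_spec(path, seed: int | None = None) -> SupplySpec:
    """Load a spec file; a --seed argument overrides any seed in the file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if seed is None and "seed" not in cfg:
        raise InputError("supply spec needs a seed (in the file or as an argument)")
    return SupplySpec(
        categories={k: dict(v) for k, v in cfg["categories"].items()},
        sales=dict(cfg.get("sales", {"mu": 4.0, "sigma": 1.2})),
        seed=int(seed if seed is not None else cfg["seed"]),
        version=str(cfg.get("version", "custom")),
    ).validate()


def _generate_category(
    rng: np.random.Generator, category: str, block: dict
) -> list[FoodProduct]:
    n = int(block.get("n", 0))
    if n == 0:
        return []
    dists = block["nutrients"]
    total_fat = _draw(rng, dists["total_fat"], n)
    sat_fat = np.minimum(_draw(rng, dists["sat_fat"], n), total_fat)
    sugars = _draw(rng, dists["total_sugars"], n)
    salt = _draw(rng, dists["salt"], n)
    fibre = (
        _draw(rng, dists["fibre"], n) if "fibre" in dists else np.zeros(n)
    )
    protein = _draw(rng, dists["protein"], n)
    if block.get("energy_from_fat"):
        energy = KJ_PER_G_FAT * total_fat
    else:
        energy = _draw(rng, dists["energy"], n)

    wholegrain = np.full(n, np.nan)
    frac = float(block.get("wholegrain_fraction", 0.0))
    if frac > 0:
        is_wg = rng.random(n) < frac
        lo, hi = block.get("wholegrain_range", [50, 100])
        wholegrain[:] = 0.0
        wholegrain[is_wg] = rng.uniform(lo, hi, size=int(is_wg.sum()))
        if "wholegrain_fibre" in block and is_wg.any():
            fibre[is_wg] = _draw(rng, block["wholegrain_fibre"], int(is_wg.sum()))

    calcium = (
        _draw(rng, block["calcium"], n) if "calcium" in block else np.full(n, np.nan)
    )
    sweetener = rng.random(n) < float(block.get("sweetener_prob", 0.0))
    baseline = block.get("added_sugar_baseline")
    added = (
        np.maximum(0.0, sugars - float(baseline)) if baseline is not None else None
    )

    products = []
    for i in range(n):
        panel = NutrientPanel(
            energy=float(energy[i]),
            total_fat=float(total_fat[i]),
            sat_fat=float(sat_fat[i]),
            total_sugars=float(sugars[i]),
            salt=float(salt[i]),
            protein=float(protein[i]),
            fibre=float(fibre[i]),
            added_sugars=float(added[i]) if added is not None else None,
            wholegrain=None if np.isnan(wholegrain[i]) else float(wholegrain[i]),
            calcium=None if np.isnan(calcium[i]) else float(calcium[i]),
            sweetener_present=bool(sweetener[i]),
        ).validate()
        products.append(
            FoodProduct(
                id=f"SYN-{category}-{i:04d}",
                name=f"synthetic {category.replace('_', ' ')} {i}",
                category=category,
                panel=panel,
            )
        )
    return products


def generate_supply(spec: SupplySpec) -> list[FoodProduct]:
    """Generate the synthetic supply (without sales); seed-deterministic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    products: list[FoodProduct] = []
    for category, block in spec.categories.items():
        products.extend(_generate_category(rng, category, block))
    logger.info("generated %d synthetic products", len(products))
    return products


def _healthiness_index(product: FoodProduct) -> float:
    """Continuous nutrient-quality index: the negated Ofcom score."""
    category = resolve_category(product, "ofcom")
    return -float(ofcom(product.panel, category).final_score)


def attach_sales(products: list[FoodProduct], spec: SupplySpec) -> list[FoodProduct]:
    """Attach heavy-tailed 12-month sales units.

    Log-sales are ``mu + b * z + sigma * eps`` with ``z`` the within-category
    standardised healthiness index and ``b`` the category's sales bias;
    ``b = 0`` leaves sales independent of composition.
    """
    rng = np.random.default_rng((int(spec.seed) << 1) ^ 0x5A1E5)
    mu = float(spec.sales.get("mu", 4.0))
    sigma = float(spec.sales.get("sigma", 1.2))
    out: list[FoodProduct] = []
    by_cat: dict[str, list[int]] = {}
    for idx, p in enumerate(products):
        by_cat.setdefault(p.category, []).append(idx)

    sales = np.zeros(len(products))
    for category, indices in by_cat.items():
        bias = float(spec.categories.get(category, {}).get("sales_bias", 0.0))
        q = np.array([_healthiness_index(products[i]) for i in indices])
        sd = q.std()
        z = (q - q.mean()) / sd if sd > 0 else np.zeros_like(q)
        log_sales = mu + bias * z + sigma * rng.standard_normal(len(indices))
        sales[indices] = np.maximum(1.0, np.round(np.exp(log_sales)))
    for idx, p in enumerate(products):
        out.append(replace(p, sales_units=float(sales[idx])))
    return out


def generate_market(spec: SupplySpec) -> list[FoodProduct]:
    """Generate the supply and attach sales in one call."""
    return attach_sales(generate_supply(spec), spec)


def synthetic_oil_supply(n: int = 50, seed: int = 0) -> list[FoodProduct]:
    """A seeded set of synthetic cooking oils only.

    Total fat uniform on [91, 100] g/100 g, saturated fat truncated-normal
    on [7, 92] (clipped to total fat), energy 37 kJ per g fat, all other
    nutrients zero — the oil block of the default spec.
    """
    base = default_spec(seed)
    oil_block = dict(base.categories["cooking_oil"], n=int(n))
    spec = SupplySpec(
        categories={"cooking_oil": oil_block},
        sales=base.sales,
        seed=int(seed),
        version=base.version,
    )
    return generate_supply(spec)
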