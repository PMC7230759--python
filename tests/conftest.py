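"""Shared fixtures: seeded random panels/products and small fixed supplies."""

from __future__ import annotations

import numpy as np
import pytest

from nutriprofile.classify import classify_product
from nutriprofile.supply import LEAF_CATEGORIES, FoodProduct, NutrientPanel

GRADE_RANK = {"E": 0, "D": 1, "C": 2, "B": 3, "A": 4}


def random_panel(rng: np.random.Generator) -> NutrientPanel:
    """One random valid panel spanning the whole plausible label space."""
    total_fat = rng.uniform(0, 100)
    sat_fat = total_fat * rng.uniform(0, 1)
    sugars = rng.uniform(0, 60)
    return NutrientPanel(
        energy=rng.uniform(0, 3800),
        total_fat=total_fat,
        sat_fat=sat_fat,
        total_sugars=sugars,
        salt=rng.uniform(0, 3),
        protein=rng.uniform(0, 30),
        fibre=rng.uniform(0, 12),
        trans_fat=float(min(total_fat - sat_fat, rng.uniform(0, 2)))
        if rng.random() < 0.3
        else None,
        added_sugars=float(sugars * rng.uniform(0, 1)) if rng.random() < 0.5 else None,
        fvn=float(rng.uniform(0, 100)) if rng.random() < 0.4 else None,
        wholegrain=float(rng.uniform(0, 100)) if rng.random() < 0.3 else None,
        calcium=float(rng.uniform(0, 1200)) if rng.random() < 0.5 else None,
        sweetener_present=bool(rng.random() < 0.1),
    )


def random_product(rng: np.random.Generator, i: int = 0) -> FoodProduct:
    return FoodProduct(
        id=f"R{i:05d}",
        name=f"random product {i}",
        category=str(rng.choice(LEAF_CATEGORIES)),
        panel=random_panel(rng),
    )


def verdict_rank(product: FoodProduct, model: str):
    """Ordinal verdict (higher = healthier) for monotonicity checks."""
    v = classify_product(product, model)
    if model == "nutriscore":
        return GRADE_RANK[v.detail.grade]
    if model == "hsr":
        return float(v.detail.grade)  # stars
    return int(v.healthier)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240331)


@pytest.fixture
def zero_panel() -> NutrientPanel:
    return NutrientPanel(
        energy=0, total_fat=0, sat_fat=0, total_sugars=0, salt=0, protein=0
    )


@pytest.fixture
def oil_panel() -> NutrientPanel:
    """Olive-oil-like panel: 100 g fat, 14% saturated, 3700 kJ."""
    return NutrientPanel(
        energy=3700, total_fat=100, sat_fat=14, total_sugars=0, salt=0, protein=0
    )


@pytest.fixture
def yoghurt_panel() -> NutrientPanel:
    """Plain-yoghurt-like panel (sodium 40 mg from 0.1 g salt)."""
    return NutrientPanel(
        energy=260, total_fat=3.5, sat_fat=2.4, total_sugars=4.7, salt=0.1, protein=4.0
    )


@pytest.fixture
def small_supply(rng) -> list[FoodProduct]:
    """A fixed 12-product mixed-category supply."""
    return [random_product(rng, i) for i in range(12)]
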