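"""Classification matrix, proportions, Cohen's kappa and scenario tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import random_product
from nutriprofile.classify import ALL_MODELS, classify_all, classify_product
from nutriprofile.errors import InputError, UndefinedProportionError
from nutriprofile.reports import (
    band_label,
    cohens_kappa,
    kappa_report,
    proportion_healthier,
    proportion_report,
    sales_weighted_proportion,
    scenario_table,
)
from nutriprofile.supply import FoodProduct, NutrientPanel


def _flag_matrix(flags_by_model, category="pasta"):
    """Build a ClassificationMatrix-like object from given healthier flags."""
    from nutriprofile.classify import ClassificationMatrix

    rows = []
    n = len(next(iter(flags_by_model.values())))
    for model, flags in flags_by_model.items():
        for i, f in enumerate(flags):
            rows.append(
                {"product_id": f"p{i}", "category": category, "model": model,
                 "healthier": bool(f), "raw": ""}
            )
    return ClassificationMatrix(
        table=pd.DataFrame(rows), versions={m: "test" for m in flags_by_model}
    )


class TestClassifyAll:
    def test_empty_supply_gives_empty_matrix(self):
        m = classify_all([])
        assert m.table.empty

    def test_one_product_ten_models_ten_cells(self, rng):
        m = classify_all([random_product(rng)])
        assert len(m.table) == len(ALL_MODELS)

    def test_matrix_matches_single_calls(self, small_supply):
        m = classify_all(small_supply)
        for p in small_supply:
            for model in ALL_MODELS:
                cell = m.table[
                    (m.table.product_id == p.id) & (m.table.model == model)
                ]
                assert bool(cell.healthier.iloc[0]) == classify_product(p, model).healthier

    def test_unknown_model_rejected(self, small_supply):
        with pytest.raises(InputError, match="nova"):
            classify_all(small_supply, ["nova"])

    def test_versions_recorded(self, small_supply):
        m = classify_all(small_supply, ["nutriscore"])
        assert m.versions["nutriscore"] == "2017-foods"

    def test_determinism(self, small_supply):
        a = classify_all(small_supply).table
        b = classify_all(small_supply).table
        pd.testing.assert_frame_equal(a, b)


class TestProportions:
    def test_three_quarters(self):
        m = _flag_matrix({"keyhole": [True, True, True, False]})
        r = proportion_healthier(m, "pasta", "keyhole")
        assert (r.n, r.n_healthier, r.proportion) == (4, 3, 0.75)

    @pytest.mark.parametrize("flags,expected", [([0, 0, 0], 0.0), ([1, 1, 1], 1.0)])
    def test_degenerate_proportions(self, flags, expected):
        m = _flag_matrix({"keyhole": flags})
        assert proportion_healthier(m, "pasta", "keyhole").proportion == expected

    def test_empty_category_is_error_not_zero(self):
        m = _flag_matrix({"keyhole": [True]})
        with pytest.raises(UndefinedProportionError):
            proportion_healthier(m, "cheese", "keyhole")


def _products_with_sales(sales, category="pasta"):
    p = NutrientPanel(energy=1500, total_fat=1.5, sat_fat=0.3, total_sugars=3,
                      salt=0.02, protein=12)
    return [
        FoodProduct(f"p{i}", "x", category, p, sales_units=s)
        for i, s in enumerate(sales)
    ]


class TestSalesWeighted:
    def test_worked_example(self):
        m = _flag_matrix({"keyhole": [True, True, True, False]})
        products = _products_with_sales([10, 10, 10, 70])
        r = sales_weighted_proportion(m, products, "pasta", "keyhole")
        assert r.proportion == pytest.approx(0.30)

    def test_equal_sales_equals_unweighted(self):
        flags = [True, False, True, False, True]
        m = _flag_matrix({"keyhole": flags})
        products = _products_with_sales([7] * 5)
        r = sales_weighted_proportion(m, products, "pasta", "keyhole")
        assert r.proportion == proportion_healthier(m, "pasta", "keyhole").proportion

    def test_single_seller_dominance(self):
        m = _flag_matrix({"keyhole": [True, False]})
        products = _products_with_sales([100, None])
        r = sales_weighted_proportion(m, products, "pasta", "keyhole")
        assert r.proportion == 1.0 and r.n_excluded == 1

    def test_zero_total_sales_is_error(self):
        m = _flag_matrix({"keyhole": [True, False]})
        products = _products_with_sales([None, None])
        with pytest.raises(UndefinedProportionError):
            sales_weighted_proportion(m, products, "pasta", "keyhole")


class TestCohensKappa:
    def test_identical_nonconstant_lists(self):
        r = cohens_kappa([1, 0, 1, 1], [1, 0, 1, 1])
        assert r.kappa == pytest.approx(1.0) and not r.degenerate

    def test_one_constant_rater_gives_zero(self):
        r = cohens_kappa([1, 1, 1, 1], [1, 0, 1, 0])
        assert r.kappa == pytest.approx(0.0) and not r.degenerate

    def test_worked_2x2_table(self):
        # a=20 TT, b=5 TF, c=10 FT, d=65 FF: p_o=0.85, p_e=0.60 -> 0.625
        x = [1] * 25 + [0] * 75
        y = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 65
        assert cohens_kappa(x, y).kappa == pytest.approx(0.625)

    def test_both_constant_degenerate_convention(self):
        r = cohens_kappa([0, 0, 0], [0, 0, 0])
        assert r.kappa == 0.0 and r.degenerate

    def test_symmetry(self, rng):
        for _ in range(100):
            x = rng.random(40) < rng.random()
            y = rng.random(40) < rng.random()
            assert cohens_kappa(x, y).kappa == pytest.approx(
                cohens_kappa(y, x).kappa, abs=1e-15
            )

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            cohens_kappa([1, 0], [1, 0, 1])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        checked = 0
        while checked < 500:
            n = int(rng.integers(10, 200))
            x = rng.random(n) < rng.random()
            y = rng.random(n) < rng.random()
            r = cohens_kappa(x, y)
            if r.degenerate:
                continue
            expected = cohen_kappa_score(x, y, labels=[False, True])
            assert r.kappa == pytest.approx(float(expected), abs=1e-12)
            checked += 1


class TestBandLabel:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (0.16, "none-to-slight"),
            (0.625, "substantial"),
            (0.96, "near perfect"),
            (0.0, "none-to-slight"),
            (-0.4, "none-to-slight"),
            (1.0, "near perfect"),
            (0.20, "none-to-slight"),
            (0.21, "fair"),
            (0.41, "moderate"),
            (0.61, "substantial"),
            (0.81, "near perfect"),
        ],
    )
    def test_printed_ranges(self, kappa, label):
        assert band_label(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            band_label(1.5)


class TestScenarioTable:
    def test_enumerated_cross_tab(self):
        m = _flag_matrix(
            {"protective_food": [1, 0, 1, 0], "nutriscore": [1, 1, 0, 0]}
        )
        sc = scenario_table(m, "protective_food", "nutriscore")
        assert sc.counts == {"A": 1, "B": 1, "C": 1, "D": 1}
        assert sc.conflict_pct == pytest.approx(25.0)
        assert sum(sc.percentages.values()) == pytest.approx(100.0)

    def test_no_symbols_means_no_conflict(self):
        m = _flag_matrix({"protective_food": [0, 0, 0], "nutriscore": [1, 0, 1]})
        assert scenario_table(m, "protective_food", "nutriscore").conflict_pct == 0.0

    def test_symbol_implies_green_means_no_conflict(self):
        m = _flag_matrix({"keyhole": [1, 1, 0, 0], "nutriscore": [1, 1, 1, 0]})
        assert scenario_table(m, "keyhole", "nutriscore").conflict_pct == 0.0

    def test_rating_model_without_green_notion_rejected(self):
        m = _flag_matrix({"keyhole": [1, 0], "ofcom": [1, 0]})
        with pytest.raises(InputError):
            scenario_table(m, "keyhole", "ofcom")

    def test_conservation_on_synthetic_market(self, small_supply):
        m = classify_all(small_supply)
        sc = scenario_table(m, "protective_food", "nutriscore")
        assert sc.n == len(small_supply)


class TestReports:
    def test_proportion_report_shape(self, small_supply):
        m = classify_all(small_supply)
        rep = proportion_report(m)
        assert set(rep["model"]) == set(ALL_MODELS)
        assert ((rep["proportion"] >= 0) & (rep["proportion"] <= 1)).all()

    def test_kappa_report_bounds_and_bands(self, small_supply):
        m = classify_all(small_supply)
        rep = kappa_report(m, "nutriscore")
        assert ((rep["kappa"] >= -1) & (rep["kappa"] <= 1)).all()
        assert all(band_label(k) == b for k, b in zip(rep["kappa"], rep["band"]))
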