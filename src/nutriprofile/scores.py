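"""The four point-scoring profiling models: Nutri-Score, Ofcom NPM,
FSANZ NPSC and the Health Star Rating.

All four share one skeleton: negative/baseline points from energy,
saturated fat, total sugars and sodium, minus positive/modifying points
from fruit-vegetable-nut content, fibre and protein, with a rule that
suppresses protein points for energy-dense products unless they are rich
in fruit/vegetables (or belong to an exempt category).  The numeric
thresholds, caps, suppression parameters and class boundaries come from
the versioned tables in :mod:`nutriprofile.config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PointTables, load_point_tables
from .errors import ConfigError, InputError
from .supply import NutrientPanel

logger = logging.getLogger(__name__)


@dataclass
class ScoreBreakdown:
    """Full scoring trace for one panel under one model."""

    model: str
    category: str
    version: str
    component_points: dict[str, int]
    negative_total: int
    positive_total: int
    protein_suppressed: bool
    final_score: int
    grade: str | float | None
    healthier: bool
    notes: list[str] = field(default_factory=list)

    @property
    def raw(self) -> str:
        """Compact human-readable verdict (grade/stars/score)."""
        if self.model == "nutriscore":
            return f"{self.grade} ({self.final_score:+d})"
        if self.model == "hsr":
            return f"{self.grade} stars ({self.final_score:+d})"
        return f"score {self.final_score:+d} ({'pass' if self.healthier else 'fail'})"


def table_points(value: float, component: dict) -> int:
    """Points for one component: count thresholds exceeded, map to points.

    ``comparator: gt`` awards the k-th points entry once value > threshold k;
    ``ge`` once value >= threshold k.
    """
    thresholds = np.asarray(component["thresholds"], dtype=float)
    side = "left" if component["comparator"] == "gt" else "right"
    k = int(np.searchsorted(thresholds, value, side=side))
    return int(component["points"][k - 1]) if k else 0


def _positive_points(
    panel: NutrientPanel, tables: PointTables
) -> tuple[dict[str, int], str]:
    fibre_variant = tables.raw.get("fibre_variant", "fibre")
    pts = {
        "fvn": table_points(panel.fvn or 0.0, tables.component("positive", "fvn")),
        "fibre": table_points(panel.fibre, tables.component("positive", fibre_variant)),
        "protein": table_points(panel.protein, tables.component("positive", "protein")),
    }
    return pts, fibre_variant


def _suppress_protein(
    tables: PointTables, category: str, negative_total: int, fvn_points: int
) -> bool:
    rule = tables.raw["protein_suppression"]
    floor = rule.get("negative_min", rule.get("baseline_min"))
    if category in rule.get("exempt_categories", []):
        return False
    return negative_total >= floor and fvn_points < rule["fvn_exempt_points"]


def _grade_from_bands(score: float, bands: list[dict], key: str):
    for band in bands:
        if band["max"] is None or score <= band["max"]:
            return band[key]
    raise ConfigError("class-boundary table has no terminal band")


def _require_category(tables: PointTables, category: str) -> None:
    if category not in tables.raw["categories"]:
        raise InputError(
            f"{tables.model} has no category {category!r}; "
            f"expected one of {tables.raw['categories']}"
        )


def nutriscore(
    panel: NutrientPanel, category: str, tables: PointTables | None = None
) -> ScoreBreakdown:
    """Nutri-Score 2017 foods algorithm.

    ``category`` is one of ``general_food``, ``cheese``, ``added_fats``.
    Added fats score saturated fat as the percentage of saturated in total
    fat; cheese is exempt from protein suppression.  Healthier = grade A/B.
    """
    tables = tables or load_point_tables("nutriscore")
    _require_category(tables, category)
    notes: list[str] = []

    points: dict[str, int] = {
        "energy": table_points(panel.energy, tables.component("negative", "energy")),
        "total_sugars": table_points(
            panel.total_sugars, tables.component("negative", "total_sugars")
        ),
        "sodium": table_points(panel.sodium, tables.component("negative", "sodium")),
    }
    if category == "added_fats":
        if panel.total_fat > 0:
            ratio = 100.0 * panel.sat_fat / panel.total_fat
            points["sat_fat"] = table_points(
                ratio, tables.component("negative", "sat_fat_ratio")
            )
        else:
            points["sat_fat"] = 0
            notes.append("added_fats with total_fat=0: ratio undefined, 0 points")
            logger.warning("added_fats panel has zero total fat; ratio points set to 0")
    else:
        points["sat_fat"] = table_points(
            panel.sat_fat, tables.component("negative", "sat_fat")
        )
    negative_total = sum(points.values())

    pos, _ = _positive_points(panel, tables)
    suppressed = _suppress_protein(tables, category, negative_total, pos["fvn"])
    if suppressed:
        pos["protein"] = 0
    points.update(pos)
    positive_total = sum(pos.values())

    score = negative_total - positive_total
    grade = _grade_from_bands(score, tables.raw["grades"], "grade")
    return ScoreBreakdown(
        model="nutriscore",
        category=category,
        version=tables.version,
        component_points=points,
        negative_total=negative_total,
        positive_total=positive_total,
        protein_suppressed=suppressed,
        final_score=score,
        grade=grade,
        healthier=grade in tables.raw["healthier_grades"],
        notes=notes,
    )


def _baseline_minus_modifying(
    panel: NutrientPanel, category: str, tables: PointTables
) -> tuple[dict[str, int], int, int, bool]:
    """Shared Ofcom/FSANZ/HSR arithmetic (NPSC-style tables)."""
    sat_component = "sat_fat"
    if category in tables.raw.get("extended_sat_fat_categories", []):
        sat_component = "sat_fat_extended"
    points = {
        "energy": table_points(panel.energy, tables.component("negative", "energy")),
        "sat_fat": table_points(
            panel.sat_fat, tables.component("negative", sat_component)
        ),
        "total_sugars": table_points(
            panel.total_sugars, tables.component("negative", "total_sugars")
        ),
        "sodium": table_points(panel.sodium, tables.component("negative", "sodium")),
    }
    negative_total = sum(points.values())
    pos, _ = _positive_points(panel, tables)
    suppressed = _suppress_protein(tables, category, negative_total, pos["fvn"])
    if suppressed:
        pos["protein"] = 0
    points.update(pos)
    return points, negative_total, sum(pos.values()), suppressed


def ofcom(
    panel: NutrientPanel, category: str, tables: PointTables | None = None
) -> ScoreBreakdown:
    """Ofcom nutrient profile model (A-points minus C-points).

    Healthier = permitted for marketing to children: score below 4 for
    foods, below 1 for drinks.
    """
    tables = tables or load_point_tables("ofcom")
    _require_category(tables, category)
    points, neg, pos, suppressed = _baseline_minus_modifying(panel, category, tables)
    score = neg - pos
    permitted = score < tables.raw["pass_below"][category]
    return ScoreBreakdown(
        model="ofcom",
        category=category,
        version=tables.version,
        component_points=points,
        negative_total=neg,
        positive_total=pos,
        protein_suppressed=suppressed,
        final_score=score,
        grade="pass" if permitted else "fail",
        healthier=permitted,
    )


def fsanz(
    panel: NutrientPanel, category: str, tables: PointTables | None = None
) -> ScoreBreakdown:
    """FSANZ nutrient profiling scoring criterion (NPSC).

    Healthier = permitted to carry nutrition/health claims: score below 1
    (beverages), 4 (foods) or 28 (oils/spreads and high-calcium cheese).
    """
    tables = tables or load_point_tables("fsanz")
    _require_category(tables, category)
    points, neg, pos, suppressed = _baseline_minus_modifying(panel, category, tables)
    score = neg - pos
    eligible = score < tables.raw["pass_below"][category]
    return ScoreBreakdown(
        model="fsanz",
        category=category,
        version=tables.version,
        component_points=points,
        negative_total=neg,
        positive_total=pos,
        protein_suppressed=suppressed,
        final_score=score,
        grade="pass" if eligible else "fail",
        healthier=eligible,
    )


def hsr(
    panel: NutrientPanel, category: str, tables: PointTables | None = None
) -> ScoreBreakdown:
    """Health Star Rating: baseline minus modifying points, then the
    category's score-to-star breakpoint table.  Healthier = >= 3.5 stars.
    """
    tables = tables or load_point_tables("hsr")
    _require_category(tables, category)
    points, neg, pos, suppressed = _baseline_minus_modifying(panel, category, tables)
    score = neg - pos
    try:
        star_bands = tables.raw["star_map"][category]
    except KeyError as exc:
        raise ConfigError(f"hsr star map lacks category {category!r}") from exc
    stars = float(_grade_from_bands(score, star_bands, "stars"))
    return ScoreBreakdown(
        model="hsr",
        category=category,
        version=tables.version,
        component_points=points,
        negative_total=neg,
        positive_total=pos,
        protein_suppressed=suppressed,
        final_score=score,
        grade=stars,
        healthier=stars >= tables.raw["healthier_min_stars"],
    )
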