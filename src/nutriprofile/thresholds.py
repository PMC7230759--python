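"""Threshold-based schemes: UK FSA traffic light, Protective Food symbol,
Keyhole, Choices, Finnish Heart and the WHO-Europe profile model.

Each scheme is a conjunction of per-category limit rules over quantities
derivable from the nutrient panel; the numeric limits are versioned config
data.  Quantities that a label may legitimately omit (trans fat, added
sugars, fruit/vegetable/nut share, wholegrain) default to zero; quantities
that cannot be defaulted (e.g. calcium) raise a configuration error when a
rule needs them and the panel lacks them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import config_version, load_config
from .errors import ConfigError
from .supply import DAIRY_CATEGORIES, NutrientPanel

logger = logging.getLogger(__name__)

TRAFFIC_NUTRIENTS = ("total_fat", "sat_fat", "total_sugars", "salt")

#: Optional panel quantities that conservatively default to zero.
_ZERO_DEFAULT = ("trans_fat", "added_sugars", "fvn", "wholegrain")


def resolve_quantity(panel: NutrientPanel, name: str) -> float:
    """Resolve a rule quantity (nutrient or derived value) from a panel."""
    if name in ("energy", "total_fat", "sat_fat", "total_sugars", "salt",
                "fibre", "protein", "sodium"):
        return float(getattr(panel, name))
    if name in _ZERO_DEFAULT:
        v = getattr(panel, name)
        return 0.0 if v is None else float(v)
    if name == "calcium":
        if panel.calcium is None:
            raise ConfigError("rule requires calcium but the panel declares none")
        return float(panel.calcium)
    if name == "sat_fat_share_pct":
        if panel.total_fat <= 0:
            return 0.0
        return 100.0 * panel.sat_fat / panel.total_fat
    if name == "unsat_fat":
        return max(0.0, panel.total_fat - panel.sat_fat - (panel.trans_fat or 0.0))
    raise ConfigError(f"rule references unknown quantity {name!r}")


@dataclass(frozen=True)
class ThresholdRule:
    """One limit: quantity OP limit, e.g. ``sat_fat <= 1.5``."""

    quantity: str
    op: str  # one of <=, <, >=, >
    limit: float
    note: str = ""

    def holds(self, panel: NutrientPanel) -> bool:
        v = resolve_quantity(panel, self.quantity)
        if self.op == "<=":
            return v <= self.limit
        if self.op == "<":
            return v < self.limit
        if self.op == ">=":
            return v >= self.limit
        if self.op == ">":
            return v > self.limit
        raise ConfigError(f"unknown comparator {self.op!r}")

    def __str__(self) -> str:
        return f"{self.quantity} {self.op} {self.limit:g}"


@dataclass(frozen=True)
class RuleSet:
    """Conjunctive rule set of one scheme for one category."""

    model: str
    version: str
    category: str
    rules: tuple[ThresholdRule, ...] = ()
    no_sweetener: bool = False
    never_eligible: bool = False
    reason: str = ""


@dataclass
class Eligibility:
    """Outcome of a rule-set evaluation: verdict plus every failed rule."""

    model: str
    category: str
    version: str
    eligible: bool
    failed: list[str] = field(default_factory=list)

    @property
    def raw(self) -> str:
        return "eligible" if self.eligible else "fail: " + "; ".join(self.failed)


def evaluate_ruleset(panel: NutrientPanel, rules: RuleSet) -> Eligibility:
    """Evaluate a conjunctive rule set; empty rule lists are vacuously true."""
    if rules.never_eligible:
        return Eligibility(
            model=rules.model,
            category=rules.category,
            version=rules.version,
            eligible=False,
            failed=[rules.reason or "category never eligible under this scheme"],
        )
    failed = [str(r) for r in rules.rules if not r.holds(panel)]
    if rules.no_sweetener and panel.sweetener_present:
        failed.append("sweetener present")
    return Eligibility(
        model=rules.model,
        category=rules.category,
        version=rules.version,
        eligible=not failed,
        failed=failed,
    )


def load_ruleset(scheme: str, category: str) -> RuleSet:
    """Load one scheme-category rule set from the shipped config."""
    cfg = load_config(scheme)
    block = cfg.get("categories", {}).get(category)
    if block is None:
        raise ConfigError(
            f"{scheme} config has no rule set (nor never-eligible marker) "
            f"for category {category!r}"
        )
    if block.get("never_eligible"):
        return RuleSet(
            model=scheme,
            version=str(cfg["version"]),
            category=category,
            never_eligible=True,
            reason=str(block.get("reason", "")),
        )
    rules = tuple(
        ThresholdRule(
            quantity=r["quantity"],
            op=r["op"],
            limit=float(r["limit"]),
            note=str(r.get("note", "")),
        )
        for r in block.get("rules", [])
    )
    return RuleSet(
        model=scheme,
        version=str(cfg["version"]),
        category=category,
        rules=rules,
        no_sweetener=bool(block.get("no_sweetener", False)),
    )


def symbol_scheme(panel: NutrientPanel, category: str, scheme: str) -> Eligibility:
    """Evaluate one of the config-driven symbol schemes
    (keyhole, choices, finnish_heart, whoe) on a leaf category."""
    if scheme not in ("keyhole", "choices", "finnish_heart", "whoe"):
        raise ConfigError(f"{scheme!r} is not a threshold symbol scheme")
    return evaluate_ruleset(panel, load_ruleset(scheme, category))


@dataclass
class TrafficLightResult:
    """Per-nutrient colours plus the no-red harmonised verdict."""

    colours: dict[str, str]
    version: str

    @property
    def healthier(self) -> bool:
        return "red" not in self.colours.values()

    @property
    def raw(self) -> str:
        return "/".join(self.colours[n][0].upper() for n in TRAFFIC_NUTRIENTS)


def traffic_light(panel: NutrientPanel, bands: dict | None = None) -> TrafficLightResult:
    """UK FSA per-100 g traffic light over fat, sat fat, sugars and salt.

    Applied to every category, including single-ingredient cooking oils.
    """
    cfg = bands or load_config("traffic_light")["bands"]
    colours = {}
    for nutrient in TRAFFIC_NUTRIENTS:
        band = cfg[nutrient]
        value = getattr(panel, nutrient)
        if value <= band["green_max"]:
            colours[nutrient] = "green"
        elif value > band["red_above"]:
            colours[nutrient] = "red"
        else:
            colours[nutrient] = "amber"
    return TrafficLightResult(colours=colours, version=config_version("traffic_light"))


def claim_high_unsaturated(panel: NutrientPanel, params: dict | None = None) -> bool:
    """Eligibility for a high-in-unsaturated-fat nutrition claim.

    True iff unsaturated fat makes up at least 70% of total fat and
    supplies more than 20% of the product's energy (37 kJ per g of fat).
    The parameters are config-replaceable (Protective Food config).
    """
    p = params or load_config("protective_food")["oil_claim"]
    if panel.total_fat <= 0:
        logger.warning("high-unsaturated claim on zero-fat panel: not eligible")
        return False
    unsat = resolve_quantity(panel, "unsat_fat")
    share_ok = 100.0 * unsat / panel.total_fat >= p["min_unsat_share_pct"]
    if panel.energy <= 0:
        # degenerate declaration: the energy share tends to infinity
        energy_ok = unsat > 0
    else:
        energy_share = 100.0 * unsat * p["kj_per_g_fat"] / panel.energy
        energy_ok = energy_share > p["min_unsat_energy_share_pct"]
    return share_ok and energy_ok


def protective_food(panel: NutrientPanel, category: str) -> Eligibility:
    """Slovenian Protective Food symbol.

    Dairy categories require total fat < 3 g and saturated fat < 1.5 g per
    100 g (strict); cooking oils must qualify for an authorised
    nutrition/health claim; every other category must have no red traffic
    light.
    """
    cfg = load_config("protective_food")
    version = str(cfg["version"])
    if category in DAIRY_CATEGORIES:
        d = cfg["dairy"]
        failed = []
        if not panel.total_fat < d["total_fat_below"]:
            failed.append(f"total_fat < {d['total_fat_below']:g}")
        if not panel.sat_fat < d["sat_fat_below"]:
            failed.append(f"sat_fat < {d['sat_fat_below']:g}")
        return Eligibility(
            model="protective_food",
            category=category,
            version=version,
            eligible=not failed,
            failed=failed,
        )
    if category == "cooking_oil":
        ok = claim_high_unsaturated(panel, cfg["oil_claim"])
        return Eligibility(
            model="protective_food",
            category=category,
            version=version,
            eligible=ok,
            failed=[] if ok else ["not eligible for high-unsaturated-fat claim"],
        )
    tl = traffic_light(panel)
    reds = [n for n, c in tl.colours.items() if c == "red"]
    return Eligibility(
        model="protective_food",
        category=category,
        version=version,
        eligible=tl.healthier,
        failed=[f"{n} red" for n in reds],
    )
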