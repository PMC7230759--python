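"""Domain types for prepacked food products and CSV supply-table I/O.

A *supply table* is one row per product with its declared nutrient
composition per 100 g, a leaf food category, and (optionally) 12-month
sales units.  All quantities are per 100 g of product as sold; salt is
converted to sodium with the EU labelling factor of 400 mg sodium per
gram of salt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, RowValidationError

logger = logging.getLogger(__name__)

#: mg of sodium per gram of salt (EU labelling convention: salt = Na x 2.5).
SALT_TO_SODIUM_MG = 400.0

#: The seven leaf food categories in scope.
LEAF_CATEGORIES = (
    "breakfast_cereals",
    "pasta",
    "cheese",
    "yoghurt_plain",
    "yoghurt_flavoured",
    "yoghurt_drink_flavoured",
    "cooking_oil",
)

DAIRY_CATEGORIES = (
    "cheese",
    "yoghurt_plain",
    "yoghurt_flavoured",
    "yoghurt_drink_flavoured",
)

#: Canonical CSV header, in order.
SUPPLY_COLUMNS = (
    "id",
    "name",
    "category",
    "energy_kj",
    "total_fat_g",
    "sat_fat_g",
    "trans_fat_g",
    "total_sugars_g",
    "added_sugars_g",
    "fibre_g",
    "protein_g",
    "salt_g",
    "fvn_pct",
    "wholegrain_pct",
    "calcium_mg",
    "sweetener",
    "sales_units",
)

#: Nutrients whose absence invalidates a row (a product without a declared
#: value cannot be profiled); fibre and the other optionals default to 0.
_MANDATORY = {
    "energy_kj": "energy",
    "total_fat_g": "total_fat",
    "sat_fat_g": "sat_fat",
    "total_sugars_g": "total_sugars",
    "salt_g": "salt",
    "protein_g": "protein",
}


@dataclass(frozen=True)
class NutrientPanel:
    """Declared composition of one product, per 100 g.

    ``fibre`` and the optional nutrients default to zero/absent: a product
    that does not declare a positive nutrient is conservatively assumed to
    contain none of it.
    """

    energy: float  # kJ/100 g
    total_fat: float  # g/100 g
    sat_fat: float  # g/100 g
    total_sugars: float  # g/100 g
    salt: float  # g/100 g
    protein: float  # g/100 g
    fibre: float = 0.0  # g/100 g (AOAC)
    trans_fat: float | None = None  # g/100 g
    added_sugars: float | None = None  # g/100 g
    fvn: float | None = None  # % fruit/vegetable/nut/legume
    wholegrain: float | None = None  # % of cereal dry matter
    calcium: float | None = None  # mg/100 g
    sweetener_present: bool = False

    @property
    def sodium(self) -> float:
        """Sodium in mg/100 g, derived from the salt declaration."""
        return self.salt * SALT_TO_SODIUM_MG

    def violations(self) -> list[str]:
        """Return every violated panel invariant (empty list = valid)."""
        reasons: list[str] = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or isinstance(v, bool):
                continue
            if not math.isfinite(v):
                reasons.append(f"{f.name} is not finite")
            elif v < 0:
                reasons.append(f"{f.name} is negative")
        if self.sat_fat > self.total_fat:
            reasons.append("sat_fat exceeds total_fat")
        if self.trans_fat is not None and self.trans_fat > self.total_fat:
            reasons.append("trans_fat exceeds total_fat")
        if self.added_sugars is not None and self.added_sugars > self.total_sugars:
            reasons.append("added_sugars exceeds total_sugars")
        for name in ("fvn", "wholegrain"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                reasons.append(f"{name} outside [0, 100]")
        return reasons

    def validate(self) -> "NutrientPanel":
        reasons = self.violations()
        if reasons:
            raise RowValidationError("; ".join(reasons))
        return self


@dataclass(frozen=True)
class FoodProduct:
    """One prepacked product: panel + leaf category + optional sales."""

    id: str
    name: str
    category: str
    panel: NutrientPanel
    sales_units: float | None = None

    def violations(self) -> list[str]:
        reasons = self.panel.violations()
        if self.category not in LEAF_CATEGORIES:
            reasons.append(f"unknown category code {self.category!r}")
        if self.sales_units is not None and self.sales_units < 0:
            reasons.append("sales_units is negative")
        if not self.id:
            reasons.append("empty product id")
        return reasons

    def with_sales(self, units: float) -> "FoodProduct":
        return replace(self, sales_units=units)


@dataclass
class RowIssue:
    """Machine-readable record of a rejected supply-table row."""

    row: int
    product_id: str
    reason: str


def _parse_float(raw, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise RowValidationError(f"{column} does not parse as a number: {s!r}") from exc


def _parse_bool(raw) -> bool:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return False
    s = str(raw).strip().lower()
    if s in ("", "0", "false", "no", "n"):
        return False
    if s in ("1", "true", "yes", "y"):
        return True
    raise RowValidationError(f"sweetener flag not boolean: {raw!r}")


def _row_to_product(row: pd.Series, index: int) -> FoodProduct:
    """Build a validated FoodProduct from one CSV row; raise on violation."""
    values: dict[str, float] = {}
    for col, attr in _MANDATORY.items():
        v = _parse_float(row[col], col)
        if v is None:
            raise RowValidationError(f"mandatory nutrient {col} missing")
        values[attr] = v

    fibre = _parse_float(row["fibre_g"], "fibre_g")
    if fibre is None:
        logger.warning("row %d: fibre missing, defaulting to 0", index)
        fibre = 0.0
    optionals = {}
    for col, attr in (
        ("trans_fat_g", "trans_fat"),
        ("added_sugars_g", "added_sugars"),
        ("fvn_pct", "fvn"),
        ("wholegrain_pct", "wholegrain"),
        ("calcium_mg", "calcium"),
    ):
        optionals[attr] = _parse_float(row[col], col)

    panel = NutrientPanel(
        fibre=fibre,
        sweetener_present=_parse_bool(row["sweetener"]),
        **values,
        **optionals,
    )
    product = FoodProduct(
        id=str(row["id"]).strip(),
        name="" if pd.isna(row["name"]) else str(row["name"]),
        category=str(row["category"]).strip(),
        panel=panel,
        sales_units=_parse_float(row["sales_units"], "sales_units"),
    )
    reasons = product.violations()
    if reasons:
        raise RowValidationError("; ".join(reasons))
    return product


def load_supply(path: str | Path) -> tuple[list[FoodProduct], list[RowIssue]]:
    """Read a supply CSV; return (accepted products, rejected rows).

    Every input row lands in exactly one of the two lists, so
    ``len(accepted) + len(rejected)`` equals the number of data rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in SUPPLY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"supply table missing column(s): {', '.join(missing)}")

    products: list[FoodProduct] = []
    rejects: list[RowIssue] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = str(row["id"]).strip()
        try:
            if pid in seen:
                raise RowValidationError(f"duplicate product id {pid!r}")
            product = _row_to_product(row, int(i))
        except RowValidationError as exc:
            rejects.append(RowIssue(row=int(i), product_id=pid, reason=str(exc)))
            continue
        seen.add(pid)
        products.append(product)
    return products, rejects


def read_supply(path: str | Path, strictness: str = "permissive") -> list[FoodProduct]:
    """Read and validate a supply CSV.

    In ``permissive`` mode invalid rows are dropped with a logged warning
    carrying the per-row reason; in ``strict`` mode the first violation
    aborts the read.
    """
    if strictness not in ("strict", "permissive"):
        raise ValueError(f"strictness must be strict|permissive, got {strictness!r}")
    products, rejects = load_supply(path)
    if rejects:
        if strictness == "strict":
            first = rejects[0]
            raise RowValidationError(
                f"row {first.row} (id {first.product_id!r}): {first.reason}"
            )
        for issue in rejects:
            logger.warning(
                "dropping row %d (id %s): %s", issue.row, issue.product_id, issue.reason
            )
    return products


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(v) if isinstance(v, float) else str(v)


def write_supply(products: Iterable[FoodProduct], path: str | Path) -> None:
    """Write products as a supply CSV; inverse of :func:`read_supply`."""
    rows = []
    for p in products:
        n = p.panel
        rows.append(
            {
                "id": p.id,
                "name": p.name,
                "category": p.category,
                "energy_kj": _fmt(n.energy),
                "total_fat_g": _fmt(n.total_fat),
                "sat_fat_g": _fmt(n.sat_fat),
                "trans_fat_g": _fmt(n.trans_fat),
                "total_sugars_g": _fmt(n.total_sugars),
                "added_sugars_g": _fmt(n.added_sugars),
                "fibre_g": _fmt(n.fibre),
                "protein_g": _fmt(n.protein),
                "salt_g": _fmt(n.salt),
                "fvn_pct": _fmt(n.fvn),
                "wholegrain_pct": _fmt(n.wholegrain),
                "calcium_mg": _fmt(n.calcium),
                "sweetener": _fmt(n.sweetener_present),
                "sales_units": _fmt(p.sales_units),
            }
        )
    df = pd.DataFrame(rows, columns=list(SUPPLY_COLUMNS))
    df.to_csv(path, index=False)
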