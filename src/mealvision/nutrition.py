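"""Volumes and packaged-product fractions to weight, energy and macros.

Each fine food category carries a density (g/mL) and per-100 g energy and
macronutrient values, so ``weight = volume x density`` and every nutrient
scales linearly from there.  Lookups try a primary table first and fall
back to a secondary one — mirroring how a production system chains
nutrient databases — and record which table answered.  Packaged products
bypass volume entirely: their per-package nutrients are scaled by the
fraction consumed, keyed by an EAN-13 barcode whose checksum is verified.

Olive oil is the canonical worked example: 54.9 mL (50 g at density
0.91 g/mL) yields 400 kcal and 45 g of fat with the bundled table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidBarcode, MissingNutrientEntry

__all__ = [
    "NutrientRecord", "PackagedProduct", "MealReport", "MealItem",
    "load_nutrient_table", "bundled_table_path", "bundled_secondary_path",
    "lookup", "item_nutrition", "packaged_nutrition",
    "aggregate", "aggregate_day", "ean13_checksum_ok",
]

MEAL_LABELS = ("breakfast", "lunch", "dinner", "snack", "drink")

_COLUMNS = ["fine_category", "density_g_per_mL", "kcal_per_100g",
            "cho_g_per_100g", "protein_g_per_100g", "fat_g_per_100g",
            "serving_volume_mL"]


@dataclass(frozen=True)
class NutrientRecord:
    fine_category: str
    density_g_per_mL: float
    kcal_per_100g: float
    cho_g_per_100g: float
    protein_g_per_100g: float
    fat_g_per_100g: float
    serving_volume_mL: float

    def __post_init__(self):
        if self.density_g_per_mL <= 0:
            raise ValueError(f"{self.fine_category}: density must be > 0")
        for name in ("kcal_per_100g", "cho_g_per_100g", "protein_g_per_100g",
                     "fat_g_per_100g", "serving_volume_mL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.fine_category}: {name} must be >= 0")
        for name in ("cho_g_per_100g", "protein_g_per_100g", "fat_g_per_100g"):
            if getattr(self, name) > 100:
                raise ValueError(
                    f"{self.fine_category}: {name} cannot exceed 100 g/100 g")


def bundled_table_path() -> str:
    return str(resources.files("mealvision.data") / "nutrients_primary.csv")


def bundled_secondary_path() -> str:
    return str(resources.files("mealvision.data") / "nutrients_secondary.csv")


def load_nutrient_table(path: str) -> dict[str, NutrientRecord]:
    """Load and validate a nutrient CSV keyed by fine category."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"nutrient table missing columns {sorted(missing)}")
    table: dict[str, NutrientRecord] = {}
    for i, row in df.iterrows():
        key = str(row["fine_category"])
        if key in table:
            raise ValueError(f"line {i + 2}: duplicate category {key!r}")
        try:
            rec = NutrientRecord(key, *(float(row[c]) for c in _COLUMNS[1:]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {i + 2}: {exc}") from None
        table[key] = rec
    return table


def lookup(category: str, primary: dict[str, NutrientRecord],
           secondary: dict[str, NutrientRecord] | None = None
           ) -> tuple[NutrientRecord, str]:
    """Primary-table hit wins; otherwise the secondary; records provenance."""
    if category in primary:
        return primary[category], "primary"
    if secondary and category in secondary:
        return secondary[category], "secondary"
    raise MissingNutrientEntry(f"category {category!r} in neither table")


def item_nutrition(volume_mL: float, record: NutrientRecord
                   ) -> tuple[float, float, float, float, float]:
    """(weight_g, kcal, cho_g, protein_g, fat_g) for a volume of one item."""
    if volume_mL < 0:
        raise ValueError("volume must be non-negative")
    weight = volume_mL * record.density_g_per_mL
    f = weight / 100.0
    return (weight, f * record.kcal_per_100g, f * record.cho_g_per_100g,
            f * record.protein_g_per_100g, f * record.fat_g_per_100g)


# ---------------------------------------------------------------------------
# packaged products


def ean13_checksum_ok(barcode: str) -> bool:
    if len(barcode) != 13 or not barcode.isdigit():
        return False
    digits = [int(c) for c in barcode]
    checksum = (10 - sum(d * (3 if i % 2 else 1)
                         for i, d in enumerate(digits[:12])) % 10) % 10
    return checksum == digits[12]


@dataclass(frozen=True)
class PackagedProduct:
    barcode: str
    kcal_per_package: float
    cho_g_per_package: float
    protein_g_per_package: float
    fat_g_per_package: float
    fraction_consumed: float
    name: str = ""

    def __post_init__(self):
        if not ean13_checksum_ok(self.barcode):
            raise InvalidBarcode(f"bad EAN-13 checksum: {self.barcode!r}")
        if not (0 < self.fraction_consumed <= 1):
            raise ValueError("fraction_consumed must be in (0, 1]")


def packaged_nutrition(product: PackagedProduct
                       ) -> tuple[float, float, float, float]:
    """Per-package nutrients scaled by the fraction actually consumed."""
    f = product.fraction_consumed
    return (f * product.kcal_per_package, f * product.cho_g_per_package,
            f * product.protein_g_per_package, f * product.fat_g_per_package)


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class MealItem:
    category: str
    volume_mL: float
    weight_g: float
    kcal: float
    cho_g: float
    protein_g: float
    fat_g: float
    flags: dict

    @classmethod
    def from_volume(cls, category: str, volume_mL: float,
                    record: NutrientRecord, flags: dict | None = None
                    ) -> "MealItem":
        w, kcal, cho, prot, fat = item_nutrition(volume_mL, record)
        return cls(category, volume_mL, w, kcal, cho, prot, fat,
                   dict(flags or {}))


@dataclass
class MealReport:
    meal_label: str
    items: list[MealItem]
    totals: dict

    def to_dict(self) -> dict:
        return {
            "meal_label": self.meal_label,
            "items": [vars(i).copy() for i in self.items],
            "totals": dict(self.totals),
        }


def aggregate(items: list[MealItem], meal_label: str) -> MealReport:
    """Element-wise nutrient totals for one meal."""
    if meal_label not in MEAL_LABELS:
        raise ValueError(f"meal_label must be one of {MEAL_LABELS}")
    totals = {k: float(sum(getattr(i, k) for i in items))
              for k in ("kcal", "cho_g", "protein_g", "fat_g", "weight_g",
                        "volume_mL")}
    return MealReport(meal_label, list(items), totals)


def aggregate_day(meal_reports: list[MealReport]) -> dict:
    """Whole-day totals: the sum over meals, independent of grouping."""
    keys = ("kcal", "cho_g", "protein_g", "fat_g", "weight_g", "volume_mL")
    return {k: float(sum(m.totals.get(k, 0.0) for m in meal_reports))
            for k in keys}
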