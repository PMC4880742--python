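"""Carbohydrate computation from food volumes and per-class densities.

Each food class carries a single mean carbohydrate density in grams of
carbohydrate per ml of served food, obtained by averaging the relevant
entries of a nutrient database (carbs per 100 g combined with a typical
served mass density).  Carbohydrate grams are then volume x density,
exactly linear and additive across the items of a meal.

The packaged ``data/carb_density.csv`` is a small plausible table for
testing and demonstration, not nutritional ground truth; deployments
must supply a table derived from a real nutrient database in the same
schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .scene_synth import FOOD_CLASSES

_COLUMNS = ["food_class", "carb_density_g_per_ml", "n_source_entries", "source_note"]


@dataclass
class DensityTable:
    """One carbohydrate density (g/ml) per food class."""

    rows: pd.DataFrame

    def density_of(self, food_class: str) -> float:
        sel = self.rows.loc[self.rows["food_class"] == food_class,
                            "carb_density_g_per_ml"]
        if sel.empty:
            raise SchemaError(f"unknown food class {food_class!r}")
        return float(sel.iloc[0])


@dataclass
class MealEstimate:
    """Per-item and total carbohydrate grams of one meal."""

    items: list[dict]            # {region_id, food_class, volume_ml, carbs_g}
    total_carbs_g: float

    def to_json(self) -> str:
        return json.dumps({"items": self.items, "total_carbs_g": self.total_carbs_g},
                          indent=1)


def default_density_table_path() -> Path:
    return Path(str(resources.files("carbplate").joinpath("data/carb_density.csv")))


def load_density_table(path: str | Path | None = None) -> DensityTable:
    """Load and validate a density table CSV.

    Requires exactly one positive-density row per food class; schema
    violations name the offending row or class.
    """
    path = Path(path) if path is not None else default_density_table_path()
    if not path.exists():
        raise SchemaError(f"density table not found: {path}")
    df = pd.read_csv(path)
    missing_cols = set(_COLUMNS[:2]) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"density table missing columns: {sorted(missing_cols)}")
    dup = df["food_class"][df["food_class"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate food class rows: {sorted(set(dup))}")
    missing = set(FOOD_CLASSES) - set(df["food_class"])
    if missing:
        raise SchemaError(f"density table missing classes: {sorted(missing)}")
    unknown = set(df["food_class"]) - set(FOOD_CLASSES)
    if unknown:
        raise SchemaError(f"density table has unknown classes: {sorted(unknown)}")
    bad = df[~(df["carb_density_g_per_ml"] > 0)]
    if not bad.empty:
        raise SchemaError(
            "nonpositive carbohydrate density for: "
            + ", ".join(bad["food_class"].astype(str)))
    return DensityTable(rows=df.reset_index(drop=True))


def mean_density(entries) -> float:
    """Arithmetic mean of per-entry densities (all must be positive)."""
    arr = np.asarray(list(entries), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_density needs at least one entry")
    if np.any(arr <= 0):
        raise ValueError("densities must be positive")
    return float(arr.mean())


def carbs_from_volume(volume_ml: float, food_class: str, table: DensityTable) -> float:
    """grams = volume (ml) x class density (g/ml)."""
    if volume_ml < 0:
        raise ValueError("volume must be nonnegative")
    return volume_ml * table.density_of(food_class)


def meal_estimate(volumes_ml: dict[int, float], classes: dict[int, str],
                  table: DensityTable) -> MealEstimate:
    """Combine per-region volumes and classes into a meal estimate."""
    items = []
    total = 0.0
    for region_id in sorted(volumes_ml):
        cls = classes[region_id]
        g = carbs_from_volume(volumes_ml[region_id], cls, table)
        items.append({"region_id": int(region_id), "food_class": cls,
                      "volume_ml": float(volumes_ml[region_id]),
                      "carbs_g": float(g)})
        total += g
    return MealEstimate(items=items, total_carbs_g=float(total))
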