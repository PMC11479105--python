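"""Per-mass scaling of compositions and dish-level nutrient totals.

FCDB values are per 100 g edible part; each ingredient use is scaled by
its served grams and the dish total is the component-wise sum over uses.
No assertion ties total energy to 4/9/4 times the macronutrients — the
energy definitions of the two databases legitimately differ (fiber).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fcdb import FoodItem
from .n5k_io import DishRecord

__all__ = [
    "AggregationError",
    "DishNutrients",
    "scale_to_mass",
    "dish_totals",
    "totals_table",
    "corpus_summary",
    "SUMMARY_ROWS",
]

SUMMARY_ROWS = ["min", "q1", "median", "q3", "mean", "sd", "max"]


class AggregationError(ValueError):
    pass


@dataclass
class DishNutrients:
    """Component totals for one dish under one source database."""

    dish_id: str
    mass: float
    totals: dict[str, float]
    source_fcdb: str = ""


def scale_to_mass(item: FoodItem, grams: float) -> dict[str, float]:
    """Component vector for ``grams`` of a finalized item (values per 100 g)."""
    if grams < 0:
        raise AggregationError("grams must be >= 0")
    out: dict[str, float] = {}
    for code, v in item.values.items():
        if not v.resolved:
            raise AggregationError(
                f"item {item.food_id!r}: component {code!r} unresolved "
                f"({v.state.value}); finalize before scaling")
        assert v.amount is not None
        out[code] = v.amount * grams / 100.0
    return out


def dish_totals(
    dish: DishRecord,
    items_by_ingredient: Mapping[str, FoodItem],
    source_fcdb: str = "",
) -> DishNutrients:
    """Sum scaled component vectors over the dish's ingredient uses."""
    totals: dict[str, float] = {}
    mass = 0.0
    for use in dish.uses:
        item = items_by_ingredient.get(use.ingr_id)
        if item is None:
            raise AggregationError(
                f"dish {dish.dish_id!r}: ingredient {use.ingr_id!r} has no "
                "matched composition")
        vec = scale_to_mass(item, use.ingr_grams)
        for code, val in vec.items():
            totals[code] = totals.get(code, 0.0) + val
        mass += use.ingr_grams
    return DishNutrients(dish.dish_id, mass, totals, source_fcdb)


def totals_table(dishes: Sequence[DishNutrients]) -> pd.DataFrame:
    """One row per dish: dish_id, mass and every component total."""
    if not dishes:
        return pd.DataFrame(columns=["dish_id", "mass"])
    codes = list(dishes[0].totals)
    rows = [
        {"dish_id": d.dish_id, "mass": d.mass,
         **{c: d.totals.get(c, 0.0) for c in codes}}
        for d in dishes
    ]
    return pd.DataFrame(rows)


def corpus_summary(
    table: pd.DataFrame, fields: Sequence[str] | None = None
) -> pd.DataFrame:
    """min/Q1/median/Q3/mean/SD/max per field (type-7 quantiles, SD ddof=1)."""
    if table.empty:
        raise AggregationError("corpus_summary: empty corpus")
    if fields is None:
        fields = [c for c in table.columns if c != "dish_id"]
    out = {}
    for f in fields:
        v = table[f].to_numpy(dtype=float)
        out[f] = [
            float(np.min(v)),
            float(np.quantile(v, 0.25)),
            float(np.quantile(v, 0.50)),
            float(np.quantile(v, 0.75)),
            float(np.mean(v)),
            float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            float(np.max(v)),
        ]
    return pd.DataFrame(out, index=SUMMARY_ROWS)
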