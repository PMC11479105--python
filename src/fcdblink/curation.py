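"""Dataset-level cleaning and the five missing-value imputation strategies.

Cleaning covers: removal of plate-only dishes, recovery of missing
ingredient names (catalogue first, manual map second), summary-statistics
screening of per-ingredient masses, and explicit mass corrections for
order-of-magnitude recording errors.

Missing FCDB cells are resolved by an ordered plan of rules, each mapping
a (component, item-class) pair to one strategy:

* ``similar_item``       — copy the value from a curated donor item;
* ``by_calculation``     — derive from other components (carbohydrate or
  fat by difference, chloride from sodium via the Cl/Na molar-mass ratio);
* ``assumed_zero``       — logical zero (e.g. vitamin B12 in plant foods);
* ``recipe_calculation`` — value computed from a recipe composition;
* ``borrowed``           — value taken from another database's table.

Outlier screening is reproducible here (default flag: mass above 100x the
ingredient's median over at least 3 uses) but corrections are always
explicit table rows — never an automatic rescale.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcdb import FoodItem, NutrientValue, ValueState
from .matching import Recipe, compose_recipe
from .n5k_io import DishRecord, IngredientCatalogEntry

__all__ = [
    "CurationError",
    "CurationWarning",
    "MassCorrection",
    "ImputationAudit",
    "ImputationRule",
    "ImputationPlan",
    "ImputationHelpers",
    "ImputationStrategy",
    "CHLORIDE_FROM_SODIUM",
    "remove_plate_only",
    "recover_missing_names",
    "detect_mass_outliers",
    "apply_mass_corrections",
    "impute_missing",
    "load_mass_corrections",
    "carbohydrate_by_difference",
    "fat_by_difference",
]

#: Cl/Na molar mass ratio (35.453 / 22.990 g/mol)
CHLORIDE_FROM_SODIUM = 35.453 / 22.990


class CurationError(ValueError):
    pass


class CurationWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# dish / long-table cleaning

def remove_plate_only(
    dishes: Sequence[DishRecord], plate_only_ids: Sequence[str]
) -> tuple[list[DishRecord], int]:
    """Drop dishes whose id is in the curated plate-only list.

    Returns the filtered list and the number removed.  Listed ids that do
    not occur warn (the curated list may outlive a data revision).
    """
    listed = set(plate_only_ids)
    present = {d.dish_id for d in dishes}
    for missing in sorted(listed - present):
        warnings.warn(f"plate-only id {missing!r} not found among dishes",
                      CurationWarning, stacklevel=2)
    kept = [d for d in dishes if d.dish_id not in listed]
    return kept, len(dishes) - len(kept)


def recover_missing_names(
    uses: pd.DataFrame,
    catalog: Sequence[IngredientCatalogEntry],
    manual_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill empty ingredient names from the catalogue, then the manual map.

    Catalogue entries flagged deprecated do not resolve a name (those are
    exactly the cases that needed manual image-based recovery).  Ids left
    unresolvable by both routes raise, listed.
    """
    manual_map = manual_map or {}
    by_id = {e.ingr_id: e for e in catalog}
    out = uses.copy()
    nameless = out["ingr_name"].fillna("").str.strip() == ""
    report = {"recovered_catalog": 0, "recovered_manual": 0}
    unresolved: set[str] = set()
    for idx in out.index[nameless]:
        ingr_id = str(out.at[idx, "ingr_id"])
        entry = by_id.get(ingr_id)
        if entry is not None and not entry.deprecated:
            out.at[idx, "ingr_name"] = entry.canonical_name
            report["recovered_catalog"] += 1
        elif ingr_id in manual_map:
            out.at[idx, "ingr_name"] = manual_map[ingr_id]
            report["recovered_manual"] += 1
        else:
            unresolved.add(ingr_id)
    if unresolved:
        raise CurationError(
            "ingredient ids with unrecoverable names: " + ", ".join(sorted(unresolved))
        )
    return out, report


def detect_mass_outliers(
    uses: pd.DataFrame,
    median_factor: float = 100.0,
    min_uses: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ingredient mass summary statistics plus flagged suspect uses.

    A use is flagged when its mass exceeds ``median_factor`` times the
    ingredient's median mass and the ingredient has at least ``min_uses``
    uses (a robust median needs support; single-use ingredients are never
    flagged).  Returns (summary table, flagged rows).
    """
    g = uses.groupby("ingr_id")["ingr_grams"]
    summary = g.agg(
        n="count", min="min",
        q1=lambda s: s.quantile(0.25), median="median",
        q3=lambda s: s.quantile(0.75),
        mean="mean", sd=lambda s: s.std(ddof=1), max="max",
    ).reset_index()
    med = uses["ingr_id"].map(summary.set_index("ingr_id")["median"])
    n = uses["ingr_id"].map(summary.set_index("ingr_id")["n"])
    flagged = uses[(n >= min_uses) & (uses["ingr_grams"] > median_factor * med)]
    return summary, flagged.copy()


@dataclass(frozen=True)
class MassCorrection:
    """An explicit (ingredient, wrong mass) -> corrected mass table row."""

    ingr_id: str
    wrong_mass: float
    corrected_mass: float
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.corrected_mass <= 0:
            raise CurationError("corrected_mass must be > 0")


def load_mass_corrections(path: str | Path) -> list[MassCorrection]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(MassCorrection(
                ingr_id=row["ingr_id"].strip(),
                wrong_mass=float(row["wrong_mass"]),
                corrected_mass=float(row["corrected_mass"]),
                rationale=row.get("rationale", "").strip(),
            ))
    return out


def apply_mass_corrections(
    uses: pd.DataFrame,
    corrections: Sequence[MassCorrection],
    rescale_declared: bool = False,
) -> pd.DataFrame:
    """Replace masses of rows matching (ingr_id, wrong_mass) exactly.

    Only targeted rows change; a correction matching nothing warns.
    Declared dish totals are *not* touched here — they are recomputed
    downstream from the corrected long table.  With ``rescale_declared``
    the declared per-use nutrient columns are scaled by
    corrected/wrong mass, so the declared (source-side) totals account
    for the fix too instead of inflating the comparison with a material
    error.
    """
    declared_cols = [c for c in uses.columns if c.startswith("declared_")]
    out = uses.copy()
    for corr in corrections:
        hit = (out["ingr_id"] == corr.ingr_id) & np.isclose(
            out["ingr_grams"], corr.wrong_mass, rtol=0, atol=1e-9)
        if not hit.any():
            warnings.warn(
                f"mass correction for {corr.ingr_id!r} at {corr.wrong_mass} g "
                "matched no rows", CurationWarning, stacklevel=2)
            continue
        out.loc[hit, "ingr_grams"] = corr.corrected_mass
        if rescale_declared and declared_cols:
            ratio = corr.corrected_mass / corr.wrong_mass
            out.loc[hit, declared_cols] = out.loc[hit, declared_cols] * ratio
    return out


# --------------------------------------------------------------------------
# missing-value imputation

class ImputationStrategy(str, enum.Enum):
    SIMILAR_ITEM = "similar_item"
    BY_CALCULATION = "by_calculation"
    ASSUMED_ZERO = "assumed_zero"
    RECIPE_CALCULATION = "recipe_calculation"
    BORROWED = "borrowed"


@dataclass
class ImputationAudit:
    """Counts of imputed cells per strategy; total is their sum."""

    counts: dict[str, int] = field(
        default_factory=lambda: {s.value: 0 for s in ImputationStrategy})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, strategy: ImputationStrategy, n: int = 1) -> None:
        self.counts[strategy.value] += n

    def as_dict(self) -> dict:
        return {**self.counts, "total": self.total}


@dataclass(frozen=True)
class ImputationRule:
    """Map (component, item-class) to a strategy; "*" wildcards both keys."""

    component: str
    item_class: str
    strategy: ImputationStrategy

    def applies(self, component: str, item_class: str) -> bool:
        return (self.component in ("*", component)
                and self.item_class in ("*", item_class))


@dataclass
class ImputationPlan:
    """Ordered rules; the first applicable rule wins."""

    rules: list[ImputationRule]

    def strategy_for(self, component: str, item_class: str) -> ImputationStrategy | None:
        for rule in self.rules:
            if rule.applies(component, item_class):
                return rule.strategy
        return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImputationPlan":
        rules = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rules.append(ImputationRule(
                    row["component"].strip(), row["item_class"].strip(),
                    ImputationStrategy(row["strategy"].strip())))
        return cls(rules)


# calculators: component code -> function(item) -> amount or None
def carbohydrate_by_difference(item: FoodItem) -> float | None:
    """100 g minus water, protein, fat, ash and alcohol."""
    parts = [item.amount(c) for c in ("water", "protein", "fat", "ash", "alcohol")]
    if any(p is None for p in parts):
        return None
    return max(0.0, 100.0 - sum(parts))


def fat_by_difference(item: FoodItem) -> float | None:
    parts = [item.amount(c) for c in ("water", "protein", "carb", "ash", "alcohol")]
    if any(p is None for p in parts):
        return None
    return max(0.0, 100.0 - sum(parts))


def _chloride_from_sodium(item: FoodItem) -> float | None:
    na = item.amount("sodium")
    return None if na is None else CHLORIDE_FROM_SODIUM * na


DEFAULT_CALCULATORS: dict[str, Callable[[FoodItem], float | None]] = {
    "carb": carbohydrate_by_difference,
    "fat": fat_by_difference,
    "chloride": _chloride_from_sodium,
}


@dataclass
class ImputationHelpers:
    """Side inputs the strategies draw on.

    ``donors`` maps (food_id, component) to a donor :class:`FoodItem`;
    ``borrowed_values`` maps (food_id, component) to an amount;
    ``recipes`` maps food_id to a recipe whose composition supplies values;
    ``calculators`` maps component code to a derivation function.
    """

    donors: dict[tuple[str, str], FoodItem] = field(default_factory=dict)
    borrowed_values: dict[tuple[str, str], float] = field(default_factory=dict)
    recipes: dict[str, Recipe] = field(default_factory=dict)
    recipe_fcdb: Mapping[str, FoodItem] = field(default_factory=dict)
    calculators: Mapping[str, Callable[[FoodItem], float | None]] = field(
        default_factory=lambda: dict(DEFAULT_CALCULATORS))


def impute_missing(
    item: FoodItem,
    plan: ImputationPlan,
    helpers: ImputationHelpers,
    item_class: str = "*",
    audit: ImputationAudit | None = None,
) -> tuple[FoodItem, ImputationAudit]:
    """Resolve every missing cell of ``item`` per the ordered plan.

    Measured and already-imputed values are never overwritten.  A missing
    component with no applicable rule — or whose selected strategy cannot
    produce a value — raises, naming (item, component).
    """
    audit = audit if audit is not None else ImputationAudit()
    values = dict(item.values)
    for code, v in item.values.items():
        if v.state is not ValueState.MISSING:
            continue
        strategy = plan.strategy_for(code, item_class)
        if strategy is None:
            raise CurationError(
                f"item {item.food_id!r}, component {code!r}: no imputation rule")
        amount = _apply_strategy(item, code, strategy, helpers)
        if amount is None:
            raise CurationError(
                f"item {item.food_id!r}, component {code!r}: strategy "
                f"{strategy.value!r} could not produce a value")
        values[code] = NutrientValue.imputed(amount, strategy.value)
        audit.add(strategy)
    return replace(item, values=values), audit


def _apply_strategy(
    item: FoodItem, code: str, strategy: ImputationStrategy,
    helpers: ImputationHelpers,
) -> float | None:
    if strategy is ImputationStrategy.ASSUMED_ZERO:
        return 0.0
    if strategy is ImputationStrategy.SIMILAR_ITEM:
        donor = helpers.donors.get((item.food_id, code))
        return None if donor is None else donor.amount(code)
    if strategy is ImputationStrategy.BORROWED:
        return helpers.borrowed_values.get((item.food_id, code))
    if strategy is ImputationStrategy.BY_CALCULATION:
        calc = helpers.calculators.get(code)
        return None if calc is None else calc(item)
    if strategy is ImputationStrategy.RECIPE_CALCULATION:
        recipe = helpers.recipes.get(item.food_id)
        if recipe is None:
            return None
        composed = compose_recipe(recipe, helpers.recipe_fcdb)
        return composed.amount(code)
    return None
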