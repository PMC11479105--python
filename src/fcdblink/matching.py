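"""Table-driven linkage of dish ingredients to target-FCDB composition.

Five strategies, applied as a configurable cascade (default order
exact -> similar -> generic_mean -> recipe -> borrowed):

* ``exact``        — curated name map, ingredient name -> target food id;
* ``similar``      — among a curated candidate set, pick the item whose
  (energy, protein, fat, carb, water) profile is closest to the
  ingredient's declared profile per 100 g;
* ``generic_mean`` — per-component arithmetic mean over a curated group
  of target items (too-generic ingredient names);
* ``recipe``       — compose a curated recipe (grams per 100 g of the
  finished preparation) from target items;
* ``borrowed``     — take the composition of a source-database item
  verbatim when the target database has no counterpart.

The distance used by ``similar`` is Euclidean after dividing each of the
five axes by the candidate-pool standard deviation of that component
(without normalization the energy axis would dominate the gram axes);
exact ties break to the lexicographically smallest food id.  Both the
metric and the tie-break are implementation choices — the curation
process they stand in for was expert judgment.

No yield or retention factors are applied anywhere, including recipes.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fcdb import FoodItem, NutrientValue

__all__ = [
    "Strategy",
    "MatchRecord",
    "Recipe",
    "RecipeComponent",
    "CurationTables",
    "MatchingError",
    "NO_MATCH",
    "PROFILE_COMPONENTS",
    "exact_match",
    "similarity_match",
    "generic_mean",
    "compose_recipe",
    "resolve_all",
    "resolved_items",
    "DEFAULT_CASCADE",
]

#: the 5-vector used by the similarity strategy, per 100 g
PROFILE_COMPONENTS = ("energy_kcal", "protein", "fat", "carb", "water")

NO_MATCH = None  # sentinel returned by exact_match when the map has no row


class MatchingError(ValueError):
    pass


class Strategy(str, enum.Enum):
    EXACT = "exact"
    SIMILAR = "similar"
    BORROWED = "borrowed"
    GENERIC_MEAN = "generic_mean"
    RECIPE = "recipe"


DEFAULT_CASCADE: tuple[Strategy, ...] = (
    Strategy.EXACT, Strategy.SIMILAR, Strategy.GENERIC_MEAN,
    Strategy.RECIPE, Strategy.BORROWED,
)


@dataclass(frozen=True)
class MatchRecord:
    """The link from one distinct ingredient to target composition."""

    ingr_id: str
    strategy: Strategy
    target: object  # food_id | tuple of food_ids | recipe_id, per strategy
    cooked_raw_discrepancy: bool = False
    note: str = ""
    distance: float | None = None


@dataclass(frozen=True)
class RecipeComponent:
    food_id: str
    grams: float  # per 100 g of finished recipe

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise MatchingError(f"recipe component {self.food_id!r}: grams must be > 0")


@dataclass(frozen=True)
class Recipe:
    recipe_id: str
    components: tuple[RecipeComponent, ...]
    source: str = ""

    def __post_init__(self) -> None:
        total = sum(c.grams for c in self.components)
        if not math.isclose(total, 100.0, rel_tol=0, abs_tol=1e-6):
            raise MatchingError(
                f"recipe {self.recipe_id!r}: component grams sum to {total}, not 100"
            )


@dataclass
class CurationTables:
    """Curated inputs driving the cascade; all plain two/three-column CSVs."""

    name_map: dict[str, str] = field(default_factory=dict)
    similar_candidates: dict[str, tuple[str, ...]] = field(default_factory=dict)
    generic_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    recipe_assignments: dict[str, str] = field(default_factory=dict)
    recipes: dict[str, Recipe] = field(default_factory=dict)
    borrowed: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dir(cls, path: str | Path) -> "CurationTables":
        """Load whichever of the standard table files exist under ``path``."""
        path = Path(path)
        t = cls()
        if (path / "name_map.csv").exists():
            t.name_map = _two_col(path / "name_map.csv")
        if (path / "similar_candidates.csv").exists():
            t.similar_candidates = _grouped(path / "similar_candidates.csv")
        if (path / "generic_sets.csv").exists():
            t.generic_sets = _grouped(path / "generic_sets.csv")
        if (path / "recipe_assignments.csv").exists():
            t.recipe_assignments = _two_col(path / "recipe_assignments.csv")
        if (path / "recipes.csv").exists():
            t.recipes = load_recipes(path / "recipes.csv")
        if (path / "borrowed.csv").exists():
            t.borrowed = _two_col(path / "borrowed.csv")
        return t


def _two_col(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    for row in rows[1:]:  # header skipped
        if not row or not row[0].strip():
            continue
        key = row[0].strip()
        if key in out and out[key] != row[1].strip():
            raise MatchingError(f"{path.name}: ambiguous rows for {key!r}")
        out[key] = row[1].strip()
    return out


def _grouped(path: Path) -> dict[str, tuple[str, ...]]:
    tmp: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        tmp.setdefault(row[0].strip(), []).append(row[1].strip())
    return {k: tuple(v) for k, v in tmp.items()}


def load_recipes(path: str | Path) -> dict[str, Recipe]:
    """Read recipes.csv (recipe_id, food_id, grams[, source])."""
    comps: dict[str, list[RecipeComponent]] = {}
    srcs: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    for row in rows[1:]:
        if not row or not row[0].strip():
            continue
        rid = row[0].strip()
        comps.setdefault(rid, []).append(
            RecipeComponent(row[1].strip(), float(row[2])))
        if len(row) > 3 and row[3].strip():
            srcs[rid] = row[3].strip()
    return {rid: Recipe(rid, tuple(c), srcs.get(rid, ""))
            for rid, c in comps.items()}


def write_recipes(recipes: Mapping[str, Recipe], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["recipe_id", "food_id", "grams", "source"])
        for r in recipes.values():
            for c in r.components:
                w.writerow([r.recipe_id, c.food_id, "%.10g" % c.grams, r.source])


# --------------------------------------------------------------------------
# individual strategies

def exact_match(
    ingredient_name: str,
    name_map: Mapping[str, str],
    ingr_id: str | None = None,
) -> MatchRecord | None:
    """Look the ingredient up in the curated name map.

    Returns ``None`` (the no-match sentinel) when the name has no row, so
    the cascade can fall through to indirect strategies.
    """
    target = name_map.get(ingredient_name)
    if target is None:
        return NO_MATCH
    return MatchRecord(ingr_id or ingredient_name, Strategy.EXACT, target)


def similarity_match(
    ingredient_profile: Sequence[float],
    candidates: Sequence[FoodItem],
    ingr_id: str = "",
) -> MatchRecord:
    """Pick the candidate closest to the declared 5-component profile."""
    if not candidates:
        raise MatchingError("similarity_match: empty candidate list")
    if len(ingredient_profile) != len(PROFILE_COMPONENTS):
        raise MatchingError(
            f"profile must have {len(PROFILE_COMPONENTS)} entries "
            f"({', '.join(PROFILE_COMPONENTS)})"
        )
    mat = np.empty((len(candidates), len(PROFILE_COMPONENTS)))
    for i, item in enumerate(candidates):
        for j, code in enumerate(PROFILE_COMPONENTS):
            a = item.amount(code)
            if a is None:
                raise MatchingError(
                    f"candidate {item.food_id!r} lacks a resolved {code!r} value"
                )
            mat[i, j] = a
    scale = mat.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0  # constant axis carries no discriminating signal
    target = np.asarray(ingredient_profile, dtype=float)
    dist = np.sqrt((((mat - target) / scale) ** 2).sum(axis=1))
    order = sorted(range(len(candidates)),
                   key=lambda i: (dist[i], candidates[i].food_id))
    best = order[0]
    return MatchRecord(ingr_id, Strategy.SIMILAR, candidates[best].food_id,
                       distance=float(dist[best]))


def generic_mean(candidates: Sequence[FoodItem], food_id: str = "generic-mean",
                 name: str = "") -> FoodItem:
    """Per-component arithmetic mean over the candidates.

    Components resolvable in only some candidates are averaged over those
    (flagged in the method tag); components missing everywhere stay missing.
    """
    if not candidates:
        raise MatchingError("generic_mean: empty candidate list")
    codes: list[str] = list(candidates[0].values)
    values: dict[str, NutrientValue] = {}
    for code in codes:
        amounts = [c.amount(code) for c in candidates]
        present = [a for a in amounts if a is not None]
        if not present:
            values[code] = NutrientValue.missing()
        else:
            tag = "generic-mean" if len(present) == len(amounts) \
                else f"generic-mean({len(present)}/{len(amounts)})"
            values[code] = NutrientValue.imputed(sum(present) / len(present), tag)
    cooked = sum(c.cooked for c in candidates) * 2 >= len(candidates)
    return FoodItem(food_id, name or f"mean of {len(candidates)} items",
                    cooked, values)


def compose_recipe(recipe: Recipe, fcdb: Mapping[str, FoodItem]) -> FoodItem:
    """Mass-weighted composition of a 100 g standard portion.

    Component values are summed as value x grams/100 over the recipe rows;
    no yield or retention correction is applied.  The cooked flag is the
    grams-weighted majority of the component items.
    """
    items: list[tuple[FoodItem, float]] = []
    for comp in recipe.components:
        item = fcdb.get(comp.food_id)
        if item is None:
            raise MatchingError(
                f"recipe {recipe.recipe_id!r}: unresolvable component "
                f"{comp.food_id!r}"
            )
        items.append((item, comp.grams))
    codes = list(items[0][0].values)
    values: dict[str, NutrientValue] = {}
    for code in codes:
        total, present = 0.0, False
        for item, grams in items:
            a = item.amount(code)
            if a is not None:
                total += a * grams / 100.0
                present = True
        values[code] = (NutrientValue.imputed(total, "recipe")
                        if present else NutrientValue.missing())
    cooked_mass = sum(g for item, g in items if item.cooked)
    return FoodItem(recipe.recipe_id, f"recipe {recipe.recipe_id}",
                    cooked_mass >= 50.0, values)


# --------------------------------------------------------------------------
# cascade

@dataclass
class MatchAudit:
    """Counts per strategy over distinct ingredients and over total uses."""

    by_strategy: dict[str, int]
    by_strategy_weighted: dict[str, int]
    n_distinct: int
    n_uses: int

    def as_dict(self) -> dict:
        return {
            "by_strategy": dict(self.by_strategy),
            "by_strategy_weighted": dict(self.by_strategy_weighted),
            "n_distinct": self.n_distinct,
            "n_uses": self.n_uses,
        }


def resolve_all(
    ingredients: Sequence[tuple[str, str]],
    tables: CurationTables,
    fcdb: Mapping[str, FoodItem],
    cascade: Sequence[Strategy] = DEFAULT_CASCADE,
    profiles: Mapping[str, Sequence[float]] | None = None,
    use_counts: Mapping[str, int] | None = None,
    assume_cooked: bool = True,
) -> tuple[list[MatchRecord], MatchAudit]:
    """Resolve every distinct ingredient through the strategy cascade.

    ``ingredients`` is (ingr_id, ingr_name) pairs; ``profiles`` supplies
    the declared 5-component per-100 g profile needed by the ``similar``
    strategy; ``use_counts`` (ingr_id -> number of uses) weights the audit.
    Served portions are assumed cooked (``assume_cooked``), so a match
    whose target item is raw is flagged as a raw/cooked discrepancy.

    Raises :class:`MatchingError` listing every ingredient the cascade
    could not resolve.
    """
    profiles = profiles or {}
    use_counts = use_counts or {}
    records: list[MatchRecord] = []
    unresolved: list[str] = []
    for ingr_id, name in ingredients:
        rec: MatchRecord | None = None
        for strat in cascade:
            if strat is Strategy.EXACT:
                hit = exact_match(name, tables.name_map, ingr_id=ingr_id)
                if hit is not NO_MATCH:
                    rec = hit
            elif strat is Strategy.SIMILAR:
                cand_ids = tables.similar_candidates.get(ingr_id) \
                    or tables.similar_candidates.get(name)
                prof = profiles.get(ingr_id)
                if cand_ids and prof is not None:
                    cands = [fcdb[c] for c in cand_ids if c in fcdb]
                    if len(cands) != len(cand_ids):
                        missing = sorted(set(cand_ids) - set(fcdb))
                        raise MatchingError(
                            f"{ingr_id!r}: similar candidates not in FCDB: {missing}")
                    rec = similarity_match(prof, cands, ingr_id=ingr_id)
            elif strat is Strategy.GENERIC_MEAN:
                group = tables.generic_sets.get(ingr_id) or tables.generic_sets.get(name)
                if group:
                    rec = MatchRecord(ingr_id, Strategy.GENERIC_MEAN, tuple(group))
            elif strat is Strategy.RECIPE:
                rid = tables.recipe_assignments.get(ingr_id) \
                    or tables.recipe_assignments.get(name)
                if rid:
                    if rid not in tables.recipes:
                        raise MatchingError(f"{ingr_id!r}: unknown recipe {rid!r}")
                    rec = MatchRecord(ingr_id, Strategy.RECIPE, rid)
            elif strat is Strategy.BORROWED:
                src = tables.borrowed.get(ingr_id) or tables.borrowed.get(name)
                if src:
                    rec = MatchRecord(ingr_id, Strategy.BORROWED, src)
            if rec is not None:
                break
        if rec is None:
            unresolved.append(f"{ingr_id} ({name})")
            continue
        records.append(_flag_discrepancy(rec, tables, fcdb, assume_cooked))
    if unresolved:
        raise MatchingError("unresolved ingredients after cascade: "
                            + ", ".join(unresolved))
    counts: dict[str, int] = {s.value: 0 for s in Strategy}
    weighted: dict[str, int] = {s.value: 0 for s in Strategy}
    for r in records:
        counts[r.strategy.value] += 1
        weighted[r.strategy.value] += use_counts.get(r.ingr_id, 1)
    audit = MatchAudit(counts, weighted, len(records),
                       sum(weighted.values()))
    return records, audit


def _flag_discrepancy(rec: MatchRecord, tables: CurationTables,
                      fcdb: Mapping[str, FoodItem], assume_cooked: bool) -> MatchRecord:
    if not assume_cooked:
        return rec
    cooked = _target_cooked(rec, tables, fcdb)
    if cooked is None or cooked:
        return rec
    return MatchRecord(rec.ingr_id, rec.strategy, rec.target,
                       cooked_raw_discrepancy=True, note=rec.note,
                       distance=rec.distance)


def _target_cooked(rec: MatchRecord, tables: CurationTables,
                   fcdb: Mapping[str, FoodItem]) -> bool | None:
    if rec.strategy in (Strategy.EXACT, Strategy.SIMILAR, Strategy.BORROWED):
        item = fcdb.get(rec.target)  # borrowed items resolved via merged map
        return None if item is None else item.cooked
    if rec.strategy is Strategy.GENERIC_MEAN:
        items = [fcdb[f] for f in rec.target if f in fcdb]
        if not items:
            return None
        return sum(i.cooked for i in items) * 2 >= len(items)
    if rec.strategy is Strategy.RECIPE:
        recipe = tables.recipes[rec.target]
        items = [(fcdb[c.food_id], c.grams) for c in recipe.components
                 if c.food_id in fcdb]
        if not items:
            return None
        return sum(g for i, g in items if i.cooked) >= 50.0
    return None


def resolved_items(
    matches: Sequence[MatchRecord],
    tables: CurationTables,
    fcdb: Mapping[str, FoodItem],
    source_fcdb: Mapping[str, FoodItem] | None = None,
) -> dict[str, FoodItem]:
    """Materialize one per-100 g :class:`FoodItem` per matched ingredient.

    ``fcdb`` is the target database; ``source_fcdb`` supplies the items the
    ``borrowed`` strategy pulls from (falls back to ``fcdb`` when omitted).
    """
    source_fcdb = source_fcdb or fcdb
    out: dict[str, FoodItem] = {}
    for rec in matches:
        if rec.strategy in (Strategy.EXACT, Strategy.SIMILAR):
            out[rec.ingr_id] = fcdb[rec.target]
        elif rec.strategy is Strategy.BORROWED:
            try:
                out[rec.ingr_id] = source_fcdb[rec.target]
            except KeyError:
                raise MatchingError(
                    f"{rec.ingr_id!r}: borrowed item {rec.target!r} absent "
                    "from the source FCDB") from None
        elif rec.strategy is Strategy.GENERIC_MEAN:
            out[rec.ingr_id] = generic_mean(
                [fcdb[f] for f in rec.target],
                food_id=f"{rec.ingr_id}:generic-mean")
        elif rec.strategy is Strategy.RECIPE:
            out[rec.ingr_id] = compose_recipe(tables.recipes[rec.target], fcdb)
    return out
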