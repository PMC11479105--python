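"""Readers and reshapers for Nutrition5k-dialect dish metadata.

The dish metadata files are "ragged wide" CSVs: one row per dish, a fixed
dish-level header block (id, totals, optionally an explicit ingredient
count) followed by a repeated 7-field block per ingredient
(id, name, grams, calories, fat, carb, protein).

Two column-order dialects are shipped: the ``public`` preset matching the
openly archived files (calories before mass, ingredient count inferred
from the block count) and the ``mass_first`` preset (mass before calories,
explicit ``num_ingrs`` column).  The public preset is the default.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Dialect",
    "DIALECTS",
    "PUBLIC_DIALECT",
    "MASS_FIRST_DIALECT",
    "IngredientUse",
    "DishRecord",
    "IngredientCatalogEntry",
    "N5kParseError",
    "TotalsMismatchWarning",
    "DuplicateDishWarning",
    "parse_dish_metadata",
    "write_dish_metadata",
    "parse_ingredient_catalog",
    "wide_to_long",
    "long_to_wide",
    "LONG_COLUMNS",
]

INGREDIENT_FIELDS = ("ingr_id", "ingr_name", "ingr_grams",
                     "ingr_calories", "ingr_fat", "ingr_carb", "ingr_protein")

LONG_COLUMNS = ["dish_id", "position", "ingr_id", "ingr_name", "ingr_grams",
                "declared_energy", "declared_fat", "declared_carb",
                "declared_protein"]


class N5kParseError(ValueError):
    """Malformed dish-metadata content; message carries row number/dish id."""


class TotalsMismatchWarning(UserWarning):
    """Declared dish totals disagree with the sum over ingredient blocks."""


class DuplicateDishWarning(UserWarning):
    """The same dish_id appeared more than once (e.g. across cafe files)."""


@dataclass(frozen=True)
class Dialect:
    """Column-order spec for the ragged-wide dish files."""

    name: str
    header_fields: tuple[str, ...]  # dish-level fields after dish_id
    has_num_ingrs: bool
    allow_trailing_comma: bool = True


PUBLIC_DIALECT = Dialect(
    "public",
    ("total_calories", "total_mass", "total_fat", "total_carb", "total_protein"),
    has_num_ingrs=False,
)
MASS_FIRST_DIALECT = Dialect(
    "mass_first",
    ("total_mass", "total_calories", "total_fat", "total_carb",
     "total_protein", "num_ingrs"),
    has_num_ingrs=True,
)
DIALECTS = {d.name: d for d in (PUBLIC_DIALECT, MASS_FIRST_DIALECT)}


@dataclass(frozen=True)
class IngredientUse:
    """One ingredient as used in one dish, with its declared nutrient block."""

    ingr_id: str
    ingr_name: str
    ingr_grams: float
    declared_energy: float
    declared_fat: float
    declared_carb: float
    declared_protein: float

    def __post_init__(self) -> None:
        for f in ("ingr_grams", "declared_energy", "declared_fat",
                  "declared_carb", "declared_protein"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise N5kParseError(f"{f} must be >= 0, got {v}")


@dataclass
class DishRecord:
    dish_id: str
    total_mass: float
    total_calories: float
    total_fat: float
    total_carb: float
    total_protein: float
    num_ingrs: int
    uses: list[IngredientUse] = field(default_factory=list)

    def mass_from_uses(self) -> float:
        return sum(u.ingr_grams for u in self.uses)


@dataclass(frozen=True)
class IngredientCatalogEntry:
    ingr_id: str
    canonical_name: str
    deprecated: bool = False


def _num(token: str, what: str, row: int, dish: str | None) -> float:
    try:
        return float(token)
    except ValueError:
        where = f"row {row}" + (f", dish {dish!r}" if dish else "")
        raise N5kParseError(f"{where}: non-numeric {what} {token!r}") from None


def parse_dish_metadata(
    path: str | Path,
    dialect: Dialect | str = PUBLIC_DIALECT,
    totals_rtol: float = 1e-3,
) -> list[DishRecord]:
    """Parse a ragged-wide dish metadata file into :class:`DishRecord` rows.

    Rows whose ingredient-block count disagrees with an explicit
    ``num_ingrs`` column raise :class:`N5kParseError` naming the dish.
    Declared totals are cross-checked against the block sums with relative
    tolerance ``totals_rtol``; mismatches warn (the source data itself
    contains mass errors) but never fail the parse.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    dishes: list[DishRecord] = []
    seen: set[str] = set()
    n_head = 1 + len(dialect.header_fields)
    with open(path, newline="", encoding="utf-8") as fh:
        for row_no, tokens in enumerate(csv.reader(fh), start=1):
            if not tokens or (len(tokens) == 1 and not tokens[0].strip()):
                continue
            if row_no == 1 and tokens[0].strip() == "dish_id":
                continue  # optional header line
            if dialect.allow_trailing_comma and tokens and tokens[-1] == "":
                tokens = tokens[:-1]
            if len(tokens) < n_head:
                raise N5kParseError(f"row {row_no}: truncated dish header")
            dish_id = tokens[0].strip()
            head = dict(zip(dialect.header_fields, tokens[1:n_head]))
            body = tokens[n_head:]
            if len(body) % len(INGREDIENT_FIELDS):
                raise N5kParseError(
                    f"row {row_no}, dish {dish_id!r}: trailing fields do not "
                    f"form whole {len(INGREDIENT_FIELDS)}-field ingredient blocks"
                )
            n_blocks = len(body) // len(INGREDIENT_FIELDS)
            if dialect.has_num_ingrs:
                declared_n = int(_num(head["num_ingrs"], "num_ingrs", row_no, dish_id))
                if declared_n != n_blocks:
                    raise N5kParseError(
                        f"row {row_no}, dish {dish_id!r}: num_ingrs={declared_n} "
                        f"but {n_blocks} ingredient blocks found"
                    )
            uses = []
            for b in range(n_blocks):
                chunk = body[b * 7:(b + 1) * 7]
                uses.append(IngredientUse(
                    ingr_id=chunk[0].strip(),
                    ingr_name=chunk[1].strip(),
                    ingr_grams=_num(chunk[2], "ingr_grams", row_no, dish_id),
                    declared_energy=_num(chunk[3], "ingr_calories", row_no, dish_id),
                    declared_fat=_num(chunk[4], "ingr_fat", row_no, dish_id),
                    declared_carb=_num(chunk[5], "ingr_carb", row_no, dish_id),
                    declared_protein=_num(chunk[6], "ingr_protein", row_no, dish_id),
                ))
            rec = DishRecord(
                dish_id=dish_id,
                total_mass=_num(head["total_mass"], "total_mass", row_no, dish_id),
                total_calories=_num(head["total_calories"], "total_calories",
                                    row_no, dish_id),
                total_fat=_num(head["total_fat"], "total_fat", row_no, dish_id),
                total_carb=_num(head["total_carb"], "total_carb", row_no, dish_id),
                total_protein=_num(head["total_protein"], "total_protein",
                                   row_no, dish_id),
                num_ingrs=n_blocks,
                uses=uses,
            )
            if uses and not math.isclose(rec.total_mass, rec.mass_from_uses(),
                                         rel_tol=totals_rtol, abs_tol=1e-6):
                warnings.warn(
                    f"dish {dish_id!r}: declared total mass {rec.total_mass} "
                    f"!= sum of ingredient masses {rec.mass_from_uses():.4g}",
                    TotalsMismatchWarning, stacklevel=2,
                )
            if dish_id in seen:
                warnings.warn(f"duplicate dish id {dish_id!r} preserved",
                              DuplicateDishWarning, stacklevel=2)
            seen.add(dish_id)
            dishes.append(rec)
    return dishes


def write_dish_metadata(
    dishes: Iterable[DishRecord],
    path: str | Path,
    dialect: Dialect | str = PUBLIC_DIALECT,
    float_fmt: str = "%.6g",
) -> None:
    """Inverse of :func:`parse_dish_metadata` for well-formed records."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for d in dishes:
            head = {
                "total_mass": float_fmt % d.total_mass,
                "total_calories": float_fmt % d.total_calories,
                "total_fat": float_fmt % d.total_fat,
                "total_carb": float_fmt % d.total_carb,
                "total_protein": float_fmt % d.total_protein,
                "num_ingrs": str(d.num_ingrs),
            }
            row = [d.dish_id] + [head[f] for f in dialect.header_fields]
            for u in d.uses:
                row += [u.ingr_id, u.ingr_name,
                        float_fmt % u.ingr_grams,
                        float_fmt % u.declared_energy,
                        float_fmt % u.declared_fat,
                        float_fmt % u.declared_carb,
                        float_fmt % u.declared_protein]
            w.writerow(row)


def parse_ingredient_catalog(
    path: str | Path,
    deprecated_token: str = "deprecated",
) -> list[IngredientCatalogEntry]:
    """Read the ingredient catalogue CSV (id, name, optional extras).

    Entries whose name is empty or equals ``deprecated_token`` are flagged
    deprecated.  Duplicate ids raise.
    """
    entries: list[IngredientCatalogEntry] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        return entries
    start = 1 if rows[0] and rows[0][0].strip() in ("id", "ingr_id") else 0
    for row in rows[start:]:
        if not row or not row[0].strip():
            continue
        ingr_id = row[0].strip()
        name = row[1].strip() if len(row) > 1 else ""
        if ingr_id in seen:
            raise N5kParseError(f"duplicate ingredient id {ingr_id!r} in catalogue")
        seen.add(ingr_id)
        entries.append(IngredientCatalogEntry(
            ingr_id=ingr_id,
            canonical_name=name,
            deprecated=(name == "" or name == deprecated_token),
        ))
    return entries


def wide_to_long(dishes: Sequence[DishRecord]) -> pd.DataFrame:
    """One output row per ingredient use, ordered as in the source files.

    Columns: dish_id, position (0-based within the dish), ingr_id,
    ingr_name, ingr_grams, declared_energy/fat/carb/protein.
    """
    records = [
        (d.dish_id, pos, u.ingr_id, u.ingr_name, u.ingr_grams,
         u.declared_energy, u.declared_fat, u.declared_carb, u.declared_protein)
        for d in dishes
        for pos, u in enumerate(d.uses)
    ]
    return pd.DataFrame.from_records(records, columns=LONG_COLUMNS)


def long_to_wide(long: pd.DataFrame) -> list[DishRecord]:
    """Rebuild :class:`DishRecord` rows from a long table.

    Declared dish totals are recomputed as the sums over the ingredient
    blocks, so ``long_to_wide(wide_to_long(dishes))`` reproduces ``dishes``
    exactly when the declared totals were consistent with the blocks.
    """
    out: list[DishRecord] = []
    for dish_id, grp in long.groupby("dish_id", sort=False):
        grp = grp.sort_values("position")
        uses = [
            IngredientUse(str(r.ingr_id), str(r.ingr_name), float(r.ingr_grams),
                          float(r.declared_energy), float(r.declared_fat),
                          float(r.declared_carb), float(r.declared_protein))
            for r in grp.itertuples()
        ]
        out.append(DishRecord(
            dish_id=str(dish_id),
            total_mass=float(grp["ingr_grams"].sum()),
            total_calories=float(grp["declared_energy"].sum()),
            total_fat=float(grp["declared_fat"].sum()),
            total_carb=float(grp["declared_carb"].sum()),
            total_protein=float(grp["declared_protein"].sum()),
            num_ingrs=len(uses),
            uses=uses,
        ))
    return out
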