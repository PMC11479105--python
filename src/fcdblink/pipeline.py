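"""End-to-end harmonization runs: curation -> matching -> imputation ->
aggregation, producing per-dish totals under the target (A) and the
declared/source (B) databases plus machine-readable audits."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import aggregation, curation, matching, n5k_io
from .curation import (ImputationAudit, ImputationHelpers, ImputationPlan,
                       impute_missing, load_mass_corrections,
                       remove_plate_only, apply_mass_corrections)
from .fcdb import (ComponentRegistry, FoodItem, NutrientValue,
                   finalize_traces, load_fcdb)
from .matching import CurationTables, MatchAudit, resolve_all, resolved_items

__all__ = ["HarmonizeResult", "harmonize", "NUTRIENT_MAP"]

#: report-facing nutrient name -> registry component code
NUTRIENT_MAP = {"energy": "energy_kcal", "protein": "protein",
                "fat": "fat", "carb": "carb"}


@dataclass
class HarmonizeResult:
    totals_a: pd.DataFrame
    totals_b: pd.DataFrame
    long: pd.DataFrame
    match_audit: MatchAudit
    imputation_audit: ImputationAudit
    matches: list
    mass_by_dish: dict[str, float] = field(default_factory=dict)
    n_ingredients: dict[str, int] = field(default_factory=dict)
    discrepancy_counts: dict[str, int] = field(default_factory=dict)
    recreated: dict[str, bool] = field(default_factory=dict)
    n_dishes_removed: int = 0


def _read_single_col(path: Path) -> list[str]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    return [r[0].strip() for r in rows[1:] if r and r[0].strip()]


def _read_cell_values(path: Path) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[(row["food_id"].strip(), row["component"].strip())] = \
                float(row["value"])
    return out


def _load_helpers(tables_dir: Path, tables: CurationTables,
                  fcdb_by_id: Mapping[str, FoodItem]) -> ImputationHelpers:
    helpers = ImputationHelpers(recipes=tables.recipes,
                                recipe_fcdb=dict(fcdb_by_id))
    donors_path = tables_dir / "donor_values.csv"
    if donors_path.exists():
        for (fid, code), val in _read_cell_values(donors_path).items():
            helpers.donors[(fid, code)] = FoodItem(
                f"donor:{fid}:{code}", "", True,
                {code: NutrientValue.measured(val)})
    borrowed_path = tables_dir / "borrowed_values.csv"
    if borrowed_path.exists():
        helpers.borrowed_values = _read_cell_values(borrowed_path)
    return helpers


def harmonize(
    dish_files: Sequence[str | Path],
    fcdb_a_path: str | Path,
    fcdb_b_path: str | Path | None,
    registry_path: str | Path,
    tables_dir: str | Path,
    dialect: str = "public",
    catalog_path: str | Path | None = None,
) -> HarmonizeResult:
    """Run the full harmonization over one or more dish metadata files.

    ``tables_dir`` holds the curation tables (matching maps, plate-only
    list, mass corrections, imputation plan and its helper value tables);
    only the files actually present are applied.
    """
    tables_dir = Path(tables_dir)
    registry = ComponentRegistry.from_csv(registry_path)
    dishes: list[n5k_io.DishRecord] = []
    for f in dish_files:
        dishes.extend(n5k_io.parse_dish_metadata(f, dialect=dialect))

    # --- curation: plate-only, missing names, mass corrections ------------
    plate_path = tables_dir / "plate_only.csv"
    plate_ids = _read_single_col(plate_path) if plate_path.exists() else []
    dishes, n_removed = remove_plate_only(dishes, plate_ids)

    long = n5k_io.wide_to_long(dishes)
    if catalog_path is not None:
        catalog = n5k_io.parse_ingredient_catalog(catalog_path)
        manual_path = tables_dir / "manual_names.csv"
        manual = {}
        if manual_path.exists():
            with open(manual_path, newline="", encoding="utf-8") as fh:
                manual = {r["ingr_id"].strip(): r["ingr_name"].strip()
                          for r in csv.DictReader(fh)}
        long, _ = curation.recover_missing_names(long, catalog, manual)

    corr_path = tables_dir / "mass_corrections.csv"
    if corr_path.exists():
        corrections = load_mass_corrections(corr_path)
        long = apply_mass_corrections(long, corrections, rescale_declared=True)

    # --- matching ---------------------------------------------------------
    tables = CurationTables.from_dir(tables_dir)
    fcdb_a = {i.food_id: i for i in load_fcdb(fcdb_a_path, registry)}
    fcdb_b = {i.food_id: i for i in load_fcdb(fcdb_b_path, registry)} \
        if fcdb_b_path else {}
    distinct = (long[["ingr_id", "ingr_name"]].drop_duplicates()
                .sort_values("ingr_id"))
    ingredients = list(distinct.itertuples(index=False, name=None))
    use_counts = long["ingr_id"].value_counts().to_dict()
    profiles = {}
    prof_path = tables_dir / "profiles.csv"
    if prof_path.exists():
        with open(prof_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                profiles[row["ingr_id"].strip()] = [
                    float(row[c]) for c in
                    ("energy_kcal", "protein", "fat", "carb", "water")]
    matches, match_audit = resolve_all(
        ingredients, tables, fcdb_a, profiles=profiles, use_counts=use_counts)

    # --- trace resolution + missing-value imputation ----------------------
    plan_path = tables_dir / "imputation_plan.csv"
    imp_audit = ImputationAudit()
    fcdb_a = {fid: finalize_traces(item, registry)
              for fid, item in fcdb_a.items()}
    if plan_path.exists():
        plan = ImputationPlan.from_csv(plan_path)
        classes: dict[str, str] = {}
        cls_path = tables_dir / "item_classes.csv"
        if cls_path.exists():
            with open(cls_path, newline="", encoding="utf-8") as fh:
                classes = {r["food_id"].strip(): r["item_class"].strip()
                           for r in csv.DictReader(fh)}
        helpers = _load_helpers(tables_dir, tables, fcdb_a)
        fcdb_a = {
            fid: impute_missing(item, plan, helpers,
                                item_class=classes.get(fid, "*"),
                                audit=imp_audit)[0]
            for fid, item in fcdb_a.items()
        }

    # --- aggregation under A ----------------------------------------------
    items = resolved_items(matches, tables, fcdb_a, source_fcdb=fcdb_b)
    corrected = n5k_io.long_to_wide(long)
    per_dish = [aggregation.dish_totals(d, items, source_fcdb="A")
                for d in corrected]
    totals_a = aggregation.totals_table(per_dish)
    totals_a = totals_a.rename(columns={v: k for k, v in NUTRIENT_MAP.items()
                                        if v in totals_a.columns})

    # --- declared (B-side) totals from the corrected long table -----------
    totals_b = (long.groupby("dish_id", sort=False)
                .agg(mass=("ingr_grams", "sum"),
                     energy=("declared_energy", "sum"),
                     fat=("declared_fat", "sum"),
                     carb=("declared_carb", "sum"),
                     protein=("declared_protein", "sum"))
                .reset_index())

    # --- model-frame covariates -------------------------------------------
    flag_by_ingr = {m.ingr_id: m.cooked_raw_discrepancy for m in matches}
    recipe_by_ingr = {m.ingr_id: m.strategy is matching.Strategy.RECIPE
                      for m in matches}
    mass_by_dish = dict(zip(totals_b["dish_id"], totals_b["mass"]))
    grouped = long.groupby("dish_id", sort=False)["ingr_id"]
    n_ingredients = grouped.count().to_dict()
    discrepancy_counts = grouped.agg(
        lambda s: int(sum(flag_by_ingr.get(i, False) for i in s))).to_dict()
    recreated = grouped.agg(
        lambda s: bool(any(recipe_by_ingr.get(i, False) for i in s))).to_dict()

    return HarmonizeResult(
        totals_a=totals_a, totals_b=totals_b, long=long,
        match_audit=match_audit, imputation_audit=imp_audit, matches=matches,
        mass_by_dish=mass_by_dish, n_ingredients=n_ingredients,
        discrepancy_counts=discrepancy_counts, recreated=recreated,
        n_dishes_removed=n_removed,
    )
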