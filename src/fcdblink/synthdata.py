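"""Synthetic paired FCDBs and dish files with known ground truth.

The generator emulates the real-world setting: two databases share food
items but source B defines carbohydrate by difference (fiber included)
while target A reports available carbohydrates (fiber excluded); dish
files in the ragged-wide dialect carry source-B-derived declared values;
curation tables plant every matching strategy, plate-only dishes,
order-of-magnitude mass errors, and missing/trace cells with recoverable
true values — so each pipeline stage can be checked against an
independently computed ground truth.

Everything is driven by one integer seed through a single
``numpy.random.default_rng`` stream; regeneration with the same config is
byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import n5k_io
from .fcdb import (ComponentRegistry, FoodItem, NutrientValue, KJ_PER_KCAL,
                   default_registry, write_fcdb)
from .curation import CHLORIDE_FROM_SODIUM, MassCorrection
from .matching import Recipe, RecipeComponent, Strategy, write_recipes
from .n5k_io import DishRecord, IngredientUse

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "SynthConfigError",
    "generate",
    "regression_design",
    "end_to_end_check",
]

MACROS = ("energy_kcal", "protein", "fat", "carb")
#: components that may be planted missing, with their recovery strategy
MISSING_ELIGIBLE = {
    "chloride": "by_calculation",
    "vitamin_b12": "assumed_zero",   # plant-class items only (true zero)
    "iron": "similar_item",
    "zinc": "borrowed",
}
TRACE_ELIGIBLE = {"retinol": 0.5, "vitamin_d": 0.05, "alpha_tocopherol": 0.005}


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic world; all randomness flows from ``seed``."""

    seed: int
    n_items: int = 40
    n_dishes: int = 300
    max_ingredients: int = 8
    carb_definition_offset: bool = True  # B's carbohydrate includes fiber
    noise_sd: float = 0.0                # lognormal SD of B-vs-A macro noise
    missing_rate: float = 0.0
    trace_rate: float = 0.0
    recipe_fraction: float = 0.0
    similar_fraction: float = 0.0
    generic_fraction: float = 0.0
    borrowed_fraction: float = 0.0
    rawcooked_rate: float = 0.0          # P(exact item is raw in A)
    plant_plate_only: bool = False
    plant_mass_outlier: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SynthConfigError("seed is mandatory")
        for name in ("noise_sd",):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be >= 0")
        for name in ("missing_rate", "trace_rate", "recipe_fraction",
                     "similar_fraction", "generic_fraction",
                     "borrowed_fraction", "rawcooked_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must be in [0, 1], got {v}")
        frac = (self.recipe_fraction + self.similar_fraction
                + self.generic_fraction + self.borrowed_fraction)
        if frac > 0.8:
            raise SynthConfigError("indirect-strategy fractions sum above 0.8")
        if self.n_items < 6:
            raise SynthConfigError("need at least 6 items")
        if self.recipe_fraction > 0 and self.n_items < 8:
            raise SynthConfigError("recipes need at least 8 items")
        if not 1 <= self.max_ingredients <= 34:
            raise SynthConfigError("max_ingredients must be in 1..34")
        if self.n_dishes < 1:
            raise SynthConfigError("need at least one dish")


@dataclass
class SynthBundle:
    """In-memory handles plus the paths of everything written to disk."""

    outdir: Path
    registry: ComponentRegistry
    fcdb_a: list[FoodItem]
    fcdb_b: list[FoodItem]
    dishes: list[DishRecord]
    ground_truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _draw_item_truth(rng: np.random.Generator, plant_class: bool) -> dict[str, float]:
    protein = rng.gamma(2.0, 3.0)
    fat = rng.gamma(2.0, 2.5)
    carb = rng.gamma(2.0, 6.0)
    fiber = rng.gamma(1.5, 1.5)
    ash = rng.uniform(0.3, 2.0)
    macro = protein + fat + carb + fiber + ash
    if macro > 96.0:
        k = 96.0 / macro
        protein, fat, carb, fiber, ash = (v * k for v in
                                          (protein, fat, carb, fiber, ash))
        macro = 96.0
    water = 100.0 - macro
    sodium = rng.gamma(2.0, 120.0)
    energy = 4.0 * protein + 9.0 * fat + 4.0 * carb + 2.0 * fiber
    return {
        "energy_kcal": energy,
        "energy_kj": energy * KJ_PER_KCAL,
        "water": water,
        "protein": protein,
        "fat": fat,
        "carb": carb,
        "fiber": fiber,
        "alcohol": 0.0,
        "ash": ash,
        "sodium": sodium,
        "chloride": CHLORIDE_FROM_SODIUM * sodium,
        "potassium": rng.gamma(2.0, 150.0),
        "calcium": rng.gamma(2.0, 40.0),
        "iron": rng.gamma(2.0, 1.0),
        "zinc": rng.gamma(2.0, 0.8),
        "retinol": rng.gamma(1.5, 30.0),
        "beta_carotene": rng.gamma(1.5, 200.0),
        "vitamin_d": rng.gamma(1.2, 0.8),
        "alpha_tocopherol": rng.gamma(2.0, 0.5),
        "vitamin_b12": 0.0 if plant_class else rng.gamma(1.5, 0.6),
    }


def generate(config: SynthConfig, outdir: str | Path) -> SynthBundle:
    """Write the full synthetic bundle under ``outdir`` and return handles."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    tables_dir = outdir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    registry = default_registry()

    n = config.n_items
    plant_class = rng.random(n) < 0.5
    truths = [_draw_item_truth(rng, bool(plant_class[i])) for i in range(n)]

    # strategy partition over distinct ingredients (ingredient k <-> item k)
    n_recipe = round(config.recipe_fraction * n)
    n_similar = round(config.similar_fraction * n)
    n_generic = round(config.generic_fraction * n)
    n_borrowed = round(config.borrowed_fraction * n)
    strategies: list[Strategy] = (
        [Strategy.RECIPE] * n_recipe + [Strategy.SIMILAR] * n_similar
        + [Strategy.GENERIC_MEAN] * n_generic + [Strategy.BORROWED] * n_borrowed)
    strategies += [Strategy.EXACT] * (n - len(strategies))
    rng.shuffle(strategies)  # type: ignore[arg-type]
    exact_idx = [i for i, s in enumerate(strategies) if s is Strategy.EXACT]

    # cooked flags: raw items planted only among exact-matched items, so the
    # dish-level discrepancy counts follow directly from the plant
    cooked = np.ones(n, dtype=bool)
    for i in exact_idx:
        if rng.random() < config.rawcooked_rate:
            cooked[i] = False

    # ---- FCDB B (source / declared side): complete, noisy macros ---------
    b_truths = []
    for i, t in enumerate(truths):
        bt = dict(t)
        noise = (np.exp(rng.normal(0.0, config.noise_sd, size=3))
                 if config.noise_sd > 0 else np.ones(3))
        bt["protein"] = t["protein"] * noise[0]
        bt["fat"] = t["fat"] * noise[1]
        carb_b = t["carb"] + (t["fiber"] if config.carb_definition_offset else 0.0)
        bt["carb"] = carb_b * noise[2]
        bt["energy_kcal"] = 4.0 * bt["protein"] + 9.0 * bt["fat"] + 4.0 * bt["carb"]
        bt["energy_kj"] = bt["energy_kcal"] * KJ_PER_KCAL
        b_truths.append(bt)

    # ---- plant missing / trace cells in A --------------------------------
    missing_cells: list[tuple[int, str]] = []
    trace_cells: list[tuple[int, str]] = []
    for i in range(n):
        for code in MISSING_ELIGIBLE:
            if code == "vitamin_b12" and not plant_class[i]:
                continue
            if rng.random() < config.missing_rate:
                missing_cells.append((i, code))
        for code, const in TRACE_ELIGIBLE.items():
            if (i, code) in missing_cells:
                continue
            if rng.random() < config.trace_rate:
                truths[i][code] = const  # truth equals the imputation constant
                trace_cells.append((i, code))

    fcdb_a: list[FoodItem] = []
    fcdb_b: list[FoodItem] = []
    for i in range(n):
        fid_a, fid_b = f"IT{i:03d}", f"US{i:03d}"
        vals_a: dict[str, NutrientValue] = {}
        for code in registry.codes:
            if (i, code) in missing_cells:
                vals_a[code] = NutrientValue.missing()
            elif (i, code) in trace_cells:
                vals_a[code] = NutrientValue.trace()
            else:
                vals_a[code] = NutrientValue.measured(truths[i][code])
        fcdb_a.append(FoodItem(fid_a, f"food_{i}", bool(cooked[i]), vals_a))
        fcdb_b.append(FoodItem(
            fid_b, f"food_{i}", True,
            {code: NutrientValue.measured(b_truths[i][code])
             for code in registry.codes}))

    # ---- curation tables for the matching cascade ------------------------
    name_map: dict[str, str] = {}
    similar_candidates: dict[str, tuple[str, ...]] = {}
    generic_sets: dict[str, tuple[str, ...]] = {}
    recipe_assignments: dict[str, str] = {}
    recipes: dict[str, Recipe] = {}
    borrowed: dict[str, str] = {}
    profiles: dict[str, list[float]] = {}
    # effective per-100 g composition each ingredient resolves to, per side
    eff_a: list[dict[str, float]] = []
    eff_b: list[dict[str, float]] = []
    expected_discrepancy: list[bool] = []

    def mean_of(idxs: list[int], side: list[dict[str, float]]) -> dict[str, float]:
        return {c: float(np.mean([side[j][c] for j in idxs]))
                for c in registry.codes}

    for i, strat in enumerate(strategies):
        ingr = f"ingr_{i}"
        name = f"food_{i}"
        if strat is Strategy.EXACT:
            name_map[name] = f"IT{i:03d}"
            eff_a.append(dict(truths[i]))
            eff_b.append(dict(b_truths[i]))
            expected_discrepancy.append(not cooked[i])
        elif strat is Strategy.SIMILAR:
            decoys = [exact_idx[k % len(exact_idx)] for k in (i, i + 1)] \
                if exact_idx else [(i + 1) % n, (i + 2) % n]
            cand = sorted({i, *decoys})
            similar_candidates[ingr] = tuple(f"IT{j:03d}" for j in cand)
            profiles[ingr] = [truths[i][c] for c in
                              ("energy_kcal", "protein", "fat", "carb", "water")]
            eff_a.append(dict(truths[i]))
            eff_b.append(dict(b_truths[i]))
            expected_discrepancy.append(not cooked[i])
        elif strat is Strategy.GENERIC_MEAN:
            partner = exact_idx[i % len(exact_idx)] if exact_idx else (i + 1) % n
            group = sorted({i, partner})
            generic_sets[ingr] = tuple(f"IT{j:03d}" for j in group)
            eff_a.append(mean_of(group, truths))
            eff_b.append(mean_of(group, b_truths))
            n_raw = sum(not cooked[j] for j in group)
            expected_discrepancy.append(n_raw * 2 > len(group))
        elif strat is Strategy.RECIPE:
            pool = exact_idx or list(range(n))
            c1, c2 = pool[i % len(pool)], pool[(i + 1) % len(pool)]
            if c1 == c2:
                c2 = pool[(i + 2) % len(pool)]
            rid = f"rcp_{i}"
            recipes[rid] = Recipe(rid, (RecipeComponent(f"IT{c1:03d}", 60.0),
                                        RecipeComponent(f"IT{c2:03d}", 40.0)),
                                  source="synthetic")
            recipe_assignments[ingr] = rid
            eff_a.append({c: 0.6 * truths[c1][c] + 0.4 * truths[c2][c]
                          for c in registry.codes})
            eff_b.append({c: 0.6 * b_truths[c1][c] + 0.4 * b_truths[c2][c]
                          for c in registry.codes})
            cooked_mass = 60.0 * cooked[c1] + 40.0 * cooked[c2]
            expected_discrepancy.append(cooked_mass < 50.0)
        else:  # borrowed: composition taken verbatim from source B
            borrowed[ingr] = f"US{i:03d}"
            eff_a.append(dict(b_truths[i]))
            eff_b.append(dict(b_truths[i]))
            expected_discrepancy.append(False)

    # ---- dishes ----------------------------------------------------------
    dishes: list[DishRecord] = []
    gt_dishes: dict[str, dict] = {}
    for d in range(config.n_dishes):
        n_uses = int(np.clip(rng.geometric(0.3), 1, config.max_ingredients))
        n_uses = min(n_uses, n)
        chosen = rng.choice(n, size=n_uses, replace=False)
        grams = rng.lognormal(np.log(40.0), 0.8, size=n_uses)
        dish_id = f"dish_{d:05d}"
        uses = []
        gt = {c: 0.0 for c in ("energy_a", "protein_a", "fat_a", "carb_a",
                               "energy_b", "protein_b", "fat_b", "carb_b")}
        fiber_mass = 0.0
        disc = 0
        has_recipe = False
        for j, g in zip(chosen, grams):
            j = int(j)
            g = float(round(g, 3))
            scale = g / 100.0
            uses.append(IngredientUse(
                ingr_id=f"ingr_{j}", ingr_name=f"food_{j}", ingr_grams=g,
                declared_energy=eff_b[j]["energy_kcal"] * scale,
                declared_fat=eff_b[j]["fat"] * scale,
                declared_carb=eff_b[j]["carb"] * scale,
                declared_protein=eff_b[j]["protein"] * scale,
            ))
            for code, key in (("energy_kcal", "energy"), ("protein", "protein"),
                              ("fat", "fat"), ("carb", "carb")):
                gt[f"{key}_a"] += eff_a[j][code] * scale
                gt[f"{key}_b"] += eff_b[j][code] * scale
            fiber_mass += eff_a[j]["fiber"] * scale
            disc += expected_discrepancy[j]
            has_recipe |= strategies[j] is Strategy.RECIPE
        mass = float(sum(u.ingr_grams for u in uses))
        dishes.append(DishRecord(
            dish_id=dish_id, total_mass=mass,
            total_calories=sum(u.declared_energy for u in uses),
            total_fat=sum(u.declared_fat for u in uses),
            total_carb=sum(u.declared_carb for u in uses),
            total_protein=sum(u.declared_protein for u in uses),
            num_ingrs=len(uses), uses=uses))
        gt_dishes[dish_id] = {
            "mass": mass, "fiber_mass": fiber_mass, "n_uses": len(uses),
            "discrepancy_count": int(disc), "has_recipe": bool(has_recipe),
            **{k: float(v) for k, v in gt.items()},
        }

    # ---- planted curation targets ----------------------------------------
    plate_only_ids: list[str] = []
    if config.plant_plate_only:
        for k in (1, 2):
            did = f"dish_plate_{k}"
            plate_use = IngredientUse("ingr_plate", "plate only", 10.0,
                                      0.0, 0.0, 0.0, 0.0)
            dishes.append(DishRecord(did, 10.0, 0.0, 0.0, 0.0, 0.0, 1,
                                     [plate_use]))
            plate_only_ids.append(did)

    corrections: list[MassCorrection] = []
    if config.plant_mass_outlier:
        victim = dishes[0]
        u = victim.uses[0]
        wrong = round(u.ingr_grams * 1000.0, 3)
        fixed = u.ingr_grams
        scale = wrong / fixed
        victim.uses[0] = IngredientUse(
            u.ingr_id, u.ingr_name, wrong,
            u.declared_energy * scale, u.declared_fat * scale,
            u.declared_carb * scale, u.declared_protein * scale)
        victim.total_mass += wrong - fixed
        victim.total_calories += u.declared_energy * (scale - 1)
        victim.total_fat += u.declared_fat * (scale - 1)
        victim.total_carb += u.declared_carb * (scale - 1)
        victim.total_protein += u.declared_protein * (scale - 1)
        corrections.append(MassCorrection(
            u.ingr_id, wrong, fixed,
            rationale="order-of-magnitude recording error (planted)"))

    # dishes are shuffled so planted rows are not positionally special
    order = rng.permutation(len(dishes))
    dishes = [dishes[int(i)] for i in order]

    # ---- write everything ------------------------------------------------
    paths: dict[str, Path] = {}

    def _p(key: str, rel: str) -> Path:
        paths[key] = outdir / rel
        return paths[key]

    registry.to_csv(_p("registry", "registry.csv"))
    write_fcdb(fcdb_a, _p("fcdb_a", "fcdb_a.csv"), registry, float_fmt="%.10g")
    write_fcdb(fcdb_b, _p("fcdb_b", "fcdb_b.csv"), registry, float_fmt="%.10g")
    n5k_io.write_dish_metadata(dishes, _p("dishes", "dish_metadata_cafe1.csv"),
                               dialect="public", float_fmt="%.10g")

    def _write(key: str, rel: str, header: list[str], rows: list[list]) -> None:
        with open(_p(key, rel), "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    _write("name_map", "tables/name_map.csv", ["ingr_name", "food_id"],
           sorted([k, v] for k, v in name_map.items()))
    _write("similar_candidates", "tables/similar_candidates.csv",
           ["ingr_id", "food_id"],
           sorted([k, f] for k, v in similar_candidates.items() for f in v))
    _write("generic_sets", "tables/generic_sets.csv", ["ingr_id", "food_id"],
           sorted([k, f] for k, v in generic_sets.items() for f in v))
    _write("recipe_assignments", "tables/recipe_assignments.csv",
           ["ingr_id", "recipe_id"], sorted([k, v] for k, v in
                                            recipe_assignments.items()))
    write_recipes(recipes, _p("recipes", "tables/recipes.csv"))
    _write("borrowed", "tables/borrowed.csv", ["ingr_id", "food_id"],
           sorted([k, v] for k, v in borrowed.items()))
    _write("profiles", "tables/profiles.csv",
           ["ingr_id", "energy_kcal", "protein", "fat", "carb", "water"],
           sorted([k, *("%.10g" % x for x in v)] for k, v in profiles.items()))
    _write("plate_only", "tables/plate_only.csv", ["dish_id"],
           [[d] for d in plate_only_ids])
    _write("mass_corrections", "tables/mass_corrections.csv",
           ["ingr_id", "wrong_mass", "corrected_mass", "rationale"],
           [[c.ingr_id, "%.10g" % c.wrong_mass, "%.10g" % c.corrected_mass,
             c.rationale] for c in corrections])
    _write("imputation_plan", "tables/imputation_plan.csv",
           ["component", "item_class", "strategy"],
           [["chloride", "*", "by_calculation"],
            ["vitamin_b12", "plant", "assumed_zero"],
            ["iron", "*", "similar_item"],
            ["zinc", "*", "borrowed"]])
    _write("item_classes", "tables/item_classes.csv", ["food_id", "item_class"],
           [[f"IT{i:03d}", "plant" if plant_class[i] else "animal"]
            for i in range(n)])
    _write("donor_values", "tables/donor_values.csv",
           ["food_id", "component", "value"],
           sorted([f"IT{i:03d}", code, "%.10g" % truths[i][code]]
                  for i, code in missing_cells
                  if MISSING_ELIGIBLE[code] == "similar_item"))
    _write("borrowed_values", "tables/borrowed_values.csv",
           ["food_id", "component", "value"],
           sorted([f"IT{i:03d}", code, "%.10g" % truths[i][code]]
                  for i, code in missing_cells
                  if MISSING_ELIGIBLE[code] == "borrowed"))

    expected_audit = {s.value: 0 for s in Strategy}
    for s in strategies:
        expected_audit[s.value] += 1
    expected_imputation = {v: 0 for v in
                           ("similar_item", "by_calculation", "assumed_zero",
                            "recipe_calculation", "borrowed")}
    for _, code in missing_cells:
        expected_imputation[MISSING_ELIGIBLE[code]] += 1

    ground_truth = {
        "config": asdict(config),
        "dishes": gt_dishes,
        "strategies": {f"ingr_{i}": s.value for i, s in enumerate(strategies)},
        "expected_match_audit": expected_audit,
        "expected_imputation_counts": expected_imputation,
        "n_missing_cells": len(missing_cells),
        "n_trace_cells": len(trace_cells),
        "plate_only_ids": plate_only_ids,
        "mass_corrections": [asdict(c) for c in corrections],
        "item_cooked": {f"IT{i:03d}": bool(cooked[i]) for i in range(n)},
        "ingredient_discrepancy": {
            f"ingr_{i}": bool(expected_discrepancy[i]) for i in range(n)},
    }
    with open(_p("ground_truth", "ground_truth.json"), "w",
              encoding="utf-8") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)

    return SynthBundle(outdir=outdir, registry=registry, fcdb_a=fcdb_a,
                       fcdb_b=fcdb_b, dishes=dishes,
                       ground_truth=ground_truth, paths=paths)


# --------------------------------------------------------------------------
# regression worlds with planted coefficients

def regression_design(
    n: int,
    betas: Mapping[str, float],
    sigma: float = 1.0,
    outlier_frac: float = 0.0,
    outlier_shift: float = 50.0,
    outlier_sign: str = "random",
    seed: int = 0,
) -> pd.DataFrame:
    """A difference-determinants design with a planted linear response.

    ``betas`` maps ``intercept`` and any of the standard design columns to
    the generating coefficients (absent columns get 0).  A fraction of
    responses can be grossly shifted (``outlier_shift`` times sigma, random
    sign) to emulate contamination.  Returns a frame with ``delta`` plus
    the design columns; the planted betas are the recovery target.
    """
    from .robust import DESIGN_COLUMNS
    rng = np.random.default_rng(seed)
    mass_25 = rng.lognormal(np.log(150.0), 0.6, n) / 25.0
    n_ingr = 1.0 + rng.poisson(3.0, n)
    raw = rng.choice(3, size=n, p=[0.4, 0.3, 0.3])  # 0 none, 1 one, 2 more
    rec = (rng.random(n) < 0.3).astype(float)
    frame = pd.DataFrame({
        "mass_25": mass_25,
        "n_ingredients": n_ingr.astype(float),
        "rawcooked_one": (raw == 1).astype(float),
        "rawcooked_more": (raw == 2).astype(float),
        "recreated_yes": rec,
    })
    frame["rawcooked_one:recreated_yes"] = frame["rawcooked_one"] * rec
    frame["rawcooked_more:recreated_yes"] = frame["rawcooked_more"] * rec
    X = np.column_stack([np.ones(n), frame[DESIGN_COLUMNS].to_numpy()])
    beta_vec = np.array([betas.get("intercept", 0.0)]
                        + [betas.get(c, 0.0) for c in DESIGN_COLUMNS])
    y = X @ beta_vec + rng.normal(0.0, sigma, n)
    if outlier_frac > 0:
        k = int(round(outlier_frac * n))
        idx = rng.choice(n, size=k, replace=False)
        signs = (np.ones(k) if outlier_sign == "positive"
                 else rng.choice([-1.0, 1.0], size=k))
        y[idx] += signs * outlier_shift * sigma
    frame.insert(0, "delta", y)
    return frame


def end_to_end_check(config: SynthConfig, workdir: str | Path) -> dict:
    """Generate a bundle, run the whole pipeline on it, compare to truth."""
    from . import pipeline  # deferred: pipeline imports half the package

    report: dict[str, object] = {"stages": []}

    def stage(name: str):
        report["stages"].append(name)  # type: ignore[union-attr]

    stage("generate")
    bundle = generate(config, Path(workdir) / "bundle")
    stage("harmonize")
    try:
        res = pipeline.harmonize(
            dish_files=[bundle.paths["dishes"]],
            fcdb_a_path=bundle.paths["fcdb_a"],
            fcdb_b_path=bundle.paths["fcdb_b"],
            registry_path=bundle.paths["registry"],
            tables_dir=bundle.outdir / "tables",
        )
    except Exception as exc:  # surface the failing stage by name
        raise RuntimeError(f"stage 'harmonize' failed: {exc}") from exc

    gt = bundle.ground_truth["dishes"]
    ta = res.totals_a.set_index("dish_id")
    errs = []
    for did, g in gt.items():
        if did in bundle.ground_truth["plate_only_ids"]:
            continue
        row = ta.loc[did]
        for key, code in (("energy_a", "energy"), ("protein_a", "protein"),
                          ("fat_a", "fat"), ("carb_a", "carb")):
            errs.append(abs(row[code] - g[key]))
    stage("compare")
    from .concordance import compare_tables
    reports = compare_tables(res.totals_a, res.totals_b,
                             ["energy", "protein", "fat", "carb"],
                             k=min(25, len(res.totals_a)))
    stage("regression")
    from .robust import DESIGN_COLUMNS, MMConfig, build_model_frame, fit_mm
    deltas = res.totals_a.merge(res.totals_b, on="dish_id",
                                suffixes=("_a", "_b"))
    deltas["carb"] = deltas["carb_a"] - deltas["carb_b"]
    frame = build_model_frame(
        deltas[["dish_id", "carb"]], res.mass_by_dish, res.n_ingredients,
        res.discrepancy_counts, res.recreated, response="carb")
    # small worlds can leave dummy columns constant or collinear; keep a
    # full-rank subset so the fit goes through
    cols: list[str] = []
    X = np.ones((len(frame), 1))
    for c in DESIGN_COLUMNS:
        cand = np.column_stack([X, frame[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            cols.append(c)
            X = cand
    fit = fit_mm(frame, "delta", cols,
                 MMConfig(n_subsamples=50, seed=config.seed))

    report.update({
        "max_abs_total_error": float(max(errs)) if errs else 0.0,
        "match_audit": res.match_audit.as_dict(),
        "expected_match_audit": bundle.ground_truth["expected_match_audit"],
        "imputation_audit": res.imputation_audit.as_dict(),
        "expected_imputation_counts":
            bundle.ground_truth["expected_imputation_counts"],
        "median_delta": {nut: r.diff_summary["median"]
                         for nut, r in reports.items()},
        "median_fiber_mass": float(np.median(
            [g["fiber_mass"] for d, g in gt.items()
             if d not in bundle.ground_truth["plate_only_ids"]])),
        "kappa": {nut: r.kappa for nut, r in reports.items()},
        "bias": {nut: r.bias for nut, r in reports.items()},
        "mm_converged": bool(fit.converged),
        "mm_coefficients": {k: float(v) for k, v in fit.params.items()},
    })
    return report
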