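import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcdblink.curation import (CHLORIDE_FROM_SODIUM, CurationError,
                               CurationWarning, ImputationAudit,
                               ImputationHelpers, ImputationPlan,
                               ImputationRule, ImputationStrategy,
                               MassCorrection, apply_mass_corrections,
                               carbohydrate_by_difference,
                               detect_mass_outliers, impute_missing,
                               recover_missing_names, remove_plate_only)
from fcdblink.fcdb import FoodItem, NutrientValue, ValueState
from fcdblink.matching import Recipe, RecipeComponent
from fcdblink.n5k_io import DishRecord, IngredientCatalogEntry, IngredientUse


def dish(dish_id):
    u = IngredientUse("i1", "apple", 100.0, 52.0, 0.2, 14.0, 0.3)
    return DishRecord(dish_id, 100.0, 52.0, 0.2, 14.0, 0.3, 1, [u])


class TestRemovePlateOnly:
    def test_removes_listed_twice(self):
        dishes = [dish(f"d{i}") for i in range(4)] + [dish("p1"), dish("p2")]
        kept, removed = remove_plate_only(dishes, ["p1", "p2"])
        assert removed == 2
        assert len(kept) == 4

    def test_empty_list_is_identity(self):
        dishes = [dish("d1"), dish("d2")]
        kept, removed = remove_plate_only(dishes, [])
        assert kept == dishes and removed == 0

    def test_all_listed_empty_output(self):
        dishes = [dish("d1"), dish("d2")]
        kept, _ = remove_plate_only(dishes, ["d1", "d2"])
        assert kept == []

    def test_absent_id_warns(self):
        with pytest.warns(CurationWarning):
            remove_plate_only([dish("d1")], ["ghost"])


def long_table(rows):
    return pd.DataFrame(rows, columns=["dish_id", "position", "ingr_id",
                                       "ingr_name", "ingr_grams",
                                       "declared_energy", "declared_fat",
                                       "declared_carb", "declared_protein"])


class TestRecoverMissingNames:
    catalog = [IngredientCatalogEntry("i1", "apple"),
               IngredientCatalogEntry("i2", "deprecated", deprecated=True)]

    def test_catalogue_recovery(self):
        uses = long_table([("d1", 0, "i1", "", 10, 0, 0, 0, 0)])
        out, report = recover_missing_names(uses, self.catalog, {})
        assert out["ingr_name"].iloc[0] == "apple"
        assert report == {"recovered_catalog": 1, "recovered_manual": 0}

    def test_manual_map_recovery_for_deprecated(self):
        uses = long_table([("d1", 0, "i2", "", 10, 0, 0, 0, 0)])
        out, report = recover_missing_names(uses, self.catalog,
                                            {"i2": "watermelon"})
        assert out["ingr_name"].iloc[0] == "watermelon"
        assert report["recovered_manual"] == 1

    def test_unresolvable_raises_listing_id(self):
        uses = long_table([("d1", 0, "iX", "", 10, 0, 0, 0, 0)])
        with pytest.raises(CurationError, match="iX"):
            recover_missing_names(uses, self.catalog, {})


class TestMassOutliers:
    def test_gross_outlier_flagged(self):
        uses = long_table([("d1", 0, "olive", "olives", m, 0, 0, 0, 0)
                           for m in (5.0, 5.0, 7974.0)])
        summary, flagged = detect_mass_outliers(uses)
        assert len(flagged) == 1
        assert flagged["ingr_grams"].iloc[0] == 7974.0
        row = summary.set_index("ingr_id").loc["olive"]
        assert row["median"] == 5.0 and row["max"] == 7974.0

    def test_uniform_masses_clean(self):
        uses = long_table([("d1", i, "i1", "x", 10.0, 0, 0, 0, 0)
                           for i in range(5)])
        _, flagged = detect_mass_outliers(uses)
        assert flagged.empty

    def test_single_use_never_flagged(self):
        uses = long_table([("d1", 0, "i1", "x", 1e9, 0, 0, 0, 0)])
        _, flagged = detect_mass_outliers(uses)
        assert flagged.empty


class TestMassCorrections:
    def test_documented_corrections(self):
        uses = long_table([
            ("d1", 0, "olives", "olives", 7974.0, 10, 1, 1, 1),
            ("d2", 0, "asparagus", "asparagus", 3324.0, 10, 1, 1, 1),
            ("d3", 0, "olives", "olives", 5.0, 10, 1, 1, 1),
        ])
        corr = [MassCorrection("olives", 7974.0, 7.974),
                MassCorrection("asparagus", 3324.0, 3.324)]
        out = apply_mass_corrections(uses, corr)
        assert out["ingr_grams"].tolist() == [7.974, 3.324, 5.0]

    def test_empty_corrections_identity(self):
        uses = long_table([("d1", 0, "i", "x", 5.0, 0, 0, 0, 0)])
        pd.testing.assert_frame_equal(apply_mass_corrections(uses, []), uses)

    def test_unmatched_correction_warns(self):
        uses = long_table([("d1", 0, "i", "x", 5.0, 0, 0, 0, 0)])
        with pytest.warns(CurationWarning):
            apply_mass_corrections(uses, [MassCorrection("i", 99.0, 9.9)])

    def test_rescale_declared_scales_nutrients(self):
        uses = long_table([("d1", 0, "i", "x", 1000.0, 500.0, 10.0, 20.0, 5.0)])
        out = apply_mass_corrections(
            uses, [MassCorrection("i", 1000.0, 1.0)], rescale_declared=True)
        assert out["declared_energy"].iloc[0] == pytest.approx(0.5)

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=8, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_total_mass_drops_by_correction_sum(self, masses):
        uses = long_table([("d", i, f"i{i}", "x", m, 0, 0, 0, 0)
                           for i, m in enumerate(masses)])
        corr = [MassCorrection("i0", masses[0], masses[0] / 1000.0)]
        out = apply_mass_corrections(uses, corr)
        drop = uses["ingr_grams"].sum() - out["ingr_grams"].sum()
        assert drop == pytest.approx(masses[0] - masses[0] / 1000.0)
        # untouched rows unchanged
        pd.testing.assert_frame_equal(out.iloc[1:], uses.iloc[1:])

    def test_nonpositive_correction_rejected(self):
        with pytest.raises(CurationError):
            MassCorrection("i", 5.0, 0.0)


def item_with(**states) -> FoodItem:
    return FoodItem("f1", "thing", True, dict(states))


PLAN = ImputationPlan([
    ImputationRule("chloride", "*", ImputationStrategy.BY_CALCULATION),
    ImputationRule("vitamin_b12", "plant", ImputationStrategy.ASSUMED_ZERO),
    ImputationRule("carb", "*", ImputationStrategy.BY_CALCULATION),
    ImputationRule("iron", "*", ImputationStrategy.SIMILAR_ITEM),
    ImputationRule("zinc", "*", ImputationStrategy.BORROWED),
    ImputationRule("retinol", "*", ImputationStrategy.RECIPE_CALCULATION),
])


class TestImputeMissing:
    def test_b12_assumed_zero_in_plant_class(self):
        item = item_with(vitamin_b12=NutrientValue.missing())
        out, audit = impute_missing(item, PLAN, ImputationHelpers(),
                                    item_class="plant")
        v = out.values["vitamin_b12"]
        assert v.amount == 0.0 and v.method == "assumed_zero"
        assert audit.counts["assumed_zero"] == 1

    def test_chloride_from_sodium(self):
        item = item_with(chloride=NutrientValue.missing(),
                         sodium=NutrientValue.measured(1000.0))
        out, _ = impute_missing(item, PLAN, ImputationHelpers())
        # Cl/Na molar mass ratio: 35.453 / 22.990
        assert out.amount("chloride") == pytest.approx(1542.105, abs=0.01)
        assert round(out.amount("chloride")) == 1542

    def test_carbohydrate_by_difference(self):
        item = item_with(
            carb=NutrientValue.missing(),
            water=NutrientValue.measured(60.0),
            protein=NutrientValue.measured(10.0),
            fat=NutrientValue.measured(5.0),
            ash=NutrientValue.measured(2.0),
            alcohol=NutrientValue.measured(0.0),
        )
        out, _ = impute_missing(item, PLAN, ImputationHelpers())
        assert out.amount("carb") == pytest.approx(23.0)
        assert out.values["carb"].method == "by_calculation"

    def test_similar_item_donor(self):
        helpers = ImputationHelpers(donors={
            ("f1", "iron"): FoodItem("donor", "", True,
                                     {"iron": NutrientValue.measured(2.5)})})
        item = item_with(iron=NutrientValue.missing())
        out, audit = impute_missing(item, PLAN, helpers)
        assert out.amount("iron") == 2.5
        assert audit.counts["similar_item"] == 1

    def test_borrowed_value(self):
        helpers = ImputationHelpers(borrowed_values={("f1", "zinc"): 0.8})
        item = item_with(zinc=NutrientValue.missing())
        out, audit = impute_missing(item, PLAN, helpers)
        assert out.amount("zinc") == 0.8
        assert audit.counts["borrowed"] == 1

    def test_recipe_calculation(self):
        fcdb = {"x": FoodItem("x", "", True,
                              {"retinol": NutrientValue.measured(30.0)}),
                "y": FoodItem("y", "", True,
                              {"retinol": NutrientValue.measured(10.0)})}
        helpers = ImputationHelpers(
            recipes={"f1": Recipe("r", (RecipeComponent("x", 50.0),
                                        RecipeComponent("y", 50.0)))},
            recipe_fcdb=fcdb)
        item = item_with(retinol=NutrientValue.missing())
        out, audit = impute_missing(item, PLAN, helpers)
        assert out.amount("retinol") == pytest.approx(20.0)
        assert audit.counts["recipe_calculation"] == 1

    def test_measured_values_never_overwritten(self):
        item = item_with(chloride=NutrientValue.measured(3.0),
                         sodium=NutrientValue.measured(1000.0))
        out, audit = impute_missing(item, PLAN, ImputationHelpers())
        assert out.amount("chloride") == 3.0
        assert audit.total == 0

    def test_audit_total_equals_missing_cells(self):
        item = item_with(
            chloride=NutrientValue.missing(),
            sodium=NutrientValue.measured(100.0),
            vitamin_b12=NutrientValue.missing(),
            zinc=NutrientValue.missing(),
        )
        helpers = ImputationHelpers(borrowed_values={("f1", "zinc"): 1.0})
        _, audit = impute_missing(item, PLAN, helpers, item_class="plant")
        assert audit.total == 3

    def test_no_rule_raises_with_names(self):
        item = item_with(potassium=NutrientValue.missing())
        with pytest.raises(CurationError, match="potassium"):
            impute_missing(item, PLAN, ImputationHelpers())

    def test_strategy_failure_raises(self):
        item = item_with(iron=NutrientValue.missing())  # no donor configured
        with pytest.raises(CurationError, match="iron"):
            impute_missing(item, PLAN, ImputationHelpers())

    def test_plan_order_wins(self):
        plan = ImputationPlan([
            ImputationRule("zinc", "*", ImputationStrategy.ASSUMED_ZERO),
            ImputationRule("zinc", "*", ImputationStrategy.BORROWED),
        ])
        item = item_with(zinc=NutrientValue.missing())
        out, _ = impute_missing(item, plan, ImputationHelpers(
            borrowed_values={("f1", "zinc"): 9.0}))
        assert out.amount("zinc") == 0.0

    def test_chloride_factor_value(self):
        assert CHLORIDE_FROM_SODIUM == pytest.approx(1.5421, abs=1e-4)
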