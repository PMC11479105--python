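import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcdblink.fcdb import NutrientValue, ValueState
from fcdblink.matching import (CurationTables, MatchingError, Recipe,
                               RecipeComponent, Strategy, compose_recipe,
                               exact_match, generic_mean, resolve_all,
                               similarity_match)


class TestExactMatch:
    def test_curated_row_matches(self):
        rec = exact_match("eggplant", {"eggplant": "IT_melanzane"})
        assert rec.strategy is Strategy.EXACT
        assert rec.target == "IT_melanzane"

    def test_absent_name_returns_sentinel(self):
        assert exact_match("durian", {"eggplant": "IT_melanzane"}) is None

    def test_ambiguous_map_rows_raise_on_load(self, tmp_path):
        d = tmp_path / "tables"
        d.mkdir()
        (d / "name_map.csv").write_text(
            "ingr_name,food_id\neggplant,IT_1\neggplant,IT_2\n")
        with pytest.raises(MatchingError, match="ambiguous"):
            CurationTables.from_dir(d)


def profile_item(make, food_id, energy=100.0, protein=5.0, fat=3.0,
                 carb=10.0, water=70.0, cooked=True):
    return make(food_id, cooked=cooked, energy_kcal=energy, protein=protein,
                fat=fat, carb=carb, water=water)


class TestSimilarityMatch:
    def test_identical_candidate_selected_with_zero_distance(self, item_factory):
        target = [100.0, 5.0, 3.0, 10.0, 70.0]
        cands = [profile_item(item_factory, "IT_b", water=40.0),
                 profile_item(item_factory, "IT_a")]
        rec = similarity_match(target, cands)
        assert rec.target == "IT_a"
        assert rec.distance == pytest.approx(0.0)
        assert rec.strategy is Strategy.SIMILAR

    def test_monotone_in_single_axis(self, item_factory):
        target = [100.0, 5.0, 3.0, 10.0, 70.0]
        cands = [profile_item(item_factory, "IT_near", water=75.0),
                 profile_item(item_factory, "IT_far", water=80.0)]
        assert similarity_match(target, cands).target == "IT_near"

    def test_tie_breaks_to_smallest_food_id(self, item_factory):
        target = [100.0, 5.0, 3.0, 10.0, 70.0]
        cands = [profile_item(item_factory, "IT_z", water=75.0),
                 profile_item(item_factory, "IT_a", water=65.0)]
        assert similarity_match(target, cands).target == "IT_a"

    def test_empty_candidates_raise(self):
        with pytest.raises(MatchingError, match="empty"):
            similarity_match([0, 0, 0, 0, 0], [])

    def test_incomplete_candidate_profile_raises(self, item_factory):
        bad = item_factory("IT_bad", energy_kcal=10.0)  # lacks the other four
        with pytest.raises(MatchingError, match="lacks"):
            similarity_match([0, 0, 0, 0, 0], [bad])


class TestGenericMean:
    def test_arithmetic_mean(self, item_factory):
        out = generic_mean([profile_item(item_factory, "a", protein=10.0),
                            profile_item(item_factory, "b", protein=20.0)])
        assert out.amount("protein") == 15.0

    def test_partial_missing_averages_present_and_flags(self, item_factory):
        items = [profile_item(item_factory, "a", protein=10.0),
                 profile_item(item_factory, "b", protein=20.0),
                 profile_item(item_factory, "c")]
        items[2].values["protein"] = NutrientValue.missing()
        out = generic_mean(items)
        assert out.amount("protein") == 15.0
        assert "2/3" in out.values["protein"].method

    def test_all_missing_stays_missing(self, item_factory):
        items = [profile_item(item_factory, "a"), profile_item(item_factory, "b")]
        for it in items:
            it.values["protein"] = NutrientValue.missing()
        assert generic_mean(items).values["protein"].state is ValueState.MISSING

    def test_single_candidate_is_identity(self, item_factory):
        item = profile_item(item_factory, "a")
        out = generic_mean([item])
        for code in item.values:
            assert out.amount(code) == item.amount(code)

    def test_empty_raises(self):
        with pytest.raises(MatchingError):
            generic_mean([])

    @given(k=st.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_k_copies_equal_the_item(self, k, item_factory):
        item = profile_item(item_factory, "a", protein=7.25)
        out = generic_mean([item] * k)
        assert out.amount("protein") == pytest.approx(7.25)


class TestComposeRecipe:
    def test_weighted_mean(self, item_factory):
        fcdb = {"x": profile_item(item_factory, "x", energy=100.0),
                "y": profile_item(item_factory, "y", energy=300.0)}
        r = Recipe("r1", (RecipeComponent("x", 50.0), RecipeComponent("y", 50.0)))
        assert compose_recipe(r, fcdb).amount("energy_kcal") == pytest.approx(200.0)

    def test_single_component_identity(self, item_factory):
        fcdb = {"x": profile_item(item_factory, "x")}
        r = Recipe("r1", (RecipeComponent("x", 100.0),))
        out = compose_recipe(r, fcdb)
        for code in fcdb["x"].values:
            assert out.amount(code) == pytest.approx(fcdb["x"].amount(code))

    def test_zero_protein_everywhere(self, item_factory):
        fcdb = {"x": profile_item(item_factory, "x", protein=0.0),
                "y": profile_item(item_factory, "y", protein=0.0)}
        r = Recipe("r1", (RecipeComponent("x", 30.0), RecipeComponent("y", 70.0)))
        assert compose_recipe(r, fcdb).amount("protein") == 0.0

    def test_unresolvable_component_named(self, item_factory):
        r = Recipe("r1", (RecipeComponent("ghost", 100.0),))
        with pytest.raises(MatchingError, match="ghost"):
            compose_recipe(r, {})

    def test_grams_must_sum_to_100(self):
        with pytest.raises(MatchingError, match="sum"):
            Recipe("r1", (RecipeComponent("x", 50.0), RecipeComponent("y", 40.0)))

    def test_component_order_irrelevant(self, item_factory):
        fcdb = {"x": profile_item(item_factory, "x", energy=100.0),
                "y": profile_item(item_factory, "y", energy=300.0)}
        r1 = Recipe("r", (RecipeComponent("x", 30.0), RecipeComponent("y", 70.0)))
        r2 = Recipe("r", (RecipeComponent("y", 70.0), RecipeComponent("x", 30.0)))
        assert compose_recipe(r1, fcdb).amount("energy_kcal") == pytest.approx(
            compose_recipe(r2, fcdb).amount("energy_kcal"))

    @given(g=st.floats(1.0, 99.0))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_component_grams(self, g, item_factory):
        fcdb = {"x": profile_item(item_factory, "x", energy=200.0, water=0.0),
                "y": profile_item(item_factory, "y", energy=0.0, water=0.0,
                                  protein=0.0, fat=0.0, carb=0.0)}
        r = Recipe("r", (RecipeComponent("x", g), RecipeComponent("y", 100.0 - g)))
        assert compose_recipe(r, fcdb).amount("energy_kcal") == pytest.approx(2.0 * g)


class TestResolveAll:
    def test_all_exact(self, item_factory):
        fcdb = {f"IT_{n}": profile_item(item_factory, f"IT_{n}")
                for n in ("a", "b", "c")}
        tables = CurationTables(name_map={n: f"IT_{n}" for n in ("a", "b", "c")})
        recs, audit = resolve_all([(f"i{n}", n) for n in ("a", "b", "c")],
                                  tables, fcdb)
        assert audit.by_strategy["exact"] == 3
        assert audit.n_distinct == 3

    def test_unresolved_listed(self, item_factory):
        tables = CurationTables(name_map={})
        with pytest.raises(MatchingError, match="ghost"):
            resolve_all([("i1", "ghost")], tables, {})

    def test_raw_target_flags_discrepancy(self, item_factory):
        fcdb = {"IT_raw": profile_item(item_factory, "IT_raw", cooked=False)}
        tables = CurationTables(name_map={"salmon": "IT_raw"})
        recs, _ = resolve_all([("i1", "salmon")], tables, fcdb)
        assert recs[0].cooked_raw_discrepancy

    def test_strategy_partition_sums_to_distinct(self, synth_bundle):
        gt = synth_bundle.ground_truth
        audit = gt["expected_match_audit"]
        assert sum(audit.values()) == len(gt["strategies"])

    def test_planted_strategies_recovered(self, synth_bundle):
        """Run the cascade over the generated tables; audit matches the plant."""
        from fcdblink import pipeline
        res = pipeline.harmonize(
            dish_files=[synth_bundle.paths["dishes"]],
            fcdb_a_path=synth_bundle.paths["fcdb_a"],
            fcdb_b_path=synth_bundle.paths["fcdb_b"],
            registry_path=synth_bundle.paths["registry"],
            tables_dir=synth_bundle.outdir / "tables",
        )
        got = res.match_audit.by_strategy
        expected = synth_bundle.ground_truth["expected_match_audit"]
        used = {m.ingr_id for m in res.matches}
        planted = {i: s for i, s in synth_bundle.ground_truth["strategies"].items()
                   if i in used}
        for strat in expected:
            assert got[strat] == sum(s == strat for s in planted.values())
        for m in res.matches:
            assert planted[m.ingr_id] == m.strategy.value
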