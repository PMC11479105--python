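import numpy as np
import pytest

from fcdblink import synthdata
from fcdblink.fcdb import (ComponentDef, ComponentRegistry, FoodItem,
                           NutrientValue, Unit, default_registry)
from fcdblink.robust import MMConfig

#: Table of printed 5x5 quintile cross-classification percentages
#: (rows: target-FCDB quintiles, cols: source-FCDB quintiles).
PRINTED_CROSSTABS = {
    "energy": [
        [18.17, 1.84, 0.0, 0.0, 0.0],
        [1.56, 15.61, 2.84, 0.0, 0.0],
        [0.28, 2.26, 14.13, 3.30, 0.02],
        [0.0, 0.26, 2.80, 13.63, 3.32],
        [0.0, 0.06, 0.22, 3.06, 16.67],
    ],
    "protein": [
        [18.35, 1.44, 0.0, 0.22, 0.0],
        [1.66, 16.15, 2.22, 0.02, 0.0],
        [0.0, 2.30, 15.47, 2.14, 0.04],
        [0.0, 0.14, 2.26, 15.67, 1.94],
        [0.0, 0.0, 0.02, 1.96, 18.03],
    ],
    "fat": [
        [17.81, 2.20, 0.0, 0.0, 0.0],
        [2.28, 13.97, 3.56, 0.20, 0.0],
        [0.0, 2.94, 12.19, 4.76, 0.10],
        [0.0, 0.64, 3.76, 11.15, 4.46],
        [0.0, 0.18, 0.48, 3.90, 15.45],
    ],
    "carb": [
        [16.89, 3.02, 0.12, 0.0, 0.0],
        [2.70, 12.17, 4.40, 0.70, 0.02],
        [0.20, 4.50, 11.07, 4.00, 0.22],
        [0.22, 0.36, 4.08, 11.75, 3.62],
        [0.0, 0.0, 0.3, 3.56, 16.13],
    ],
}


@pytest.fixture(scope="session")
def printed_crosstabs() -> dict:
    return PRINTED_CROSSTABS


@pytest.fixture(scope="session")
def registry() -> ComponentRegistry:
    return default_registry()


@pytest.fixture
def tiny_registry() -> ComponentRegistry:
    return ComponentRegistry([
        ComponentDef("energy_kcal", "Energy", Unit.KCAL),
        ComponentDef("protein", "Proteins", Unit.G),
        ComponentDef("fat", "Fats", Unit.G),
        ComponentDef("carb", "Carbohydrates", Unit.G),
        ComponentDef("water", "Water", Unit.G),
        ComponentDef("retinol", "Retinol", Unit.UG, trace_threshold=0.6),
    ])


def make_item(food_id: str, cooked: bool = True, **amounts) -> FoodItem:
    values = {k: NutrientValue.measured(v) for k, v in amounts.items()}
    return FoodItem(food_id, food_id, cooked, values)


@pytest.fixture(scope="session")
def item_factory():
    return make_item


@pytest.fixture(scope="session")
def fast_mm() -> MMConfig:
    """Reduced fast-S subsampling so the suite stays quick."""
    return MMConfig(n_subsamples=50, seed=20240101)


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory):
    """A feature-complete synthetic bundle shared across test modules."""
    cfg = synthdata.SynthConfig(
        seed=20240915, n_items=24, n_dishes=80, max_ingredients=6,
        carb_definition_offset=True, noise_sd=0.05,
        missing_rate=0.25, trace_rate=0.15,
        recipe_fraction=0.1, similar_fraction=0.1, generic_fraction=0.1,
        borrowed_fraction=0.1, rawcooked_rate=0.3,
        plant_plate_only=True, plant_mass_outlier=True,
    )
    out = tmp_path_factory.mktemp("bundle")
    return synthdata.generate(cfg, out)


@pytest.fixture(scope="session")
def offset_bundle(tmp_path_factory):
    """Offset-only world: no noise, all matches exact."""
    cfg = synthdata.SynthConfig(seed=777, n_items=20, n_dishes=150,
                                carb_definition_offset=True)
    out = tmp_path_factory.mktemp("offset_bundle")
    return synthdata.generate(cfg, out)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
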