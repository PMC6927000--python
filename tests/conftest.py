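import pytest

from dietopt import (
    FoodCategory,
    FoodDatabase,
    FoodItem,
    GeneratorParams,
    NutrientProfile,
    generate_food_db,
)
from dietopt.synthetic import DEFAULT_N_ITEMS

#: Reduced per-category item counts used for solver sweeps (about 80 items),
#: keeping many-instance suites fast while spanning all 10 categories.
SMALL_N_ITEMS = {c: max(2, n * 2 // 5) for c, n in DEFAULT_N_ITEMS.items()}


@pytest.fixture(scope="session")
def tiny_db() -> FoodDatabase:
    """Three hand-written items with easy arithmetic."""
    return FoodDatabase(
        [
            FoodItem(
                item_id="rice",
                name="plain rice",
                category=FoodCategory.CEREALS,
                profile=NutrientProfile(
                    {"energy_kcal": 130, "carb_g": 30, "protein_g": 2.5, "iron_mg": 0.5}
                ),
                price=0.30,
                serving_note="30 g carbohydrate",
            ),
            FoodItem(
                item_id="kangkung",
                name="water spinach",
                category=FoodCategory.VEGETABLES,
                profile=NutrientProfile(
                    {"energy_kcal": 25, "vitA_RE": 300, "vitC_mg": 20, "iron_mg": 1.6}
                ),
                price=0.50,
            ),
            FoodItem(
                item_id="patin",
                name="silver catfish",
                category=FoodCategory.FISH,
                profile=NutrientProfile(
                    {"energy_kcal": 110, "protein_g": 14, "fat_g": 5, "iron_mg": 1.1}
                ),
                price=1.40,
            ),
        ]
    )


@pytest.fixture(scope="session")
def default_db() -> FoodDatabase:
    return generate_food_db(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def small_db() -> FoodDatabase:
    return generate_food_db(GeneratorParams(seed=1, n_items=SMALL_N_ITEMS))
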