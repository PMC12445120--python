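import pytest

from ecomenu.io import load_groups, load_refs
from ecomenu.model import (
    FoodItem,
    Ingredient,
    NutrientVector,
    Recipe,
    index_foods,
)
from ecomenu.synth import SynthConfig, generate_study_fixture


@pytest.fixture(scope="session")
def refs():
    return load_refs()


@pytest.fixture(scope="session")
def groups():
    return load_groups()


@pytest.fixture(scope="session")
def tiny_foods():
    """Hand-built five-food database with one trace spice."""
    return [
        FoodItem(
            food_id="beef",
            name="beef stew meat",
            food_group="red_meat",
            nutrients=NutrientVector(
                energy_kcal=250, protein_g=26, fat_g=17, satfat_g=7,
                sodium_mg=72, iron_mg=2.6, potassium_mg=330,
            ),
            cf_factor=27.0,
            wf_factor=15000.0,
            price_per_kg=10.0,
        ),
        FoodItem(
            food_id="rice",
            name="white rice",
            food_group="cereal",
            nutrients=NutrientVector(
                energy_kcal=360, protein_g=7, fat_g=0.6, carb_g=79,
                fiber_g=1.3, magnesium_mg=25, potassium_mg=86,
            ),
            cf_factor=1.2,
            wf_factor=1600.0,
            price_per_kg=1.5,
        ),
        FoodItem(
            food_id="tomato",
            name="tomato",
            food_group="vegetable_fruit",
            nutrients=NutrientVector(
                energy_kcal=18, protein_g=0.9, fat_g=0.2, carb_g=3.9,
                fiber_g=1.2, vitc_mg=14, vita_ug=42, potassium_mg=237,
            ),
            cf_factor=1.1,
            wf_factor=214.0,
            price_per_kg=1.0,
        ),
        FoodItem(
            food_id="oliveoil",
            name="olive oil",
            food_group="oil",
            nutrients=NutrientVector(
                energy_kcal=884, fat_g=100, satfat_g=14, vite_mg=14,
            ),
            cf_factor=5.4,
            wf_factor=14400.0,
            price_per_kg=6.0,
        ),
        FoodItem(
            food_id="blackpepper",
            name="black pepper",
            food_group="vegetable_fruit",
            nutrients=NutrientVector(
                energy_kcal=251, protein_g=10, fat_g=3.3, satfat_g=1.4,
                carb_g=64, fiber_g=25, sodium_mg=20, calcium_mg=443,
                iron_mg=9.7, magnesium_mg=171, potassium_mg=1329,
            ),
            cf_factor=None,
            wf_factor=None,
            price_per_kg=25.0,
            is_trace=True,
        ),
    ]


@pytest.fixture(scope="session")
def tiny_lookup(tiny_foods):
    return index_foods(tiny_foods)


@pytest.fixture(scope="session")
def stew_recipe():
    return Recipe(
        recipe_id="stew",
        name="beef and tomato stew",
        meal_type="I",
        course_category="main-meat",
        ingredients=(
            Ingredient("beef", 100.0),
            Ingredient("tomato", 80.0),
            Ingredient("oliveoil", 10.0),
            Ingredient("blackpepper", 1.0),
        ),
    )


@pytest.fixture(scope="session")
def pilaf_recipe():
    return Recipe(
        recipe_id="pilaf",
        name="rice pilaf",
        meal_type="II",
        course_category="pilaf/pasta",
        ingredients=(Ingredient("rice", 70.0), Ingredient("oliveoil", 8.0)),
    )


@pytest.fixture(scope="session")
def study_fixture(groups):
    """One full 5-group x 3-source synthetic study, shared across tests."""
    return generate_study_fixture(SynthConfig(seed=11), groups=groups)
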