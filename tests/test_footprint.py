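"""Footprint accounting: unit conversions, exclusion rule, aggregation."""

import dataclasses

import numpy as np
import pytest

from ecomenu.footprint import (
    carbon_footprint,
    menu_footprints,
    recipe_footprint,
    summarize_by_meal_type,
    water_footprint,
)
from ecomenu.model import (
    FoodItem,
    Ingredient,
    Menu,
    MenuDay,
    NutrientVector,
    Recipe,
    index_foods,
    scale_recipe,
)


def _food(fid, cf=None, wf=None, trace=False):
    return FoodItem(
        food_id=fid,
        name=fid,
        food_group="vegetable_fruit",
        nutrients=NutrientVector(energy_kcal=50),
        cf_factor=cf,
        wf_factor=wf,
        is_trace=trace,
    )


def _recipe(*ingredients, meal_type="I"):
    return Recipe(
        recipe_id="r",
        name="r",
        meal_type=meal_type,
        course_category="x",
        ingredients=tuple(Ingredient(f, m) for f, m in ingredients),
    )


class TestUnitArithmetic:
    def test_carbon_200g_at_27_per_kg(self):
        foods = index_foods([_food("a", cf=27.0, wf=0.0)])
        assert carbon_footprint(_recipe(("a", 200.0)), foods) == pytest.approx(5.4)

    def test_water_300g_at_4000_m3_per_ton(self):
        foods = index_foods([_food("a", cf=0.0, wf=4000.0)])
        assert water_footprint(_recipe(("a", 300.0)), foods) == pytest.approx(1.2)

    def test_factorless_and_trace_contribute_zero(self):
        foods = index_foods(
            [_food("bare"), _food("spice", cf=9.0, wf=9.0, trace=True)]
        )
        recipe = _recipe(("bare", 100.0), ("spice", 100.0))
        assert carbon_footprint(recipe, foods) == 0.0
        assert water_footprint(recipe, foods) == 0.0
        assert recipe_footprint(recipe, foods).covered_mass_fraction == 0.0


class TestAlgebraicProperties:
    """Additivity/homogeneity/trace-neutrality vs an independent enumeration."""

    def _random_world(self, rng):
        foods = []
        for i in range(5):
            foods.append(
                _food(
                    f"f{i}",
                    cf=float(rng.uniform(0, 30)) if rng.uniform() < 0.8 else None,
                    wf=float(rng.uniform(0, 15000)) if rng.uniform() < 0.8 else None,
                    trace=bool(rng.uniform() < 0.2),
                )
            )
        k = int(rng.integers(1, 6))
        ingredients = [
            (f"f{int(rng.integers(5))}", float(rng.uniform(1, 300))) for _ in range(k)
        ]
        return index_foods(foods), _recipe(*ingredients)

    def test_matches_per_ingredient_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            foods, recipe = self._random_world(rng)
            # oracle: literal per-ingredient sum, written independently
            exp_c = exp_w = 0.0
            for ing in recipe.ingredients:
                f = foods[ing.food_id]
                if not f.is_trace and f.cf_factor is not None:
                    exp_c += ing.mass_g * f.cf_factor / 1e3
                if not f.is_trace and f.wf_factor is not None:
                    exp_w += ing.mass_g * f.wf_factor / 1e6
            assert carbon_footprint(recipe, foods) == pytest.approx(exp_c, rel=1e-12, abs=1e-15)
            assert water_footprint(recipe, foods) == pytest.approx(exp_w, rel=1e-12, abs=1e-15)

    def test_additive_over_ingredient_split(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            foods, recipe = self._random_world(rng)
            whole = carbon_footprint(recipe, foods)
            parts = sum(
                carbon_footprint(_recipe((ing.food_id, ing.mass_g)), foods)
                for ing in recipe.ingredients
            )
            assert whole == pytest.approx(parts, rel=1e-12, abs=1e-15)

    def test_homogeneous_in_portion_scale(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            foods, recipe = self._random_world(rng)
            alpha = float(rng.uniform(0.1, 5))
            assert carbon_footprint(scale_recipe(recipe, alpha), foods) == pytest.approx(
                alpha * carbon_footprint(recipe, foods), rel=1e-12, abs=1e-15
            )
            assert water_footprint(scale_recipe(recipe, alpha), foods) == pytest.approx(
                alpha * water_footprint(recipe, foods), rel=1e-12, abs=1e-15
            )

    def test_trace_toggle_neutral_on_factorless_food(self):
        plain = _food("a")  # no factors at all
        foods_off = index_foods([plain, _food("b", cf=2.0, wf=100.0)])
        foods_on = index_foods(
            [dataclasses.replace(plain, is_trace=True), _food("b", cf=2.0, wf=100.0)]
        )
        recipe = _recipe(("a", 50.0), ("b", 100.0))
        assert carbon_footprint(recipe, foods_off) == carbon_footprint(recipe, foods_on)
        assert water_footprint(recipe, foods_off) == water_footprint(recipe, foods_on)

    def test_trace_toggle_removes_exactly_own_contribution(self):
        factored = _food("a", cf=3.0, wf=500.0)
        other = _food("b", cf=2.0, wf=100.0)
        recipe = _recipe(("a", 200.0), ("b", 100.0))
        foods = index_foods([factored, other])
        traced = index_foods([dataclasses.replace(factored, is_trace=True), other])
        assert carbon_footprint(recipe, foods) - carbon_footprint(recipe, traced) == pytest.approx(0.2 * 3.0)
        assert water_footprint(recipe, foods) - water_footprint(recipe, traced) == pytest.approx(200.0 / 1e6 * 500.0)

    def test_adding_factored_ingredient_strictly_increases(self):
        foods = index_foods([_food("a", cf=2.0, wf=100.0), _food("b", cf=1.0, wf=50.0)])
        small = _recipe(("a", 100.0))
        bigger = _recipe(("a", 100.0), ("b", 10.0))
        assert carbon_footprint(bigger, foods) > carbon_footprint(small, foods)
        assert water_footprint(bigger, foods) > water_footprint(small, foods)


class TestMenuAggregation:
    def _world(self):
        foods = index_foods(
            [_food("a", cf=10.0, wf=1000.0), _food("b", cf=2.0, wf=500.0)]
        )
        r1 = dataclasses.replace(_recipe(("a", 100.0)), recipe_id="r1", meal_type="I")
        r2 = dataclasses.replace(_recipe(("b", 200.0)), recipe_id="r2", meal_type="II")
        r3 = dataclasses.replace(_recipe(("a", 50.0), ("b", 100.0)), recipe_id="r3", meal_type="I")
        book = {"r1": r1, "r2": r2, "r3": r3}
        return foods, book

    def test_identical_days_have_zero_sd(self):
        foods, book = self._world()
        days = tuple(
            MenuDay(day_index=i + 1, selections={"I": "r1", "II": "r2"})
            for i in range(5)
        )
        menu = Menu(target_group="prison", source="DPM", days=days)
        by_type, _ = summarize_by_meal_type(menu_footprints(menu, book, foods))
        assert (by_type[("carbon_kgco2e", "std")] == 0.0).all()

    def test_two_day_menu_matches_hand_sums(self):
        foods, book = self._world()
        menu = Menu(
            target_group="prison",
            source="DPM",
            days=(
                MenuDay(1, {"I": "r1", "II": "r2"}),
                MenuDay(2, {"I": "r3", "II": "r2"}),
            ),
        )
        per_meal = menu_footprints(menu, book, foods)
        by_type, overall = summarize_by_meal_type(per_meal)
        # hand sums: r1 carbon 1.0, r3 carbon 0.5+0.2=0.7, r2 carbon 0.4
        assert by_type.loc["I", ("carbon_kgco2e", "mean")] == pytest.approx(0.85)
        assert by_type.loc["II", ("carbon_kgco2e", "mean")] == pytest.approx(0.4)
        # per-menu mean = mean over the four served meals
        assert overall["carbon_kgco2e"] == pytest.approx((1.0 + 0.7 + 0.4 + 0.4) / 4)

    def test_per_menu_mean_equals_mean_over_all_meals(self):
        foods, book = self._world()
        menu = Menu(
            target_group="prison",
            source="DPM",
            days=(
                MenuDay(1, {"I": "r1", "II": "r2"}),
                MenuDay(2, {"I": "r3", "II": "r2"}),
            ),
        )
        per_meal = menu_footprints(menu, book, foods)
        _, overall = summarize_by_meal_type(per_meal)
        assert overall["water_m3"] == pytest.approx(per_meal["water_m3"].mean())

    def test_empty_menu_rejected(self):
        foods, book = self._world()
        menu = Menu(target_group="prison", source="DPM", days=())
        with pytest.raises(ValueError):
            menu_footprints(menu, book, foods)
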