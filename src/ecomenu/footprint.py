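"""Carbon and water footprint accounting for portions, meals and menus.

Carbon: sum over contributing ingredients of ``mass_g/1000 × cf_factor``
(kg CO2e per portion).  Water: ``mass_g/1e6 × wf_factor`` — mass in tons
times m³/ton gives m³ per portion.  Trace ingredients (spices, flavourings)
and ingredients without a factor are excluded from the sums; exclusion is a
reported condition (``covered_mass_fraction``), never an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import Menu, Recipe, as_food_lookup, as_recipe_lookup

__all__ = [
    "FootprintResult",
    "carbon_footprint",
    "water_footprint",
    "recipe_footprint",
    "menu_footprints",
    "summarize_by_meal_type",
]


@dataclass(frozen=True)
class FootprintResult:
    """Per-portion footprints plus the mass fraction actually covered.

    ``covered_mass_fraction`` is the fraction of total ingredient mass that
    is non-trace and carries *both* footprint factors; it discloses how much
    of the recipe the exclusion rule dropped.
    """

    carbon: float  # kg CO2e / portion
    water: float  # m3 / portion
    covered_mass_fraction: float

    def __post_init__(self) -> None:
        assert self.carbon >= 0.0 and self.water >= 0.0
        assert 0.0 <= self.covered_mass_fraction <= 1.0 + 1e-12


def carbon_footprint(recipe: Recipe, food_db) -> float:
    """kg CO2e per portion, excluding trace and factor-less ingredients."""
    foods = as_food_lookup(food_db)
    total = 0.0
    for ing in recipe.ingredients:
        food = foods[ing.food_id]
        if food.is_trace or food.cf_factor is None:
            continue
        total += (ing.mass_g / 1000.0) * food.cf_factor
    return total


def water_footprint(recipe: Recipe, food_db) -> float:
    """m³ per portion: mass in tons × (m³/ton), same exclusion rule."""
    foods = as_food_lookup(food_db)
    total = 0.0
    for ing in recipe.ingredients:
        food = foods[ing.food_id]
        if food.is_trace or food.wf_factor is None:
            continue
        total += (ing.mass_g / 1_000_000.0) * food.wf_factor
    return total


def recipe_footprint(recipe: Recipe, food_db) -> FootprintResult:
    foods = as_food_lookup(food_db)
    total_mass = 0.0
    covered_mass = 0.0
    for ing in recipe.ingredients:
        food = foods[ing.food_id]
        total_mass += ing.mass_g
        if not food.is_trace and food.cf_factor is not None and food.wf_factor is not None:
            covered_mass += ing.mass_g
    return FootprintResult(
        carbon=carbon_footprint(recipe, foods),
        water=water_footprint(recipe, foods),
        covered_mass_fraction=covered_mass / total_mass if total_mass else 0.0,
    )


def menu_footprints(menu: Menu, recipe_book, food_db) -> pd.DataFrame:
    """Per-meal footprint rows for a menu.

    Columns: menu_id, meal_type, day, carbon_kgco2e, water_m3,
    covered_mass_fraction — one row per (day, meal slot).
    """
    if not menu.days:
        raise ValueError("empty menu")
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    menu_id = f"{menu.target_group}-{menu.source}"
    rows = []
    for day in menu.days:
        for meal_type, recipe_id in sorted(day.selections.items()):
            fp = recipe_footprint(recipes[recipe_id], foods)
            rows.append(
                {
                    "menu_id": menu_id,
                    "meal_type": meal_type,
                    "day": day.day_index,
                    "carbon_kgco2e": fp.carbon,
                    "water_m3": fp.water,
                    "covered_mass_fraction": fp.covered_mass_fraction,
                }
            )
    return pd.DataFrame(rows)


def summarize_by_meal_type(
    per_meal: pd.DataFrame, value_cols=("carbon_kgco2e", "water_m3")
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-meal-type mean ± SD and the per-menu mean over all meal instances.

    The per-menu value averages every meal of the month equally (not a mean
    of meal-type means), matching a whole-menu "average of the meal types"
    reading; SD uses the sample convention (ddof=1).
    """
    by_type = per_meal.groupby("meal_type")[list(value_cols)].agg(["mean", "std"])
    overall = per_meal[list(value_cols)].mean()
    return by_type, overall
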