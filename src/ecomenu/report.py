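"""Sustainability report assembly and table writers.

``score_menu`` produces one row per served meal carrying all six
sustainability metrics (carbon, water, NRF 9.3, SAIN, LIM, SAIN-LIM class)
plus cost and energy/macros; ``menu_summary`` reduces it to the per-menu
means; ``to_long`` reshapes per-meal rows into the long form consumed by
:func:`ecomenu.stats.compare_sources`; ``table1`` aggregates food-group
grams and macros per menu-day across sources.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .costing import portion_cost
from .footprint import recipe_footprint
from .model import (
    FOOD_GROUPS,
    Menu,
    ReferenceValues,
    as_food_lookup,
    as_recipe_lookup,
    recipe_totals,
)
from .profiling import profile_meal

__all__ = ["score_menu", "menu_summary", "to_long", "table1", "METRIC_COLUMNS"]

#: Per-meal numeric metric columns eligible for source comparison.
METRIC_COLUMNS = (
    "carbon_kgco2e",
    "water_m3",
    "nrf93",
    "sain",
    "lim",
    "sain_lim_class",
    "cost_usd",
    "energy_kcal",
    "protein_g",
    "fat_g",
    "carb_g",
)


def score_menu(
    menu: Menu,
    recipe_book,
    food_db,
    refs: ReferenceValues,
    fx_rate: float = 1.0,
    nrf_variant: str = "sum",
) -> pd.DataFrame:
    """Score every meal of a menu on all sustainability metrics.

    Returns one row per (day, meal slot) with identification columns
    (menu_id, target_group, source, meal_type, day) and the metric columns
    in :data:`METRIC_COLUMNS` plus covered_mass_fraction.
    """
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    menu_id = f"{menu.target_group}-{menu.source}"
    rows = []
    for day in menu.days:
        for meal_type, recipe_id in sorted(day.selections.items()):
            recipe = recipes[recipe_id]
            fp = recipe_footprint(recipe, foods)
            scores = profile_meal(recipe, foods, refs, variant=nrf_variant)
            cost = portion_cost(recipe, foods, fx_rate)
            totals = recipe_totals(recipe, foods)
            rows.append(
                {
                    "menu_id": menu_id,
                    "target_group": menu.target_group,
                    "source": menu.source,
                    "meal_type": meal_type,
                    "day": day.day_index,
                    "carbon_kgco2e": fp.carbon,
                    "water_m3": fp.water,
                    "covered_mass_fraction": fp.covered_mass_fraction,
                    "nrf93": scores.nrf93,
                    "sain": scores.sain,
                    "lim": scores.lim,
                    "sain_lim_class": scores.sain_lim_class,
                    "cost_usd": cost.cost_usd,
                    "energy_kcal": totals["energy_kcal"],
                    "protein_g": totals["protein_g"],
                    "fat_g": totals["fat_g"],
                    "carb_g": totals["carb_g"],
                }
            )
    return pd.DataFrame(rows)


def menu_summary(per_meal: pd.DataFrame) -> pd.DataFrame:
    """Per-menu mean of every metric over all meal instances of the month."""
    cols = [c for c in METRIC_COLUMNS if c in per_meal.columns]
    return (
        per_meal.groupby(["menu_id", "target_group", "source"], as_index=False)[cols]
        .mean()
    )


def to_long(per_meal_frames: Iterable[pd.DataFrame], metrics=METRIC_COLUMNS) -> pd.DataFrame:
    """Stack per-meal score frames into long form for source comparison.

    Output columns: source, target_group, meal_type, day, metric, value.
    """
    frames = [f for f in per_meal_frames if len(f)]
    stacked = pd.concat(frames, ignore_index=True)
    return stacked.melt(
        id_vars=["source", "target_group", "meal_type", "day"],
        value_vars=[m for m in metrics if m in stacked.columns],
        var_name="metric",
        value_name="value",
    )


def table1(menus: Sequence[Menu], recipe_book, food_db) -> pd.DataFrame:
    """Food-group grams and energy/macros per menu-day, averaged per source.

    Rows: the ten food groups (grams per menu-day) followed by
    energy_kcal / protein_g / fat_g / carb_g per menu-day; one column per
    source.  Grams conserve: the food-group rows of one source sum to that
    source's mean total ingredient mass per day.
    """
    if not menus:
        raise ValueError("no menus given")
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    per_source: dict[str, list[dict[str, float]]] = {}
    for menu in menus:
        day_rows = []
        for day in menu.days:
            row = dict.fromkeys(FOOD_GROUPS, 0.0)
            row.update(energy_kcal=0.0, protein_g=0.0, fat_g=0.0, carb_g=0.0)
            for recipe_id in day.selections.values():
                recipe = recipes[recipe_id]
                for ing in recipe.ingredients:
                    row[foods[ing.food_id].food_group] += ing.mass_g
                totals = recipe_totals(recipe, foods)
                for k in ("energy_kcal", "protein_g", "fat_g", "carb_g"):
                    row[k] += totals[k]
            day_rows.append(row)
        per_source.setdefault(menu.source, []).extend(day_rows)

    out = {}
    for source in sorted(per_source):
        df = pd.DataFrame(per_source[source])
        out[source] = df.mean()
    result = pd.DataFrame(out)
    result.index.name = "row"
    return result
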