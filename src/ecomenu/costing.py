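"""Raw-material cost per portion and per menu.

Only ingredient purchase cost enters: ``cost_local = Σ mass_g ×
price_per_kg / 1000``; labour, energy and other overheads are excluded.
Unlike footprints, a missing price is a hard error — a silently zero-priced
meal would corrupt any cost comparison.  ``cost_usd = cost_local / fx_rate``
with ``fx_rate`` local currency units per USD.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import Menu, ModelError, Recipe, as_food_lookup, as_recipe_lookup

__all__ = ["CostResult", "portion_cost", "menu_costs"]


@dataclass(frozen=True)
class CostResult:
    cost_local: float
    cost_usd: float
    fx_rate: float


def portion_cost(recipe: Recipe, food_db, fx_rate: float = 1.0) -> CostResult:
    """Raw-material cost of one portion; errors name any unpriced food."""
    if not (fx_rate > 0.0):
        raise ValueError(f"fx_rate must be > 0, got {fx_rate!r}")
    foods = as_food_lookup(food_db)
    total = 0.0
    for ing in recipe.ingredients:
        food = foods[ing.food_id]
        if food.price_per_kg is None:
            raise ModelError(
                f"recipe {recipe.recipe_id!r}: food {ing.food_id!r} has no price"
            )
        total += ing.mass_g * food.price_per_kg / 1000.0
    return CostResult(cost_local=total, cost_usd=total / fx_rate, fx_rate=fx_rate)


def menu_costs(menu: Menu, recipe_book, food_db, fx_rate: float = 1.0) -> pd.DataFrame:
    """Per-meal USD cost rows: menu_id, meal_type, day, cost_usd.

    Aggregate with :func:`ecomenu.footprint.summarize_by_meal_type` using
    ``value_cols=('cost_usd',)`` — the aggregation convention mirrors the
    footprint one (per-meal-type mean ± SD; per-menu mean over all meals).
    """
    if not menu.days:
        raise ValueError("empty menu")
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    menu_id = f"{menu.target_group}-{menu.source}"
    rows = []
    for day in menu.days:
        for meal_type, recipe_id in sorted(day.selections.items()):
            cost = portion_cost(recipes[recipe_id], foods, fx_rate)
            rows.append(
                {
                    "menu_id": menu_id,
                    "meal_type": meal_type,
                    "day": day.day_index,
                    "cost_usd": cost.cost_usd,
                }
            )
    return pd.DataFrame(rows)
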