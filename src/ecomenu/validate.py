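"""Standalone menu constraint validator.

Deliberately written as a straight re-statement of the planning constraints,
independent of the planner's search internals, so it can serve as an oracle
for planner output.  Energy and macronutrient windows apply to the day's
three core courses (I-III); a hospital's fourth course is an extra outside
the lunch energy budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    Menu,
    TargetGroup,
    as_food_lookup,
    as_recipe_lookup,
    recipe_totals,
    validate_menu_shape,
)

__all__ = ["Violation", "validate_menu"]

CORE_SLOTS = ("I", "II", "III")


@dataclass(frozen=True)
class Violation:
    day_index: int  # 0 for menu-level problems
    constraint: str  # e.g. "season", "energy", "repeat_window"
    detail: str

    def __str__(self) -> str:
        where = f"day {self.day_index}: " if self.day_index else ""
        return f"{where}[{self.constraint}] {self.detail}"


def validate_menu(
    menu: Menu,
    group: TargetGroup,
    recipe_book,
    food_db,
    season: str = "autumn",
    repeat_window: int = 7,
    check_shape: bool = True,
) -> list[Violation]:
    """Check a menu against every planning constraint; return all violations.

    Checks: slot completeness, recipe/slot agreement, season eligibility,
    day energy within the group tolerance and macros within the gram
    windows (core courses I-III), no recipe recurring within
    ``repeat_window`` days, and course-category frequency caps per 7 days.
    """
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    out: list[Violation] = []

    if check_shape:
        for msg in validate_menu_shape(menu, group.n_meal_slots):
            out.append(Violation(0, "shape", msg))

    days = sorted(menu.days, key=lambda d: d.day_index)
    for day in days:
        energy = 0.0
        macros = {"protein_g": 0.0, "fat_g": 0.0, "carb_g": 0.0}
        for meal_type, recipe_id in day.selections.items():
            if recipe_id not in recipes:
                out.append(
                    Violation(day.day_index, "unknown_recipe", recipe_id)
                )
                continue
            recipe = recipes[recipe_id]
            if recipe.meal_type != meal_type:
                out.append(
                    Violation(
                        day.day_index,
                        "slot_mismatch",
                        f"{recipe_id} is a type-{recipe.meal_type} recipe in slot {meal_type}",
                    )
                )
            if season not in recipe.seasons:
                out.append(
                    Violation(
                        day.day_index,
                        "season",
                        f"{recipe_id} not offered in {season}",
                    )
                )
            if meal_type in CORE_SLOTS:
                totals = recipe_totals(recipe, foods)
                energy += totals["energy_kcal"]
                for k in macros:
                    macros[k] += totals[k]
        if set(CORE_SLOTS) <= set(day.selections) and all(
            day.selections[mt] in recipes for mt in CORE_SLOTS
        ):
            lo = group.energy_target_kcal * (1.0 - group.energy_tolerance)
            hi = group.energy_target_kcal * (1.0 + group.energy_tolerance)
            if not (lo <= energy <= hi):
                out.append(
                    Violation(
                        day.day_index,
                        "energy",
                        f"{energy:.1f} kcal outside [{lo:.1f}, {hi:.1f}]",
                    )
                )
            for k, (mlo, mhi) in group.macro_targets.items():
                if not (mlo <= macros[k] <= mhi):
                    out.append(
                        Violation(
                            day.day_index,
                            "macro",
                            f"{k} {macros[k]:.1f} g outside [{mlo}, {mhi}]",
                        )
                    )

    # repeat window: a recipe may not recur within repeat_window days
    for i, day in enumerate(days):
        for j in range(i + 1, len(days)):
            other = days[j]
            if other.day_index - day.day_index >= repeat_window:
                break
            shared = set(day.selections.values()) & set(other.selections.values())
            for rid in sorted(shared):
                out.append(
                    Violation(
                        other.day_index,
                        "repeat_window",
                        f"{rid} already served on day {day.day_index}",
                    )
                )

    # frequency rules: course-category caps per sliding 7-day window
    if group.frequency_rules:
        cats_by_day = {}
        for day in days:
            cats = []
            for rid in day.selections.values():
                if rid in recipes:
                    cats.append(recipes[rid].course_category)
            cats_by_day[day.day_index] = cats
        indices = sorted(cats_by_day)
        for cat, cap in group.frequency_rules.items():
            for start in indices:
                window = [
                    c
                    for d in indices
                    if start <= d < start + 7
                    for c in cats_by_day[d]
                ]
                count = sum(1 for c in window if c == cat)
                if count > cap:
                    out.append(
                        Violation(
                            start,
                            "frequency",
                            f"{cat} served {count}x in days {start}-{start + 6} (max {cap})",
                        )
                    )
    return out
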