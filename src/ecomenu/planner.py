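"""Seeded constraint-based menu planning (the "decision mechanism").

The planner is a seeded randomized greedy search with day-level
backtracking: for each day it shuffles the eligible recipes per course slot,
walks slot combinations in shuffled order, and accepts the first combination
whose summed energy and macronutrients fall inside the target group's
windows while respecting the repeat window and course-category frequency
caps.  If a day runs dry it backtracks to the previous day's next candidate.
The same seed and inputs always yield the same menu.

Three core courses (I-III) are planned; a hospital's fourth course is added
afterwards with :func:`add_fourth_course`, mirroring manual placement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    Menu,
    MenuDay,
    ModelError,
    Recipe,
    TargetGroup,
    as_food_lookup,
    as_recipe_lookup,
    recipe_totals,
)
from .validate import CORE_SLOTS, Violation, validate_menu

__all__ = [
    "PlannerConfig",
    "PlanningError",
    "plan_menu",
    "apply_manual_override",
    "add_fourth_course",
]


class PlanningError(RuntimeError):
    """Raised when no feasible menu exists within the backtracking budget."""


@dataclass(frozen=True)
class PlannerConfig:
    seed: int = 0
    energy_tolerance: Optional[float] = None  # None -> use the group's
    repeat_window: int = 7
    frequency_rules: Optional[Mapping[str, int]] = None  # None -> the group's
    season: str = "autumn"
    max_attempts: int = 200_000

    def __post_init__(self) -> None:
        if self.energy_tolerance is not None and not (
            0.0 < self.energy_tolerance < 0.5
        ):
            raise ModelError("energy_tolerance must lie in (0, 0.5)")
        if self.repeat_window < 1:
            raise ModelError("repeat_window must be >= 1")
        if self.max_attempts < 1:
            raise ModelError("max_attempts must be >= 1")


def _effective(group: TargetGroup, config: PlannerConfig):
    tol = config.energy_tolerance if config.energy_tolerance is not None else group.energy_tolerance
    freq = dict(config.frequency_rules if config.frequency_rules is not None else group.frequency_rules)
    return tol, freq


def plan_menu(
    group: TargetGroup,
    recipe_book,
    food_db,
    n_days: int,
    config: PlannerConfig,
    source: str = "DPM",
) -> Menu:
    """Plan ``n_days`` of three-course lunches for one target group.

    Raises :class:`PlanningError` after ``config.max_attempts`` candidate
    evaluations, reporting the first unsatisfiable day and the constraint
    that rejected the most candidates there.
    """
    if n_days < 1:
        raise ModelError("n_days must be >= 1")
    recipes = as_recipe_lookup(recipe_book)
    foods = as_food_lookup(food_db)
    tol, freq_rules = _effective(group, config)
    lo = group.energy_target_kcal * (1.0 - tol)
    hi = group.energy_target_kcal * (1.0 + tol)

    eligible: dict[str, list[str]] = {}
    for slot in CORE_SLOTS:
        ids = [
            r.recipe_id
            for r in recipes.values()
            if r.meal_type == slot and config.season in r.seasons
        ]
        if len(ids) < 2:
            raise PlanningError(
                f"need >= 2 in-season type-{slot} recipes, found {len(ids)}"
            )
        eligible[slot] = sorted(ids)

    totals = {
        rid: recipe_totals(recipes[rid], foods) for ids in eligible.values() for rid in ids
    }

    rng = np.random.default_rng(config.seed)

    def day_candidates(chosen: Sequence[dict[str, str]]):
        """Lazily yield candidate slot->recipe maps for day ``len(chosen)+1``.

        Candidates already respect the repeat window; the paired
        ``cat_counts`` give course-category usage over the trailing 6 days
        for the frequency check.
        """
        day_idx = len(chosen) + 1
        recent: set[str] = set()
        for past in chosen[max(0, day_idx - config.repeat_window) :]:
            recent.update(past.values())
        cat_counts: dict[str, int] = {}
        for past in chosen[max(0, day_idx - 7) :]:
            for rid in past.values():
                cat = recipes[rid].course_category
                cat_counts[cat] = cat_counts.get(cat, 0) + 1
        pools = []
        for slot in CORE_SLOTS:
            pool = [rid for rid in eligible[slot] if rid not in recent]
            rng.shuffle(pool)
            pools.append(pool)
        # branch-and-bound on the energy window: prune a partial slot
        # assignment when no completion can land inside [lo, hi]; pruned
        # combinations are recorded as energy rejections (without consuming
        # the attempt budget) so failure reports stay attributable
        def note_pruned(n: int) -> None:
            rc = reject_counts.setdefault(day_idx, {})
            rc["energy"] = rc.get("energy", 0) + n

        bounds = []
        for pool in pools:
            energies = [totals[rid]["energy_kcal"] for rid in pool]
            bounds.append((min(energies, default=0.0), max(energies, default=0.0)))
        for r1 in pools[0]:
            e1 = totals[r1]["energy_kcal"]
            if e1 + bounds[1][0] + bounds[2][0] > hi or e1 + bounds[1][1] + bounds[2][1] < lo:
                note_pruned(len(pools[1]) * len(pools[2]))
                continue
            for r2 in pools[1]:
                e2 = e1 + totals[r2]["energy_kcal"]
                if e2 + bounds[2][0] > hi or e2 + bounds[2][1] < lo:
                    note_pruned(len(pools[2]))
                    continue
                for r3 in pools[2]:
                    yield dict(zip(CORE_SLOTS, (r1, r2, r3))), cat_counts

    def feasible(combo: dict[str, str], cat_counts: dict[str, int]) -> Optional[str]:
        """Return the violated constraint name, or None when acceptable."""
        if freq_rules:
            counts = dict(cat_counts)
            for rid in combo.values():
                cat = recipes[rid].course_category
                counts[cat] = counts.get(cat, 0) + 1
                if cat in freq_rules and counts[cat] > freq_rules[cat]:
                    return "frequency"
        energy = sum(totals[rid]["energy_kcal"] for rid in combo.values())
        if not (lo <= energy <= hi):
            return "energy"
        for k, (mlo, mhi) in group.macro_targets.items():
            amount = sum(totals[rid][k] for rid in combo.values())
            if not (mlo <= amount <= mhi):
                return "macro"
        return None

    chosen: list[dict[str, str]] = []
    iterators = [day_candidates(chosen)]
    attempts = 0
    reject_counts: dict[int, dict[str, int]] = {}
    deepest_failure = 1

    def _fail(prefix: str) -> PlanningError:
        rc = reject_counts.get(deepest_failure, {})
        binding = max(rc, key=rc.get) if rc else "candidate exhaustion"
        return PlanningError(
            f"{prefix}; first unsatisfiable day {deepest_failure}, "
            f"binding constraint: {binding}"
        )

    while len(chosen) < n_days:
        day_idx = len(chosen) + 1
        advanced = False
        for combo, cat_counts in iterators[-1]:
            attempts += 1
            if attempts > config.max_attempts:
                deepest_failure = max(deepest_failure, day_idx)
                raise _fail(
                    f"no feasible plan within {config.max_attempts} attempts"
                )
            reason = feasible(combo, cat_counts)
            if reason is None:
                chosen.append(combo)
                if len(chosen) < n_days:
                    iterators.append(day_candidates(chosen))
                advanced = True
                break
            reject_counts.setdefault(day_idx, {})
            reject_counts[day_idx][reason] = reject_counts[day_idx].get(reason, 0) + 1
        if not advanced:
            deepest_failure = max(deepest_failure, day_idx)
            iterators.pop()
            if not chosen:
                raise _fail("infeasible instance")
            chosen.pop()

    days = tuple(
        MenuDay(day_index=i + 1, selections=sel) for i, sel in enumerate(chosen)
    )
    return Menu(target_group=group.group_id, source=source, days=days)


def apply_manual_override(
    menu: Menu,
    day_index: int,
    meal_type: str,
    recipe_id: str,
    group: TargetGroup,
    recipe_book,
    food_db,
    config: PlannerConfig,
) -> tuple[Menu, list[Violation]]:
    """Replace one slot selection; list (never block) violations introduced.

    Manual intervention is allowed to break constraints — the report names
    every violation present after the change that was not present before.
    """
    recipes = as_recipe_lookup(recipe_book)
    if recipe_id not in recipes:
        raise ModelError(f"unknown recipe {recipe_id!r}")
    if recipes[recipe_id].meal_type != meal_type:
        raise ModelError(
            f"recipe {recipe_id!r} is type {recipes[recipe_id].meal_type}, "
            f"not {meal_type}"
        )
    day_map = {d.day_index: d for d in menu.days}
    if day_index not in day_map:
        raise ModelError(f"menu has no day {day_index}")
    if meal_type not in day_map[day_index].selections:
        raise ModelError(f"day {day_index} has no slot {meal_type}")

    tol, freq = _effective(group, config)
    group_eff = replace(group, energy_tolerance=tol, frequency_rules=freq)
    before = set(
        map(str, validate_menu(menu, group_eff, recipe_book, food_db,
                               season=config.season,
                               repeat_window=config.repeat_window,
                               check_shape=False))
    )
    new_selections = dict(day_map[day_index].selections)
    new_selections[meal_type] = recipe_id
    new_days = tuple(
        replace(d, selections=new_selections) if d.day_index == day_index else d
        for d in menu.days
    )
    new_menu = replace(menu, days=new_days)
    after = validate_menu(new_menu, group_eff, recipe_book, food_db,
                          season=config.season,
                          repeat_window=config.repeat_window,
                          check_shape=False)
    introduced = [v for v in after if str(v) not in before]
    return new_menu, introduced


def add_fourth_course(
    menu: Menu,
    selections: Mapping[int, str],
    recipe_book,
) -> tuple[Menu, list[int]]:
    """Fill meal slot IV on a hospital menu for the given days.

    Returns the updated menu and the day indices still lacking a fourth
    course (flagged incomplete rather than failing).
    """
    if menu.target_group != "hospital":
        raise ModelError("fourth courses are reserved for hospital menus")
    recipes = as_recipe_lookup(recipe_book)
    for day_idx, rid in selections.items():
        if rid not in recipes:
            raise ModelError(f"unknown recipe {rid!r}")
        if recipes[rid].meal_type != "IV":
            raise ModelError(f"recipe {rid!r} is not a type-IV course")
    known_days = {d.day_index for d in menu.days}
    unknown = set(selections) - known_days
    if unknown:
        raise ModelError(f"menu has no days {sorted(unknown)}")
    new_days = []
    incomplete = []
    for d in menu.days:
        if d.day_index in selections:
            sel = dict(d.selections)
            sel["IV"] = selections[d.day_index]
            new_days.append(replace(d, selections=sel))
        else:
            if "IV" not in d.selections:
                incomplete.append(d.day_index)
            new_days.append(d)
    return replace(menu, days=tuple(new_days)), incomplete
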