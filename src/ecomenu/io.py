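"""File I/O: foods.csv, recipes.json, groups.yaml, refs.yaml, menu JSON.

Formats
-------
foods.csv
    One row per food, columns in the fixed order of :data:`FOOD_COLUMNS`.
    ``seasons`` is pipe-delimited; empty ``cf_kgco2e_per_kg`` /
    ``wf_m3_per_ton`` / ``price_per_kg`` cells mean "factor absent", not zero.
recipes.json
    List of ``{recipe_id, name, meal_type, course_category, seasons,
    ingredients: [{food_id, mass_g}]}``.
groups.yaml / refs.yaml
    Target-group requirement profiles and NRF/SAIN-LIM reference baskets;
    defaults ship as package data and are plain editable YAML.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .model import (
    FoodItem,
    Ingredient,
    Menu,
    MenuDay,
    ModelError,
    NutrientVector,
    Recipe,
    ReferenceValues,
    TargetGroup,
    NUTRIENT_FIELDS,
    SEASONS,
    as_food_lookup,
)

__all__ = [
    "FOOD_COLUMNS",
    "load_food_db",
    "write_food_db",
    "load_recipes",
    "write_recipes",
    "load_groups",
    "write_groups",
    "load_refs",
    "write_refs",
    "load_menu",
    "write_menu",
]

#: foods.csv column order (fixed external contract).
FOOD_COLUMNS = (
    "food_id",
    "name",
    "food_group",
    "energy_kcal",
    "protein_g",
    "fat_g",
    "satfat_g",
    "carb_g",
    "addedsugar_g",
    "fiber_g",
    "sodium_mg",
    "vita_ug",
    "vitc_mg",
    "vite_mg",
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "potassium_mg",
    "cf_kgco2e_per_kg",
    "wf_m3_per_ton",
    "price_per_kg",
    "seasons",
    "is_trace",
)

_OPTIONAL_NUMERIC = ("cf_kgco2e_per_kg", "wf_m3_per_ton", "price_per_kg")


def _parse_optional(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def load_food_db(path) -> list[FoodItem]:
    """Load a food-composition CSV into a validated list of FoodItem.

    Duplicate ids and negative numeric fields are hard errors naming the
    offending row; empty footprint/price cells become absent factors.
    """
    df = pd.read_csv(path, dtype={"food_id": str, "seasons": str, "name": str})
    missing = [c for c in FOOD_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(f"foods CSV {path}: missing columns {missing}")
    foods: list[FoodItem] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        food_id = str(row["food_id"])
        if food_id in seen:
            raise ModelError(f"foods CSV row {i}: duplicate food_id {food_id!r}")
        seen.add(food_id)
        for col in NUTRIENT_FIELDS:
            if row[col] < 0:
                raise ModelError(
                    f"foods CSV row {i} ({food_id}): negative {col} = {row[col]}"
                )
        for col in _OPTIONAL_NUMERIC:
            v = _parse_optional(row[col])
            if v is not None and v < 0:
                raise ModelError(
                    f"foods CSV row {i} ({food_id}): negative {col} = {v}"
                )
        seasons_cell = row["seasons"]
        if seasons_cell is None or (isinstance(seasons_cell, float) and pd.isna(seasons_cell)):
            seasons = frozenset(SEASONS)
        else:
            seasons = frozenset(s for s in str(seasons_cell).split("|") if s)
        try:
            foods.append(
                FoodItem(
                    food_id=food_id,
                    name=str(row["name"]),
                    food_group=str(row["food_group"]),
                    nutrients=NutrientVector(
                        **{c: float(row[c]) for c in NUTRIENT_FIELDS}
                    ),
                    cf_factor=_parse_optional(row["cf_kgco2e_per_kg"]),
                    wf_factor=_parse_optional(row["wf_m3_per_ton"]),
                    price_per_kg=_parse_optional(row["price_per_kg"]),
                    seasons=seasons,
                    is_trace=_parse_bool(row["is_trace"]),
                )
            )
        except ModelError as e:
            raise ModelError(f"foods CSV row {i} ({food_id}): {e}") from None
    return foods


def write_food_db(foods: Sequence[FoodItem], path) -> None:
    rows = []
    for f in foods:
        row = {"food_id": f.food_id, "name": f.name, "food_group": f.food_group}
        row.update({c: getattr(f.nutrients, c) for c in NUTRIENT_FIELDS})
        row["cf_kgco2e_per_kg"] = "" if f.cf_factor is None else repr(f.cf_factor)
        row["wf_m3_per_ton"] = "" if f.wf_factor is None else repr(f.wf_factor)
        row["price_per_kg"] = "" if f.price_per_kg is None else repr(f.price_per_kg)
        row["seasons"] = "|".join(s for s in SEASONS if s in f.seasons)
        row["is_trace"] = str(f.is_trace).lower()
        rows.append(row)
    # default float formatting is shortest round-trip repr: load(write(x)) == x
    pd.DataFrame(rows, columns=list(FOOD_COLUMNS)).to_csv(path, index=False)


def load_recipes(path, food_db) -> list[Recipe]:
    """Load recipes.json and check referential integrity against ``food_db``."""
    foods = as_food_lookup(food_db)
    with open(path) as fh:
        raw = json.load(fh)
    recipes: list[Recipe] = []
    for entry in raw:
        rid = entry["recipe_id"]
        ingredients = []
        for ing in entry["ingredients"]:
            if ing["food_id"] not in foods:
                raise ModelError(
                    f"recipe {rid!r}: unknown food_id {ing['food_id']!r}"
                )
            try:
                ingredients.append(
                    Ingredient(food_id=ing["food_id"], mass_g=float(ing["mass_g"]))
                )
            except ModelError as e:
                raise ModelError(f"recipe {rid!r}: {e}") from None
        recipes.append(
            Recipe(
                recipe_id=rid,
                name=entry["name"],
                meal_type=entry["meal_type"],
                course_category=entry["course_category"],
                ingredients=tuple(ingredients),
                seasons=frozenset(entry.get("seasons") or SEASONS),
            )
        )
    return recipes


def write_recipes(recipes: Sequence[Recipe], path) -> None:
    payload = [
        {
            "recipe_id": r.recipe_id,
            "name": r.name,
            "meal_type": r.meal_type,
            "course_category": r.course_category,
            "seasons": sorted(r.seasons),
            "ingredients": [
                {"food_id": ing.food_id, "mass_g": ing.mass_g}
                for ing in r.ingredients
            ],
        }
        for r in recipes
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def _group_from_dict(group_id: str, cfg: dict) -> TargetGroup:
    macro = {
        k: (float(v[0]), float(v[1]))
        for k, v in (cfg.get("macro_targets") or {}).items()
    }
    return TargetGroup(
        group_id=group_id,
        energy_target_kcal=float(cfg["energy_target_kcal"]),
        energy_tolerance=float(cfg.get("energy_tolerance", 0.10)),
        macro_targets=macro,
        n_meal_slots=int(cfg.get("n_meal_slots", 3)),
        frequency_rules=dict(cfg.get("frequency_rules") or {}),
    )


def load_groups(path=None) -> dict[str, TargetGroup]:
    """Load target-group profiles from YAML (package default when path=None)."""
    if path is None:
        text = resources.files("ecomenu.data").joinpath("groups.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {gid: _group_from_dict(gid, cfg) for gid, cfg in raw.items()}


def write_groups(groups: dict[str, TargetGroup], path) -> None:
    payload = {
        g.group_id: {
            "energy_target_kcal": g.energy_target_kcal,
            "energy_tolerance": g.energy_tolerance,
            "macro_targets": {k: list(v) for k, v in g.macro_targets.items()},
            "n_meal_slots": g.n_meal_slots,
            "frequency_rules": dict(g.frequency_rules),
        }
        for g in groups.values()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_refs(path=None) -> ReferenceValues:
    """Load NRF/SAIN-LIM reference baskets (package default when path=None)."""
    if path is None:
        text = resources.files("ecomenu.data").joinpath("refs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return ReferenceValues(
        nrf_dv={k: float(v) for k, v in raw["nrf_dv"].items()},
        nrf_mrv={k: float(v) for k, v in raw["nrf_mrv"].items()},
        sain_rv={k: float(v) for k, v in raw["sain_rv"].items()},
        lim_mrv={k: float(v) for k, v in raw["lim_mrv"].items()},
        energy_basis=float(raw.get("energy_basis", 100.0)),
        mass_basis=float(raw.get("mass_basis", 100.0)),
    )


def write_refs(refs: ReferenceValues, path) -> None:
    payload = {
        "nrf_dv": dict(refs.nrf_dv),
        "nrf_mrv": dict(refs.nrf_mrv),
        "sain_rv": dict(refs.sain_rv),
        "lim_mrv": dict(refs.lim_mrv),
        "energy_basis": refs.energy_basis,
        "mass_basis": refs.mass_basis,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_menu(path) -> Menu:
    with open(path) as fh:
        raw = json.load(fh)
    return Menu(
        target_group=raw["target_group"],
        source=raw["source"],
        days=tuple(
            MenuDay(day_index=int(d["day_index"]), selections=dict(d["selections"]))
            for d in raw["days"]
        ),
    )


def write_menu(menu: Menu, path) -> None:
    payload = {
        "target_group": menu.target_group,
        "source": menu.source,
        "days": [
            {"day_index": d.day_index, "selections": dict(d.selections)}
            for d in menu.days
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
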