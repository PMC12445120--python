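"""Seeded synthetic study fixtures.

Generates a Turkish-style institutional food database (ten food groups),
a recipe book across meal types I-IV, and the full study design of five
target groups × three menu sources × one month, so every other module is
testable without any external data.

The generated world states, not tunes, its conditions: animal foods carry
higher carbon-footprint factors than plant foods by construction; DPM menus
come from the constraint planner; NMPG and IAM menus are perturbed
resamples — each day's selections are redrawn (seeded, with replacement)
from the DPM menu's per-slot choices and served from recipe variants whose
animal-ingredient masses are multiplied by a per-source
``animal_share_shift`` (defaults 1.00 / 0.85 / 0.67 for DPM / NMPG / IAM,
the red-meat grams ratio across the three sources in the study design this
emulates).  Everything is deterministic under a fixed seed.  Because the
DPM menu is a *designed* balanced selection rather than an i.i.d. sample,
fixture-level rank tests under equal shifts are conservative (they reject
well below nominal); see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import load_groups
from .model import (
    ANIMAL_GROUPS,
    FOOD_GROUPS,
    SEASONS,
    FoodItem,
    Ingredient,
    Menu,
    MenuDay,
    ModelError,
    NutrientVector,
    Recipe,
    TargetGroup,
    index_foods,
    index_recipes,
    recipe_totals,
    scale_recipe,
)
from .planner import PlannerConfig, add_fourth_course, plan_menu

__all__ = [
    "SynthConfig",
    "StudyFixture",
    "generate_food_db",
    "generate_recipe_book",
    "generate_study_fixture",
]

# Per-100 g nutrient templates (mean, sd) per food group.  Order-of-magnitude
# realistic for cooked institutional fare; they are config data, not claims
# about any national composition table.
NUTRIENT_TEMPLATES: dict[str, dict[str, tuple[float, float]]] = {
    "red_meat": {
        "energy_kcal": (250, 30), "protein_g": (26, 2), "fat_g": (17, 3),
        "satfat_g": (7, 1), "carb_g": (0, 0), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (72, 15), "vita_ug": (10, 4),
        "vitc_mg": (0, 0), "vite_mg": (0.4, 0.1), "calcium_mg": (15, 4),
        "iron_mg": (2.6, 0.4), "magnesium_mg": (21, 3), "potassium_mg": (330, 40),
    },
    "poultry": {
        "energy_kcal": (190, 20), "protein_g": (27, 2), "fat_g": (8, 2),
        "satfat_g": (2.3, 0.5), "carb_g": (0, 0), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (85, 15), "vita_ug": (15, 6),
        "vitc_mg": (0, 0), "vite_mg": (0.3, 0.1), "calcium_mg": (14, 4),
        "iron_mg": (1.1, 0.2), "magnesium_mg": (25, 4), "potassium_mg": (250, 30),
    },
    "fish": {
        "energy_kcal": (150, 25), "protein_g": (22, 2), "fat_g": (6, 2),
        "satfat_g": (1.4, 0.4), "carb_g": (0, 0), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (75, 20), "vita_ug": (25, 10),
        "vitc_mg": (0, 0), "vite_mg": (1.0, 0.3), "calcium_mg": (20, 8),
        "iron_mg": (0.9, 0.3), "magnesium_mg": (30, 6), "potassium_mg": (380, 50),
    },
    "dairy": {
        "energy_kcal": (80, 15), "protein_g": (4.0, 0.8), "fat_g": (4.5, 1.2),
        "satfat_g": (2.8, 0.7), "carb_g": (5.0, 1.0), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (55, 15), "vita_ug": (45, 10),
        "vitc_mg": (1.0, 0.5), "vite_mg": (0.1, 0.05), "calcium_mg": (120, 20),
        "iron_mg": (0.1, 0.03), "magnesium_mg": (11, 2), "potassium_mg": (150, 20),
    },
    "egg": {
        "energy_kcal": (143, 10), "protein_g": (12.5, 1.0), "fat_g": (10, 1.0),
        "satfat_g": (3.2, 0.4), "carb_g": (1.0, 0.3), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (140, 20), "vita_ug": (160, 25),
        "vitc_mg": (0, 0), "vite_mg": (1.1, 0.2), "calcium_mg": (55, 8),
        "iron_mg": (1.8, 0.3), "magnesium_mg": (12, 2), "potassium_mg": (135, 15),
    },
    "legume": {
        "energy_kcal": (330, 25), "protein_g": (22, 2), "fat_g": (1.8, 0.5),
        "satfat_g": (0.3, 0.1), "carb_g": (55, 4), "addedsugar_g": (0, 0),
        "fiber_g": (16, 3), "sodium_mg": (12, 5), "vita_ug": (3, 1.5),
        "vitc_mg": (3, 1.5), "vite_mg": (0.5, 0.2), "calcium_mg": (100, 25),
        "iron_mg": (6.0, 1.0), "magnesium_mg": (140, 25), "potassium_mg": (1100, 150),
    },
    "cereal": {
        "energy_kcal": (350, 20), "protein_g": (11, 1.5), "fat_g": (2.0, 0.6),
        "satfat_g": (0.4, 0.1), "carb_g": (72, 4), "addedsugar_g": (0.5, 0.3),
        "fiber_g": (8, 2.5), "sodium_mg": (5, 2.5), "vita_ug": (0, 0),
        "vitc_mg": (0, 0), "vite_mg": (0.6, 0.2), "calcium_mg": (30, 8),
        "iron_mg": (3.5, 0.7), "magnesium_mg": (120, 20), "potassium_mg": (360, 50),
    },
    "vegetable_fruit": {
        "energy_kcal": (45, 12), "protein_g": (1.5, 0.5), "fat_g": (0.3, 0.1),
        "satfat_g": (0.05, 0.02), "carb_g": (9, 2.5), "addedsugar_g": (0, 0),
        "fiber_g": (2.5, 0.8), "sodium_mg": (15, 8), "vita_ug": (80, 40),
        "vitc_mg": (30, 12), "vite_mg": (0.8, 0.3), "calcium_mg": (30, 10),
        "iron_mg": (0.6, 0.2), "magnesium_mg": (15, 5), "potassium_mg": (260, 60),
    },
    "oil": {
        "energy_kcal": (884, 5), "protein_g": (0, 0), "fat_g": (100, 0),
        "satfat_g": (14, 3), "carb_g": (0, 0), "addedsugar_g": (0, 0),
        "fiber_g": (0, 0), "sodium_mg": (1, 0.5), "vita_ug": (0, 0),
        "vitc_mg": (0, 0), "vite_mg": (14, 4), "calcium_mg": (1, 0.5),
        "iron_mg": (0.1, 0.05), "magnesium_mg": (0.5, 0.2), "potassium_mg": (1, 0.5),
    },
    "nut": {
        "energy_kcal": (600, 30), "protein_g": (18, 2.5), "fat_g": (54, 4),
        "satfat_g": (6, 1.2), "carb_g": (18, 3), "addedsugar_g": (0, 0),
        "fiber_g": (8, 2), "sodium_mg": (5, 2.5), "vita_ug": (2, 1),
        "vitc_mg": (1, 0.5), "vite_mg": (15, 6), "calcium_mg": (120, 40),
        "iron_mg": (3.5, 1.0), "magnesium_mg": (230, 40), "potassium_mg": (650, 100),
    },
}

# (cf low, cf high) kg CO2e/kg, (wf low, wf high) m3/ton, (price low, high)
# currency units/kg.  Ruminant meat sits strictly above vegetables on carbon
# by construction, matching the animal > plant emission ordering.
FACTOR_RANGES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "red_meat": ((20.0, 30.0), (12000.0, 16000.0), (8.0, 12.0)),
    "poultry": ((5.0, 8.0), (3800.0, 4600.0), (4.0, 6.0)),
    "fish": ((4.0, 7.0), (2000.0, 3500.0), (6.0, 10.0)),
    "dairy": ((1.5, 3.5), (900.0, 1300.0), (1.5, 3.0)),
    "egg": ((3.5, 5.0), (3000.0, 3600.0), (3.0, 5.0)),
    "legume": ((0.8, 2.0), (3000.0, 5000.0), (2.0, 4.0)),
    "cereal": ((0.8, 1.6), (1300.0, 1900.0), (1.0, 2.5)),
    "vegetable_fruit": ((0.3, 2.0), (200.0, 900.0), (0.8, 2.5)),
    "oil": ((3.0, 6.0), (4000.0, 8000.0), (4.0, 8.0)),
    "nut": ((1.5, 3.0), (8000.0, 10000.0), (10.0, 16.0)),
}

#: Energy share of the lunch target carried by each core course.
MEAL_ENERGY_SHARES = {"I": 0.45, "II": 0.35, "III": 0.20}
#: Absolute energy target (kcal) for the extra hospital course.
FOURTH_COURSE_KCAL = 100.0


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic world (defaults are the stated conditions)."""

    seed: int = 0
    n_foods_per_group: int = 6
    n_trace_foods: int = 3
    n_recipes_per_type: int = 12
    n_days: int = 30
    season: str = "autumn"
    reference_energy_kcal: float = 700.0
    energy_noise_sd: float = 0.06
    animal_share_shift: Mapping[str, float] = field(
        default_factory=lambda: {"DPM": 1.00, "NMPG": 0.85, "IAM": 0.67}
    )
    nutrient_templates: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: NUTRIENT_TEMPLATES
    )
    factor_ranges: Mapping[str, tuple] = field(default_factory=lambda: FACTOR_RANGES)

    def __post_init__(self) -> None:
        for grp, (cf, wf, price) in self.factor_ranges.items():
            for lo, hi in (cf, wf, price):
                if lo > hi or lo < 0:
                    raise ModelError(f"invalid factor range for {grp}: ({lo}, {hi})")
        for grp, tpl in self.nutrient_templates.items():
            for name, (mean, sd) in tpl.items():
                if sd < 0:
                    raise ModelError(f"negative sd for {grp}.{name}")
        if self.n_foods_per_group < 1 or self.n_recipes_per_type < 2:
            raise ModelError("need >= 1 food per group and >= 2 recipes per type")


def _sample_nutrients(rng: np.random.Generator, template) -> NutrientVector:
    """Draw a per-100 g profile from the template, truncated into validity."""
    vals = {}
    for name, (mean, sd) in template.items():
        vals[name] = max(0.0, float(rng.normal(mean, sd))) if sd > 0 else float(mean)
    macro = vals["protein_g"] + vals["fat_g"] + vals["carb_g"]
    if macro > 100.0:
        shrink = 100.0 / macro
        for k in ("protein_g", "fat_g", "carb_g"):
            vals[k] *= shrink
    vals["satfat_g"] = min(vals["satfat_g"], vals["fat_g"])
    vals["addedsugar_g"] = min(vals["addedsugar_g"], vals["carb_g"])
    return NutrientVector(**vals)


def generate_food_db(config: SynthConfig) -> list[FoodItem]:
    """Generate the ten-group food table plus sugar and trace spice items."""
    rng = np.random.default_rng([config.seed, 0xF00D])
    foods: list[FoodItem] = []
    for grp in FOOD_GROUPS:
        tpl = config.nutrient_templates[grp]
        (cf_lo, cf_hi), (wf_lo, wf_hi), (p_lo, p_hi) = config.factor_ranges[grp]
        for i in range(config.n_foods_per_group):
            foods.append(
                FoodItem(
                    food_id=f"{grp}_{i:02d}",
                    name=f"synthetic {grp.replace('_', ' ')} {i + 1}",
                    food_group=grp,
                    nutrients=_sample_nutrients(rng, tpl),
                    cf_factor=float(rng.uniform(cf_lo, cf_hi)),
                    wf_factor=float(rng.uniform(wf_lo, wf_hi)),
                    price_per_kg=float(rng.uniform(p_lo, p_hi)),
                    seasons=frozenset(SEASONS),
                )
            )
    # refined sugar: pure added carbohydrate for dessert recipes
    foods.append(
        FoodItem(
            food_id="sugar",
            name="granulated sugar (synthetic)",
            food_group="cereal",
            nutrients=NutrientVector(energy_kcal=400.0, carb_g=100.0, addedsugar_g=100.0),
            cf_factor=float(rng.uniform(0.5, 1.5)),
            wf_factor=float(rng.uniform(1500.0, 2000.0)),
            price_per_kg=float(rng.uniform(0.8, 1.5)),
            seasons=frozenset(SEASONS),
        )
    )
    # trace spices: priced but without footprint factors, excluded from sums
    for i in range(config.n_trace_foods):
        foods.append(
            FoodItem(
                food_id=f"spice_{i:02d}",
                name=f"synthetic spice {i + 1}",
                food_group="vegetable_fruit",
                nutrients=NutrientVector(
                    energy_kcal=250.0, protein_g=10.0, fat_g=5.0, satfat_g=1.0,
                    carb_g=50.0, fiber_g=25.0, sodium_mg=30.0, iron_mg=20.0,
                    calcium_mg=800.0, magnesium_mg=200.0, potassium_mg=1000.0,
                ),
                cf_factor=None,
                wf_factor=None,
                price_per_kg=float(rng.uniform(10.0, 40.0)),
                seasons=frozenset(SEASONS),
                is_trace=True,
            )
        )
    return foods


# recipe archetypes: (meal_type, course_category, [(ingredient role, grams)])
_ARCHETYPES: list[tuple[str, str, list[tuple[str, float]]]] = [
    ("I", "main-meat", [("red_meat", 110), ("vegetable_fruit", 90), ("oil", 10), ("spice", 1.5)]),
    ("I", "main-poultry", [("poultry", 130), ("vegetable_fruit", 80), ("oil", 10), ("spice", 1.5)]),
    ("I", "main-fish", [("fish", 140), ("vegetable_fruit", 70), ("oil", 10), ("spice", 1.5)]),
    ("I", "main-legume", [("legume", 70), ("red_meat", 40), ("vegetable_fruit", 60), ("oil", 8), ("spice", 1.5)]),
    ("II", "soup", [("legume", 30), ("vegetable_fruit", 70), ("oil", 8), ("spice", 1.0)]),
    ("II", "pilaf/pasta", [("cereal", 70), ("oil", 10), ("spice", 1.0)]),
    ("II", "pastry", [("cereal", 60), ("dairy", 40), ("egg", 15), ("oil", 8)]),
    ("III", "salad", [("vegetable_fruit", 150), ("oil", 6), ("nut", 5)]),
    ("III", "dessert-milk", [("dairy", 150), ("sugar", 20), ("cereal", 15)]),
    ("III", "dessert-syrup", [("cereal", 55), ("sugar", 40), ("oil", 12), ("nut", 8)]),
    ("III", "fruit", [("vegetable_fruit", 170)]),
    ("IV", "side-fruit", [("vegetable_fruit", 150)]),
    ("IV", "side-yogurt", [("dairy", 180)]),
]


def generate_recipe_book(config: SynthConfig, food_db: Sequence[FoodItem]) -> list[Recipe]:
    """Generate recipes per meal type from course archetypes.

    Ingredient foods are drawn from the matching group; masses are then
    rescaled so the portion energy lands on the course's share of the
    reference lunch energy, times multiplicative noise
    (``energy_noise_sd``).  Type-I mains always carry an animal or legume
    protein base.
    """
    foods = index_foods(food_db)
    by_group: dict[str, list[str]] = {}
    for f in food_db:
        if f.is_trace or f.food_id == "sugar":
            continue
        by_group.setdefault(f.food_group, []).append(f.food_id)
    for grp in FOOD_GROUPS:
        if grp not in by_group:
            raise ModelError(f"food_db lacks group {grp!r}")
    spices = sorted(f.food_id for f in food_db if f.is_trace)

    rng = np.random.default_rng([config.seed, 0xEC1BE])
    recipes: list[Recipe] = []
    counter = 0
    for meal_type in ("I", "II", "III", "IV"):
        archetypes = [a for a in _ARCHETYPES if a[0] == meal_type]
        n = config.n_recipes_per_type
        n_out_of_season = 0
        for k in range(n):
            _, category, roles = archetypes[k % len(archetypes)]
            ingredients = []
            for role, grams in roles:
                if role == "spice":
                    if not spices:
                        continue
                    fid = spices[int(rng.integers(len(spices)))]
                elif role == "sugar":
                    fid = "sugar"
                else:
                    pool = by_group[role]
                    fid = pool[int(rng.integers(len(pool)))]
                jitter = float(rng.uniform(0.85, 1.15))
                ingredients.append(Ingredient(food_id=fid, mass_g=grams * jitter))
            if meal_type == "IV":
                target = FOURTH_COURSE_KCAL
            else:
                target = MEAL_ENERGY_SHARES[meal_type] * config.reference_energy_kcal
            target *= float(
                np.clip(rng.normal(1.0, config.energy_noise_sd), 0.8, 1.2)
            )
            draft = Recipe(
                recipe_id=f"R{counter:03d}",
                name=f"synthetic {category} {k + 1}",
                meal_type=meal_type,
                course_category=category,
                ingredients=tuple(ingredients),
            )
            energy = recipe_totals(draft, foods)["energy_kcal"]
            recipe = scale_recipe(draft, target / energy)
            # most recipes run all year; at most two per meal type are out
            # of season (exercises the season filter without starving the
            # planner's variety window, which needs >= repeat_window
            # in-season recipes per slot)
            if rng.uniform() < 0.15 and k >= 2 and n_out_of_season < 2:
                seasons = frozenset(s for s in SEASONS if s != config.season)
                recipe = replace(recipe, seasons=seasons)
                n_out_of_season += 1
            recipes.append(recipe)
            counter += 1
    return recipes


@dataclass(frozen=True)
class StudyFixture:
    """The full emulated study: 15 menus over a shared variant recipe book."""

    food_db: list[FoodItem]
    base_recipes: list[Recipe]
    recipe_book: list[Recipe]  # group x source portion/shift variants
    menus: list[Menu]
    groups: dict[str, TargetGroup]


def _variant_book(
    base: Sequence[Recipe],
    foods: Mapping[str, FoodItem],
    group: TargetGroup,
    source: str,
    portion_factor: float,
    shift: float,
) -> list[Recipe]:
    """Group-portioned, source-shifted recipe variants.

    Animal-ingredient masses are multiplied by ``shift``; plant ingredients
    are untouched.  A shift below 1 emulates a source serving smaller
    animal-protein portions.
    """
    out = []
    for r in base:
        scaled = scale_recipe(r, portion_factor)
        shifted = replace(
            scaled,
            ingredients=tuple(
                replace(ing, mass_g=ing.mass_g * shift)
                if foods[ing.food_id].food_group in ANIMAL_GROUPS
                else ing
                for ing in scaled.ingredients
            ),
        )
        out.append(
            replace(shifted, recipe_id=f"{r.recipe_id}@{group.group_id}@{source}")
        )
    return out


def generate_study_fixture(
    config: SynthConfig,
    groups: Mapping[str, TargetGroup] | None = None,
    sources: Sequence[str] = ("DPM", "NMPG", "IAM"),
) -> StudyFixture:
    """Emulate the 5-group × 3-source one-month design (15 menus).

    DPM menus are planned under the group constraints; NMPG and IAM menus
    resample the DPM selections day by day (with replacement, seeded) and
    serve them from that source's mass-shifted recipe variants.  Hospital
    menus additionally receive a fourth course on every day.
    """
    if groups is None:
        groups = load_groups()
    food_db = generate_food_db(config)
    foods = index_foods(food_db)
    base = generate_recipe_book(config, food_db)

    all_variants: list[Recipe] = []
    menus: list[Menu] = []
    for gi, gid in enumerate(sorted(groups)):
        group = groups[gid]
        portion_factor = group.energy_target_kcal / config.reference_energy_kcal
        books = {}
        for source in sources:
            shift = float(config.animal_share_shift.get(source, 1.0))
            book = _variant_book(base, foods, group, source, portion_factor, shift)
            books[source] = index_recipes(book)
            all_variants.extend(book)

        plan_cfg = PlannerConfig(
            seed=int((config.seed * 1000 + gi) % 2**31), season=config.season
        )
        dpm = plan_menu(
            group, books["DPM"], foods, config.n_days, plan_cfg, source="DPM"
        )
        rng = np.random.default_rng([config.seed, 0x3E5A, gi])
        per_source_menus = {"DPM": dpm}
        for source in sources:
            if source == "DPM":
                continue
            days = []
            for day in dpm.days:
                selections = {}
                for slot in sorted(day.selections):
                    pool = [d.selections[slot] for d in dpm.days]
                    pick = pool[int(rng.integers(len(pool)))]
                    base_id = pick.split("@")[0]
                    selections[slot] = f"{base_id}@{group.group_id}@{source}"
                days.append(MenuDay(day_index=day.day_index, selections=selections))
            per_source_menus[source] = Menu(
                target_group=gid, source=source, days=tuple(days)
            )

        if gid == "hospital":
            for source in sources:
                book = books[source]
                fourth = sorted(
                    rid for rid, r in book.items() if r.meal_type == "IV"
                )
                menu = per_source_menus[source]
                selections = {
                    d.day_index: fourth[int(rng.integers(len(fourth)))]
                    for d in menu.days
                }
                per_source_menus[source], _ = add_fourth_course(
                    menu, selections, book
                )

        menus.extend(per_source_menus[s] for s in sources)

    return StudyFixture(
        food_db=food_db,
        base_recipes=base,
        recipe_book=all_variants,
        menus=menus,
        groups=dict(groups),
    )
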