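"""Domain types for institutional menu planning and sustainability scoring.

The model follows food-composition-table conventions: nutrients are stored
per 100 g edible portion and per-portion amounts are derived as
``mass_g / 100 × value``.  Carbon footprint factors are kg CO2e per kg
product, water footprint factors m³ per ton product, prices currency units
per kg.  Missing footprint factors are *absent* (``None``), never zero, so
downstream accounting can report coverage instead of silently diluting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "FOOD_GROUPS",
    "ANIMAL_GROUPS",
    "MEAL_TYPES",
    "SEASONS",
    "SOURCES",
    "GROUP_IDS",
    "NUTRIENT_FIELDS",
    "NRF_QUALIFYING",
    "NRF_DISQUALIFYING",
    "SAIN_NUTRIENTS",
    "LIM_NUTRIENTS",
    "NutrientVector",
    "FoodItem",
    "Ingredient",
    "Recipe",
    "TargetGroup",
    "MenuDay",
    "Menu",
    "ReferenceValues",
    "ModelError",
    "index_foods",
    "index_recipes",
    "as_food_lookup",
    "as_recipe_lookup",
    "scale_recipe",
    "recipe_totals",
    "recipe_mass",
    "validate_menu_shape",
]

#: The ten food groups of a Turkish-style institutional food database.
FOOD_GROUPS = (
    "red_meat",
    "poultry",
    "fish",
    "dairy",
    "egg",
    "legume",
    "cereal",
    "vegetable_fruit",
    "oil",
    "nut",
)

#: Animal-based groups (used by the synthetic generator's animal-share shift).
ANIMAL_GROUPS = frozenset({"red_meat", "poultry", "fish", "dairy", "egg"})

#: Institutional lunch courses: I main dish, II soup/cereal/olive-oil dish,
#: III salad/dessert/fruit, IV extra hospital course.
MEAL_TYPES = ("I", "II", "III", "IV")

SEASONS = ("spring", "summer", "autumn", "winter")

#: Menu sources: digitally planned menus, national menu-planning-guide sample
#: menus, internet-accessible catering menus.
SOURCES = ("DPM", "NMPG", "IAM")

GROUP_IDS = ("preschool", "hospital", "nursing_home", "prison", "workplace")

#: Per-100 g nutrient fields, in food-composition CSV column order.
NUTRIENT_FIELDS = (
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
)

#: NRF 9.3 qualifying basket (9 nutrients, scored against daily values).
NRF_QUALIFYING = (
    "protein_g",
    "fiber_g",
    "vita_ug",
    "vitc_mg",
    "vite_mg",
    "calcium_mg",
    "iron_mg",
    "magnesium_mg",
    "potassium_mg",
)

#: NRF 9.3 / LIM disqualifying basket (3 restricted nutrients).
NRF_DISQUALIFYING = ("satfat_g", "addedsugar_g", "sodium_mg")

#: SAIN basic 5-nutrient basket.
SAIN_NUTRIENTS = ("protein_g", "fiber_g", "vitc_mg", "calcium_mg", "iron_mg")

LIM_NUTRIENTS = NRF_DISQUALIFYING

_EPS = 1e-9


class ModelError(ValueError):
    """Raised when domain invariants or referential integrity are violated."""


@dataclass(frozen=True)
class NutrientVector:
    """Nutrient content per 100 g edible portion."""

    energy_kcal: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0
    satfat_g: float = 0.0
    carb_g: float = 0.0
    addedsugar_g: float = 0.0
    fiber_g: float = 0.0
    sodium_mg: float = 0.0
    vita_ug: float = 0.0
    vitc_mg: float = 0.0
    vite_mg: float = 0.0
    calcium_mg: float = 0.0
    iron_mg: float = 0.0
    magnesium_mg: float = 0.0
    potassium_mg: float = 0.0

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ModelError(f"nutrient {name} must be >= 0, got {v!r}")
        if self.protein_g + self.fat_g + self.carb_g > 100.0 + _EPS:
            raise ModelError(
                "protein + fat + carbohydrate exceed 100 g per 100 g "
                f"({self.protein_g} + {self.fat_g} + {self.carb_g})"
            )
        if self.satfat_g > self.fat_g + _EPS:
            raise ModelError("saturated fat exceeds total fat")
        if self.addedsugar_g > self.carb_g + _EPS:
            raise ModelError("added sugar exceeds total carbohydrate")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in NUTRIENT_FIELDS}


@dataclass(frozen=True)
class FoodItem:
    """One food: per-100 g nutrients, footprint factors, price, seasons.

    ``cf_factor`` (kg CO2e/kg) and ``wf_factor`` (m³/ton) are optional;
    trace foods (spices, flavourings) typically lack them and are excluded
    from footprint sums.  ``price_per_kg`` may be absent, but costing treats
    an unpriced ingredient as a hard error.
    """

    food_id: str
    name: str
    food_group: str
    nutrients: NutrientVector
    cf_factor: Optional[float] = None
    wf_factor: Optional[float] = None
    price_per_kg: Optional[float] = None
    seasons: frozenset[str] = frozenset(SEASONS)
    is_trace: bool = False

    def __post_init__(self) -> None:
        if self.food_group not in FOOD_GROUPS:
            raise ModelError(
                f"food {self.food_id!r}: unknown food_group {self.food_group!r}"
            )
        for label, v in (
            ("cf_factor", self.cf_factor),
            ("wf_factor", self.wf_factor),
            ("price_per_kg", self.price_per_kg),
        ):
            if v is not None and not (v >= 0.0):
                raise ModelError(f"food {self.food_id!r}: {label} must be >= 0")
        bad = set(self.seasons) - set(SEASONS)
        if bad:
            raise ModelError(f"food {self.food_id!r}: unknown seasons {sorted(bad)}")
        object.__setattr__(self, "seasons", frozenset(self.seasons))


@dataclass(frozen=True)
class Ingredient:
    """A food mass (g) per single portion of a recipe."""

    food_id: str
    mass_g: float

    def __post_init__(self) -> None:
        if not (self.mass_g > 0.0):
            raise ModelError(
                f"ingredient {self.food_id!r}: mass must be > 0, got {self.mass_g!r}"
            )


@dataclass(frozen=True)
class Recipe:
    recipe_id: str
    name: str
    meal_type: str
    course_category: str
    ingredients: tuple[Ingredient, ...]
    seasons: frozenset[str] = frozenset(SEASONS)

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ModelError(
                f"recipe {self.recipe_id!r}: meal_type must be one of {MEAL_TYPES}"
            )
        if not self.ingredients:
            raise ModelError(f"recipe {self.recipe_id!r}: needs >= 1 ingredient")
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        object.__setattr__(self, "seasons", frozenset(self.seasons))


@dataclass(frozen=True)
class TargetGroup:
    """Requirement profile for one served population.

    ``energy_target_kcal`` is the per-lunch energy target; a day's three (or
    four) courses must sum to within ``energy_tolerance`` of it.
    ``macro_targets`` maps protein_g/fat_g/carb_g to (low, high) gram ranges.
    ``frequency_rules`` caps how often a course category may appear in any
    7-day window.
    """

    group_id: str
    energy_target_kcal: float
    energy_tolerance: float = 0.10
    macro_targets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_meal_slots: int = 3
    frequency_rules: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_id not in GROUP_IDS:
            raise ModelError(f"unknown target group {self.group_id!r}")
        if not (0.0 < self.energy_tolerance < 1.0):
            raise ModelError("energy_tolerance must lie in (0, 1)")
        if self.n_meal_slots not in (3, 4):
            raise ModelError("n_meal_slots must be 3 or 4")
        if self.n_meal_slots == 4 and self.group_id != "hospital":
            raise ModelError("four meal slots are reserved for hospital menus")

    @property
    def required_meal_types(self) -> tuple[str, ...]:
        return MEAL_TYPES[: self.n_meal_slots]


@dataclass(frozen=True)
class MenuDay:
    day_index: int
    selections: Mapping[str, str]  # meal_type -> recipe_id

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ModelError("day_index must be >= 1")
        object.__setattr__(self, "selections", dict(self.selections))


@dataclass(frozen=True)
class Menu:
    """One target group × one source × about a month of daily selections."""

    target_group: str
    source: str
    days: tuple[MenuDay, ...]

    def __post_init__(self) -> None:
        if self.target_group not in GROUP_IDS:
            raise ModelError(f"unknown target group {self.target_group!r}")
        if self.source not in SOURCES:
            raise ModelError(f"unknown menu source {self.source!r}")
        object.__setattr__(self, "days", tuple(self.days))


@dataclass(frozen=True)
class ReferenceValues:
    """Reference baskets for NRF 9.3 and SAIN-LIM.

    ``nrf_dv``: daily values for the 9 qualifying nutrients; ``nrf_mrv``:
    maximal recommended values for the 3 disqualifying nutrients;
    ``sain_rv``: recommended values for the 5 SAIN nutrients; ``lim_mrv``:
    maximal values for the 3 LIM nutrients.  ``energy_basis`` (kcal) and
    ``mass_basis`` (g) fix the per-100 kcal / per-100 g score bases.
    """

    nrf_dv: Mapping[str, float]
    nrf_mrv: Mapping[str, float]
    sain_rv: Mapping[str, float]
    lim_mrv: Mapping[str, float]
    energy_basis: float = 100.0
    mass_basis: float = 100.0

    def __post_init__(self) -> None:
        for label, basket, expected in (
            ("nrf_dv", self.nrf_dv, set(NRF_QUALIFYING)),
            ("nrf_mrv", self.nrf_mrv, set(NRF_DISQUALIFYING)),
            ("sain_rv", self.sain_rv, set(SAIN_NUTRIENTS)),
            ("lim_mrv", self.lim_mrv, set(LIM_NUTRIENTS)),
        ):
            if set(basket) != expected:
                raise ModelError(
                    f"{label} basket must contain exactly {sorted(expected)}, "
                    f"got {sorted(basket)}"
                )
            for k, v in basket.items():
                if not (v > 0.0):
                    raise ModelError(f"{label}[{k}] must be > 0")
        if not (self.energy_basis > 0.0 and self.mass_basis > 0.0):
            raise ModelError("energy_basis and mass_basis must be > 0")
        object.__setattr__(self, "nrf_dv", dict(self.nrf_dv))
        object.__setattr__(self, "nrf_mrv", dict(self.nrf_mrv))
        object.__setattr__(self, "sain_rv", dict(self.sain_rv))
        object.__setattr__(self, "lim_mrv", dict(self.lim_mrv))


# ---------------------------------------------------------------------------
# lookups and small structural operations


def index_foods(foods: Sequence[FoodItem]) -> dict[str, FoodItem]:
    """Index foods by id, rejecting duplicates."""
    out: dict[str, FoodItem] = {}
    for f in foods:
        if f.food_id in out:
            raise ModelError(f"duplicate food_id {f.food_id!r}")
        out[f.food_id] = f
    return out


def index_recipes(recipes: Sequence[Recipe]) -> dict[str, Recipe]:
    out: dict[str, Recipe] = {}
    for r in recipes:
        if r.recipe_id in out:
            raise ModelError(f"duplicate recipe_id {r.recipe_id!r}")
        out[r.recipe_id] = r
    return out


def as_food_lookup(food_db) -> Mapping[str, FoodItem]:
    """Accept either a list of FoodItem or an id->FoodItem mapping."""
    if isinstance(food_db, Mapping):
        return food_db
    return index_foods(food_db)


def as_recipe_lookup(recipe_book) -> Mapping[str, Recipe]:
    if isinstance(recipe_book, Mapping):
        return recipe_book
    return index_recipes(recipe_book)


def scale_recipe(recipe: Recipe, factor: float) -> Recipe:
    """Scale every ingredient mass by ``factor`` (> 0); identity at 1."""
    if not (factor > 0.0):
        raise ModelError(f"scale factor must be > 0, got {factor!r}")
    if factor == 1.0:
        return recipe
    return replace(
        recipe,
        ingredients=tuple(
            replace(ing, mass_g=ing.mass_g * factor) for ing in recipe.ingredients
        ),
    )


def recipe_totals(recipe: Recipe, food_db) -> dict[str, float]:
    """Per-portion nutrient totals: sum over ingredients of mass/100 × per-100 g."""
    foods = as_food_lookup(food_db)
    totals = dict.fromkeys(NUTRIENT_FIELDS, 0.0)
    for ing in recipe.ingredients:
        try:
            food = foods[ing.food_id]
        except KeyError:
            raise ModelError(
                f"recipe {recipe.recipe_id!r}: unknown food_id {ing.food_id!r}"
            ) from None
        w = ing.mass_g / 100.0
        for name in NUTRIENT_FIELDS:
            totals[name] += w * getattr(food.nutrients, name)
    return totals


def recipe_mass(recipe: Recipe) -> float:
    """Total portion mass in grams."""
    return sum(ing.mass_g for ing in recipe.ingredients)


def validate_menu_shape(menu: Menu, n_meal_slots: int) -> list[str]:
    """Structural menu check: every day fills exactly the required distinct slots.

    Returns a list of violation messages (empty when valid).  Day count is
    checked against the one-month design (20–31 days).
    """
    required = set(MEAL_TYPES[:n_meal_slots])
    problems: list[str] = []
    if not (20 <= len(menu.days) <= 31):
        problems.append(f"menu has {len(menu.days)} days; expected 20-31")
    seen_days: set[int] = set()
    for day in menu.days:
        if day.day_index in seen_days:
            problems.append(f"day {day.day_index}: duplicate day_index")
        seen_days.add(day.day_index)
        slots = set(day.selections)
        if slots != required:
            problems.append(
                f"day {day.day_index}: slots {sorted(slots)} != required "
                f"{sorted(required)}"
            )
    return problems
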