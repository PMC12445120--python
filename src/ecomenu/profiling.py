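"""NRF 9.3 and SAIN-LIM nutrient profiling.

NRF 9.3 (Nutrient Rich Food index): on a 100 kcal basis, the sum of capped
percent daily values of 9 qualifying nutrients (protein, fiber, vitamins A,
C, E, calcium, iron, magnesium, potassium) minus the uncapped sum of percent
maximal values of 3 disqualifying nutrients (saturated fat, added sugar,
sodium).  The ``mean`` variant divides each sum by its basket size.

SAIN: mean, over a 5-nutrient basket (protein, fiber, vitamin C, calcium,
iron), of percent of recommended value supplied per 100 kcal.  LIM: mean,
over the 3 restricted nutrients, of percent of maximal value per 100 g.
The SAIN-LIM quadrant at thresholds SAIN 5 / LIM 7.5 assigns classes 1-4;
a high class indicates low nutritional value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .model import (
    LIM_NUTRIENTS,
    NRF_DISQUALIFYING,
    NRF_QUALIFYING,
    SAIN_NUTRIENTS,
    Recipe,
    ReferenceValues,
    recipe_mass,
    recipe_totals,
)

__all__ = [
    "ProfileScores",
    "nrf93",
    "sain",
    "lim",
    "sain_lim_class",
    "profile_meal",
]

SAIN_THRESHOLD = 5.0
LIM_THRESHOLD = 7.5


@dataclass(frozen=True)
class ProfileScores:
    nrf93: float
    sain: float
    lim: float
    sain_lim_class: int


def _amount(nutrients: Mapping[str, float], key: str) -> float:
    try:
        return float(nutrients[key])
    except KeyError:
        raise ValueError(f"missing nutrient amount for {key!r}") from None


def nrf93(
    nutrients: Mapping[str, float],
    energy_kcal: float,
    refs: ReferenceValues,
    variant: str = "sum",
) -> float:
    """NRF 9.3 of per-portion amounts, rescaled to the reference energy basis.

    Qualifying terms are capped at 100 %DV; disqualifying terms are not.
    ``variant='sum'`` returns NR9 − LIM3; ``variant='mean'`` returns
    NR9/9 − LIM3/3.
    """
    if not (energy_kcal > 0.0):
        raise ValueError(f"energy must be > 0 kcal, got {energy_kcal!r}")
    if variant not in ("sum", "mean"):
        raise ValueError(f"variant must be 'sum' or 'mean', got {variant!r}")
    scale = refs.energy_basis / energy_kcal
    nr9 = 0.0
    for key in NRF_QUALIFYING:
        pct_dv = 100.0 * _amount(nutrients, key) * scale / refs.nrf_dv[key]
        nr9 += min(pct_dv, 100.0)
    lim3 = 0.0
    for key in NRF_DISQUALIFYING:
        lim3 += 100.0 * _amount(nutrients, key) * scale / refs.nrf_mrv[key]
    if variant == "mean":
        return nr9 / len(NRF_QUALIFYING) - lim3 / len(NRF_DISQUALIFYING)
    return nr9 - lim3


def sain(
    nutrients: Mapping[str, float], energy_kcal: float, refs: ReferenceValues
) -> float:
    """Mean percent of recommended value per 100 kcal over the SAIN basket."""
    if not (energy_kcal > 0.0):
        raise ValueError(f"energy must be > 0 kcal, got {energy_kcal!r}")
    scale = refs.energy_basis / energy_kcal
    ratios = [
        100.0 * _amount(nutrients, key) * scale / refs.sain_rv[key]
        for key in SAIN_NUTRIENTS
    ]
    return sum(ratios) / len(ratios)


def lim(nutrients_per_100g: Mapping[str, float], refs: ReferenceValues) -> float:
    """Mean percent of maximal value per 100 g over the 3 LIM nutrients."""
    ratios = [
        100.0 * _amount(nutrients_per_100g, key) / refs.lim_mrv[key]
        for key in LIM_NUTRIENTS
    ]
    return sum(ratios) / len(ratios)


def sain_lim_class(sain_score: float, lim_score: float) -> int:
    """SAIN-LIM quadrant class, 1 (recommended) to 4 (limit).

    Rules are evaluated in order 1-4, first match wins; this resolves the
    boundary LIM = 7.5 to class 1 when SAIN >= 5 and to class 4 when
    SAIN < 5, and makes the function total on [0, inf)².
    """
    if sain_score < 0.0 or lim_score < 0.0:
        raise ValueError("SAIN and LIM scores must be non-negative")
    if sain_score >= SAIN_THRESHOLD and lim_score <= LIM_THRESHOLD:
        return 1  # recommended foods
    if sain_score < SAIN_THRESHOLD and lim_score < LIM_THRESHOLD:
        return 2  # neutral foods
    if sain_score >= SAIN_THRESHOLD and lim_score >= LIM_THRESHOLD:
        return 3  # should be consumed less
    return 4  # should be limited


def profile_meal(recipe: Recipe, food_db, refs: ReferenceValues, variant: str = "sum") -> ProfileScores:
    """Score one meal: per-portion totals → NRF 9.3, SAIN, LIM and the class.

    LIM is computed on the per-100 g composition of the dish (totals divided
    by portion mass); NRF and SAIN are on the energy basis and therefore
    invariant to portion scaling, as is LIM.
    """
    totals = recipe_totals(recipe, food_db)
    energy = totals["energy_kcal"]
    if not (energy > 0.0):
        raise ValueError(f"recipe {recipe.recipe_id!r} has zero energy")
    mass = recipe_mass(recipe)
    per_100g = {k: v * refs.mass_basis / mass for k, v in totals.items()}
    sain_score = sain(totals, energy, refs)
    lim_score = lim(per_100g, refs)
    return ProfileScores(
        nrf93=nrf93(totals, energy, refs, variant=variant),
        sain=sain_score,
        lim=lim_score,
        sain_lim_class=sain_lim_class(sain_score, lim_score),
    )
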