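# Methods

## Scope and data model

`ecomenu` models institutional lunch service: a food-composition table
(per-100 g nutrients, carbon/water footprint factors, price), a recipe book
(ingredient grams per portion, course types I–IV, seasons), target-group
requirement profiles, and one-month menus of daily course selections.
Nutrients are stored per 100 g edible portion; per-portion amounts are
`mass_g/100 ×` the per-100 g value, the food-composition-table convention.
Meal types follow the Turkish institutional lunch structure: type I main
dish (usually animal protein), type II soup/cereal/olive-oil dish, type III
salad/dessert/fruit, type IV an extra course served only on hospital menus.

A missing footprint factor is *absent*, never zero.  Footprint sums skip
trace ingredients (spices, flavourings) and factor-less foods and report the
covered mass fraction, so the user sees how much of a dish the exclusion
rule dropped.  Costing takes the opposite stance: an unpriced ingredient is
a hard error, because a silently zero-priced meal would corrupt cost
comparisons while a dropped spice barely moves a footprint.

## Sustainability metrics

**Footprints.** Carbon: `Σ mass_g/1000 × CF` (kg CO₂e/portion) with CF in
kg CO₂e per kg product.  Water: `Σ mass_g/1e6 × WF` (m³/portion) with WF in
m³ per ton; mass-in-tons × (m³/ton) is the only dimensionally consistent
reading, so report headers say m³/portion even where source tables label
the column m³/ton.  Only the total water footprint is modelled; green/blue/
grey components are out of scope.  Both metrics are additive and
degree-1 homogeneous in ingredient mass, which the tests verify against an
independent per-ingredient enumeration.

**NRF 9.3.** Computed on a 100 kcal basis (`energy_basis`, configurable).
The nine qualifying %DV terms are capped at 100; the three disqualifying
%MRV terms are uncapped, following the canonical index.  Both the `sum`
(NR9 − LIM3, default) and `mean` (NR9/9 − LIM3/3) variants are exposed; the
choice of basis and variant changes the scale but not the ordering under
portion rescaling, and all profile scores are invariant to portion size by
construction.

**SAIN-LIM.** SAIN: mean % of recommended value per 100 kcal over the basic
5-nutrient basket (protein, fiber, vitamin C, calcium, iron).  LIM: mean %
of maximal value per 100 g over saturated fat, added sugar, sodium.  The
four published decision rules overlap on the boundary LIM = 7.5 (class 1
claims ≤ 7.5, class 3 claims ≥ 7.5, and SAIN < 5 ∧ LIM = 7.5 is claimed by
neither strict rule 2 nor unambiguously by rule 4).  Rules are therefore
evaluated in order 1, 2, 3, 4 with first match winning: LIM = 7.5 resolves
to class 1 when SAIN ≥ 5 and to class 4 when SAIN < 5.  This makes the
classifier total on [0, ∞)² and monotone (class never improves as LIM
worsens at fixed SAIN; never worsens as SAIN rises at fixed LIM ≥ 7.5).

Default reference values ship as editable YAML data (`ecomenu/data/refs.yaml`):
FDA adult daily values for the NRF baskets; SAIN recommended values protein
65 g, fiber 30 g, vitamin C 110 mg, calcium 900 mg, iron 12.5 mg and LIM
maxima saturated fat 22 g, added sugar 50 g, sodium 3153 mg.  The exact
basket an institution uses is policy, not code: both baskets are
constructor arguments.  Added sugar is a stored field, never inferred from
total sugar.

**Cost.** Raw-material cost only (`Σ mass_g × price_per_kg / 1000`),
converted to USD by a user-supplied exchange rate; labor, energy and other
overheads are deliberately excluded.

## The planner

The planning algorithm is a seeded randomized greedy search with day-level
backtracking.  For each day, eligible recipes per slot (right meal type,
in season, not served within `repeat_window` days) are shuffled with a
`numpy` PCG64 generator; slot combinations are walked in shuffled order
with branch-and-bound pruning on the energy window, and the first
combination satisfying all constraints is accepted:

- day energy (courses I–III) within `energy_tolerance` (default ±10%) of
  the group's lunch target;
- macronutrient gram windows (defaults derive from 8–30 %E protein,
  15–50 %E fat, 30–70 %E carbohydrate);
- no recipe repetition within `repeat_window` days (default 7);
- course-category frequency caps per sliding 7-day window (off by default;
  e.g. `main-meat: 2` limits red-meat mains to twice a week).

If a day has no candidate, the search backtracks to the previous day's next
candidate; after `max_attempts` candidate evaluations (default 200 000) it
fails loudly, reporting the first unsatisfiable day and the constraint that
rejected the most candidates.  Identical inputs and seed give identical
menus on any platform.  A hospital's fourth course sits outside the lunch
energy budget and is placed afterwards (`add_fourth_course`), mirroring
manual placement; manual overrides of any slot are allowed and never
blocked — the violations they introduce are listed instead.

The validator (`ecomenu.validate`) restates every constraint independently
of the search code and is used as the planner's test oracle.

## Comparison statistics

Sources are compared per (target group × meal type × metric) stratum.
Kruskal–Wallis uses the tie-corrected H against χ² (g−1 df); the degenerate
all-tied stratum returns H = 0, p = 1 rather than erroring.  Mann–Whitney U
counts wins with half credit for ties; for combined n ≤ 12 the two-sided
p-value is an exact permutation enumeration over all C(n, n₁) assignments
(valid under ties), otherwise the normal approximation with tie and
continuity corrections.  Spearman is the Pearson correlation of mid-ranks
with a t-approximation p-value; constant input is flagged, not raised.

Pairwise tests run only in strata where Kruskal–Wallis rejects at α
(a protected Fisher-style procedure) and no further multiplicity
correction is applied — a faithfulness choice mirroring common practice in
foodservice studies that print homogeneity letters beside a global p, not a
statistical endorsement.  Letters come from an insert-and-absorb compact
letter display, so non-transitive significance patterns (A ≠ C but A ~ B ~ C)
render correctly as shared letters.

## The synthetic world

The generator emulates the study design end to end so that every module is
testable offline: a ten-group food database (~60 foods) with group-wise
nutrient templates and factor ranges, an archetype recipe book (mains,
soups, pilafs, pastries, salads, milk and syrup desserts, fruit), and the
full 5 target groups × 3 sources × 30 days design.

Stated conditions, chosen once:

- Factor ranges are order-of-magnitude realistic (ruminant meat 20–30
  kg CO₂e/kg strictly above vegetables' 0.3–2 by construction, matching the
  animal > plant emission ordering; water and price ranges likewise).
  They are config data, not estimates of any national table.
- Course energy shares of the lunch target: I 45%, II 35%, III 20%;
  hospital course IV ≈ 100 kcal.  Recipes are mass-scaled onto their share
  of a 700 kcal reference lunch with 6% multiplicative noise, then
  portion-scaled per group (450–850 kcal lunch targets — placeholder
  values, flagged as such in `groups.yaml`).
- At most two recipes per meal type are out of season, so the in-season
  pool (≥ 10) always exceeds the 7-day variety window.
- Per-source animal-share multipliers on animal-ingredient masses default
  to DPM 1.00 / NMPG 0.85 / IAM 0.67, the red-meat grams ratio across the
  three menu sources in the design this emulates.
- DPM menus come from the planner; NMPG and IAM menus resample the DPM
  menu's per-slot selections day by day (seeded, with replacement) on their
  shifted recipe variants — external menus emulated as perturbations of the
  planned one, since no real menu data ships with the package.

What the generator does **not** emulate: real Turkish recipes or prices,
correlated nutrient profiles within a food, seasonality of supply,
preference/taste structure, or menus that violate the planner's own
constraints.  A green test on this world establishes computational
correctness and statistical behaviour, not agreement with any published
menu's absolute values.

### Statistical behaviour of the fixture

Because the DPM menu is a *designed*, variety-balanced selection rather
than an i.i.d. sample — and the resampled sources draw from its empirical
distribution — rank tests across fixture sources under equal shifts are
conservative: measured rejection ≈ 1–3% of strata at α = 0.05, not the
nominal 5%.  This is a property of designed menus generally, worth knowing
when reading real-menu comparisons.  Calibration of the statistics
themselves is therefore checked on i.i.d. simulated strata (rejection
5% ± 2 points over 2000 strata), and the fixture-level check asserts the
conservative band [1%, 10%] fixed a priori.  Power: an injected IAM
animal-share shift of 1.6 yields a distinct carbon-footprint letter for
that source in ≥ 95% of seeded replicates (the acceptance test requires
≥ 90% over 200).

## Numerical choices

- Sample SDs use ddof = 1 throughout; a one-observation group reports NaN.
- Per-menu summary values average all meal instances of the month equally
  (not a mean of meal-type means); per-meal-type rows report mean ± SD over
  days.
- The exact/approximate Mann–Whitney switch sits at combined n = 12
  (C(12,6) = 924 enumerations — desk-scale exactness where cheap).
- Report CSVs print 6 significant digits; food CSVs round-trip floats
  bit-exactly via shortest-repr formatting.
- Seeds derived internally (per group, per stream) stay below 2³¹.

## Known limitations

- The planner is greedy-feasible, not optimal: it finds *a* constraint-
  satisfying menu, makes no attempt to minimise footprint or cost, and its
  failure report names the empirically binding constraint, which need not
  be the cause of a deep infeasibility.
- Coverage disclosure (`covered_mass_fraction`) treats carbon and water
  factors jointly; a food with only one factor counts as uncovered.
- The compact-letter procedure inherits the unprotected pairwise error
  rate of letter displays; with three sources this is mild but real.
- Group requirement profiles ship as placeholders and must be replaced
  with institutional values before any operational use.
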