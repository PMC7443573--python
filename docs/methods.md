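# Methods

## Scope and data flow

The package models least-cost nutritionally adequate ("LACON") weekly
diets for six individual categories — children 6–8, 9–11, 12–23 months
and non-pregnant/non-lactating, pregnant, lactating women — across two
market seasons (plenty, lean). The stages are:

1. **Price aggregation** (`food_model`). Each market observation is a
   weighed purchase (price paid, grams of edible portion obtained). The
   seasonal price of a food is the unweighted arithmetic mean of
   `100·price/weight` over all observations in that (food, season)
   group, pooling villages and traders equally. Pooling by simple mean
   is an assumption; survey write-ups of this kind typically do not
   state the pooling rule, and trader-level weights are rarely
   available.
2. **Composition conversions** (`food_model`). Calcium and iron enter
   all tables on an *absorbed* basis: raw survey values are multiplied
   by fixed bioavailability factors 0.48 (Ca) and 0.05 (Fe). Vitamin A
   is carried as retinol equivalents with β-carotene converted 12:1.
   No phytate-, fibre-, or meal-composition-dependent absorption is
   modeled. Wild (collected) foods carry an opportunity-cost price —
   the rounded mean of comparable purchased foods (7.7 KES/100 g for
   the case-study fruits, 7.8 for vegetables) — to represent collection
   and preparation effort.
3. **Constraints** (`constraint_builder`). Weekly serving bounds per
   food come from household 24-h-recall counts: min = 25th percentile,
   max = 75th percentile, linear-interpolation quantiles rounded
   half-up to whole servings (the estimator is a choice; only the
   percentile levels are given by the source procedure). Quantile
   monotonicity guarantees min ≤ max. Where focus-group bounds
   disagree with recall bounds, the recall wins (observed intake over
   stated norms). Wild foods carry fixed program bounds of 1–3
   servings/week; the micronutrient powder (MNP) 3–4 sachets/week
   (15/month distribution), with a 7/7 daily sensitivity mode.
4. **Optimization** (`lp_core`), 5. **Scenarios** (`scenarios`),
   6. **Affordability** (`affordability`) — described below.

## The LP

Decision variables are continuous weekly servings per food, boxed by
the frequency bounds. Continuity is a deliberate relaxation: it is
convex and reproducible, whereas established cost-of-diet software does
not document how (or whether) it enforces whole servings; an integer
mode exists through the enumeration oracle for testing. Constraints:

- **Energy**: hard two-sided band `[1.00, 1.10] × weekly requirement`.
  The upper edge prevents the solver padding diets with unboundedly
  cheap calories to harvest incidental micronutrients; the width is
  configurable (`LPConfig.energy_band`).
- **Protein, fat**: hard lower bounds at the weekly requirement.
- **Micronutrients** (all 16 remaining slots with a positive
  requirement): elastic. Each row gets a normalized deficit variable
  `d ∈ [0, 1]` with objective weight `P = 10⁶ × max serving cost`, so
  deficit minimization is lexicographically prior to cost. This mirrors
  the observed behaviour of cost-of-diet modeling in poor food
  environments: optimized diets can still fail iron and zinc, and the
  useful output is the shortfall, not an infeasibility flag.

Status labels: `optimal` (all deficits < 1e-6 normalized),
`optimal_with_deficit`, or `infeasible_bounds` when the box bounds
alone cannot satisfy a hard row (e.g. forced minimum servings exceed
the energy ceiling); the violating constraint is named by interval
analysis over the box.

Solved with HiGHS (`scipy.optimize.linprog`), feasibility tolerances
1e-8; deterministic for a fixed configuration. Equal-cost ties are
resolved by the solver's deterministic pivoting; costs are reported to
0.1 KES so ties are cosmetic. Weekly cost is converted to daily by /7;
a 365-day year annualizes daily costs. Currency is KES internally with
USD display at a configurable 103.6 KES/$.

Unknown composition entries (unmeasured values in source tables)
contribute zero to every constraint — a food is never credited with a
nutrient nobody measured — and foods with incomplete composition are
listed by `DietProblem.incomplete_composition_foods()`.

### Enumeration oracle

`brute_force_oracle` exhaustively scores the serving grid (≤ 5 foods,
≤ 8 points per food) against the same penalized objective. Two regimes
matter for validation:

- Without hard macro rows, rounding the LP optimum up to the next grid
  point is always feasible, adds at most one serving's cost per food,
  and cannot create deficits — so the grid optimum provably lies within
  `Σ_f c_f × step` of the LP on the penalized objective, and status
  labels agree exactly. This is the regime used for the 200-instance
  agreement study.
- With the hard energy band, deficit pressure can pin the LP against
  the band's ceiling where rounding up is infeasible; the grid is then
  a strict subset of the continuum and its label can only be equally or
  more pessimistic. Tests assert exactly that ordering.

### Directional laws

Under the elastic objective, "adding a free food never raises cost"
holds lexicographically: the pair (total deficit, cost) never worsens
in that order, but a new food may legitimately buy a deficit down for
money. The pure cost form of the law is exact whenever the baseline is
already adequate, and that is how it is tested. Uniform price scaling
scales the optimal cost exactly and leaves servings unchanged; raising
every price (lean season) weakly raises cost; a forced minimum on a
net-expensive food strictly raises it.

## Scenario ladder

Interventions add foods (with their own prices, bounds, portions) to
the baseline list and re-solve every (category, season) cell: each wild
food alone, the three fruits, the three vegetables, all six, and — for
child categories only — the MNP sachet (zero cost; its collection
effort is not priced) with and without the six wild foods. Percent
reductions are computed per season and then averaged across seasons
(not computed on season-averaged costs); the meaningful flag requires a
≥ 25 % decrease in both seasons, and a cost increase never qualifies.

The case-study MNP formulation enters iron on the same absorbed basis
(5 %) as food iron; the source material does not state whether
supplement iron is converted, and since the sachet is free this choice
affects only its adequacy contribution, not any cost conclusion.

## Affordability

The per-person benchmark cost is the mean daily cost over all 12
(category, season) cells of the cheapest scenario, annualized at 365
days. Every household member is assumed to cost this same amount
regardless of age and sex, so per-person budget comparisons are exact
and household-level totals cancel. Two budget rules are evaluated per
wealth group: annual income per individual × food-expenditure share,
and (sensitivity) the entire income.

## Synthetic data

`generate_market` / `generate_recall` emulate the survey *shape*: 56
market foods in seven composition groups (staples, legumes, vegetables,
oils, animal-source, sugar, misc), 6 villages × 4 traders × 2 seasons
of weighed price observations, and 180 households of zero-inflated
Poisson weekly counts (wild foods and fruits absent from baseline
consumption). Per-food base prices are mean-preserving log-normal
around group levels; each trader's lean price is the plenty price times
a 1.2 inflation factor with bounded jitter, so lean ≥ plenty holds
food-by-food and the seasonal cost ordering follows from LP price
monotonicity. `gap_severity` scales down iron/zinc content of market
foods so baseline diets exhibit the characteristic gaps. These
generators are distributional: they do not reproduce any particular
published cost cell, and passing tests on them demonstrates pipeline
correctness, not real-market calibration. Real surveys differ in ways
the generator ignores: correlated prices across foods and villages,
seasonal availability changes in the food list itself, measurement
error in weights, and recall counts correlated within households.

`engineered_gap_instance` is the parameter-recovery construction, exact
by design: a fortified staple is the sole energy source (14 servings
meet the weekly energy floor exactly, and it covers protein, fat, and
all non-gap micronutrients down to 13 servings); a relish capped at 7
servings/week supplies exactly `1 − gap_severity` of the weekly iron
and zinc requirements; a dominated distractor is never selected. The
unique baseline optimum is therefore staple-at-floor + relish-at-cap
with an iron/zinc deficit of exactly `gap_severity`. The added wild
vegetable covers both requirements fully at its 3-servings cap, and the
relish price is solved in closed form so the swap changes the optimal
cost by exactly the configured percentage; optimality of the
pure-vegetable corner over any vegetable/relish mix follows from the
derived price inequality and is asserted during construction. Seeded
jitter varies the staple price/energy density and vegetable energy
across seeds without touching the analytic optimum. A variant adds a
net-expensive forced-minimum wild fruit whose exact positive cost
effect is also recorded. Prices reach the pipeline as identical
weighed observations (so aggregation is exact) and bounds as recall
patterns whose quartiles reproduce the intended boxes.

## Problem sizes

The test suite solves only small LPs (≤ 56 foods); the acceptance
script uses 200 random oracle instances, 3 configured reductions × 10
seeds of engineered instances, and one 56-food synthetic market — the
whole script runs in a few seconds, chosen to keep the checks quick to
re-run while the constructions remain exact.

## Known limitations

- Requirement profiles and portion sizes are WHO/FAO-informed modeling
  defaults, not clinical guidance, and should be replaced with
  program-specific tables (`requirements.csv`, `portions.csv`) for any
  real application; no reproduction check depends on their values.
- Two fixed bioavailability factors stand in for true absorption
  modeling; supplement iron shares the food factor (see above).
- Continuous servings can prescribe fractional weekly portions.
- The elastic penalty makes deficit minimization effectively, not
  formally, lexicographic; with the default 10⁶ factor the residual
  cost/deficit trade is below 1e-4 normalized units on any instance in
  the test envelope.
- Multi-person household optimization, food-list seasonality beyond
  prices, and integer programming in the main path are out of scope.
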