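"""Least-cost diet linear program with elastic micronutrient constraints.

One problem instance covers one individual category, one season, and one
food set.  Decision variables are continuous servings/week per food,
boxed by frequency bounds.  Energy is a hard two-sided band (a multiple
of the weekly requirement), protein and fat are hard lower bounds, and
every micronutrient with a positive requirement is elastic: a deficit
variable absorbs any shortfall at a penalty so large that the solver
first minimizes total normalized deficit, then money.  This mirrors how
least-cost diet tools report diets that remain short of iron or zinc
even at the optimum, instead of declaring the whole problem infeasible.

Costs are KES; a weekly plan is solved and reported as weekly and daily
(weekly/7) cost.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .constraint_builder import FrequencyBound, IndividualProfile, PortionSpec
from .food_model import FoodItem, SeasonalPriceTable
from .nutrients import MICRO_NUTRIENTS, NUTRIENTS, nutrient_index

DAYS_PER_WEEK = 7

#: Solution status labels.
STATUS_OPTIMAL = "optimal"
STATUS_OPTIMAL_WITH_DEFICIT = "optimal_with_deficit"
STATUS_INFEASIBLE_BOUNDS = "infeasible_bounds"

#: Normalized deficit below this is treated as zero (numerical noise).
DEFICIT_TOL = 1e-6


@dataclass(frozen=True)
class LPConfig:
    """Solver-facing knobs.

    ``energy_band`` multiplies the weekly energy requirement into a hard
    [lower, upper] corridor (the upper edge stops the solver padding the
    diet with cheap calories).  ``penalty_factor`` scales the deficit
    penalty relative to the most expensive serving on offer, making
    deficit minimization lexicographically prior to cost.
    """

    energy_band: tuple[float, float] = (1.0, 1.1)
    penalty_factor: float = 1e6
    solver_tol: float = 1e-8


@dataclass
class DietData:
    """Everything food-side a problem needs: foods, prices, portions, bounds."""

    foods: list[FoodItem]
    prices: SeasonalPriceTable
    portions: dict[tuple[str, str], PortionSpec]  # (category, food_id) -> spec
    bounds: dict[str, FrequencyBound]  # food_id -> bound

    def with_added_foods(
        self,
        foods: Sequence[FoodItem],
        prices: SeasonalPriceTable,
        portions: Mapping[tuple[str, str], PortionSpec],
        bounds: Mapping[str, FrequencyBound],
    ) -> "DietData":
        existing = {f.id for f in self.foods}
        clash = existing & {f.id for f in foods}
        if clash:
            raise ValueError(f"added foods overlap baseline food list: {sorted(clash)}")
        return DietData(
            foods=[*self.foods, *foods],
            prices=self.prices.merged(prices),
            portions={**self.portions, **portions},
            bounds={**self.bounds, **bounds},
        )


@dataclass
class DietProblem:
    """One assembled LP instance (matrices in canonical nutrient order)."""

    individual: IndividualProfile
    season: str
    foods: list[FoodItem]
    cost_per_serving: np.ndarray  # KES per serving, len n_foods
    supply_per_serving: np.ndarray  # (n_nutrients, n_foods), unknowns coerced to 0
    weekly_requirement: np.ndarray  # len n_nutrients, NaN = unconstrained
    lower: np.ndarray  # servings/week lower bounds
    upper: np.ndarray  # servings/week upper bounds
    config: LPConfig = field(default_factory=LPConfig)

    @property
    def food_ids(self) -> list[str]:
        return [f.id for f in self.foods]

    @property
    def elastic_nutrients(self) -> list[str]:
        """Micronutrients with a positive weekly requirement (deficit-buffered rows)."""
        out = []
        for n in MICRO_NUTRIENTS:
            r = self.weekly_requirement[nutrient_index(n)]
            if np.isfinite(r) and r > 0:
                out.append(n)
        return out

    @property
    def penalty(self) -> float:
        # per unit *normalized* deficit; dominates any attainable cost saving
        return self.config.penalty_factor * max(float(self.cost_per_serving.max(initial=0.0)), 1.0)

    def incomplete_composition_foods(self) -> list[str]:
        """Foods whose composition has unknown entries (flagged in adequacy reports)."""
        return [f.id for f in self.foods if f.composition.unknown_nutrients]

    def to_frame(self) -> pd.DataFrame:
        """Audit dump: per-food cost and per-serving nutrient supplies."""
        df = pd.DataFrame(self.supply_per_serving.T, columns=list(NUTRIENTS))
        df.insert(0, "food_id", self.food_ids)
        df.insert(1, "cost_per_serving_kes", self.cost_per_serving)
        df.insert(2, "min_per_week", self.lower)
        df.insert(3, "max_per_week", self.upper)
        return df


@dataclass
class DietSolution:
    """Optimized weekly portions with cost and adequacy profile."""

    status: str
    servings_per_week: dict[str, float]
    weekly_cost: float
    adequacy: dict[str, float]  # nutrient -> % of weekly requirement supplied (unrounded)
    deficits: dict[str, float]  # nutrient -> normalized shortfall in [0, 1]
    violated_constraint: str | None = None

    @property
    def daily_cost(self) -> float:
        return self.weekly_cost / DAYS_PER_WEEK

    def to_json(self, path: str | Path) -> None:
        payload = {
            "status": self.status,
            "servings_per_week": self.servings_per_week,
            "weekly_cost_kes": self.weekly_cost,
            "daily_cost_kes": self.daily_cost,
            "adequacy_pct": self.adequacy,
            "deficits": self.deficits,
            "violated_constraint": self.violated_constraint,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# problem assembly


def _serving_supply(food: FoodItem, grams: float) -> np.ndarray:
    """Per-serving nutrient supply; supplements are dosed per sachet, foods per 100 g."""
    comp = food.composition.filled(0.0)
    if food.is_supplement:
        return comp * grams  # grams_per_serving is sachets' mass in g; composition per 1 g sachet
    return comp * grams / 100.0


def build_problem(
    profile: IndividualProfile,
    season: str,
    data: DietData,
    config: LPConfig | None = None,
) -> DietProblem:
    """Assemble the LP for one (category, season) from cross-checked inputs.

    Foods not available in ``season`` are dropped together with their
    bounds; every remaining food must have a price, a portion for the
    category, and a frequency bound.
    """
    config = config or LPConfig()
    foods = [f for f in data.foods if season in f.season_availability]
    if not foods:
        raise ValueError(f"no foods available in season {season!r}")

    cost = np.zeros(len(foods))
    supply = np.zeros((len(NUTRIENTS), len(foods)))
    lower = np.zeros(len(foods))
    upper = np.zeros(len(foods))
    for j, food in enumerate(foods):
        spec = data.portions.get((profile.category, food.id))
        if spec is None:
            raise ValueError(f"no portion size for food {food.id!r} / category {profile.category!r}")
        bound = data.bounds.get(food.id)
        if bound is None:
            raise ValueError(f"no frequency bound for food {food.id!r}")
        price = data.prices.get(food.id, season)  # raises MissingPriceError
        grams = spec.grams_per_serving
        cost[j] = 0.0 if food.is_supplement else price * grams / 100.0
        supply[:, j] = _serving_supply(food, grams)
        lower[j], upper[j] = bound.min_per_week, bound.max_per_week

    weekly_req = profile.requirements.values * DAYS_PER_WEEK
    return DietProblem(
        individual=profile,
        season=season,
        foods=foods,
        cost_per_serving=cost,
        supply_per_serving=supply,
        weekly_requirement=weekly_req,
        lower=lower,
        upper=upper,
        config=config,
    )


# ---------------------------------------------------------------------------
# solving


def _hard_rows(problem: DietProblem) -> list[tuple[str, np.ndarray, float, str]]:
    """(label, coefficient row, rhs, sense) for the hard macro constraints; sense 'ge'/'le'."""
    rows = []
    lo_mult, hi_mult = problem.config.energy_band
    e = problem.weekly_requirement[nutrient_index("energy")]
    if np.isfinite(e) and e > 0:
        row = problem.supply_per_serving[nutrient_index("energy")]
        rows.append(("energy lower band", row, lo_mult * e, "ge"))
        rows.append(("energy upper band", row, hi_mult * e, "le"))
    for n in ("protein", "fat"):
        r = problem.weekly_requirement[nutrient_index(n)]
        if np.isfinite(r) and r > 0:
            rows.append((f"{n} minimum", problem.supply_per_serving[nutrient_index(n)], r, "ge"))
    return rows


def _diagnose_infeasibility(problem: DietProblem) -> str:
    """Name the hard constraint the box bounds alone cannot satisfy."""
    for label, row, rhs, sense in _hard_rows(problem):
        # extreme achievable value of row·x over the box
        best = float(row @ (problem.upper if sense == "ge" else problem.lower))
        if sense == "ge" and best < rhs - 1e-9:
            return f"{label}: maximum achievable {best:.3f} < required {rhs:.3f}"
        if sense == "le" and best > rhs + 1e-9:
            return f"{label}: forced minimum servings supply {best:.3f} > allowed {rhs:.3f}"
    return "hard constraints jointly infeasible within frequency bounds"


def _solution_from_servings(problem: DietProblem, x: np.ndarray) -> DietSolution:
    supplied = problem.supply_per_serving @ x
    adequacy: dict[str, float] = {}
    deficits: dict[str, float] = {}
    for n in NUTRIENTS:
        r = problem.weekly_requirement[nutrient_index(n)]
        if np.isfinite(r) and r > 0:
            adequacy[n] = 100.0 * supplied[nutrient_index(n)] / r
    for n in problem.elastic_nutrients:
        r = problem.weekly_requirement[nutrient_index(n)]
        d = max(0.0, 1.0 - supplied[nutrient_index(n)] / r)
        deficits[n] = 0.0 if d < DEFICIT_TOL else d
    status = STATUS_OPTIMAL if all(d == 0.0 for d in deficits.values()) else STATUS_OPTIMAL_WITH_DEFICIT
    return DietSolution(
        status=status,
        servings_per_week=dict(zip(problem.food_ids, (float(v) for v in x))),
        weekly_cost=float(problem.cost_per_serving @ x),
        adequacy=adequacy,
        deficits=deficits,
    )


def solve(problem: DietProblem) -> DietSolution:
    """Solve the elastic LP (HiGHS); deterministic for a fixed configuration."""
    n_foods = len(problem.foods)
    elastic = problem.elastic_nutrients
    n_var = n_foods + len(elastic)

    c = np.zeros(n_var)
    c[:n_foods] = problem.cost_per_serving
    c[n_foods:] = problem.penalty

    rows_A: list[np.ndarray] = []
    rows_b: list[float] = []
    for _, row, rhs, sense in _hard_rows(problem):
        coef = np.zeros(n_var)
        coef[:n_foods] = row
        if sense == "ge":
            rows_A.append(-coef)
            rows_b.append(-rhs)
        else:
            rows_A.append(coef)
            rows_b.append(rhs)
    for k, n in enumerate(elastic):
        r = problem.weekly_requirement[nutrient_index(n)]
        coef = np.zeros(n_var)
        coef[:n_foods] = problem.supply_per_serving[nutrient_index(n)]
        coef[n_foods + k] = r  # deficit is normalized: supply + r*d >= r
        rows_A.append(-coef)
        rows_b.append(-r)

    bounds = [(float(lo), float(hi)) for lo, hi in zip(problem.lower, problem.upper)]
    bounds += [(0.0, 1.0)] * len(elastic)

    res = linprog(
        c,
        A_ub=np.array(rows_A) if rows_A else None,
        b_ub=np.array(rows_b) if rows_b else None,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": problem.config.solver_tol,
                 "dual_feasibility_tolerance": problem.config.solver_tol},
    )
    if res.status == 2:  # infeasible
        return DietSolution(
            status=STATUS_INFEASIBLE_BOUNDS,
            servings_per_week={},
            weekly_cost=float("nan"),
            adequacy={},
            deficits={},
            violated_constraint=_diagnose_infeasibility(problem),
        )
    if not res.success:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"LP solver failed: {res.message}")
    x = np.clip(res.x[:n_foods], problem.lower, problem.upper)
    return _solution_from_servings(problem, x)


def adequacy(solution: DietSolution, ndigits: int = 0) -> dict[str, float]:
    """Percent of each weekly requirement supplied, uncapped, rounded for reporting."""
    return {n: round(v, ndigits) for n, v in solution.adequacy.items()}


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)


MAX_ORACLE_FOODS = 5
MAX_ORACLE_GRID = 8


def brute_force_oracle(problem: DietProblem, grid_step: float = 1.0) -> DietSolution:
    """Exhaustive grid search over servings; independent check for tiny instances.

    Enumerates every combination of servings on the grid
    ``min, min+step, ..., max`` per food, keeps those satisfying the hard
    macro constraints, and minimizes the same cost-plus-penalized-deficit
    objective as the LP.  Refuses instances beyond 5 foods or 8 grid
    points per food.
    """
    if len(problem.foods) > MAX_ORACLE_FOODS:
        raise ValueError(f"oracle refuses >{MAX_ORACLE_FOODS} foods")
    grids = []
    for lo, hi in zip(problem.lower, problem.upper):
        pts = list(np.arange(lo, hi, grid_step)) + [hi]
        if len(pts) > MAX_ORACLE_GRID:
            raise ValueError(f"oracle refuses >{MAX_ORACLE_GRID} grid points per food")
        grids.append(pts)

    points = np.array(list(itertools.product(*grids)))  # (n_points, n_foods)
    supplied = points @ problem.supply_per_serving.T  # (n_points, n_nutrients)

    feasible = np.ones(len(points), dtype=bool)
    for _, row, rhs, sense in _hard_rows(problem):
        vals = points @ row
        feasible &= vals >= rhs - 1e-9 if sense == "ge" else vals <= rhs + 1e-9
    if not feasible.any():
        return DietSolution(
            status=STATUS_INFEASIBLE_BOUNDS,
            servings_per_week={},
            weekly_cost=float("nan"),
            adequacy={},
            deficits={},
            violated_constraint=_diagnose_infeasibility(problem),
        )

    objective = points @ problem.cost_per_serving
    for n in problem.elastic_nutrients:
        r = problem.weekly_requirement[nutrient_index(n)]
        deficit = np.maximum(0.0, 1.0 - supplied[:, nutrient_index(n)] / r)
        objective = objective + problem.penalty * deficit
    objective = np.where(feasible, objective, np.inf)
    best = int(np.argmin(objective))
    return _solution_from_servings(problem, points[best])
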