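"""Intervention scenario ladder: wild foods and micronutrient powder.

The ladder adds candidate foods to the baseline market food set —
each wild food alone, the three wild fruits together, the three wild
vegetables together, all six together, and (for children) the
micronutrient powder with and without the six wild foods — re-solves
the least-cost diet per individual category and season, and compares
costs.  A scenario is a *meaningful* cost reduction when it cuts the
optimal diet cost by at least 25% in both seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint_builder import (
    CATEGORIES,
    CHILD_CATEGORIES,
    FrequencyBound,
    IndividualProfile,
    PortionSpec,
    default_portions,
    mnp_bounds,
    wild_food_bounds,
)
from .food_model import SEASONS, FoodItem, SeasonalPriceTable, _round_half_up
from .lp_core import (
    STATUS_INFEASIBLE_BOUNDS,
    DietData,
    DietSolution,
    LPConfig,
    build_problem,
    solve,
)

MEANINGFUL_REDUCTION_PCT = 25.0


class ScenarioInfeasibleError(RuntimeError):
    """A scenario LP was infeasible; carries the scenario context."""


@dataclass(frozen=True)
class Intervention:
    """Foods added on top of the baseline list, with prices, bounds, portions.

    ``applies_to`` restricts the individual categories (the micronutrient
    powder is a child-only program); ``None`` means all categories.
    """

    name: str
    added_foods: tuple[FoodItem, ...]
    prices: SeasonalPriceTable
    bounds: Mapping[str, FrequencyBound]
    portions: Mapping[tuple[str, str], PortionSpec]
    applies_to: frozenset[str] | None = None

    def categories(self, all_categories: Sequence[str]) -> list[str]:
        if self.applies_to is None:
            return list(all_categories)
        return [c for c in all_categories if c in self.applies_to]


@dataclass
class ScenarioResult:
    """Baseline-vs-intervention comparison for one scenario across categories and seasons."""

    name: str
    baseline_daily: dict[tuple[str, str], float]  # (category, season) -> KES/day
    scenario_daily: dict[tuple[str, str], float]
    baseline_adequacy: dict[tuple[str, str], dict[str, float]]
    scenario_adequacy: dict[tuple[str, str], dict[str, float]]

    def reduction(self, category: str, season: str) -> float:
        return percent_reduction(
            self.baseline_daily[(category, season)],
            self.scenario_daily[(category, season)],
            ndigits=None,
        )

    def average_reduction(self, category: str, seasons: Sequence[str] = SEASONS) -> float:
        """Season-averaged percent reduction (computed per season, then averaged)."""
        return season_average([self.reduction(category, s) for s in seasons])

    def meaningful(self, category: str, seasons: Sequence[str] = SEASONS) -> bool:
        reductions = [self.reduction(category, s) for s in seasons]
        return is_meaningful(*reductions)

    @property
    def categories(self) -> list[str]:
        return sorted({cat for cat, _ in self.scenario_daily}, key=_category_order)


def _category_order(cat: str) -> int:
    return CATEGORIES.index(cat) if cat in CATEGORIES else len(CATEGORIES)


# ---------------------------------------------------------------------------
# arithmetic


def percent_reduction(baseline: float, intervention: float, ndigits: int | None = 1) -> float:
    """Percent change of daily cost vs baseline; negative means cheaper."""
    if baseline <= 0:
        raise ValueError("baseline cost must be positive")
    value = 100.0 * (intervention - baseline) / baseline
    return value if ndigits is None else _round_half_up(value, ndigits)


def is_meaningful(reduction_plenty: float, reduction_lean: float) -> bool:
    """True when the cost falls by at least 25% in both seasons."""
    return (
        reduction_plenty <= -MEANINGFUL_REDUCTION_PCT
        and reduction_lean <= -MEANINGFUL_REDUCTION_PCT
    )


def season_average(values: Sequence[float]) -> float:
    """Arithmetic mean across seasons."""
    return float(np.mean(values))


def seasonal_increase(plenty_cost: float, lean_cost: float) -> float:
    """Percent cost increase from the plenty to the lean season."""
    if plenty_cost <= 0:
        raise ValueError("plenty-season cost must be positive")
    return 100.0 * (lean_cost - plenty_cost) / plenty_cost


# ---------------------------------------------------------------------------
# ladder construction and execution


def _solve_cell(data: DietData, profile: IndividualProfile, season: str,
                config: LPConfig, context: str) -> DietSolution:
    sol = solve(build_problem(profile, season, data, config))
    if sol.status == STATUS_INFEASIBLE_BOUNDS:
        raise ScenarioInfeasibleError(
            f"{context}: infeasible for {profile.category}/{season}: {sol.violated_constraint}"
        )
    return sol


def run_ladder(
    baseline: DietData,
    interventions: Sequence[Intervention],
    profiles: Mapping[str, IndividualProfile],
    seasons: Sequence[str] = SEASONS,
    config: LPConfig | None = None,
) -> list[ScenarioResult]:
    """Solve baseline and every intervention per (category, season)."""
    config = config or LPConfig()
    base_cost: dict[tuple[str, str], float] = {}
    base_adeq: dict[tuple[str, str], dict[str, float]] = {}
    for cat, profile in profiles.items():
        for season in seasons:
            sol = _solve_cell(baseline, profile, season, config, "baseline")
            base_cost[(cat, season)] = sol.daily_cost
            base_adeq[(cat, season)] = dict(sol.adequacy)

    results = []
    for iv in interventions:
        data = baseline.with_added_foods(iv.added_foods, iv.prices, iv.portions, iv.bounds)
        scen_cost: dict[tuple[str, str], float] = {}
        scen_adeq: dict[tuple[str, str], dict[str, float]] = {}
        for cat in iv.categories(list(profiles)):
            for season in seasons:
                sol = _solve_cell(data, profiles[cat], season, config, f"scenario {iv.name!r}")
                scen_cost[(cat, season)] = sol.daily_cost
                scen_adeq[(cat, season)] = dict(sol.adequacy)
        results.append(
            ScenarioResult(
                name=iv.name,
                baseline_daily={k: base_cost[k] for k in scen_cost},
                scenario_daily=scen_cost,
                baseline_adequacy={k: base_adeq[k] for k in scen_adeq},
                scenario_adequacy=scen_adeq,
            )
        )
    return results


def make_intervention(
    name: str,
    foods: Sequence[FoodItem],
    prices: SeasonalPriceTable,
    categories: Sequence[str] = CATEGORIES,
    applies_to: Sequence[str] | None = None,
    mnp_daily: bool = False,
    portions: Mapping[tuple[str, str], PortionSpec] | None = None,
) -> Intervention:
    """Intervention with standard bounds (wild foods 1-3/week, supplement 3-4 or 7/7)."""
    bounds: dict[str, FrequencyBound] = {}
    for f in foods:
        if f.is_supplement:
            bounds[f.id] = mnp_bounds(f, daily=mnp_daily)
        elif f.is_wild:
            bounds[f.id] = wild_food_bounds(f)
        else:
            raise ValueError(f"intervention food {f.id} must be wild or supplement")
    prices = SeasonalPriceTable(dict(prices.prices))
    for f in foods:
        if f.is_supplement:  # distributed free of charge
            for season in SEASONS:
                prices.set(f.id, season, 0.0)
    return Intervention(
        name=name,
        added_foods=tuple(foods),
        prices=prices,
        bounds=bounds,
        portions=dict(portions) if portions is not None else default_portions(foods, categories),
        applies_to=None if applies_to is None else frozenset(applies_to),
    )


def standard_ladder(
    wild_foods: Sequence[FoodItem],
    wild_prices: SeasonalPriceTable,
    mnp: FoodItem | None = None,
    categories: Sequence[str] = CATEGORIES,
    child_categories: Sequence[str] = CHILD_CATEGORIES,
    mnp_daily: bool = False,
) -> list[Intervention]:
    """The full scenario ladder: singles, fruits, vegetables, all six, MNP, MNP+six."""
    ivs = [
        make_intervention(f.name, [f], wild_prices, categories) for f in wild_foods
    ]
    fruits = [f for f in wild_foods if f.category == "wild_fruit"]
    vegetables = [f for f in wild_foods if f.category == "wild_vegetable"]
    if fruits:
        ivs.append(make_intervention("all wild fruits", fruits, wild_prices, categories))
    if vegetables:
        ivs.append(make_intervention("all wild vegetables", vegetables, wild_prices, categories))
    if fruits and vegetables:
        ivs.append(make_intervention("all wild plant foods", list(wild_foods), wild_prices, categories))
    if mnp is not None:
        ivs.append(
            make_intervention("MNP", [mnp], wild_prices, categories,
                              applies_to=child_categories, mnp_daily=mnp_daily)
        )
        if wild_foods:
            ivs.append(
                make_intervention("MNP + all wild plant foods", [*wild_foods, mnp], wild_prices,
                                  categories, applies_to=child_categories, mnp_daily=mnp_daily)
            )
    return ivs


def scenario_report_frame(results: Sequence[ScenarioResult], seasons: Sequence[str] = SEASONS) -> pd.DataFrame:
    """Long-format report: one row per (scenario, category, season)."""
    rows = []
    for res in results:
        for cat in res.categories:
            for season in seasons:
                rows.append(
                    {
                        "scenario": res.name,
                        "category": cat,
                        "season": season,
                        "baseline_kes": _round_half_up(res.baseline_daily[(cat, season)], 1),
                        "scenario_kes": _round_half_up(res.scenario_daily[(cat, season)], 1),
                        "reduction_pct": _round_half_up(res.reduction(cat, season), 1),
                        "avg_reduction_pct": _round_half_up(res.average_reduction(cat, seasons), 1),
                        "meaningful": res.meaningful(cat, seasons),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["scenario", "category", "season", "baseline_kes", "scenario_kes",
                 "reduction_pct", "avg_reduction_pct", "meaningful"],
    )
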