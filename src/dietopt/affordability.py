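"""Affordability of the cheapest nutritious diet for household wealth groups.

The cheapest per-person diet cost (the mean daily cost across the six
woman/child categories and both seasons) is annualized and compared to
each wealth group's food budget — annual income per individual times the
share of income spent on food — and, as a sensitivity, to the entire
income.  Every household member is assumed to cost the same per-person
amount regardless of age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constraint_builder import CATEGORIES
from .food_model import SEASONS, _round_half_up

DAYS_PER_YEAR = 365

WEALTH_GROUP_NAMES: tuple[str, ...] = ("very_poor", "poor", "middle", "better_off")


@dataclass(frozen=True)
class WealthGroup:
    """One household-economy stratum with income and food-expenditure share."""

    name: str
    household_size: float
    annual_income_per_individual: float  # KES
    pct_income_on_food: float

    def __post_init__(self) -> None:
        if self.annual_income_per_individual < 0:
            raise ValueError(f"negative income for wealth group {self.name}")
        if not 0 <= self.pct_income_on_food <= 100:
            raise ValueError(f"food-expenditure share for {self.name} must be in [0, 100]")

    def food_budget(self, use_total_income: bool = False) -> float:
        """Annual KES available for food per individual."""
        if use_total_income:
            return self.annual_income_per_individual
        return self.annual_income_per_individual * self.pct_income_on_food / 100.0


@dataclass(frozen=True)
class AffordabilityResult:
    group: str
    budget: float  # annual KES per individual
    annual_cost: float
    affordable: bool
    shortfall: float  # KES, 0 when affordable


def lacon_daily_cost(
    costs: Mapping[tuple[str, str], float],
    categories: Sequence[str] = CATEGORIES,
    seasons: Sequence[str] = SEASONS,
) -> float:
    """Mean daily cost across every (category, season) cell; all cells required."""
    cells = []
    for cat in categories:
        for season in seasons:
            if (cat, season) not in costs:
                raise KeyError(f"missing diet cost for ({cat!r}, {season!r})")
            cells.append(costs[(cat, season)])
    return float(np.mean(cells))


def annualize(daily: float, days: int = DAYS_PER_YEAR) -> float:
    """Annual cost from a daily cost (365-day year)."""
    return daily * days


def can_afford(
    group: WealthGroup, annual_cost: float, use_total_income: bool = False
) -> AffordabilityResult:
    """Compare an annual per-person diet cost to a group's food budget."""
    if annual_cost < 0:
        raise ValueError("annual cost must be nonnegative")
    budget = group.food_budget(use_total_income)
    return AffordabilityResult(
        group=group.name,
        budget=budget,
        annual_cost=annual_cost,
        affordable=budget >= annual_cost,
        shortfall=max(0.0, annual_cost - budget),
    )


def affordability_report(
    groups: Sequence[WealthGroup], annual_cost: float
) -> pd.DataFrame:
    """Per-group affordability under both budget rules."""
    rows = []
    for group in groups:
        for rule, total in (("food_share", False), ("total_income", True)):
            res = can_afford(group, annual_cost, use_total_income=total)
            rows.append(
                {
                    "group": group.name,
                    "budget_rule": rule,
                    "budget_kes": _round_half_up(res.budget, 1),
                    "annual_cost_kes": _round_half_up(res.annual_cost, 1),
                    "affordable": res.affordable,
                    "shortfall_kes": _round_half_up(res.shortfall, 1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "budget_rule", "budget_kes", "annual_cost_kes", "affordable", "shortfall_kes"],
    )


# ---------------------------------------------------------------------------
# CSV I/O (wealth.csv)


def write_wealth_csv(groups: Sequence[WealthGroup], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "group": g.name,
                "household_size": g.household_size,
                "annual_income_per_individual_kes": g.annual_income_per_individual,
                "pct_income_on_food": g.pct_income_on_food,
            }
            for g in groups
        ]
    ).to_csv(path, index=False)


def load_wealth_csv(path: str | Path) -> list[WealthGroup]:
    df = pd.read_csv(path, dtype={"group": str})
    return [
        WealthGroup(
            name=row.group,
            household_size=float(row.household_size),
            annual_income_per_individual=float(row.annual_income_per_individual_kes),
            pct_income_on_food=float(row.pct_income_on_food),
        )
        for row in df.itertuples()
    ]
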