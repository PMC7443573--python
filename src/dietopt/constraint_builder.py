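"""Weekly intake-frequency bounds, portion sizes, and requirement profiles.

Frequency bounds come from two sources: per-household weekly consumption
counts from a 24-h recall (25th/75th percentiles become min/max), and
focus-group statements.  When the two disagree the recall wins, since it
reflects observed intake.  Wild foods and the micronutrient powder (MNP)
carry fixed programmatic bounds instead: wild foods 1-3 servings/week,
MNP 3-4 sachets/week (or 7/7 in the daily sensitivity mode).

Requirement profiles for the six woman/child categories ship as
documented WHO/FAO-informed defaults and are fully user-replaceable via
``requirements.csv``; calcium and iron requirements are expressed on the
same absorbed basis as the food compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .food_model import FoodItem
from .nutrients import NUTRIENTS, NutrientVector

#: Individual categories modeled (the 1,000-day window).
CATEGORIES: tuple[str, ...] = (
    "child_6_8m",
    "child_9_11m",
    "child_12_23m",
    "woman_NPNL",
    "woman_pregnant",
    "woman_lactating",
)
CHILD_CATEGORIES: tuple[str, ...] = CATEGORIES[:3]
WOMAN_CATEGORIES: tuple[str, ...] = CATEGORIES[3:]

MAX_WEEKLY_SERVINGS = 21  # three servings a day


@dataclass(frozen=True)
class FrequencyBound:
    """Min/max servings of one food per week."""

    food_id: str
    min_per_week: float
    max_per_week: float

    def __post_init__(self) -> None:
        if not 0 <= self.min_per_week <= self.max_per_week:
            raise ValueError(
                f"invalid bound for {self.food_id}: min {self.min_per_week} > max {self.max_per_week}"
            )
        if self.max_per_week > MAX_WEEKLY_SERVINGS:
            raise ValueError(f"bound for {self.food_id} exceeds {MAX_WEEKLY_SERVINGS}/week")


@dataclass(frozen=True)
class PortionSpec:
    """Grams of edible portion per serving of one food for one individual category."""

    food_id: str
    category: str
    grams_per_serving: float

    def __post_init__(self) -> None:
        if self.grams_per_serving <= 0:
            raise ValueError(f"portion for {self.food_id}/{self.category} must be positive")


@dataclass(frozen=True)
class IndividualProfile:
    """Daily recommended intakes for one woman/child category.

    ``energy_band`` multiplies the energy requirement into a hard [lower,
    upper] corridor; all other constrained nutrients are lower bounds.
    """

    category: str
    requirements: NutrientVector
    energy_band: tuple[float, float] = (1.0, 1.1)

    def __post_init__(self) -> None:
        lo, hi = self.energy_band
        if not 0 < lo <= hi:
            raise ValueError(f"invalid energy band {self.energy_band} for {self.category}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# operations


def bounds_from_recall(food_id: str, weekly_counts: Sequence[float]) -> FrequencyBound:
    """Frequency bound at the 25th/75th percentiles of household weekly counts.

    Quantiles use linear interpolation between order statistics, then
    round half-up to whole servings; quantile monotonicity guarantees
    min <= max.
    """
    counts = np.asarray(weekly_counts, dtype=float)
    if counts.size == 0:
        raise ValueError(f"no recall counts for food {food_id!r}")
    if np.any(counts < 0):
        raise ValueError(f"negative recall count for food {food_id!r}")
    lo, hi = np.percentile(counts, [25, 75], method="linear")
    return FrequencyBound(food_id, _round_half_up(float(lo)), _round_half_up(float(hi)))


def reconcile(fgd_bound: FrequencyBound, recall_bound: FrequencyBound) -> FrequencyBound:
    """Resolve FGD vs recall bounds for one food: the recall is preferred."""
    if fgd_bound.food_id != recall_bound.food_id:
        raise ValueError(
            f"cannot reconcile bounds for different foods: {fgd_bound.food_id!r} vs {recall_bound.food_id!r}"
        )
    return recall_bound


def wild_food_bounds(food: FoodItem) -> FrequencyBound:
    """Fixed 1-3 servings/week bound for collected wild vegetables and fruits."""
    if not food.is_wild:
        raise ValueError(f"{food.id} is {food.category}, not a wild food")
    return FrequencyBound(food.id, 1, 3)


def mnp_bounds(food: FoodItem, daily: bool = False) -> FrequencyBound:
    """Sachets/week bound for a micronutrient-powder supplement.

    The distribution program supplied 15 sachets/month, i.e. 3-4 per week;
    ``daily=True`` switches to the one-sachet-a-day sensitivity mode (7/7).
    """
    if not food.is_supplement:
        raise ValueError(f"{food.id} is {food.category}, not a supplement")
    return FrequencyBound(food.id, 7, 7) if daily else FrequencyBound(food.id, 3, 4)


def bounds_from_recall_table(recall: pd.DataFrame) -> dict[str, FrequencyBound]:
    """Per-food bounds from a long-format recall table (household_id, food_id, count_per_week)."""
    out: dict[str, FrequencyBound] = {}
    for food_id, group in recall.groupby("food_id", sort=True):
        out[str(food_id)] = bounds_from_recall(str(food_id), group["count_per_week"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# default requirement profiles
#
# Daily recommended intakes per category, WHO/FAO-informed; calcium and
# iron on the absorbed basis (intake recommendations multiplied by the
# 0.48 / 0.05 bioavailability factors used for compositions).  These are
# defaults for modeling, not clinical guidance, and are replaceable via
# requirements.csv.

_DEFAULT_REQUIREMENTS: dict[str, dict[str, float]] = {
    "child_6_8m": {
        "energy": 615, "protein": 9.1, "fat": 27, "calcium_absorbed": 192,
        "iron_absorbed": 0.93, "zinc": 4.1, "thiamine": 0.3, "riboflavin": 0.4,
        "niacin": 4, "magnesium": 54, "vitamin_c": 30, "retinol_equivalent": 400,
        "folate": 80, "vitamin_b6": 0.3, "vitamin_b12": 0.7, "vitamin_d": 5,
        "vitamin_e": 2.7, "copper": 0.3, "selenium": 10,
    },
    "child_9_11m": {
        "energy": 686, "protein": 9.6, "fat": 28, "calcium_absorbed": 192,
        "iron_absorbed": 0.93, "zinc": 4.1, "thiamine": 0.3, "riboflavin": 0.4,
        "niacin": 4, "magnesium": 54, "vitamin_c": 30, "retinol_equivalent": 400,
        "folate": 80, "vitamin_b6": 0.3, "vitamin_b12": 0.7, "vitamin_d": 5,
        "vitamin_e": 2.7, "copper": 0.3, "selenium": 10,
    },
    "child_12_23m": {
        "energy": 894, "protein": 10.9, "fat": 35, "calcium_absorbed": 240,
        "iron_absorbed": 0.58, "zinc": 4.1, "thiamine": 0.5, "riboflavin": 0.5,
        "niacin": 6, "magnesium": 60, "vitamin_c": 30, "retinol_equivalent": 400,
        "folate": 150, "vitamin_b6": 0.5, "vitamin_b12": 0.9, "vitamin_d": 5,
        "vitamin_e": 5, "copper": 0.56, "selenium": 17,
    },
    "woman_NPNL": {
        "energy": 2240, "protein": 46, "fat": 55, "calcium_absorbed": 480,
        "iron_absorbed": 1.47, "zinc": 4.9, "thiamine": 1.1, "riboflavin": 1.1,
        "niacin": 14, "magnesium": 220, "vitamin_c": 45, "retinol_equivalent": 500,
        "folate": 400, "vitamin_b6": 1.3, "vitamin_b12": 2.4, "vitamin_d": 5,
        "vitamin_e": 7.5, "copper": 1.15, "selenium": 26,
    },
    "woman_pregnant": {
        "energy": 2525, "protein": 71, "fat": 60, "calcium_absorbed": 576,
        "iron_absorbed": 2.0, "zinc": 7.0, "thiamine": 1.4, "riboflavin": 1.4,
        "niacin": 18, "magnesium": 220, "vitamin_c": 55, "retinol_equivalent": 800,
        "folate": 600, "vitamin_b6": 1.9, "vitamin_b12": 2.6, "vitamin_d": 5,
        "vitamin_e": 7.5, "copper": 1.15, "selenium": 28,
    },
    "woman_lactating": {
        "energy": 2730, "protein": 71, "fat": 65, "calcium_absorbed": 480,
        "iron_absorbed": 0.75, "zinc": 9.5, "thiamine": 1.5, "riboflavin": 1.6,
        "niacin": 17, "magnesium": 270, "vitamin_c": 70, "retinol_equivalent": 850,
        "folate": 500, "vitamin_b6": 2.0, "vitamin_b12": 2.8, "vitamin_d": 5,
        "vitamin_e": 7.5, "copper": 1.25, "selenium": 35,
    },
}


def default_profiles(energy_band: tuple[float, float] = (1.0, 1.1)) -> dict[str, IndividualProfile]:
    """The six default woman/child requirement profiles."""
    return {
        cat: IndividualProfile(cat, NutrientVector.from_dict(req), energy_band)
        for cat, req in _DEFAULT_REQUIREMENTS.items()
    }


def load_requirements_csv(
    path: str | Path, energy_band: tuple[float, float] = (1.0, 1.1)
) -> dict[str, IndividualProfile]:
    """Profiles from a long-format ``requirements.csv`` (category, nutrient, daily_amount)."""
    df = pd.read_csv(path, dtype={"category": str, "nutrient": str})
    profiles = {}
    for cat, group in df.groupby("category", sort=True):
        req = dict(zip(group["nutrient"], group["daily_amount"].astype(float)))
        unknown = set(req) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrients in {path}: {sorted(unknown)}")
        profiles[str(cat)] = IndividualProfile(str(cat), NutrientVector.from_dict(req), energy_band)
    return profiles


def write_requirements_csv(profiles: Mapping[str, IndividualProfile], path: str | Path) -> None:
    rows = [
        {"category": cat, "nutrient": n, "daily_amount": prof.requirements.get(n)}
        for cat, prof in sorted(profiles.items())
        for n in NUTRIENTS
        if prof.requirements.is_known(n)
    ]
    pd.DataFrame(rows, columns=["category", "nutrient", "daily_amount"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# default portion sizes
#
# Grams of edible portion per serving, by food category and age class.
# Children eat smaller servings than women; supplements are one 1 g
# sachet per serving.  Replaceable via portions.csv.

_PORTION_BY_FOOD_CATEGORY: dict[str, dict[str, float]] = {
    "market": {"child_6_8m": 50, "child_9_11m": 60, "child_12_23m": 80, "woman": 130},
    "wild_vegetable": {"child_6_8m": 30, "child_9_11m": 40, "child_12_23m": 50, "woman": 100},
    "wild_fruit": {"child_6_8m": 30, "child_9_11m": 40, "child_12_23m": 50, "woman": 100},
    "supplement": {"child_6_8m": 1, "child_9_11m": 1, "child_12_23m": 1, "woman": 1},
}


def default_portion(food: FoodItem, category: str) -> PortionSpec:
    key = category if category in _PORTION_BY_FOOD_CATEGORY[food.category] else "woman"
    grams = _PORTION_BY_FOOD_CATEGORY[food.category][key]
    return PortionSpec(food.id, category, grams)


def default_portions(foods: Iterable[FoodItem], categories: Sequence[str] = CATEGORIES) -> dict[tuple[str, str], PortionSpec]:
    """(category, food_id) -> PortionSpec for every food/category pair."""
    return {(cat, f.id): default_portion(f, cat) for f in foods for cat in categories}


def load_portions_csv(path: str | Path) -> dict[tuple[str, str], PortionSpec]:
    df = pd.read_csv(path, dtype={"category": str, "food_id": str})
    return {
        (row.category, row.food_id): PortionSpec(row.food_id, row.category, float(row.grams))
        for row in df.itertuples()
    }


def write_portions_csv(portions: Mapping[tuple[str, str], PortionSpec], path: str | Path) -> None:
    rows = [
        {"category": cat, "food_id": fid, "grams": spec.grams_per_serving}
        for (cat, fid), spec in sorted(portions.items())
    ]
    pd.DataFrame(rows, columns=["category", "food_id", "grams"]).to_csv(path, index=False)


def write_bounds_csv(bounds: Mapping[str, FrequencyBound], path: str | Path) -> None:
    rows = [
        {"food_id": fid, "min_per_week": b.min_per_week, "max_per_week": b.max_per_week}
        for fid, b in sorted(bounds.items())
    ]
    pd.DataFrame(rows, columns=["food_id", "min_per_week", "max_per_week"]).to_csv(path, index=False)


def load_bounds_csv(path: str | Path) -> dict[str, FrequencyBound]:
    df = pd.read_csv(path, dtype={"food_id": str})
    return {
        row.food_id: FrequencyBound(row.food_id, float(row.min_per_week), float(row.max_per_week))
        for row in df.itertuples()
    }
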