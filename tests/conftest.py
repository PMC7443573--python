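"""Shared builders: tiny hand-checkable diet problems and random LP instances."""

from __future__ import annotations

import numpy as np
import pytest

from dietopt.constraint_builder import FrequencyBound, IndividualProfile, PortionSpec
from dietopt.food_model import SEASONS, FoodItem, SeasonalPriceTable
from dietopt.lp_core import DietData, DietProblem, LPConfig, build_problem
from dietopt.nutrients import MICRO_NUTRIENTS, NutrientVector

TEST_CATEGORY = "test_adult"


def make_profile(requirements: dict[str, float], band: tuple[float, float] = (1.0, 1.1)) -> IndividualProfile:
    return IndividualProfile(TEST_CATEGORY, NutrientVector.from_dict(requirements), band)


def make_data(food_specs: list[dict], season: str = "plenty") -> DietData:
    """DietData from shorthand specs.

    Each spec: id, price (KES/100 g), comp (per 100 g), bounds (lo, hi);
    optional category, portion grams (default 100 so per-serving ==
    per-100 g numbers).
    """
    foods, prices, portions, bounds = [], SeasonalPriceTable(), {}, {}
    for spec in food_specs:
        food = FoodItem(
            id=spec["id"],
            name=spec.get("name", spec["id"]),
            category=spec.get("category", "market"),
            composition=NutrientVector.from_dict(spec["comp"]),
        )
        foods.append(food)
        for s in SEASONS:
            prices.set(food.id, s, spec.get("price", 0.0))
        grams = spec.get("portion", 100.0)
        portions[(TEST_CATEGORY, food.id)] = PortionSpec(food.id, TEST_CATEGORY, grams)
        lo, hi = spec.get("bounds", (0, 21))
        bounds[food.id] = FrequencyBound(food.id, lo, hi)
    return DietData(foods=foods, prices=prices, portions=portions, bounds=bounds)


def make_problem(
    food_specs: list[dict],
    requirements: dict[str, float],
    band: tuple[float, float] = (1.0, 1.1),
    config: LPConfig | None = None,
) -> DietProblem:
    data = make_data(food_specs)
    profile = make_profile(requirements, band)
    return build_problem(profile, "plenty", data, config or LPConfig(energy_band=band))


def random_problem(rng: np.random.Generator, hard_energy: bool = True) -> DietProblem:
    """Random <=5-food instance sized for the brute-force oracle.

    With ``hard_energy`` the instance carries the usual two-sided energy
    band (and sometimes a protein floor); without it only elastic
    micronutrient rows remain, so rounding any point up to the next
    serving grid point is always feasible and the grid optimum provably
    lies within one serving's cost of the continuous optimum.
    """
    n_foods = int(rng.integers(1, 6))
    micros = list(rng.choice(MICRO_NUTRIENTS, size=int(rng.integers(1, 4)), replace=False))
    specs = []
    energies = rng.uniform(50, 500, n_foods)
    for j in range(n_foods):
        comp = {"energy": energies[j], "protein": rng.uniform(0, 20)}
        for m in micros:
            comp[m] = rng.uniform(0, 2)
        specs.append(
            {
                "id": f"f{j}",
                "price": rng.uniform(0.5, 10),
                "comp": comp,
                "bounds": (0, int(rng.integers(1, 8))),
            }
        )
    req = {}
    hi_mult = 1.1
    if hard_energy:
        total_max_energy = sum(s["comp"]["energy"] * s["bounds"][1] for s in specs)
        weekly_energy = rng.uniform(0.2, 0.6) * total_max_energy
        hi_mult = 1.0 + sum(s["comp"]["energy"] for s in specs) / weekly_energy + 0.05
        req["energy"] = weekly_energy / 7.0
        max_protein = sum(s["comp"]["protein"] * s["bounds"][1] for s in specs)
        if rng.random() < 0.5 and max_protein > 0:
            req["protein"] = rng.uniform(0.1, 0.7) * max_protein / 7.0
    for m in micros:
        max_m = sum(s["comp"][m] * s["bounds"][1] for s in specs)
        req[m] = rng.uniform(0.3, 1.5) * max(max_m, 0.1) / 7.0
    return make_problem(specs, req, band=(1.0, hi_mult))


@pytest.fixture
def two_food_energy_problem() -> DietProblem:
    """Foods A (10 KES, 100 kcal) and B (5 KES, 100 kcal), weekly energy 700 kcal."""
    return make_problem(
        [
            {"id": "A", "price": 10.0, "comp": {"energy": 100.0}, "bounds": (0, 21)},
            {"id": "B", "price": 5.0, "comp": {"energy": 100.0}, "bounds": (0, 21)},
        ],
        {"energy": 100.0},
        band=(1.0, 1.1),
    )
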