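"""Synthetic inputs: market survey, recall counts, and engineered LP instances.

Two kinds of synthetic data are produced:

``generate_market`` / ``generate_recall`` emulate the *shape* of a
two-season, multi-village market survey (four traders per village, two
weighed price observations streams per season) and a 180-household 24-h
recall, with controllable lean-season price inflation and controllable
scarcity of the gap nutrients (iron, zinc).  They are distributional:
realistic-looking, deterministic under a fixed seed, but with no closed
form for the optimum.

``engineered_gap_instance`` instead *constructs* a tiny baseline food
set whose least-cost diet provably leaves iron and zinc at a configured
fraction of the requirement, plus a cheap nutrient-dense wild vegetable
whose inclusion closes both gaps and changes the optimal cost by an
exactly configured percentage.  The analytic optimum of both LPs is
recorded alongside the generated files, so the whole pipeline (price
aggregation -> bounds -> LP -> scenario comparison) can be checked
against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constraint_builder import (
    IndividualProfile,
    PortionSpec,
    default_portions,
    default_profiles,
    write_portions_csv,
    write_requirements_csv,
)
from .food_model import (
    SEASONS,
    FoodItem,
    PriceObservation,
    SeasonalPriceTable,
    aggregate_prices,
    write_foods_csv,
    write_prices_csv,
)
from .lp_core import DAYS_PER_WEEK, DietData
from .nutrients import NutrientVector
from .scenarios import Intervention, make_intervention

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SyntheticConfig:
    """Controls for the synthetic market/recall generators.

    Defaults mirror the surveyed setting: 56 market foods, six villages,
    four traders per village, two seasons, 180 recall households, and a
    20% lean-season price mark-up.  ``gap_severity`` scales down the
    iron/zinc content of market foods so baseline diets run short of the
    gap nutrients.
    """

    seed: int = 0
    n_foods: int = 56
    n_villages: int = 6
    n_traders_per_village: int = 4
    n_households: int = 180
    lean_inflation: float = 1.2
    lean_spread: float = 0.08  # relative trader-level jitter on the lean factor
    price_noise_sd: float = 0.05  # per-observation log-noise
    base_price_sd: float = 0.3  # per-food log-spread around the group price
    gap_nutrients: tuple[str, ...] = ("iron_absorbed", "zinc")
    gap_severity: float = 0.4

    def __post_init__(self) -> None:
        if self.lean_inflation <= 1:
            raise ValueError("lean_inflation must exceed 1")
        if not 0 <= self.gap_severity < 1:
            raise ValueError("gap_severity must be in [0, 1)")
        if self.lean_inflation * (1 - self.lean_spread) <= 1:
            raise ValueError("lean_spread too wide: lean prices could drop below plenty prices")


# food-group templates: composition per 100 g, KES/100 g price level, and the
# zero-inflated Poisson (zero probability, rate) for weekly recall counts.
_GROUP_TEMPLATES: dict[str, dict] = {
    "staple_grain": dict(
        share=0.15, price=6.0, zero_p=0.35, rate=4.0,
        composition=dict(energy=360, protein=9, fat=2, calcium_absorbed=15,
                         iron_absorbed=0.18, zinc=2.0, thiamine=0.3, riboflavin=0.1,
                         niacin=3.0, magnesium=120, folate=25, vitamin_b6=0.3,
                         vitamin_e=0.5, copper=0.3, selenium=10),
    ),
    "legume": dict(
        share=0.15, price=10.0, zero_p=0.5, rate=2.0,
        composition=dict(energy=340, protein=22, fat=1.5, calcium_absorbed=40,
                         iron_absorbed=0.3, zinc=3.0, thiamine=0.5, riboflavin=0.2,
                         niacin=2.0, magnesium=150, folate=400, vitamin_b6=0.4,
                         vitamin_e=0.5, copper=0.8, selenium=8),
    ),
    "vegetable": dict(
        share=0.20, price=8.0, zero_p=0.4, rate=3.0,
        composition=dict(energy=35, protein=2, fat=0.3, calcium_absorbed=60,
                         iron_absorbed=0.1, zinc=0.5, thiamine=0.07, riboflavin=0.1,
                         niacin=0.6, magnesium=30, vitamin_c=25, retinol_equivalent=170,
                         folate=60, vitamin_b6=0.15, vitamin_e=0.8, copper=0.1, selenium=1),
    ),
    "oil": dict(
        share=0.07, price=18.0, zero_p=0.4, rate=2.0,
        composition=dict(energy=884, fat=100, vitamin_e=15),
    ),
    "animal": dict(
        share=0.18, price=45.0, zero_p=0.5, rate=1.5,
        composition=dict(energy=150, protein=15, fat=8, calcium_absorbed=55,
                         iron_absorbed=0.1, zinc=3.0, riboflavin=0.2, niacin=4.0,
                         magnesium=20, retinol_equivalent=30, vitamin_b12=2.0,
                         vitamin_d=1.0, copper=0.1, selenium=15),
    ),
    "sugar": dict(
        share=0.07, price=10.0, zero_p=0.3, rate=4.0,
        composition=dict(energy=390),
    ),
    "misc": dict(
        share=0.18, price=5.0, zero_p=0.6, rate=2.0,
        composition=dict(energy=80, protein=1.5, fat=0.5, magnesium=15,
                         vitamin_c=5, folate=10),
    ),
}

_PACK_WEIGHTS_G = (100.0, 250.0, 500.0, 1000.0)


def _allocate_counts(n_foods: int) -> dict[str, int]:
    """Largest-remainder allocation of foods to groups by template share."""
    shares = {g: t["share"] * n_foods for g, t in _GROUP_TEMPLATES.items()}
    counts = {g: int(np.floor(v)) for g, v in shares.items()}
    remainder = n_foods - sum(counts.values())
    by_frac = sorted(shares, key=lambda g: shares[g] - counts[g], reverse=True)
    for g in by_frac[:remainder]:
        counts[g] += 1
    return counts


# ---------------------------------------------------------------------------
# market survey


def generate_market(config: SyntheticConfig) -> tuple[list[FoodItem], list[PriceObservation]]:
    """Synthetic market food list and weighed seasonal price observations.

    Per-food base prices are drawn log-normally (mean-preserving) around
    the group level; each trader's lean price is their plenty price times
    ``lean_inflation`` with a bounded jitter, so every lean price strictly
    exceeds the plenty price.
    """
    rng = np.random.default_rng(config.seed)
    counts = _allocate_counts(config.n_foods)

    foods: list[FoodItem] = []
    base_price: dict[str, float] = {}
    for group, n in counts.items():
        template = _GROUP_TEMPLATES[group]
        for i in range(n):
            fid = f"{group}_{i:02d}"
            jitter = np.exp(rng.normal(0, 0.2))
            comp = {}
            for nutrient, value in template["composition"].items():
                v = value * jitter * np.exp(rng.normal(0, 0.15))
                if nutrient in config.gap_nutrients:
                    v *= 1 - config.gap_severity
                comp[nutrient] = v
            foods.append(
                FoodItem(id=fid, name=fid.replace("_", " "), category="market",
                         composition=NutrientVector.from_dict(comp))
            )
            base_price[fid] = template["price"] * np.exp(
                rng.normal(0, config.base_price_sd) - config.base_price_sd**2 / 2
            )

    observations: list[PriceObservation] = []
    for food in foods:
        for v in range(config.n_villages):
            village = f"village_{v}"
            for trader in range(config.n_traders_per_village):
                weight = float(rng.choice(_PACK_WEIGHTS_G))
                noise = np.exp(rng.normal(0, config.price_noise_sd) - config.price_noise_sd**2 / 2)
                plenty_per_100g = base_price[food.id] * noise
                lean_factor = config.lean_inflation * (
                    1 + rng.uniform(-config.lean_spread, config.lean_spread)
                )
                for season, per_100g in (
                    ("plenty", plenty_per_100g),
                    ("lean", plenty_per_100g * lean_factor),
                ):
                    observations.append(
                        PriceObservation(
                            food_id=food.id, village=village, trader=trader,
                            season=season, price=per_100g * weight / 100.0, weight=weight,
                        )
                    )
    return foods, observations


def _recall_params_for(food: FoodItem) -> tuple[float, float]:
    for group, template in _GROUP_TEMPLATES.items():
        if food.id.startswith(group):
            return template["zero_p"], template["rate"]
    return 0.4, 3.0


def generate_recall(config: SyntheticConfig, foods: Sequence[FoodItem]) -> pd.DataFrame:
    """Per-household weekly consumption counts (zero-inflated Poisson, capped at 21).

    Only market foods appear: wild foods and fruits are absent from
    baseline consumption, matching a setting where no fruit intake is
    recorded.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for household in range(config.n_households):
        hid = f"hh_{household:03d}"
        for food in foods:
            if food.category != "market":
                continue
            zero_p, rate = _recall_params_for(food)
            count = 0 if rng.random() < zero_p else min(int(rng.poisson(rate)), 21)
            rows.append({"household_id": hid, "food_id": food.id, "count_per_week": count})
    return pd.DataFrame(rows, columns=["household_id", "food_id", "count_per_week"])


# ---------------------------------------------------------------------------
# engineered instance with analytic ground truth


@dataclass
class EngineeredInstance:
    """A constructed pipeline input bundle plus the analytic optima of its LPs."""

    category: str
    profile: IndividualProfile
    foods: list[FoodItem]
    observations: list[PriceObservation]
    recall: pd.DataFrame
    portions: dict[tuple[str, str], PortionSpec]
    vegetable_intervention: Intervention
    fruit_intervention: Intervention | None
    truth: dict = field(default_factory=dict)

    @property
    def data(self) -> DietData:
        from .constraint_builder import bounds_from_recall_table

        return DietData(
            foods=list(self.foods),
            prices=aggregate_prices(self.observations),
            portions=dict(self.portions),
            bounds=bounds_from_recall_table(self.recall),
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_foods_csv(self.foods, outdir / "foods.csv")
        write_prices_csv(self.observations, outdir / "prices.csv")
        self.recall.to_csv(outdir / "recall.csv", index=False)
        write_requirements_csv({self.category: self.profile}, outdir / "requirements.csv")
        write_portions_csv(self.portions, outdir / "portions.csv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def engineered_gap_instance(
    config: SyntheticConfig,
    reduction_pct: float = -45.0,
    category: str = "child_12_23m",
    include_fruit: bool = True,
    fruit_price_kes_per_100g: float = 50.0,
) -> EngineeredInstance:
    """Construct a baseline with a provable iron/zinc gap and a wild vegetable
    whose inclusion closes the gap and changes cost by exactly ``reduction_pct``.

    The baseline holds four foods: a fortified staple (sole energy source;
    covers protein, fat, and every micronutrient except iron and zinc), a
    costly iron/zinc relish capped at 7 servings/week that can supply only
    ``1 - gap_severity`` of both weekly requirements, a dominated distractor,
    and nothing else.  The least-cost baseline therefore takes the staple at
    exactly the energy floor, the relish at its cap, and leaves an iron/zinc
    deficit of exactly ``gap_severity``.  The added wild vegetable covers the
    full iron/zinc requirement at 3 servings/week; its price is fixed and the
    relish price is solved so that swapping relish for vegetable moves the
    optimal cost by the configured percentage.  Jitters (seeded) vary the
    staple's price, energy density, and the vegetable's energy across seeds
    without touching the analytic optimum.
    """
    if not -100.0 < reduction_pct <= 0.0:
        raise ValueError("configured reduction_pct must lie in (-100, 0]")
    sev = config.gap_severity
    r = -reduction_pct / 100.0  # magnitude of the relative cost reduction
    rng = np.random.default_rng(config.seed + 2)
    profile = default_profiles()[category]
    req = profile.requirements
    energy_wk = req.get("energy") * DAYS_PER_WEEK
    protein_wk = req.get("protein") * DAYS_PER_WEEK
    fat_wk = req.get("fat") * DAYS_PER_WEEK
    iron_wk = req.get("iron_absorbed") * DAYS_PER_WEEK
    zinc_wk = req.get("zinc") * DAYS_PER_WEEK

    # staple: 14 servings meet the weekly energy floor exactly
    staple_servings = 14.0
    energy_per_100g = rng.uniform(400, 500)
    staple_grams = 100.0 * energy_wk / (staple_servings * energy_per_100g)
    staple_price_100g = rng.uniform(4, 6)
    staple_cost_serving = staple_price_100g * staple_grams / 100.0
    energy_per_serving = energy_wk / staple_servings
    # macros and non-gap micros sized to stay covered down to 13 staple servings
    staple_comp = {"energy": energy_per_100g,
                   "protein": (protein_wk / 13.0) * 100.0 / staple_grams,
                   "fat": (fat_wk / 13.0) * 100.0 / staple_grams}
    for nutrient in ("calcium_absorbed", "thiamine", "riboflavin", "niacin", "magnesium",
                     "vitamin_c", "retinol_equivalent", "folate", "vitamin_b6",
                     "vitamin_b12", "vitamin_d", "vitamin_e", "copper", "selenium"):
        daily = req.get(nutrient)
        if np.isfinite(daily) and daily > 0:
            staple_comp[nutrient] = (daily * DAYS_PER_WEEK / 13.0) * 100.0 / staple_grams

    # vegetable: closes both gaps at its 3-servings/week cap
    veg_price_100g = 7.8
    veg_energy_100g = rng.uniform(50, 90)
    veg_cost_serving = veg_price_100g  # 100 g portion
    delta_energy = 3 * veg_energy_100g * staple_cost_serving / energy_per_serving
    staple_weekly_cost = staple_servings * staple_cost_serving

    # relish price solved so the vegetable swap yields the configured reduction
    relish_cap = 7.0
    relish_cost_serving = (r * staple_weekly_cost + 3 * veg_cost_serving - delta_energy) / (
        relish_cap * (1 - r)
    )
    if relish_cost_serving <= 0:
        raise ValueError(
            f"cannot construct instance: reduction {reduction_pct}% needs a nonpositive relish price"
        )

    foods = [
        FoodItem("staple", "fortified staple flour", "market",
                 NutrientVector.from_dict(staple_comp)),
        FoodItem("relish", "dried iron-zinc relish", "market",
                 NutrientVector.from_dict({
                     "protein": 10.0,
                     "iron_absorbed": (1 - sev) * iron_wk / relish_cap,
                     "zinc": (1 - sev) * zinc_wk / relish_cap,
                 })),
        FoodItem("distractor", "herbal infusion", "market",
                 NutrientVector.from_dict({"vitamin_c": 30.0})),
    ]
    vegetable = FoodItem("gap_vegetable", "synthetic wild vegetable", "wild_vegetable",
                         NutrientVector.from_dict({
                             "energy": veg_energy_100g, "protein": 3.0, "fat": 0.3,
                             "iron_absorbed": iron_wk / 3.0, "zinc": zinc_wk / 3.0,
                             "vitamin_c": 20.0,
                         }))

    prices_100g = {"staple": staple_price_100g, "relish": relish_cost_serving, "distractor": 20.0}
    observations = [
        PriceObservation(fid, f"village_{v}", t, season,
                         price=prices_100g[fid] * 2.5, weight=250.0)
        for fid in prices_100g
        for season in SEASONS
        for v, t in ((0, 0), (0, 1), (1, 0))
    ]
    # recall counts whose 25th/75th percentiles give (0, 21), (0, 7), (0, 5)
    recall_patterns = {"staple": (0, 21), "relish": (0, relish_cap), "distractor": (0, 5)}
    recall_rows = [
        {"household_id": f"hh_{i}", "food_id": fid, "count_per_week": lo if i < 3 else hi}
        for fid, (lo, hi) in recall_patterns.items()
        for i in range(6)
    ]
    recall = pd.DataFrame(recall_rows, columns=["household_id", "food_id", "count_per_week"])

    portions = {
        (category, "staple"): PortionSpec("staple", category, staple_grams),
        (category, "relish"): PortionSpec("relish", category, 100.0),
        (category, "distractor"): PortionSpec("distractor", category, 100.0),
    }

    veg_prices = SeasonalPriceTable()
    for season in SEASONS:
        veg_prices.set(vegetable.id, season, veg_price_100g)
    veg_iv = make_intervention(
        "engineered wild vegetable", [vegetable], veg_prices, categories=[category],
        portions={(category, vegetable.id): PortionSpec(vegetable.id, category, 100.0)},
    )

    fruit_iv = None
    truth_fruit = {}
    if include_fruit:
        fruit_energy_100g = rng.uniform(250, 320)
        fruit = FoodItem("forced_fruit", "synthetic expensive wild fruit", "wild_fruit",
                         NutrientVector.from_dict({"energy": fruit_energy_100g,
                                                   "vitamin_c": 40.0}))
        fruit_prices = SeasonalPriceTable()
        for season in SEASONS:
            fruit_prices.set(fruit.id, season, fruit_price_kes_per_100g)
        fruit_iv = make_intervention(
            "engineered forced fruit", [fruit], fruit_prices, categories=[category],
            portions={(category, fruit.id): PortionSpec(fruit.id, category, 100.0)},
        )
        fruit_net = fruit_price_kes_per_100g - fruit_energy_100g * staple_cost_serving / energy_per_serving
        if fruit_net <= 0:
            raise ValueError("forced fruit is not net-expensive; raise its price")

    baseline_weekly = staple_weekly_cost + relish_cap * relish_cost_serving
    veg_weekly = staple_weekly_cost - delta_energy + 3 * veg_cost_serving
    truth = {
        "category": category,
        "gap_severity": sev,
        "baseline_weekly_cost_kes": baseline_weekly,
        "baseline_daily_cost_kes": baseline_weekly / DAYS_PER_WEEK,
        "vegetable_weekly_cost_kes": veg_weekly,
        "vegetable_daily_cost_kes": veg_weekly / DAYS_PER_WEEK,
        "vegetable_reduction_pct": 100.0 * (veg_weekly - baseline_weekly) / baseline_weekly,
        "adequacy_before_pct": {n: (1 - sev) * 100.0 for n in ("iron_absorbed", "zinc")},
        "adequacy_after_pct": {n: 100.0 for n in ("iron_absorbed", "zinc")},
    }
    if include_fruit:
        fruit_weekly = baseline_weekly + fruit_net
        truth_fruit = {
            "fruit_weekly_cost_kes": fruit_weekly,
            "fruit_daily_cost_kes": fruit_weekly / DAYS_PER_WEEK,
            "fruit_reduction_pct": 100.0 * (fruit_weekly - baseline_weekly) / baseline_weekly,
        }
    truth.update(truth_fruit)
    # sanity: the configured reduction is reproduced by the closed-form costs
    assert abs(truth["vegetable_reduction_pct"] - reduction_pct) < 1e-9

    return EngineeredInstance(
        category=category,
        profile=profile,
        foods=foods,
        observations=observations,
        recall=recall,
        portions=portions,
        vegetable_intervention=veg_iv,
        fruit_intervention=fruit_iv,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle writer


def generate_bundle(config: SyntheticConfig, outdir: str | Path) -> None:
    """Write a complete synthetic input bundle (foods, prices, recall,
    requirements, portions) to ``outdir``; byte-identical under a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    foods, observations = generate_market(config)
    write_foods_csv(foods, outdir / "foods.csv")
    write_prices_csv(observations, outdir / "prices.csv")
    generate_recall(config, foods).to_csv(outdir / "recall.csv", index=False)
    profiles = default_profiles()
    write_requirements_csv(profiles, outdir / "requirements.csv")
    write_portions_csv(default_portions(foods), outdir / "portions.csv")
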