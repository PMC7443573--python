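"""Foods, nutrient-composition conversions, and market-price aggregation.

Market surveys record the price paid and the edible weight obtained for
each food, trader, village, and season.  This module aggregates those
observations to a seasonal price per 100 g edible portion, and performs
the fixed composition conversions used throughout:

* absorbed calcium  = raw calcium x 0.48
* absorbed iron     = raw iron    x 0.05
* retinol equivalent = beta-carotene / 12

Wild (collected) foods have no market price; an opportunity-cost price is
assigned by averaging the market prices of comparable purchased foods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .nutrients import NUTRIENTS, UNITS, NutrientVector

#: Market seasons with distinct price tables.
SEASONS: tuple[str, str] = ("plenty", "lean")

#: Food categories.
FOOD_CATEGORIES: tuple[str, ...] = ("market", "wild_vegetable", "wild_fruit", "supplement")
WILD_CATEGORIES: frozenset[str] = frozenset({"wild_vegetable", "wild_fruit"})

CALCIUM_ABSORPTION = 0.48
IRON_ABSORPTION = 0.05
BETA_CAROTENE_PER_RE = 12.0

#: CSV column name per nutrient (with unit suffix), in canonical order.
NUTRIENT_COLUMNS: dict[str, str] = {n: f"{n}_{UNITS[n]}" for n in NUTRIENTS}


class MissingPriceError(KeyError):
    """A (food, season) pair has no price observation or table entry."""


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style half-up rounding (symmetric about zero); NaN passes through."""
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FoodItem:
    """A purchasable or collectable food.

    ``composition`` is per 100 g edible fresh portion for market and wild
    foods, and per 1 g sachet for supplements.
    """

    id: str
    name: str
    category: str
    composition: NutrientVector
    season_availability: frozenset[str] = frozenset(SEASONS)

    def __post_init__(self) -> None:
        if self.category not in FOOD_CATEGORIES:
            raise ValueError(f"unknown food category {self.category!r} for {self.id}")
        object.__setattr__(self, "season_availability", frozenset(self.season_availability))
        bad = self.season_availability - set(SEASONS)
        if bad:
            raise ValueError(f"unknown seasons {sorted(bad)} for food {self.id}")

    @property
    def is_wild(self) -> bool:
        return self.category in WILD_CATEGORIES

    @property
    def is_supplement(self) -> bool:
        return self.category == "supplement"


@dataclass(frozen=True)
class PriceObservation:
    """One weighed market purchase: ``price`` KES paid for ``weight`` g edible portion."""

    food_id: str
    village: str
    trader: int
    season: str
    price: float
    weight: float

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.price < 0:
            raise ValueError(f"negative price for {self.food_id}")
        if self.weight <= 0:
            raise ValueError(f"non-positive weight for {self.food_id}")

    @property
    def price_per_100g(self) -> float:
        return 100.0 * self.price / self.weight


@dataclass
class SeasonalPriceTable:
    """(food_id, season) -> KES per 100 g edible portion."""

    prices: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, food_id: str, season: str) -> float:
        try:
            return self.prices[(food_id, season)]
        except KeyError:
            raise MissingPriceError(f"no price for food {food_id!r} in season {season!r}") from None

    def set(self, food_id: str, season: str, price: float) -> None:
        if price < 0:
            raise ValueError(f"negative price for {food_id}/{season}")
        self.prices[(food_id, season)] = float(price)

    def scaled(self, k: float) -> "SeasonalPriceTable":
        return SeasonalPriceTable({key: p * k for key, p in self.prices.items()})

    def merged(self, other: "SeasonalPriceTable") -> "SeasonalPriceTable":
        out = dict(self.prices)
        out.update(other.prices)
        return SeasonalPriceTable(out)


# ---------------------------------------------------------------------------
# operations


def aggregate_prices(observations: Sequence[PriceObservation]) -> SeasonalPriceTable:
    """Average per-100 g prices of the observations within each (food, season).

    Each observation contributes ``100 * price / weight``; groups are pooled
    with a simple (unweighted) arithmetic mean across villages and traders.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for obs in observations:
        groups.setdefault((obs.food_id, obs.season), []).append(obs.price_per_100g)
    table = SeasonalPriceTable()
    for (food_id, season), values in groups.items():
        table.set(food_id, season, float(np.mean(values)))
    return table


def _convert(raw: float | None, factor: float, what: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return float("nan")
    if raw < 0:
        raise ValueError(f"negative raw {what}: {raw}")
    return raw * factor


def absorbed_calcium(raw_mg: float | None) -> float:
    """Absorbed calcium (mg) from raw calcium, at 48% bioavailability."""
    return _convert(raw_mg, CALCIUM_ABSORPTION, "calcium")


def absorbed_iron(raw_mg: float | None) -> float:
    """Absorbed iron (mg) from raw iron, at 5% bioavailability."""
    return _convert(raw_mg, IRON_ABSORPTION, "iron")


def beta_carotene_to_re(beta_carotene_ug: float | None) -> float:
    """Retinol equivalents (ug RE) from beta-carotene at the 12:1 ratio."""
    return _convert(beta_carotene_ug, 1.0 / BETA_CAROTENE_PER_RE, "beta-carotene")


def opportunity_cost_price(proxy_prices: Sequence[float]) -> float:
    """Opportunity-cost price of a collected food: mean of market proxies, to 0.1 KES."""
    if len(proxy_prices) == 0:
        raise ValueError("opportunity_cost_price needs at least one proxy price")
    return _round_half_up(float(np.mean(proxy_prices)), 1)


# ---------------------------------------------------------------------------
# CSV I/O  (foods.csv / prices.csv)


def foods_to_frame(foods: Iterable[FoodItem]) -> pd.DataFrame:
    rows = []
    for f in foods:
        row: dict[str, object] = {
            "id": f.id,
            "name": f.name,
            "category": f.category,
            "season_availability": ";".join(s for s in SEASONS if s in f.season_availability),
        }
        for nutrient, col in NUTRIENT_COLUMNS.items():
            v = f.composition.get(nutrient)
            row[col] = "" if np.isnan(v) else v
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "name", "category", "season_availability", *NUTRIENT_COLUMNS.values()])


def write_foods_csv(foods: Iterable[FoodItem], path: str | Path) -> None:
    foods_to_frame(foods).to_csv(path, index=False)


def load_foods_csv(path: str | Path) -> list[FoodItem]:
    """Read ``foods.csv``; empty composition cells become unknown (NaN)."""
    df = pd.read_csv(path, dtype={"id": str, "name": str})
    foods = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        fid = str(row["id"])
        if fid in seen:
            raise ValueError(f"duplicate food id {fid!r} in {path}")
        seen.add(fid)
        comp = {n: _parse_cell(row.get(col)) for n, col in NUTRIENT_COLUMNS.items()}
        avail = str(row.get("season_availability", "")) or ";".join(SEASONS)
        foods.append(
            FoodItem(
                id=fid,
                name=str(row["name"]),
                category=str(row["category"]),
                composition=NutrientVector.from_dict(comp),
                season_availability=frozenset(s for s in avail.split(";") if s),
            )
        )
    return foods


def _parse_cell(value: object) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"n/a", "na", "nan"}:
        return None
    return float(s)


def write_prices_csv(observations: Iterable[PriceObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "food_id": o.food_id,
                "village": o.village,
                "trader": o.trader,
                "season": o.season,
                "price_kes": o.price,
                "weight_g": o.weight,
            }
            for o in observations
        ],
        columns=["food_id", "village", "trader", "season", "price_kes", "weight_g"],
    )
    df.to_csv(path, index=False)


def load_prices_csv(path: str | Path) -> list[PriceObservation]:
    df = pd.read_csv(path, dtype={"food_id": str, "village": str})
    return [
        PriceObservation(
            food_id=row.food_id,
            village=row.village,
            trader=int(row.trader),
            season=row.season,
            price=float(row.price_kes),
            weight=float(row.weight_g),
        )
        for row in df.itertuples()
    ]


def price_table_to_frame(table: SeasonalPriceTable) -> pd.DataFrame:
    rows = [
        {"food_id": food_id, "season": season, "price_kes_per_100g": price}
        for (food_id, season), price in sorted(table.prices.items())
    ]
    return pd.DataFrame(rows, columns=["food_id", "season", "price_kes_per_100g"])


# currency display -----------------------------------------------------------

DEFAULT_KES_PER_USD = 103.6


def kes_to_usd(kes: float, rate: float = DEFAULT_KES_PER_USD) -> float:
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return kes / rate
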