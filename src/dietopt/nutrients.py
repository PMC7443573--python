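"""Nutrient vocabulary and the NutrientVector container.

All compositions are expressed per 100 g edible fresh portion, except
supplements (per 1 g sachet).  Requirement profiles use the same nutrient
slots but are per day.  Calcium and iron are carried on an *absorbed*
basis (raw survey values are converted with fixed bioavailability factors
before they enter a vector); vitamin A is carried as retinol equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Canonical nutrient order used by every matrix in the package.
NUTRIENTS: tuple[str, ...] = (
    "energy",
    "protein",
    "fat",
    "calcium_absorbed",
    "iron_absorbed",
    "zinc",
    "thiamine",
    "riboflavin",
    "niacin",
    "magnesium",
    "vitamin_c",
    "retinol_equivalent",
    "folate",
    "vitamin_b6",
    "vitamin_b12",
    "vitamin_d",
    "vitamin_e",
    "copper",
    "selenium",
)

#: Display / CSV units per nutrient.
UNITS: dict[str, str] = {
    "energy": "kcal",
    "protein": "g",
    "fat": "g",
    "calcium_absorbed": "mg",
    "iron_absorbed": "mg",
    "zinc": "mg",
    "thiamine": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "magnesium": "mg",
    "vitamin_c": "mg",
    "retinol_equivalent": "ug",
    "folate": "ug",
    "vitamin_b6": "mg",
    "vitamin_b12": "ug",
    "vitamin_d": "ug",
    "vitamin_e": "mg",
    "copper": "mg",
    "selenium": "ug",
}

#: Macronutrients handled as hard LP constraints (energy banded, protein/fat lower-bounded).
MACRO_NUTRIENTS: tuple[str, ...] = ("energy", "protein", "fat")

#: Micronutrients handled elastically (deficit variables) in the LP.
MICRO_NUTRIENTS: tuple[str, ...] = tuple(n for n in NUTRIENTS if n not in MACRO_NUTRIENTS)

_INDEX = {name: i for i, name in enumerate(NUTRIENTS)}


def nutrient_index(name: str) -> int:
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown nutrient {name!r}; valid names: {', '.join(NUTRIENTS)}") from None


@dataclass(frozen=True)
class NutrientVector:
    """Quantities for every nutrient slot; NaN marks an unknown (unmeasured) value.

    Unknown values are preserved through arithmetic and only coerced to zero
    when an LP matrix is assembled (a food is never credited with a nutrient
    nobody measured).
    """

    values: np.ndarray = field(default_factory=lambda: np.full(len(NUTRIENTS), np.nan))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(NUTRIENTS),):
            raise ValueError(f"expected {len(NUTRIENTS)} nutrient slots, got shape {arr.shape}")
        if np.any(arr[~np.isnan(arr)] < 0):
            bad = [NUTRIENTS[i] for i in np.where(arr < 0)[0]]
            raise ValueError(f"negative nutrient quantities for: {', '.join(bad)}")
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_dict(cls, quantities: Mapping[str, float | None]) -> "NutrientVector":
        arr = np.full(len(NUTRIENTS), np.nan)
        for name, value in quantities.items():
            arr[nutrient_index(name)] = np.nan if value is None else float(value)
        return cls(arr)

    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls(np.zeros(len(NUTRIENTS)))

    def get(self, name: str) -> float:
        """Value for one nutrient; NaN if unknown."""
        return float(self.values[nutrient_index(name)])

    def is_known(self, name: str) -> bool:
        return not np.isnan(self.values[nutrient_index(name)])

    @property
    def unknown_nutrients(self) -> tuple[str, ...]:
        return tuple(NUTRIENTS[i] for i in np.where(np.isnan(self.values))[0])

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Dense array with unknowns replaced by ``fill`` (LP-build coercion)."""
        return np.nan_to_num(self.values, nan=fill)

    def scaled(self, k: float) -> "NutrientVector":
        return NutrientVector(self.values * k)

    def to_dict(self, skip_unknown: bool = False) -> dict[str, float]:
        out = {}
        for i, name in enumerate(NUTRIENTS):
            v = self.values[i]
            if skip_unknown and np.isnan(v):
                continue
            out[name] = float(v)
        return out


def iter_known(vector: NutrientVector) -> Iterable[tuple[str, float]]:
    for name in NUTRIENTS:
        if vector.is_known(name):
            yield name, vector.get(name)
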