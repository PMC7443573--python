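"""Reference inputs from the Turkana County (northern Kenya) case study.

These are the published survey-derived quantities the package's worked
example and reproduction checks run on: nutrient compositions of the six
selected wild plant foods (per 100 g edible fresh portion, calcium and
iron already on the absorbed basis, vitamin A as retinol equivalents),
the 1 g micronutrient-powder sachet formulation, the opportunity-cost
prices assigned to collected wild foods, the four household-economy
wealth groups, and the modeled baseline daily diet costs per individual
category and season together with the season-averaged percent cost
reductions of each intervention scenario.

Missing composition values (not measured in the literature the food
entries were compiled from) are stored as unknown and contribute nothing
to any diet optimization.
"""

from __future__ import annotations

from .affordability import WealthGroup
from .food_model import SEASONS, FoodItem, SeasonalPriceTable, absorbed_iron
from .nutrients import NutrientVector

# ---------------------------------------------------------------------------
# wild plant foods (composition per 100 g edible fresh portion)

_WILD_FOOD_ROWS: list[dict] = [
    dict(
        id="amaranthus_hybridus", name="Amaranth", category="wild_vegetable",
        energy=80.31, protein=6.30, fat=0.50, calcium_absorbed=265.44,
        iron_absorbed=0.55, zinc=5.08, thiamine=0.45, riboflavin=0.70,
        niacin=0.25, magnesium=329.00, vitamin_c=11.16, retinol_equivalent=436.67,
    ),
    dict(
        id="solanum_americanum", name="American nightshade", category="wild_vegetable",
        energy=50.33, protein=1.61, fat=2.86, calcium_absorbed=337.21,
        iron_absorbed=4.90, zinc=1.47, magnesium=30.01,
    ),
    dict(
        id="celosia_argentea", name="Celosia", category="wild_vegetable",
        protein=4.71, fat=1.00, calcium_absorbed=77.92,
        iron_absorbed=0.70, zinc=6.61, magnesium=36.14,
    ),
    dict(
        id="sterculia_africana", name="African-star chestnut", category="wild_fruit",
        energy=287.52, protein=23.83, fat=6.55, calcium_absorbed=46.67,
        iron_absorbed=0.63, zinc=5.50, magnesium=172.77, vitamin_c=4.85,
    ),
    dict(
        id="berchemia_discolor", name="Wild almond", category="wild_fruit",
        energy=266.20, protein=0.99, fat=2.80, calcium_absorbed=9.00,
        iron_absorbed=8.75, zinc=0.89, magnesium=1250.00, vitamin_c=59.43,
        retinol_equivalent=33.71,
    ),
    dict(
        id="grewia_tenax", name="White crossberry", category="wild_fruit",
        energy=322.68, protein=4.50, fat=6.80, calcium_absorbed=900.00,
        iron_absorbed=6.25, zinc=1.65, magnesium=1250.00, vitamin_c=161.09,
        retinol_equivalent=116.67,
    ),
]

#: Opportunity-cost prices for collected wild foods, KES per 100 g edible portion.
WILD_FRUIT_PRICE_KES = 7.7
WILD_VEGETABLE_PRICE_KES = 7.8


def wild_foods() -> list[FoodItem]:
    """The three wild vegetables and three wild fruits selected for modeling."""
    items = []
    for row in _WILD_FOOD_ROWS:
        comp = {k: v for k, v in row.items() if k not in ("id", "name", "category")}
        items.append(
            FoodItem(
                id=row["id"],
                name=row["name"],
                category=row["category"],
                composition=NutrientVector.from_dict(comp),
            )
        )
    return items


def wild_food_prices() -> SeasonalPriceTable:
    """Opportunity-cost price table for the wild foods, identical across seasons."""
    table = SeasonalPriceTable()
    for row in _WILD_FOOD_ROWS:
        price = WILD_VEGETABLE_PRICE_KES if row["category"] == "wild_vegetable" else WILD_FRUIT_PRICE_KES
        for season in SEASONS:
            table.set(row["id"], season, price)
    return table


# ---------------------------------------------------------------------------
# micronutrient powder (per 1 g sachet; iron converted to the absorbed basis
# with the same 5% bioavailability factor used for food compositions)

MNP_SACHET_IRON_MG = 10.0


def mnp() -> FoodItem:
    """The 1 g micronutrient-powder sachet distributed to children 6-59 months."""
    return FoodItem(
        id="mnp_sachet",
        name="Micronutrient powder (1 g sachet)",
        category="supplement",
        composition=NutrientVector.from_dict(
            {
                "retinol_equivalent": 400,
                "vitamin_d": 5,
                "vitamin_e": 5,
                "vitamin_c": 30,
                "thiamine": 0.5,
                "riboflavin": 0.5,
                "niacin": 6,
                "vitamin_b6": 0.5,
                "vitamin_b12": 0.9,
                "folate": 150,
                "iron_absorbed": absorbed_iron(MNP_SACHET_IRON_MG),
                "zinc": 4.1,
                "copper": 0.56,
                "selenium": 17,
            }
        ),
    )


# ---------------------------------------------------------------------------
# household-economy wealth groups (Loima sub-county)


def wealth_groups() -> list[WealthGroup]:
    return [
        WealthGroup("very_poor", 7, 11786, 68),
        WealthGroup("poor", 7, 14286, 55),
        WealthGroup("middle", 8, 21875, 50),
        WealthGroup("better_off", 13, 21154, 38),
    ]


# ---------------------------------------------------------------------------
# modeled baseline daily diet costs (KES/day) per category and season, and
# season-averaged percent cost reductions per intervention scenario

#: (category) -> {season -> baseline daily cost KES}
BASELINE_DAILY_COST_KES: dict[str, dict[str, float]] = {
    "child_6_8m": {"plenty": 50.0, "lean": 59.4},
    "child_9_11m": {"plenty": 65.5, "lean": 82.3},
    "child_12_23m": {"plenty": 101.5, "lean": 119.0},
    "woman_NPNL": {"plenty": 173.1, "lean": 226.3},
    "woman_pregnant": {"plenty": 247.8, "lean": 304.7},
    "woman_lactating": {"plenty": 210.3, "lean": 244.9},
}

#: Season-averaged % reduction in daily diet cost per scenario (None = scenario
#: not run for that category; the MNP program covered children only).
SCENARIO_REDUCTION_PCT: dict[str, dict[str, float | None]] = {
    "child_6_8m": {
        "grewia_tenax": -0.3, "berchemia_discolor": 0.0, "sterculia_africana": -0.2,
        "all_wild_fruits": -27.2, "amaranthus_hybridus": 10.9, "celosia_argentea": 20.2,
        "solanum_americanum": 3.0, "all_wild_vegetables": -71.4,
        "all_wild_plant_foods": -70.3, "mnp": 0.0,
    },
    "child_9_11m": {
        "grewia_tenax": -19.0, "berchemia_discolor": -12.0, "sterculia_africana": -19.0,
        "all_wild_fruits": -35.2, "amaranthus_hybridus": -8.2, "celosia_argentea": -6.7,
        "solanum_americanum": -27.7, "all_wild_vegetables": -66.1,
        "all_wild_plant_foods": -66.4, "mnp": 0.0,
    },
    "child_12_23m": {
        "grewia_tenax": -65.2, "berchemia_discolor": -56.4, "sterculia_africana": -33.6,
        "all_wild_fruits": -69.2, "amaranthus_hybridus": -62.6, "celosia_argentea": -60.0,
        "solanum_americanum": -66.0, "all_wild_vegetables": -67.6,
        "all_wild_plant_foods": -68.9, "mnp": -0.6,
    },
    "woman_NPNL": {
        "grewia_tenax": -26.2, "berchemia_discolor": -30.3, "sterculia_africana": -10.5,
        "all_wild_fruits": -16.3, "amaranthus_hybridus": -8.7, "celosia_argentea": 3.9,
        "solanum_americanum": -28.6, "all_wild_vegetables": -29.8,
        "all_wild_plant_foods": -22.8, "mnp": None,
    },
    "woman_pregnant": {
        "grewia_tenax": -44.9, "berchemia_discolor": -46.0, "sterculia_africana": -12.5,
        "all_wild_fruits": -40.5, "amaranthus_hybridus": -21.2, "celosia_argentea": -34.0,
        "solanum_americanum": -46.7, "all_wild_vegetables": -45.3,
        "all_wild_plant_foods": -36.0, "mnp": None,
    },
    "woman_lactating": {
        "grewia_tenax": -31.3, "berchemia_discolor": -32.6, "sterculia_africana": -2.5,
        "all_wild_fruits": -27.1, "amaranthus_hybridus": -15.2, "celosia_argentea": -24.8,
        "solanum_americanum": -33.3, "all_wild_vegetables": -31.6,
        "all_wild_plant_foods": -22.6, "mnp": None,
    },
}

#: Published annual per-person cost of the cheapest diet (with the three wild
#: vegetables), KES and USD.
PUBLISHED_ANNUAL_COST_KES = 31295
PUBLISHED_ANNUAL_COST_USD = 302
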