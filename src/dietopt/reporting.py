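"""Run configuration, pipeline drivers, and publication-style tables.

The drivers here glue the modules into the three shell-level workflows:
optimize the baseline diets per (category, season), run the intervention
scenario ladder, and assess affordability.  Tables are plain UTF-8 CSV;
costs round to 0.1 KES and percentages to 0.1, with meaningful cost
reductions (>= 25% in both seasons) marked with a trailing ``*``.
Regenerating a report from the same results directory is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import turkana
from .affordability import affordability_report, annualize, lacon_daily_cost, load_wealth_csv
from .constraint_builder import (
    CATEGORIES,
    bounds_from_recall_table,
    default_portion,
    load_portions_csv,
    load_requirements_csv,
)
from .food_model import (
    DEFAULT_KES_PER_USD,
    SEASONS,
    _round_half_up,
    aggregate_prices,
    load_foods_csv,
    load_prices_csv,
)
from .lp_core import DietData, LPConfig, build_problem, solve
from .scenarios import ScenarioResult, run_ladder, scenario_report_frame, standard_ladder


@dataclass
class RunConfig:
    """File paths and model knobs for one pipeline run (YAML-loadable)."""

    foods_csv: str = "foods.csv"
    prices_csv: str = "prices.csv"
    recall_csv: str = "recall.csv"
    requirements_csv: str = "requirements.csv"
    portions_csv: str = "portions.csv"
    wealth_csv: str = "wealth.csv"
    exchange_rate: float = DEFAULT_KES_PER_USD
    energy_band: tuple[float, float] = (1.0, 1.1)
    penalty_factor: float = 1e6
    mnp_daily: bool = False
    seed: int = 0
    outdir: str = "results"

    def lp_config(self) -> LPConfig:
        return LPConfig(energy_band=tuple(self.energy_band), penalty_factor=self.penalty_factor)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        if "energy_band" in raw:
            raw["energy_band"] = tuple(raw["energy_band"])
        return cls(**raw)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file missing: {path}")
    return path


def load_diet_data(data_dir: str | Path, config: RunConfig | None = None):
    """Load a full input bundle from a directory; returns (DietData, profiles)."""
    config = config or RunConfig()
    data_dir = Path(data_dir)
    foods = load_foods_csv(_require(data_dir / config.foods_csv))
    observations = load_prices_csv(_require(data_dir / config.prices_csv))
    recall = pd.read_csv(_require(data_dir / config.recall_csv), dtype={"food_id": str})
    profiles = load_requirements_csv(
        _require(data_dir / config.requirements_csv), energy_band=tuple(config.energy_band)
    )
    portions_path = data_dir / config.portions_csv
    portions = load_portions_csv(portions_path) if portions_path.exists() else {}
    for food in foods:
        for cat in profiles:
            portions.setdefault((cat, food.id), default_portion(food, cat))
    data = DietData(
        foods=foods,
        prices=aggregate_prices(observations),
        portions=portions,
        bounds=bounds_from_recall_table(recall),
    )
    return data, profiles


# ---------------------------------------------------------------------------
# drivers


def run_optimize(data_dir: str | Path, outdir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Solve the baseline diet per (category, season); write solutions and a summary."""
    config = config or RunConfig()
    data, profiles = load_diet_data(data_dir, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cat in sorted(profiles, key=_category_sort):
        for season in SEASONS:
            sol = solve(build_problem(profiles[cat], season, data, config.lp_config()))
            sol.to_json(outdir / f"solution_{cat}_{season}.json")
            rows.append(
                {
                    "category": cat,
                    "season": season,
                    "daily_cost_kes": _round_half_up(sol.daily_cost, 1),
                    "daily_cost_usd": _round_half_up(sol.daily_cost / config.exchange_rate, 2),
                    "status": sol.status,
                }
            )
    summary = pd.DataFrame(rows, columns=["category", "season", "daily_cost_kes", "daily_cost_usd", "status"])
    summary.to_csv(outdir / "summary.csv", index=False)
    return summary


def run_scenario_ladder(
    data_dir: str | Path, outdir: str | Path, config: RunConfig | None = None
) -> list[ScenarioResult]:
    """Run the wild-food / MNP scenario ladder on a data bundle; write the report."""
    config = config or RunConfig()
    data, profiles = load_diet_data(data_dir, config)
    interventions = standard_ladder(
        turkana.wild_foods(),
        turkana.wild_food_prices(),
        mnp=turkana.mnp(),
        categories=list(profiles),
        child_categories=[c for c in profiles if c.startswith("child")],
        mnp_daily=config.mnp_daily,
    )
    results = run_ladder(data, interventions, profiles, SEASONS, config.lp_config())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario_report_frame(results).to_csv(outdir / "scenario_report.csv", index=False)
    reduction_matrix_from_report(pd.read_csv(outdir / "scenario_report.csv")).to_csv(
        outdir / "reduction_matrix.csv", index=False
    )
    return results


def run_affordability(
    scenario_report: str | Path,
    wealth_csv: str | Path,
    outdir: str | Path,
    scenario: str = "all wild vegetables",
) -> pd.DataFrame:
    """Annualize one scenario's mean daily cost and test it against wealth budgets."""
    report = pd.read_csv(_require(Path(scenario_report)))
    sub = report[report["scenario"] == scenario]
    if sub.empty:
        raise ValueError(f"scenario {scenario!r} not present in {scenario_report}")
    costs = {
        (row.category, row.season): float(row.scenario_kes) for row in sub.itertuples()
    }
    categories = sorted({c for c, _ in costs}, key=_category_sort)
    daily = lacon_daily_cost(costs, categories=categories)
    annual = annualize(daily)
    groups = load_wealth_csv(_require(Path(wealth_csv)))
    table = affordability_report(groups, annual)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "affordability_report.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# tables


def _category_sort(cat: str) -> tuple[int, str]:
    try:
        return (CATEGORIES.index(cat), cat)
    except ValueError:
        return (len(CATEGORIES), cat)


def reduction_matrix_from_report(report: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix: per category, seasonal baseline costs and one season-averaged
    reduction column per scenario, meaningful reductions marked with ``*``."""
    if report.empty:
        return pd.DataFrame(columns=["category", "cost_plenty_kes", "cost_lean_kes"])
    categories = sorted(report["category"].unique(), key=_category_sort)
    scenarios = list(dict.fromkeys(report["scenario"]))
    rows = []
    for cat in categories:
        sub = report[report["category"] == cat]
        row: dict[str, object] = {"category": cat}
        for season in SEASONS:
            cell = sub[sub["season"] == season]
            row[f"cost_{season}_kes"] = cell["baseline_kes"].iloc[0] if len(cell) else ""
        for scen in scenarios:
            cell = sub[sub["scenario"] == scen]
            if cell.empty:
                row[scen] = ""
            else:
                value = float(cell["avg_reduction_pct"].iloc[0])
                flag = "*" if bool(cell["meaningful"].iloc[0]) else ""
                row[scen] = f"{value:.1f}{flag}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["category", "cost_plenty_kes", "cost_lean_kes", *scenarios])


def adequacy_table(
    results: Sequence[ScenarioResult],
    nutrients: Sequence[str] = ("iron_absorbed", "zinc"),
    seasons: Sequence[str] = SEASONS,
) -> pd.DataFrame:
    """Season-averaged percent of requirements met, before and after each scenario."""
    rows = []
    for res in results:
        for cat in res.categories:
            for nutrient in nutrients:
                before = [res.baseline_adequacy[(cat, s)].get(nutrient) for s in seasons]
                after = [res.scenario_adequacy[(cat, s)].get(nutrient) for s in seasons]
                if any(v is None for v in before + after):
                    continue
                rows.append(
                    {
                        "scenario": res.name,
                        "category": cat,
                        "nutrient": nutrient,
                        "baseline_pct": _round_half_up(sum(before) / len(before), 1),
                        "scenario_pct": _round_half_up(sum(after) / len(after), 1),
                    }
                )
    return pd.DataFrame(rows, columns=["scenario", "category", "nutrient", "baseline_pct", "scenario_pct"])
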