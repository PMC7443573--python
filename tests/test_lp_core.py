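"""Elastic least-cost LP: hand-solved instances, oracle agreement, directional laws."""

import numpy as np
import pytest

from dietopt.lp_core import (
    STATUS_INFEASIBLE_BOUNDS,
    STATUS_OPTIMAL,
    STATUS_OPTIMAL_WITH_DEFICIT,
    adequacy,
    brute_force_oracle,
    build_problem,
    solve,
)
from tests.conftest import make_data, make_problem, make_profile, random_problem


class TestHandSolvedInstances:
    def test_cheapest_energy_source_fills_the_diet(self, two_food_energy_problem):
        # energy floor 700 kcal/week, B half the price of A -> all-B diet
        sol = solve(two_food_energy_problem)
        assert sol.status == STATUS_OPTIMAL
        assert sol.servings_per_week["B"] == pytest.approx(7.0)
        assert sol.servings_per_week["A"] == pytest.approx(0.0, abs=1e-9)
        assert sol.weekly_cost == pytest.approx(35.0)
        assert sol.daily_cost == pytest.approx(5.0)

    def test_capped_cheap_food_forces_expensive_remainder(self):
        sol = solve(
            make_problem(
                [
                    {"id": "A", "price": 10.0, "comp": {"energy": 100.0}, "bounds": (0, 21)},
                    {"id": "B", "price": 5.0, "comp": {"energy": 100.0}, "bounds": (0, 3)},
                ],
                {"energy": 100.0},
            )
        )
        assert sol.servings_per_week["B"] == pytest.approx(3.0)
        assert sol.servings_per_week["A"] == pytest.approx(4.0)
        assert sol.weekly_cost == pytest.approx(55.0)

    def test_unreachable_micronutrient_reports_deficit(self):
        sol = solve(
            make_problem(
                [{"id": "A", "price": 1.0, "comp": {"energy": 100.0, "iron_absorbed": 0.1},
                  "bounds": (0, 21)}],
                {"energy": 100.0, "iron_absorbed": 1.0},
            )
        )
        assert sol.status == STATUS_OPTIMAL_WITH_DEFICIT
        assert sol.adequacy["iron_absorbed"] < 100
        assert sol.deficits["iron_absorbed"] > 0
        # deficit minimization outranks cost: servings pushed to the energy ceiling
        assert sol.servings_per_week["A"] == pytest.approx(7.7)

    def test_forced_minimums_above_energy_ceiling_are_infeasible(self):
        sol = solve(
            make_problem(
                [{"id": "A", "price": 1.0, "comp": {"energy": 100.0}, "bounds": (10, 21)}],
                {"energy": 100.0},  # ceiling 770 kcal < forced 1000 kcal
            )
        )
        assert sol.status == STATUS_INFEASIBLE_BOUNDS
        assert "energy upper band" in sol.violated_constraint
        assert np.isnan(sol.weekly_cost)

    def test_unreachable_energy_floor_is_infeasible(self):
        sol = solve(
            make_problem(
                [{"id": "A", "price": 1.0, "comp": {"energy": 10.0}, "bounds": (0, 3)}],
                {"energy": 100.0},
            )
        )
        assert sol.status == STATUS_INFEASIBLE_BOUNDS
        assert "energy lower band" in sol.violated_constraint


class TestProblemAssembly:
    def test_missing_portion_and_bound_are_named(self):
        data = make_data([{"id": "A", "price": 1.0, "comp": {"energy": 100.0}}])
        profile = make_profile({"energy": 100.0})
        del data.portions[("test_adult", "A")]
        with pytest.raises(ValueError, match="portion.*'A'"):
            build_problem(profile, "plenty", data)
        data2 = make_data([{"id": "A", "price": 1.0, "comp": {"energy": 100.0}}])
        del data2.bounds["A"]
        with pytest.raises(ValueError, match="bound.*'A'"):
            build_problem(profile, "plenty", data2)

    def test_supplement_is_free_and_dosed_per_sachet(self):
        specs = [
            {"id": "A", "price": 5.0, "comp": {"energy": 100.0}, "bounds": (0, 21)},
            {"id": "S", "price": 99.0, "comp": {"zinc": 4.1}, "bounds": (3, 4),
             "category": "supplement", "portion": 1.0},
        ]
        problem = make_problem(specs, {"energy": 100.0, "zinc": 1.0})
        j = problem.food_ids.index("S")
        assert problem.cost_per_serving[j] == 0.0
        # per-serving zinc equals the per-sachet amount, not per-100 g scaling
        assert problem.supply_per_serving[5, j] == pytest.approx(4.1)

    def test_unknown_composition_contributes_nothing(self):
        problem = make_problem(
            [{"id": "A", "price": 1.0, "comp": {"energy": 100.0}, "bounds": (0, 21)}],
            {"energy": 100.0, "zinc": 1.0},
        )
        assert problem.supply_per_serving[5].sum() == 0.0
        assert problem.incomplete_composition_foods() == ["A"]


class TestAdequacy:
    def test_adequacy_scale_and_uncapped(self):
        sol = solve(
            make_problem(
                [{"id": "A", "price": 1.0,
                  "comp": {"energy": 100.0, "iron_absorbed": 1.0, "zinc": 10.0},
                  "bounds": (7, 7)}],
                {"energy": 100.0, "iron_absorbed": 1.0, "zinc": 2.0},
            )
        )
        assert sol.adequacy["iron_absorbed"] == pytest.approx(100.0)
        assert sol.adequacy["zinc"] == pytest.approx(500.0)  # uncapped surplus
        rounded = adequacy(sol)
        assert rounded["zinc"] == 500

    def test_half_supplied_reports_half(self):
        sol = solve(
            make_problem(
                [{"id": "A", "price": 1.0, "comp": {"energy": 100.0, "iron_absorbed": 0.48},
                  "bounds": (0, 7)}],
                {"energy": 100.0, "iron_absorbed": 1.0},
                band=(1.0, 1.0),
            )
        )
        assert sol.adequacy["iron_absorbed"] == pytest.approx(48.0)


class TestOracleAgreement:
    def test_two_food_example_matches_oracle(self):
        problem = make_problem(
            [
                {"id": "A", "price": 10.0, "comp": {"energy": 100.0}, "bounds": (0, 7)},
                {"id": "B", "price": 5.0, "comp": {"energy": 100.0}, "bounds": (0, 7)},
            ],
            {"energy": 100.0},
        )
        lp = solve(problem)
        grid = brute_force_oracle(problem, grid_step=1.0)
        assert grid.status == lp.status == STATUS_OPTIMAL
        assert lp.weekly_cost == pytest.approx(35.0)
        assert grid.weekly_cost == pytest.approx(lp.weekly_cost)

    def test_infeasible_instance_agrees(self):
        problem = make_problem(
            [{"id": "A", "price": 1.0, "comp": {"energy": 100.0}, "bounds": (10, 14)}],
            {"energy": 100.0},
        )
        assert solve(problem).status == brute_force_oracle(problem).status == STATUS_INFEASIBLE_BOUNDS

    def test_all_foods_forced_instance_matches_exactly(self):
        # box degenerate to a point: LP and enumeration see the same diet
        problem = make_problem(
            [
                {"id": "A", "price": 3.0, "comp": {"energy": 100.0, "zinc": 0.5}, "bounds": (4, 4)},
                {"id": "B", "price": 2.0, "comp": {"energy": 100.0, "zinc": 1.0}, "bounds": (3, 3)},
            ],
            {"energy": 100.0, "zinc": 1.0},
        )
        lp, grid = solve(problem), brute_force_oracle(problem)
        assert lp.weekly_cost == pytest.approx(grid.weekly_cost, rel=1e-6)
        assert lp.status == grid.status

    def test_oracle_refuses_large_instances(self):
        problem = make_problem(
            [{"id": f"f{i}", "price": 1.0, "comp": {"energy": 100.0}, "bounds": (0, 21)}
             for i in range(6)],
            {"energy": 100.0},
        )
        with pytest.raises(ValueError, match="refuses"):
            brute_force_oracle(problem)

    def test_random_instances_match_within_grid_resolution(self):
        # without hard macro rows, rounding the LP optimum up to the next grid
        # point is always feasible, costs at most one serving per food, and
        # cannot create deficits -> two-sided grid-resolution bound
        rng = np.random.default_rng(20240601)
        matched = 0
        for _ in range(60):
            problem = random_problem(rng, hard_energy=False)
            lp = solve(problem)
            grid = brute_force_oracle(problem, grid_step=1.0)
            assert grid.status == lp.status
            slack = float(problem.cost_per_serving.sum()) + 1e-6

            def objective(sol):
                return sol.weekly_cost + problem.penalty * sum(sol.deficits.values())

            assert objective(lp) <= objective(grid) + 1e-7
            assert objective(grid) - objective(lp) <= slack
            if lp.status == STATUS_OPTIMAL:
                assert abs(grid.weekly_cost - lp.weekly_cost) <= slack
            matched += 1
        assert matched == 60

    def test_random_banded_instances_grid_never_beats_lp(self):
        # with the hard energy band the grid is a subset of the continuum: the
        # grid label can only be equally or more pessimistic, and the grid
        # objective can never undercut the LP optimum
        rank = {STATUS_OPTIMAL: 0, STATUS_OPTIMAL_WITH_DEFICIT: 1, STATUS_INFEASIBLE_BOUNDS: 2}
        rng = np.random.default_rng(20240602)
        seen = set()
        for _ in range(60):
            problem = random_problem(rng, hard_energy=True)
            lp = solve(problem)
            grid = brute_force_oracle(problem, grid_step=1.0)
            assert rank[grid.status] >= rank[lp.status]
            seen.add(lp.status)
            if STATUS_INFEASIBLE_BOUNDS in (lp.status, grid.status):
                continue

            def objective(sol):
                return sol.weekly_cost + problem.penalty * sum(sol.deficits.values())

            assert objective(lp) <= objective(grid) + 1e-7
        assert len(seen) >= 2  # the sample exercises more than one outcome


class TestDirectionalLaws:
    def _specs(self, rng):
        n = int(rng.integers(2, 5))
        return [
            {
                "id": f"f{j}",
                "price": float(rng.uniform(1, 10)),
                "comp": {"energy": float(rng.uniform(80, 400)),
                         "iron_absorbed": float(rng.uniform(0, 1))},
                "bounds": (0, int(rng.integers(3, 10))),
            }
            for j in range(n)
        ]

    def _req(self, specs, rng):
        total = sum(s["comp"]["energy"] * s["bounds"][1] for s in specs)
        return {"energy": float(rng.uniform(0.2, 0.5)) * total / 7.0,
                "iron_absorbed": float(rng.uniform(0.1, 1.0))}

    def test_free_addition_never_raises_cost(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            base = solve(make_problem(specs, req))
            extra = {"id": "extra", "price": float(rng.uniform(0.5, 20)),
                     "comp": {"energy": float(rng.uniform(50, 500)),
                              "iron_absorbed": float(rng.uniform(0, 2))},
                     "bounds": (0, 5)}
            augmented = solve(make_problem(specs + [extra], req))
            # deficit minimization outranks cost: the new food may buy down a
            # shortfall for money, but never worsens (deficit, cost) in that order
            base_deficit = sum(base.deficits.values())
            aug_deficit = sum(augmented.deficits.values())
            assert aug_deficit <= base_deficit + 1e-6
            if abs(aug_deficit - base_deficit) <= 1e-6:
                assert augmented.weekly_cost <= base.weekly_cost + 1e-6

    def test_free_addition_never_raises_cost_when_baseline_adequate(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            req["iron_absorbed"] = 0.0  # drop the scarce nutrient: baseline is adequate
            req = {k: v for k, v in req.items() if v > 0}
            base = solve(make_problem(specs, req))
            assert base.status == STATUS_OPTIMAL
            extra = {"id": "extra", "price": float(rng.uniform(0.5, 20)),
                     "comp": {"energy": float(rng.uniform(50, 500))}, "bounds": (0, 5)}
            augmented = solve(make_problem(specs + [extra], req))
            assert augmented.weekly_cost <= base.weekly_cost + 1e-6

    def test_zero_price_supplement_never_raises_cost(self):
        rng = np.random.default_rng(11)
        for forced_min in (0, 3):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            base = solve(make_problem(specs, req))
            supplement = {"id": "mnp", "price": 50.0, "category": "supplement", "portion": 1.0,
                          "comp": {"iron_absorbed": 10.0}, "bounds": (forced_min, forced_min + 1)}
            augmented = solve(make_problem(specs + [supplement], req))
            assert augmented.weekly_cost <= base.weekly_cost + 1e-6

    def test_forced_expensive_food_raises_cost(self):
        specs = [{"id": "staple", "price": 2.0, "comp": {"energy": 400.0}, "bounds": (0, 21)}]
        req = {"energy": 400.0}
        base = solve(make_problem(specs, req))
        pricey = {"id": "pricey", "price": 60.0, "comp": {"energy": 50.0}, "bounds": (1, 3)}
        forced = solve(make_problem(specs + [pricey], req))
        assert forced.weekly_cost > base.weekly_cost

    def test_uniform_price_scaling_scales_cost_exactly(self):
        rng = np.random.default_rng(13)
        for k in (0.5, 2.0, 7.3):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            base = solve(make_problem(specs, req))
            scaled_specs = [dict(s, price=s["price"] * k) for s in specs]
            scaled = solve(make_problem(scaled_specs, req))
            assert scaled.weekly_cost == pytest.approx(k * base.weekly_cost, rel=1e-7)
            for fid, v in base.servings_per_week.items():
                assert scaled.servings_per_week[fid] == pytest.approx(v, abs=1e-6)

    def test_raising_every_price_weakly_raises_cost(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            base = solve(make_problem(specs, req))
            lean_specs = [dict(s, price=s["price"] * float(rng.uniform(1.05, 1.4)))
                          for s in specs]
            lean = solve(make_problem(lean_specs, req))
            assert lean.weekly_cost >= base.weekly_cost - 1e-6

    def test_tightening_bounds_never_lowers_cost(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            specs = self._specs(rng)
            req = self._req(specs, rng)
            base = solve(make_problem(specs, req))
            tightened = [dict(s, bounds=(s["bounds"][0], max(1, s["bounds"][1] - 1)))
                         for s in specs]
            tight = solve(make_problem(tightened, req))
            if tight.status != STATUS_INFEASIBLE_BOUNDS and tight.deficits == base.deficits:
                assert tight.weekly_cost >= base.weekly_cost - 1e-6
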