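"""Exact integer optimization, oracle agreement and diagnostics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dietopt import (
    Bound,
    DietSolution,
    FoodCategory,
    FoodDatabase,
    FoodItem,
    GroupConstraints,
    ItemCaps,
    NutrientConstraints,
    NutrientProfile,
    ProblemSpec,
    SupplementScenario,
    binding_report,
    brute_force,
    build_problem,
    check_solution,
    compare_scenarios,
    diagnose_infeasibility,
    generate_small_instance,
    optimize,
)
from dietopt.food_db import ALL_CATEGORIES
from dietopt.nutrients import NUTRIENTS


def _free_nutrients(**bounds):
    """All-nutrient constraint set, unconstrained except the given codes."""
    full = {c: Bound(0.0, None) for c in NUTRIENTS}
    for code, b in bounds.items():
        full[code] = b
    return NutrientConstraints(full)


def _free_groups(**bounds):
    full = {c: Bound(0.0, None) for c in ALL_CATEGORIES}
    for code, b in bounds.items():
        full[FoodCategory(code)] = b
    return GroupConstraints(full)


def _item(item_id, category, price, **amounts):
    return FoodItem(item_id, item_id, category, NutrientProfile(amounts), price)


class TestOptimize:
    def test_unique_feasible_point(self):
        """A single item whose 1 serving exactly meets a pinned bound."""
        db = FoodDatabase([_item("only", FoodCategory.FISH, 1.25, iron_mg=20.0)])
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(iron_mg=Bound(20, 20)),
            group_constraints=_free_groups(),
            item_caps=ItemCaps(default=2.0, by_category={}),
            granularity=0.5,
        )
        sol = optimize(problem)
        assert sol.is_optimal
        assert sol.servings == {"only": 1.0}
        assert sol.total_cost == pytest.approx(1.25)

    def test_two_item_hand_computed_optimum(self):
        """iron >= 12 from A (10 mg, price 1.0) and B (4 mg, price 0.6):
        the cheapest half-serving combination is A x 1 + B x 0.5."""
        db = FoodDatabase(
            [
                _item("A", FoodCategory.MEAT, 1.0, iron_mg=10.0),
                _item("B", FoodCategory.LEGUMES, 0.6, iron_mg=4.0),
            ]
        )
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(iron_mg=Bound(12, None)),
            group_constraints=_free_groups(),
            item_caps=ItemCaps(default=2.0, by_category={}),
        )
        sol = optimize(problem)
        assert sol.is_optimal
        assert sol.total_cost == pytest.approx(1.3)
        assert sol.servings == {"A": 1.0, "B": 0.5}
        assert brute_force(problem).servings == sol.servings

    def test_pigeonhole_infeasibility(self, tiny_db):
        """Iron demand above the capped total supply is infeasible."""
        caps = ItemCaps(default=2.0, by_category={})
        max_iron = sum(2.0 * item.profile["iron_mg"] for item in tiny_db)
        problem = ProblemSpec(
            db=tiny_db,
            nutrient_constraints=_free_nutrients(iron_mg=Bound(max_iron + 1, None)),
            group_constraints=_free_groups(),
            item_caps=caps,
        )
        assert optimize(problem).status == "infeasible"
        assert brute_force(problem).status == "infeasible"

    def test_solutions_are_granularity_multiples_and_feasible(self, small_db):
        problem = build_problem(small_db, 2)
        sol = optimize(problem, refine_ties=False)
        assert sol.is_optimal
        assert check_solution(sol, problem)
        for s in sol.servings.values():
            assert abs(s / 0.5 - round(s / 0.5)) < 1e-9

    def test_price_scaling_preserves_servings_and_scales_cost(self):
        problem = generate_small_instance(11)
        base = optimize(problem)
        lam = 3.7
        scaled_db = FoodDatabase(
            [replace(item, price=lam * item.price) for item in problem.db]
        )
        scaled = optimize(replace(problem, db=scaled_db))
        assert base.status == scaled.status
        if base.is_optimal:
            assert scaled.total_cost == pytest.approx(lam * base.total_cost, rel=1e-9)
            assert scaled.servings == base.servings

    def test_determinism_bit_identical(self):
        for seed in (3, 5):  # one feasible, one infeasible instance
            problem = generate_small_instance(seed)
            a, b = optimize(problem), optimize(problem)
            assert a.status == b.status
            assert a.servings == b.servings
            if a.is_optimal:
                assert a.total_cost == b.total_cost

    def test_relaxation_monotonicity_lower_bound(self):
        """Dropping a binding lower bound never increases the optimal cost."""
        for seed in range(6):
            problem = generate_small_instance(seed)
            base = optimize(problem, refine_ties=False)
            if not base.is_optimal:
                continue
            for code in NUTRIENTS:
                b = problem.nutrient_constraints[code]
                if b.lower <= 0:
                    continue
                relaxed = replace(
                    problem,
                    nutrient_constraints=problem.nutrient_constraints.replace(
                        **{code: Bound(0.0, b.upper)}
                    ),
                )
                sol = optimize(relaxed, refine_ties=False)
                assert sol.is_optimal
                assert sol.total_cost <= base.total_cost + 1e-9


class TestBruteForce:
    def test_one_item_enumerates_three_candidates(self):
        db = FoodDatabase([_item("x", FoodCategory.SUGAR, 0.1, carb_g=5.0)])
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(carb_g=Bound(9, None)),
            group_constraints=_free_groups(),
            item_caps=ItemCaps(default=2.0, by_category={}),
            granularity=1.0,
        )
        sol = brute_force(problem)  # k in {0,1,2}: need 2 servings
        assert sol.servings == {"x": 2.0}

    def test_guard_refuses_oversized_search(self, default_db):
        problem = build_problem(default_db, 2)
        with pytest.raises(ValueError, match="exceeds guard"):
            brute_force(problem, guard=10**4)

    def test_oracle_agreement_sample(self):
        """Status, cost and tie-broken serving vectors agree on a sample of
        random small instances (the full 200-instance sweep runs in the
        acceptance suite)."""
        for seed in range(25):
            problem = generate_small_instance(seed, n_items=5 + seed % 3)
            a = optimize(problem)
            b = brute_force(problem)
            assert a.status == b.status, f"seed {seed}"
            if a.is_optimal:
                assert a.total_cost == pytest.approx(b.total_cost, abs=1e-9)
                assert np.array_equal(
                    a.serving_vector(problem.db), b.serving_vector(problem.db)
                ), f"seed {seed}"


class TestBindingReport:
    def _problem_and_solution(self, achieved, trimester=1):
        db = FoodDatabase([_item("x", FoodCategory.CEREALS, 1.0, energy_kcal=1.0)])
        problem = build_problem(db, trimester)
        groups = {c: 0.0 for c in ALL_CATEGORIES}
        mid_groups = {
            c: (b.lower + (b.upper if b.upper is not None else b.lower + 2)) / 2
            for c, b in problem.group_constraints.items()
        }
        sol = DietSolution(
            status="optimal",
            servings={"x": 1.0},
            total_cost=1.0,
            achieved=NutrientProfile(achieved),
            group_servings=mid_groups,
        )
        return problem, sol

    def test_potassium_near_floor_classified_at_lower(self):
        achieved = {c: 1000.0 for c in NUTRIENTS}
        achieved["potassium_mg"] = 4703.5  # floor 4700, unbounded above
        problem, sol = self._problem_and_solution(achieved)
        report = binding_report(sol, problem, tol_fraction=0.05)
        assert report["potassium_mg"].side == "lower"
        assert report["potassium_mg"].slack_lower == pytest.approx(3.5)

    def test_interior_energy_relative_position(self):
        achieved = {c: 1000.0 for c in NUTRIENTS}
        achieved["energy_kcal"] = 1806.0  # within [1680, 1880]
        problem, sol = self._problem_and_solution(achieved)
        report = binding_report(sol, problem, tol_fraction=0.05)
        assert report["energy_kcal"].side == "none"
        assert report["energy_kcal"].relative_position == pytest.approx(0.63)

    def test_midpoint_with_zero_tolerance_is_interior(self):
        achieved = {c: 0.0 for c in NUTRIENTS}
        achieved["fibre_g"] = 25.0  # midway in [20, 30]
        problem, sol = self._problem_and_solution(achieved)
        report = binding_report(sol, problem, tol_fraction=0.0)
        entry = report["fibre_g"]
        assert entry.side == "none"
        assert entry.slack_lower == pytest.approx(entry.slack_upper) == pytest.approx(5.0)

    def test_requires_optimal_solution(self, tiny_db):
        problem = build_problem(tiny_db, 1)
        with pytest.raises(ValueError, match="optimal"):
            binding_report(DietSolution(status="infeasible"), problem)


class TestDiagnoseInfeasibility:
    def test_iron_lower_is_sole_culprit(self):
        """Feasible base made infeasible only by an unattainable iron floor."""
        db = FoodDatabase(
            [
                _item("a", FoodCategory.MEAT, 1.0, iron_mg=2.0, energy_kcal=100),
                _item("b", FoodCategory.LEGUMES, 0.5, iron_mg=1.0, energy_kcal=80),
            ]
        )
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(iron_mg=Bound(50, None)),
            group_constraints=_free_groups(),
            item_caps=ItemCaps(default=2.0, by_category={}),
        )
        diag = diagnose_infeasibility(problem)
        assert diag.culprit_constraints == ["iron_mg:lower"]
        assert not diag.irreducible

    def test_two_independent_impossibilities_are_irreducible(self):
        db = FoodDatabase([_item("a", FoodCategory.MEAT, 1.0, iron_mg=1.0, vitC_mg=1.0)])
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(
                iron_mg=Bound(50, None), vitC_mg=Bound(50, None)
            ),
            group_constraints=_free_groups(),
            item_caps=ItemCaps(default=2.0, by_category={}),
        )
        diag = diagnose_infeasibility(problem)
        assert diag.irreducible
        assert diag.culprit_constraints == []

    def test_group_lower_bound_culprit(self):
        """Cereals floor of 4 servings with every cereal capped at 0."""
        db = FoodDatabase(
            [
                _item("grain", FoodCategory.CEREALS, 0.3, carb_g=30),
                _item("fruit", FoodCategory.FRUITS, 0.8, carb_g=15),
            ]
        )
        problem = ProblemSpec(
            db=db,
            nutrient_constraints=_free_nutrients(),
            group_constraints=_free_groups(**{"cereals and grains": Bound(4, 8)}),
            item_caps=ItemCaps(default=2.0, by_category={}, by_item={"grain": 0.0}),
        )
        diag = diagnose_infeasibility(problem)
        assert "cereals and grains:lower" in diag.culprit_constraints

    def test_rejects_feasible_problem(self):
        problem = generate_small_instance(3)  # feasible under this seed
        assert optimize(problem).is_optimal
        with pytest.raises(ValueError, match="feasible"):
            diagnose_infeasibility(problem)


class TestCompareScenarios:
    def test_zero_supplement_matches_baseline(self, small_db):
        table = compare_scenarios(
            small_db, 2, [SupplementScenario("nothing", NutrientProfile())]
        )
        assert list(table["scenario"]) == ["baseline", "nothing"]
        base, null = table.iloc[0], table.iloc[1]
        assert base["status"] == null["status"] == "optimal"
        assert base["total_cost"] == pytest.approx(null["total_cost"], abs=1e-9)

    def test_iron_supplement_never_costlier(self, small_db):
        iron = SupplementScenario("iron-100", NutrientProfile({"iron_mg": 100.0}))
        table = compare_scenarios(small_db, 2, [iron])
        base, supp = table.iloc[0], table.iloc[1]
        assert supp["total_cost"] <= base["total_cost"] + 1e-9

    def test_rows_preserve_scenario_order(self, small_db):
        scenarios = [
            SupplementScenario(f"s{i}", NutrientProfile({"iron_mg": float(i)}))
            for i in range(3)
        ]
        table = compare_scenarios(small_db, 2, scenarios)
        assert list(table["scenario"]) == ["baseline", "s0", "s1", "s2"]
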