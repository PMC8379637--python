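"""Strategy enumeration, convex frontiers, and greedy budget allocation."""

import math

import numpy as np
import pytest
from scipy.optimize import linprog

from poolcost import (
    KSGStrategy,
    allocate_budget,
    build_frontier,
    enumerate_strategies,
    min_tests_for_cost,
    no_test_cost,
    subpopulation_frontier,
)
from poolcost.frontier import StrategyPoint, strategy_point


def _num_divisor_chains(u1_max):
    """Count of distinct kSG strategies with k <= 2 and u1 <= u1_max, plus
    the no-test and individual points."""
    count = 2  # none + individual (= 1SG(1))
    for u1 in range(2, u1_max + 1):
        proper_divisors = sum(1 for d in range(1, u1) if u1 % d == 0)
        count += 1 + proper_divisors
    return count


class TestEnumeration:
    def test_tiny_exhaustive(self, make_sub):
        pts = enumerate_strategies(make_sub(0.01, 1, 50), max_k=1, max_group=3)
        notations = {pt.notation for pt in pts}
        assert notations == {"none", "individual", "1SG(2)", "1SG(3)"}

    def test_contains_the_scarce_budget_optimum(self, toy_sub):
        pts = enumerate_strategies(toy_sub, max_k=2, max_group=100)
        by_notation = {pt.notation: pt for pt in pts}
        assert "2SG(66,22)" in by_notation
        assert by_notation["2SG(66,22)"].rate == pytest.approx(0.0372, abs=1e-4)

    def test_combinatorial_count(self, make_sub):
        pts = enumerate_strategies(make_sub(0.01, 1, 50), max_k=2, max_group=12)
        assert len(pts) == _num_divisor_chains(12)

    def test_individual_only_restriction(self, toy_sub):
        pts = enumerate_strategies(toy_sub, strategies="individual")
        assert {pt.notation for pt in pts} == {"none", "individual"}


def _assert_valid_lower_hull(frontier, points, no_test):
    """Frontier oracle: vertices come from the input, start at rate 0, have
    strictly decreasing cost and increasing slope, dominate every input
    point, and every vertex is necessary."""
    vs = frontier.vertices
    everything = [no_test, *points]
    assert vs[0].rate == 0
    for v in vs:
        assert any(v is q or (v.rate, v.cost) == (q.rate, q.cost) for q in everything)
    costs = [v.cost for v in vs]
    assert all(a > b for a, b in zip(costs, costs[1:]))
    slopes = [
        (b.cost - a.cost) / (b.rate - a.rate) for a, b in zip(vs, vs[1:])
    ]
    assert all(s < 0 for s in slopes)
    assert all(s2 > s1 for s1, s2 in zip(slopes, slopes[1:]))
    for q in everything:
        assert frontier.cost_at_rate(q.rate) <= q.cost + 1e-9
    # necessity: dropping an interior vertex must lose some input point
    for i in range(1, len(vs) - 1):
        from poolcost.frontier import Frontier

        reduced = Frontier(vs[:i] + vs[i + 1 :])
        assert any(
            reduced.cost_at_rate(q.rate) > q.cost + 1e-12 for q in everything
        )


class TestBuildFrontier:
    def test_single_point(self):
        no_test = StrategyPoint(None, 0.0, 1.0)
        pt = StrategyPoint(KSGStrategy((2,)), 0.5, 0.3)
        fr = build_frontier([pt], no_test)
        assert fr.vertices == (no_test, pt)

    def test_first_vertex_after_no_test_is_two_stage_66_22(self, toy_sub):
        # with scarce tests the best k<=2 strategy at p=1%, a=50
        fr = subpopulation_frontier(toy_sub, max_k=2, max_group=100)
        first = fr.vertices[1]
        assert first.notation == "2SG(66,22)"
        assert fr.vertices[0].cost == pytest.approx(0.5)
        # frontier ends at zero cost (perfect identification is on the hull)
        assert fr.vertices[-1].cost == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_clouds_against_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        no_test = StrategyPoint(None, 0.0, 1.0)
        pts = [
            StrategyPoint(KSGStrategy((i + 2,)), r, c)
            for i, (r, c) in enumerate(
                zip(rng.uniform(0.01, 1.5, 50), rng.uniform(0, 1.2, 50))
            )
        ]
        fr = build_frontier(pts, no_test)
        _assert_valid_lower_hull(fr, pts, no_test)


def _lp_optimal_cost(pop, budget, max_k, max_group):
    """Independent LP oracle for the allocation problem: coverage fractions
    x_{i,s} over all enumerated strategies, minimizing expected total cost
    subject to the test budget and per-subpopulation coverage <= 1."""
    cols = []
    c = []
    a_budget = []
    a_cover = []
    base = 0.0
    for i, sub in enumerate(pop):
        base += sub.size * no_test_cost(sub)
        for pt in enumerate_strategies(sub, max_k, max_group):
            if pt.strategy is None:
                continue
            cols.append(i)
            # switching fraction x from untested to strategy pt
            c.append(sub.size * (pt.cost - no_test_cost(sub)))
            a_budget.append(sub.size * pt.rate)
    a_ub = [a_budget]
    b_ub = [budget]
    for i in range(len(pop)):
        a_cover = [1.0 if j == i else 0.0 for j in cols]
        a_ub.append(a_cover)
        b_ub.append(1.0)
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=(0, 1), method="highs")
    assert res.success
    n = sum(s.size for s in pop)
    return (base + res.fun) / n


class TestAllocation:
    def test_zero_budget_gives_no_test_cost(self, austria_pop):
        plan = allocate_budget(austria_pop, 0)
        assert plan.expected_cost == pytest.approx(0.9558590411743167, abs=1e-9)
        assert plan.tests_used == 0

    def test_cost_monotone_in_budget(self, austria_pop):
        budgets = [0, 10_000, 103_621, 500_000, 2_000_000, 8_916_845]
        costs = [allocate_budget(austria_pop, b).expected_cost for b in budgets]
        assert all(a >= b - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_budget_is_respected(self, austria_pop):
        for budget in (50_000, 103_621, 1_000_000):
            plan = allocate_budget(austria_pop, budget)
            assert plan.tests_used <= budget + 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_lp_oracle_on_random_scenarios(self, make_sub, seed):
        rng = np.random.default_rng(seed)
        n_subs = rng.integers(1, 4)
        pop = [
            make_sub(
                p=float(rng.uniform(0.01, 0.4)),
                b=float(rng.uniform(0.5, 5.0)),
                c=float(rng.uniform(0.5, 40.0)),
                size=int(rng.integers(50, 500)),
                name=f"s{i}",
            )
            for i in range(n_subs)
        ]
        budget = float(rng.uniform(0, sum(s.size for s in pop)))
        plan = allocate_budget(pop, budget, max_k=2, max_group=6)
        oracle = _lp_optimal_cost(pop, budget, 2, 6)
        assert plan.expected_cost == pytest.approx(oracle, abs=1e-9)

    def test_individual_only_baseline(self, austria_pop):
        plan = allocate_budget(austria_pop, 103_621, strategies="individual")
        assert plan.expected_cost == pytest.approx(0.944, abs=5e-4)

    def test_negative_budget_rejected(self, austria_pop):
        with pytest.raises(ValueError):
            allocate_budget(austria_pop, -1)


class TestMinTests:
    def test_no_test_cost_needs_zero_tests(self, austria_pop):
        tests, _ = min_tests_for_cost(austria_pop, 0.96)
        assert tests == 0

    def test_inverse_of_allocate_budget(self, austria_pop):
        no_test = 0.9558590411743167
        for target in np.linspace(0.2, 0.95, 6):
            tests, plan = min_tests_for_cost(austria_pop, float(target))
            assert plan.expected_cost <= target + 1e-9
            # one fewer test cannot reach the target
            if tests > 0:
                cheaper = allocate_budget(austria_pop, tests - 1)
                assert cheaper.expected_cost > target - 1e-6
        assert min_tests_for_cost(austria_pop, no_test)[0] == 0

    def test_rejects_negative_target(self, austria_pop):
        with pytest.raises(ValueError):
            min_tests_for_cost(austria_pop, -0.1)


class TestInfectedCount:
    def test_no_tests_all_healthy_defaults(self, make_sub):
        pop = [make_sub(p=0.01, b=1, c=50, size=100)]
        plan = allocate_budget(pop, 0)
        assert plan.expected_infected == 0.0

    def test_plan_report_is_consistent(self, austria_pop):
        plan = allocate_budget(austria_pop, 103_621)
        report = plan.to_dict()
        total = sum(r["expected_declared_infected"] for r in report["rows"])
        assert total == pytest.approx(plan.expected_infected, rel=1e-12)
        assert report["tests_used"] == math.ceil(plan.tests_used)
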