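"""Achievable rate-cost frontiers and budget allocation across subpopulations.

For one subpopulation every kSG strategy is a point (R, D) in the rate-cost
plane; testing only a fraction of the individuals and applying the default
assignment to the rest traces the straight line between two such points.  The
achievable set is therefore the lower convex hull of the strategy points
together with the no-test point at R = 0.

With several subpopulations and one global test budget, the optimal
allocation walks all frontier segments in order of cost reduction per test
(steepest first) and spends the budget greedily; convexity of each frontier
makes this exchange argument exact up to the fractional coverage on the
marginal segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .strategies import (
    INDIVIDUAL,
    KSGStrategy,
    Subpopulation,
    default_assignment,
    format_strategy,
    ksg_cost,
    ksg_rate,
    no_test_cost,
    positive_probability,
)

__all__ = [
    "StrategyPoint",
    "Frontier",
    "SubAllocation",
    "AllocationPlan",
    "enumerate_strategies",
    "build_frontier",
    "subpopulation_frontier",
    "allocate_budget",
    "min_tests_for_cost",
    "expected_infected_count",
]


@dataclass(frozen=True)
class StrategyPoint:
    """A strategy together with its rate (TpI) and expected cost per
    individual; ``strategy=None`` is the no-test point."""

    strategy: KSGStrategy | None
    rate: float
    cost: float

    @property
    def notation(self) -> str:
        return format_strategy(self.strategy)


@dataclass(frozen=True)
class Frontier:
    """Lower convex hull of achievable (rate, cost) points for one
    subpopulation, sorted by rate; the first vertex is the no-test point."""

    vertices: tuple[StrategyPoint, ...]

    def cost_at_rate(self, rate: float) -> float:
        """Piecewise-linear interpolation of the frontier; constant at the
        last vertex's cost beyond its rate."""
        vs = self.vertices
        if rate <= vs[0].rate:
            return vs[0].cost
        for a, b in zip(vs, vs[1:]):
            if rate <= b.rate:
                t = (rate - a.rate) / (b.rate - a.rate)
                return a.cost + t * (b.cost - a.cost)
        return vs[-1].cost


def strategy_point(sub: Subpopulation, strategy: KSGStrategy | None) -> StrategyPoint:
    """Rate and expected cost of a strategy (or of not testing) for ``sub``."""
    if strategy is None:
        return StrategyPoint(None, 0.0, no_test_cost(sub))
    return StrategyPoint(
        strategy,
        ksg_rate(sub.prevalence, strategy),
        ksg_cost(sub.prevalence, sub.fp_cost, strategy),
    )


def _divisor_chains(u: int, depth: int) -> list[tuple[int, ...]]:
    """All strictly decreasing divisor chains starting at u with <= depth
    further stages."""
    chains: list[tuple[int, ...]] = [(u,)]
    if depth <= 0:
        return chains
    for d in range(u - 1, 0, -1):
        if u % d == 0:
            chains.extend((u, *c) for c in _divisor_chains(d, depth - 1))
    return chains


def enumerate_strategies(
    sub: Subpopulation,
    max_k: int = 2,
    max_group: int = 100,
    strategies: Literal["ksg", "individual"] = "ksg",
) -> list[StrategyPoint]:
    """All candidate strategy points for one subpopulation.

    Includes the no-test point, individual testing, and every kSG strategy
    with at most ``max_k`` stages and first group size at most ``max_group``
    (group sizes strictly decreasing, each dividing its parent).  Points with
    identical (rate, cost) are deduplicated keeping the lexicographically
    smallest group-size tuple.  ``strategies='individual'`` restricts the set
    to {none, individual}.
    """
    if max_k < 1 or max_group < 1:
        raise ValueError("max_k and max_group must be >= 1")
    points: dict[tuple[float, float], StrategyPoint] = {}

    def add(strategy: KSGStrategy | None) -> None:
        pt = strategy_point(sub, strategy)
        key = (round(pt.rate, 12), round(pt.cost, 12))
        old = points.get(key)
        if old is None or (
            pt.strategy is not None
            and old.strategy is not None
            and pt.strategy.group_sizes < old.strategy.group_sizes
        ):
            points[key] = pt

    add(None)
    add(INDIVIDUAL)
    if strategies == "ksg":
        for u1 in range(2, max_group + 1):
            for chain in _divisor_chains(u1, max_k - 1):
                add(KSGStrategy(chain))
    elif strategies != "individual":
        raise ValueError(f"unknown strategy set {strategies!r}")
    return sorted(points.values(), key=lambda pt: (pt.rate, pt.cost))


def _cross(o: StrategyPoint, a: StrategyPoint, b: StrategyPoint) -> float:
    return (a.rate - o.rate) * (b.cost - o.cost) - (a.cost - o.cost) * (
        b.rate - o.rate
    )


def build_frontier(
    points: Sequence[StrategyPoint], no_test: StrategyPoint
) -> Frontier:
    """Lower convex hull of {no_test} ∪ points, trimmed to the decreasing
    part that starts at rate 0."""
    if not points:
        raise ValueError("need at least one strategy point")
    best: dict[float, StrategyPoint] = {}
    for pt in [no_test, *points]:
        key = round(pt.rate, 12)
        if key not in best or pt.cost < best[key].cost:
            best[key] = pt
    pts = sorted(best.values(), key=lambda pt: pt.rate)
    hull: list[StrategyPoint] = []
    for pt in pts:
        while len(hull) >= 2 and _cross(hull[-2], hull[-1], pt) <= 0:
            hull.pop()
        hull.append(pt)
    # keep the decreasing stretch from the rate-0 vertex to the cost minimum
    end = min(range(len(hull)), key=lambda i: (hull[i].cost, hull[i].rate))
    return Frontier(tuple(hull[: end + 1]))


def subpopulation_frontier(
    sub: Subpopulation,
    max_k: int = 2,
    max_group: int = 100,
    strategies: Literal["ksg", "individual"] = "ksg",
) -> Frontier:
    """Convenience: enumerate strategies for ``sub`` and build its frontier."""
    pts = enumerate_strategies(sub, max_k, max_group, strategies)
    no_test = next(pt for pt in pts if pt.strategy is None)
    rest = [pt for pt in pts if pt.strategy is not None]
    return build_frontier(rest, no_test)


@dataclass(frozen=True)
class SubAllocation:
    """Allocation for one subpopulation: tested strategies with coverage
    fractions; the remaining fraction is untested at the default status."""

    sub: Subpopulation
    items: tuple[tuple[StrategyPoint, float], ...]
    untested_fraction: float
    default_status: str

    @property
    def tests(self) -> float:
        return self.sub.size * sum(f * pt.rate for pt, f in self.items)

    @property
    def expected_cost(self) -> float:
        """Expected cost per individual of this subpopulation."""
        untested = no_test_cost(self.sub) * self.untested_fraction
        return untested + sum(f * pt.cost for pt, f in self.items)

    @property
    def expected_infected(self) -> float:
        """Expected number of individuals declared infected."""
        n = self.sub.size
        total = 0.0
        if self.default_status == "infected":
            total += n * self.untested_fraction
        for pt, f in self.items:
            assert pt.strategy is not None
            total += n * f * positive_probability(
                self.sub.prevalence, pt.strategy.final_size
            )
        return total


@dataclass(frozen=True)
class AllocationPlan:
    """A complete allocation of the test budget across subpopulations."""

    allocations: tuple[SubAllocation, ...]
    budget_tests: float

    @property
    def population(self) -> int:
        return sum(a.sub.size for a in self.allocations)

    @property
    def tests_used(self) -> float:
        return sum(a.tests for a in self.allocations)

    @property
    def expected_cost(self) -> float:
        """Expected cost per individual over the whole population."""
        n = self.population
        return sum(a.sub.size * a.expected_cost for a in self.allocations) / n

    @property
    def expected_infected(self) -> float:
        return sum(a.expected_infected for a in self.allocations)

    def to_dict(self) -> dict:
        """Structured report of the plan (JSON-serialisable)."""
        rows = []
        for a in self.allocations:
            for pt, f in a.items:
                rows.append(
                    {
                        "subpopulation": a.sub.name,
                        "strategy": pt.notation,
                        "coverage_fraction": f,
                        "individuals_covered": a.sub.size * f,
                        "tests": math.ceil(a.sub.size * f * pt.rate),
                        "expected_cost_contribution": a.sub.size * f * pt.cost,
                        "expected_declared_infected": a.sub.size
                        * f
                        * positive_probability(
                            a.sub.prevalence, pt.strategy.final_size
                        ),
                    }
                )
            rows.append(
                {
                    "subpopulation": a.sub.name,
                    "strategy": "none",
                    "coverage_fraction": a.untested_fraction,
                    "individuals_covered": a.sub.size * a.untested_fraction,
                    "tests": 0,
                    "expected_cost_contribution": a.sub.size
                    * a.untested_fraction
                    * no_test_cost(a.sub),
                    "expected_declared_infected": (
                        a.sub.size * a.untested_fraction
                        if a.default_status == "infected"
                        else 0.0
                    ),
                    "default_status": a.default_status,
                }
            )
        return {
            "budget_tests": self.budget_tests,
            "tests_used": math.ceil(self.tests_used),
            "expected_cost_per_individual": self.expected_cost,
            "expected_declared_infected": self.expected_infected,
            "population": self.population,
            "rows": rows,
        }


@dataclass
class _Segment:
    sub_index: int
    vertex_index: int  # segment from vertex i to i+1 of that frontier
    tests: float  # tests to traverse the whole segment
    reduction: float  # total expected-cost reduction over the segment

    @property
    def reduction_per_test(self) -> float:
        return self.reduction / self.tests

    def sort_key(self, frontiers: list[Frontier]) -> tuple:
        b = frontiers[self.sub_index].vertices[self.vertex_index + 1]
        u1 = (
            b.strategy.group_sizes[0]
            if b.strategy is not None
            else float("inf")
        )
        return (-self.reduction_per_test, self.sub_index, u1)


def _segments(
    pop: Sequence[Subpopulation], frontiers: list[Frontier]
) -> list[_Segment]:
    segs = []
    for i, (sub, fr) in enumerate(zip(pop, frontiers)):
        for j, (a, b) in enumerate(zip(fr.vertices, fr.vertices[1:])):
            tests = sub.size * (b.rate - a.rate)
            reduction = sub.size * (a.cost - b.cost)
            if tests > 0 and reduction > 0:
                segs.append(_Segment(i, j, tests, reduction))
    segs.sort(key=lambda s: s.sort_key(frontiers))
    return segs


def _plan_from_positions(
    pop: Sequence[Subpopulation],
    frontiers: list[Frontier],
    positions: list[tuple[int, float]],
    budget: float,
) -> AllocationPlan:
    allocs = []
    for sub, fr, (j, t) in zip(pop, frontiers, positions):
        # position: vertex j moved fraction t toward vertex j+1
        mix: list[tuple[StrategyPoint, float]] = []
        if t > 0:
            mix.append((fr.vertices[j], 1.0 - t))
            mix.append((fr.vertices[j + 1], t))
        else:
            mix.append((fr.vertices[j], 1.0))
        items = tuple(
            (pt, f) for pt, f in mix if pt.strategy is not None and f > 0
        )
        untested = sum(f for pt, f in mix if pt.strategy is None)
        allocs.append(
            SubAllocation(sub, items, untested, default_assignment(sub))
        )
    return AllocationPlan(tuple(allocs), budget)


def allocate_budget(
    pop: Sequence[Subpopulation],
    budget_tests: float,
    max_k: int = 2,
    max_group: int = 100,
    strategies: Literal["ksg", "individual"] = "ksg",
) -> AllocationPlan:
    """Cost-minimal allocation of ``budget_tests`` tests across ``pop``.

    Builds each subpopulation's frontier, merges all frontier segments sorted
    by expected-cost reduction per test, and spends the budget greedily with
    fractional coverage on the marginal segment.
    """
    if budget_tests < 0:
        raise ValueError("test budget must be non-negative")
    frontiers = [
        subpopulation_frontier(s, max_k, max_group, strategies) for s in pop
    ]
    positions: list[tuple[int, float]] = [(0, 0.0) for _ in pop]
    remaining = float(budget_tests)
    for seg in _segments(pop, frontiers):
        if remaining <= 0:
            break
        if seg.tests <= remaining:
            remaining -= seg.tests
            positions[seg.sub_index] = (seg.vertex_index + 1, 0.0)
        else:
            positions[seg.sub_index] = (seg.vertex_index, remaining / seg.tests)
            remaining = 0.0
    return _plan_from_positions(pop, frontiers, positions, budget_tests)


def min_tests_for_cost(
    pop: Sequence[Subpopulation],
    target_cost: float,
    max_k: int = 2,
    max_group: int = 100,
    strategies: Literal["ksg", "individual"] = "ksg",
) -> tuple[int, AllocationPlan]:
    """Smallest expected number of tests whose optimal plan reaches an
    expected cost per individual <= ``target_cost``.

    Exact piecewise-linear inversion of the merged frontier; the returned
    test count is rounded up for feasibility.
    """
    if target_cost < 0:
        raise ValueError("target cost must be non-negative")
    n = sum(s.size for s in pop)
    frontiers = [
        subpopulation_frontier(s, max_k, max_group, strategies) for s in pop
    ]
    total_cost = sum(s.size * no_test_cost(s) for s in pop)
    target_total = target_cost * n
    positions: list[tuple[int, float]] = [(0, 0.0) for _ in pop]
    tests = 0.0
    if total_cost > target_total:
        for seg in _segments(pop, frontiers):
            if total_cost - seg.reduction <= target_total:
                t = (total_cost - target_total) / seg.reduction
                tests += t * seg.tests
                total_cost -= t * seg.reduction
                positions[seg.sub_index] = (seg.vertex_index, t)
                break
            tests += seg.tests
            total_cost -= seg.reduction
            positions[seg.sub_index] = (seg.vertex_index + 1, 0.0)
        else:
            raise ValueError(
                f"target cost {target_cost} is unreachable with max_k={max_k}, "
                f"max_group={max_group}"
            )
    plan = _plan_from_positions(pop, frontiers, positions, tests)
    return math.ceil(tests - 1e-9), plan


def expected_infected_count(
    pop: Sequence[Subpopulation], plan: AllocationPlan
) -> float:
    """Expected number of individuals declared infected under ``plan``."""
    del pop  # population is carried inside the plan
    return plan.expected_infected
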