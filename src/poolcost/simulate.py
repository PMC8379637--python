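"""Monte-Carlo verification of the closed-form rate and cost formulas.

Populations are vectors of independent Bernoulli statuses; the adaptive
pooling tree is executed with perfect tests (a pool is positive iff it
contains an infected individual) and tests, false assignments and declared
infections are counted.  The closed forms of :mod:`poolcost.strategies`
ignore the remainder group when the population is not a multiple of the
first group size; here remainders are pooled and split explicitly, so the
empirical rate differs from the closed form by at most one test per
remainder group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frontier import AllocationPlan
from .strategies import KSGStrategy, Subpopulation

__all__ = ["SimulationResult", "simulate_statuses", "simulate_ksg", "simulate_plan"]


@dataclass(frozen=True)
class SimulationResult:
    """Counts from one simulated testing campaign."""

    n: int
    tests_used: int
    false_positives: int
    false_negatives: int
    declared_infected: int
    cost_total: float
    seed: int | None

    @property
    def empirical_rate(self) -> float:
        return self.tests_used / self.n

    @property
    def empirical_cost(self) -> float:
        return self.cost_total / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "tests_used": self.tests_used,
            "empirical_rate": self.empirical_rate,
            "empirical_cost": self.empirical_cost,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "declared_infected": self.declared_infected,
            "seed": self.seed,
        }


def _run_tree(
    statuses: np.ndarray, sizes: tuple[int, ...]
) -> tuple[int, np.ndarray]:
    """Pooling tree on a status block whose length is a multiple of sizes[0].

    Returns (tests used, boolean declared-infected vector).
    """
    n = statuses.size
    declared = np.zeros(n, dtype=bool)
    if n == 0:
        return 0, declared
    u1 = sizes[0]
    groups = statuses.reshape(-1, u1)
    positive = groups.any(axis=1)
    tests = groups.shape[0]
    # indices (into statuses) of the members of currently positive groups
    idx = np.arange(n).reshape(-1, u1)[positive]
    for u_next in sizes[1:]:
        if idx.size == 0:
            break
        sub_idx = idx.reshape(-1, u_next)
        tests += sub_idx.shape[0]
        positive = statuses[sub_idx].any(axis=1)
        idx = sub_idx[positive]
    declared[idx.ravel()] = True
    return tests, declared


def _run_remainder(
    statuses: np.ndarray, sizes: tuple[int, ...]
) -> tuple[int, np.ndarray]:
    """Pooling tree on a remainder group smaller than sizes[0]: the group is
    tested as-is, and positive groups split into chunks of the next stage
    size (last chunk smaller if needed)."""
    declared = np.zeros(statuses.size, dtype=bool)
    if statuses.size == 0:
        return 0, declared
    groups: list[np.ndarray] = [np.arange(statuses.size)]
    tests = 0
    for depth, _ in enumerate(sizes):
        next_groups: list[np.ndarray] = []
        for g in groups:
            tests += 1
            if not statuses[g].any():
                continue
            if depth == len(sizes) - 1:
                declared[g] = True
            else:
                u_next = sizes[depth + 1]
                next_groups.extend(
                    g[i : i + u_next] for i in range(0, g.size, u_next)
                )
        groups = next_groups
    return tests, declared


def simulate_statuses(
    statuses: np.ndarray, strategy: KSGStrategy
) -> tuple[int, np.ndarray]:
    """Execute the pooling tree on a given 0/1 status vector.

    Deterministic; exposed so that exhaustive and forced-status oracles can
    drive the same code path as the random simulations.

    Returns
    -------
    (tests_used, declared) : tuple[int, numpy.ndarray]
        Total tests consumed and the boolean declared-infected vector.
    """
    statuses = np.asarray(statuses, dtype=bool)
    u1 = strategy.group_sizes[0]
    n_full = (statuses.size // u1) * u1
    tests, declared = _run_tree(statuses[:n_full], strategy.group_sizes)
    t2, d2 = _run_remainder(statuses[n_full:], strategy.group_sizes)
    return tests + t2, np.concatenate([declared, d2])


def _result_from(
    statuses: np.ndarray,
    declared: np.ndarray,
    tests: int,
    b: float,
    c: float,
    seed: int | None,
) -> SimulationResult:
    fp = int(np.count_nonzero(~statuses & declared))
    fn = int(np.count_nonzero(statuses & ~declared))
    return SimulationResult(
        n=statuses.size,
        tests_used=tests,
        false_positives=fp,
        false_negatives=fn,
        declared_infected=int(np.count_nonzero(declared)),
        cost_total=b * fp + c * fn,
        seed=seed,
    )


def simulate_ksg(
    p: float,
    b: float,
    c: float,
    strategy: KSGStrategy,
    n: int,
    seed: int,
) -> SimulationResult:
    """Simulate a kSG campaign on n independent Bernoulli(p) individuals."""
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    statuses = rng.random(n) < p
    tests, declared = simulate_statuses(statuses, strategy)
    return _result_from(statuses, declared, tests, b, c, seed)


def simulate_plan(
    pop: Sequence[Subpopulation],
    plan: AllocationPlan,
    scale: float = 1.0,
    seed: int = 0,
) -> SimulationResult:
    """Simulate an allocation plan on a population scaled by ``scale``.

    Each subpopulation is simulated at round(scale * N_i) individuals; the
    plan's coverage fractions pick how many fall under each strategy, the
    rest receive the default assignment.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    tot_n = tot_tests = tot_fp = tot_fn = tot_decl = 0
    tot_cost = 0.0
    for alloc in plan.allocations:
        sub = alloc.sub
        n_i = int(round(scale * sub.size))
        if n_i < 1:
            raise ValueError(
                f"scaled size of subpopulation {sub.name!r} is zero"
            )
        statuses = rng.random(n_i) < sub.prevalence
        counts = [int(round(f * n_i)) for _, f in alloc.items]
        start = 0
        declared = np.zeros(n_i, dtype=bool)
        for (pt, _), cnt in zip(alloc.items, counts):
            block = statuses[start : start + cnt]
            assert pt.strategy is not None
            t, d = simulate_statuses(block, pt.strategy)
            tot_tests += t
            declared[start : start + cnt] = d
            start += cnt
        if alloc.default_status == "infected":
            declared[start:] = True
        fp = int(np.count_nonzero(~statuses & declared))
        fn = int(np.count_nonzero(statuses & ~declared))
        tot_n += n_i
        tot_fp += fp
        tot_fn += fn
        tot_decl += int(np.count_nonzero(declared))
        tot_cost += sub.fp_cost * fp + sub.fn_cost * fn
    return SimulationResult(
        n=tot_n,
        tests_used=tot_tests,
        false_positives=tot_fp,
        false_negatives=tot_fn,
        declared_infected=tot_decl,
        cost_total=tot_cost,
        seed=seed,
    )
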