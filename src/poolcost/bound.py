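"""Information-theoretic lower bound on expected cost for heterogeneous
populations.

For a population split into subpopulations i with sizes N_i, prevalences p_i
and costs (b_i, c_i), the achievable region is bounded by the parametric
curve

    R(v) = (1/N) * sum_i N_i * rbar(p_i, a_i, v**b_i)
    D(v) = (1/N) * sum_i N_i * b_i * dbar(p_i, a_i, v**b_i)

over v in [0, 1]: no testing strategy using at most R(v) tests per individual
can achieve an expected cost per individual below D(v).  Each subpopulation
enters through the single-population curve evaluated at v**b_i, so
subpopulations clamp (stop contributing rate) at different v.
"""

from __future__ import annotations

import math
import warnings
from functools import lru_cache
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import binary_entropy, critical_v, dbar, rbar
from .strategies import Subpopulation, no_test_cost

__all__ = [
    "BoundCurve",
    "bound_point",
    "bound_cost_at_budget",
    "bound_tests_for_cost",
    "bound_curve",
]

_GRID_POINTS = 1000
_V_LO = 1e-12


@dataclass(frozen=True)
class BoundCurve:
    """Sampled lower-bound frontier: (v, rate TpI, cost per individual),
    sorted by v (rate non-increasing, cost non-decreasing)."""

    samples: tuple[tuple[float, float, float], ...]

    def to_rows(self) -> list[dict]:
        return [
            {"v": v, "rate_tpi": r, "cost_per_individual": d}
            for v, r, d in self.samples
        ]


def _exponent(v: float, b: float) -> float:
    # v**b for positive b, with exact endpoint branches
    if v == 0.0:
        return 0.0
    if v == 1.0:
        return 1.0
    return math.exp(b * math.log(v))


def bound_point(
    pop: Sequence[Subpopulation], v: float
) -> tuple[float, float]:
    """The point (R(v), D(v)) of the lower-bound curve."""
    if not 0.0 <= v <= 1.0:
        raise ValueError("v must lie in [0, 1]")
    n = sum(s.size for s in pop)
    rate = 0.0
    cost = 0.0
    for s in pop:
        vb = _exponent(v, s.fp_cost)
        a = s.cost_ratio
        rate += s.size * rbar(s.prevalence, a, vb)
        cost += s.size * s.fp_cost * dbar(s.prevalence, a, vb)
    return rate / n, cost / n


def _rate_only(pop: Sequence[Subpopulation], v: float) -> float:
    n = sum(s.size for s in pop)
    return (
        sum(
            s.size * rbar(s.prevalence, s.cost_ratio, _exponent(v, s.fp_cost))
            for s in pop
        )
        / n
    )


def _cost_only(pop: Sequence[Subpopulation], v: float) -> float:
    n = sum(s.size for s in pop)
    return (
        sum(
            s.size
            * s.fp_cost
            * dbar(s.prevalence, s.cost_ratio, _exponent(v, s.fp_cost))
            for s in pop
        )
        / n
    )


def _v_grid(pop: Sequence[Subpopulation], n_samples: int) -> np.ndarray:
    """Log-spaced grid on (0, 1] refined around each subpopulation's clamp
    transition, plus both exact endpoints."""
    # R(v) is steep near v = 0 while D(v) moves fastest near v = 1, so the
    # grid is log-spaced toward both endpoints
    half = max(2, n_samples // 2)
    base = np.concatenate(
        [
            np.logspace(math.log10(_V_LO), 0.0, half),
            1.0 - np.logspace(-9, math.log10(0.5), n_samples - half),
        ]
    )
    extra = []
    for s in pop:
        v0 = critical_v(s.prevalence, s.cost_ratio)
        # transition of this subpopulation in the aggregate curve: v**b = v0
        vt = v0 ** (1.0 / s.fp_cost)
        extra.extend([max(_V_LO, vt * (1 - 1e-9)), min(1.0, vt)])
    grid = np.unique(np.concatenate([[0.0], base, extra, [1.0]]))
    return grid


@lru_cache(maxsize=256)
def _check_monotone(pop: tuple[Subpopulation, ...]) -> bool:
    grid = np.logspace(math.log10(_V_LO), 0.0, _GRID_POINTS)
    rates = np.array([_rate_only(pop, v) for v in grid])
    return bool(np.all(np.diff(rates) <= 1e-12))


def bound_cost_at_budget(
    pop: Sequence[Subpopulation], budget_tests: float
) -> float:
    """Lower bound on the expected cost per individual achievable with
    ``budget_tests`` tests in total.

    Inverts R(v) = budget/N by bisection in v (R is verified to be monotone
    on a 1000-point grid first; a non-monotone aggregate falls back to a
    conservative grid minimum with a warning).
    """
    if budget_tests < 0:
        raise ValueError("test budget must be non-negative")
    n = sum(s.size for s in pop)
    target_rate = budget_tests / n
    if target_rate >= _rate_only(pop, _V_LO):
        # budget at or above the perfect-identification rate (up to the
        # bracket resolution): the bound is 0
        return 0.0 if target_rate >= _rate_only(pop, 0.0) else _cost_only(pop, _V_LO)
    if target_rate <= 0.0:
        return _cost_only(pop, 1.0)
    if not _check_monotone(tuple(pop)):
        warnings.warn(
            "aggregate rate R(v) is not monotone on the check grid; "
            "falling back to a grid search",
            RuntimeWarning,
        )
        grid = _v_grid(pop, _GRID_POINTS)
        feas = [v for v in grid if _rate_only(pop, v) <= target_rate]
        return min(_cost_only(pop, v) for v in feas)
    v_star = brentq(
        lambda v: _rate_only(pop, v) - target_rate,
        _V_LO,
        1.0,
        xtol=1e-12,
    )
    return _cost_only(pop, v_star)


def bound_tests_for_cost(
    pop: Sequence[Subpopulation], target_cost: float
) -> int:
    """Minimum number of tests (lower bound, rounded up) any strategy needs
    to reach an expected cost per individual of ``target_cost``."""
    n = sum(s.size for s in pop)
    max_cost = _cost_only(pop, 1.0)
    if not 0.0 <= target_cost <= max_cost + 1e-12:
        raise ValueError(
            f"target cost must lie in [0, {max_cost:.6g}] (the no-test cost)"
        )
    if target_cost >= max_cost:
        return 0
    if target_cost <= 0.0:
        return math.ceil(n * _rate_only(pop, 0.0))
    v_star = brentq(
        lambda v: _cost_only(pop, v) - target_cost,
        _V_LO,
        1.0,
        xtol=1e-12,
    )
    return math.ceil(n * _rate_only(pop, v_star))


def bound_curve(pop: Sequence[Subpopulation], n_samples: int = 1000) -> BoundCurve:
    """Sample the lower-bound curve for plotting or CSV export.

    The grid is log-spaced in v (the curve is steep near v = 0) with extra
    points at each subpopulation's clamp transition; ``n_samples=2`` yields
    the endpoints only.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if n_samples == 2:
        grid = np.array([0.0, 1.0])
    else:
        grid = _v_grid(pop, n_samples)
    samples = []
    for v in grid:
        r, d = bound_point(pop, float(v))
        samples.append((float(v), r, d))
    return BoundCurve(tuple(samples))


def no_test_cost_population(pop: Sequence[Subpopulation]) -> float:
    """Population-wide expected cost per individual when nobody is tested."""
    n = sum(s.size for s in pop)
    return sum(s.size * no_test_cost(s) for s in pop) / n


def entropy_rate_population(pop: Sequence[Subpopulation]) -> float:
    """Population-averaged binary entropy: the zero-cost rate R(0) in TpI."""
    n = sum(s.size for s in pop)
    return sum(s.size * binary_entropy(s.prevalence) for s in pop) / n
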