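"""Information-theoretic primitives for the rate-cost analysis of group testing.

The infection status of an individual is a Bernoulli(p) variable and wrong
status assignments are penalised asymmetrically: a false positive costs b and
a false negative costs c = a*b.  The minimum expected cost achievable with R
tests per individual is bounded below by the distortion-rate function of this
source, which admits a closed-form parametric solution in a slope parameter
``v`` in [0, 1]:

* ``rbar(p, a, v)`` is the rate (in bits = tests per individual) and
* ``dbar(p, a, v)`` the normalised distortion (expected cost per individual in
  units of b) of the point of the distortion-rate curve whose slope
  dD/dR equals 1/log2(v).

At ``v = 0`` the curve starts at (R, D) = (H2(p), 0): perfect identification
costs the binary entropy of the prevalence.  The curve ends at a critical
parameter ``v0``, beyond which no tests are worth spending and the optimum is
the better of the two blanket assignments, D = min(1-p, a*p) at R = 0.

``v0`` is the smallest positive root of

    (p*v^(a+1) + 1 - p - v) * (p*v^(-a-1) + 1 - p - 1/v) = 0,

each factor being the condition that one of the two output letters of the
optimal test channel drops out of use.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = ["binary_entropy", "critical_v", "dbar", "rbar", "distortion_rate"]

#: points in the log-spaced sign-change scan for the roots of the v0 equation
_SCAN_POINTS = 10_000
_SCAN_LO = 1e-12


def _check_prob(p: float, name: str = "p", open_interval: bool = False) -> float:
    p = float(p)
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    if open_interval and (p == 0.0 or p == 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1), got {p!r}")
    return p


def _check_ratio(a: float) -> float:
    a = float(a)
    if not np.isfinite(a) or a <= 0.0:
        raise ValueError(f"cost ratio a = c/b must be positive, got {a!r}")
    return a


def binary_entropy(p: float) -> float:
    """Binary entropy H2(p) in bits, with the convention 0*log 0 = 0.

    Parameters
    ----------
    p : float
        A probability in [0, 1].

    Returns
    -------
    float
        -p*log2(p) - (1-p)*log2(1-p), in [0, 1].
    """
    p = _check_prob(p)
    if p == 0.0 or p == 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def _factor_one(p: float, a: float, v: float) -> float:
    # p*v^(a+1) + 1 - p - v ; root <=> output letter "infected" unused
    return p * v ** (a + 1.0) + 1.0 - p - v


def _factor_two_in_t(p: float, a: float, t: float) -> float:
    # second factor scaled by v^(a+1) and substituted t = v^a: its root
    # always satisfies t >= p, so a fixed scan grid in t cannot miss it
    # (in v the root can sit at 2^(-const/a), arbitrarily close to 0)
    return p + (1.0 - p) * t ** ((a + 1.0) / a) - t


def _smallest_root(f, p: float, a: float) -> float | None:
    grid = np.logspace(math.log10(_SCAN_LO), 0.0, _SCAN_POINTS)
    vals = np.array([f(p, a, v) for v in grid])
    for i in range(len(grid) - 1):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            return float(grid[i])
        if lo * hi < 0.0:
            return float(
                brentq(lambda v: f(p, a, v), grid[i], grid[i + 1], xtol=1e-15)
            )
    # v = 1 is always a root of both factors; the scan can miss it when the
    # function only touches zero there
    if abs(f(p, a, 1.0)) < 1e-12:
        return 1.0
    return None


@lru_cache(maxsize=4096)
def critical_v(p: float, a: float) -> float:
    """Critical slope parameter v0: the smallest positive root of the
    clamp equation.

    For v >= v0 the distortion-rate curve is exhausted: the rate is 0 and the
    distortion clamps at min(1-p, a*p).  For a = 1 and p < 1/2 the root is
    p/(1-p) in closed form, which the root finder reproduces.

    Raises
    ------
    RuntimeError
        If no root is found in (0, 1] (not expected for valid inputs).
    """
    p = _check_prob(p, open_interval=True)
    a = _check_ratio(a)
    roots = []
    if (r := _smallest_root(_factor_one, p, a)) is not None:
        roots.append(r)
    if (t := _smallest_root(_factor_two_in_t, p, a)) is not None:
        roots.append(t ** (1.0 / a))
    if not roots:
        raise RuntimeError(
            f"no root of the clamp equation found in (0, 1] for p={p}, a={a}; "
            "the sign-change scan covered "
            f"[{_SCAN_LO}, 1] with {_SCAN_POINTS} points"
        )
    return min(roots)


def _dbar_interior(p: float, a: float, v: float) -> float:
    # parametric distortion for 0 < v < v0
    va = v**a
    va1 = v ** (a + 1.0)
    num = (
        p * v * (1.0 - va) / (1.0 - v)
        - (1.0 - p) * va1
        + a * (1.0 - p) * va * (1.0 - v) / (1.0 - va)
        - a * p * va1
    )
    return num / (1.0 - va1)


def dbar(p: float, a: float, v: float) -> float:
    """Normalised distortion D-bar(p, a, v): expected cost per individual in
    units of the false-positive cost b, at slope parameter v.

    Increases from 0 at v = 0 to the clamp value min(1-p, a*p) at v = v0, and
    stays clamped for v in [v0, 1].
    """
    p = _check_prob(p, open_interval=True)
    a = _check_ratio(a)
    v = _check_prob(v, name="v")
    if v == 0.0:
        return 0.0
    if v >= critical_v(p, a):
        return min(1.0 - p, a * p)
    return _dbar_interior(p, a, v)


def rbar(p: float, a: float, v: float) -> float:
    """Rate R-bar(p, a, v) in bits (= tests per individual) at slope
    parameter v.

    Decreases from H2(p) at v = 0 to 0 at v = v0 and stays 0 for v >= v0.
    """
    p = _check_prob(p, open_interval=True)
    a = _check_ratio(a)
    v = _check_prob(v, name="v")
    if v == 0.0:
        return binary_entropy(p)
    if v >= critical_v(p, a):
        return 0.0
    va = v**a
    va1 = v ** (a + 1.0)
    return (
        _dbar_interior(p, a, v) * math.log2(v)
        + binary_entropy(p)
        - math.log2((1.0 - va1) / (1.0 - va))
        + p * math.log2((1.0 - v) / (1.0 - va))
    )


def distortion_rate(p: float, a: float, v: float) -> tuple[float, float]:
    """Return the pair (rbar, dbar) at slope parameter v (one v0 lookup)."""
    return rbar(p, a, v), dbar(p, a, v)
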