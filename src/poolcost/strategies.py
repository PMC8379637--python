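"""Closed-form rate and expected cost of k-stage group-testing strategies.

A kSG(u1, ..., uk) strategy pools the population into disjoint groups of u1
individuals and tests each pool.  A positive pool at stage l is split into
equal subgroups of size u_{l+1} which are tested in turn; members of a
positive final-stage subgroup are declared infected, everyone else healthy.
With perfect tests this decision rule never produces a false negative, so the
expected cost depends only on the final group size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Subpopulation",
    "KSGStrategy",
    "INDIVIDUAL",
    "default_assignment",
    "no_test_cost",
    "ksg_rate",
    "ksg_cost",
    "positive_probability",
    "parse_strategy",
    "format_strategy",
]


@dataclass(frozen=True)
class Subpopulation:
    """A homogeneous slice of the population.

    Attributes
    ----------
    name : str
        Label used in reports.
    size : int
        Number of individuals N (>= 1).
    prevalence : float
        Marginal infection probability p, strictly inside (0, 1);
        independent across individuals.
    fp_cost : float
        Cost b > 0 of assigning infected status to a healthy individual.
    fn_cost : float
        Cost c > 0 of assigning healthy status to an infected individual.
    """

    name: str
    size: int
    prevalence: float
    fp_cost: float
    fn_cost: float

    def __post_init__(self) -> None:
        if int(self.size) != self.size or self.size < 1:
            raise ValueError(f"{self.name}: size must be a positive integer")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.fp_cost <= 0 or self.fn_cost <= 0:
            raise ValueError(f"{self.name}: costs must be positive")

    @property
    def cost_ratio(self) -> float:
        """a = c/b, the false-negative to false-positive cost ratio."""
        return self.fn_cost / self.fp_cost


@dataclass(frozen=True)
class KSGStrategy:
    """Nested group sizes (u1, ..., uk) of a k-stage strategy.

    Sizes strictly decrease and each stage's size divides its parent's, so a
    positive group always splits into equal disjoint subgroups.
    """

    group_sizes: tuple[int, ...] = field()

    def __post_init__(self) -> None:
        us = tuple(int(u) for u in self.group_sizes)
        object.__setattr__(self, "group_sizes", us)
        if len(us) < 1:
            raise ValueError("strategy needs at least one stage")
        if any(u < 1 for u in us):
            raise ValueError(f"group sizes must be positive: {us}")
        for ul, un in zip(us, us[1:]):
            if un >= ul:
                raise ValueError(f"group sizes must strictly decrease: {us}")
            if ul % un != 0:
                raise ValueError(
                    f"each stage size must divide its parent ({un} does not divide {ul})"
                )

    @property
    def stages(self) -> int:
        return len(self.group_sizes)

    @property
    def final_size(self) -> int:
        return self.group_sizes[-1]

    def __str__(self) -> str:
        return format_strategy(self)


#: individual testing, the degenerate one-stage strategy with groups of one
INDIVIDUAL = KSGStrategy((1,))


def positive_probability(p: float, u: int) -> float:
    """Probability 1 - (1-p)^u that a pool of u independent individuals tests
    positive; equally, the probability an individual is declared infected by a
    strategy whose final group size is u."""
    if u < 1:
        raise ValueError("group size must be >= 1")
    return 1.0 - (1.0 - p) ** u


def ksg_rate(p: float, strategy: KSGStrategy) -> float:
    """Expected tests per individual of a kSG strategy at prevalence p.

    1/u1 for the first stage, plus, for each later stage, one test per
    subgroup of every pool that turned positive at the previous stage:
    R = 1/u1 + sum_l (1 - (1-p)^{u_l}) / u_{l+1}.
    """
    us = strategy.group_sizes
    rate = 1.0 / us[0]
    for ul, un in zip(us, us[1:]):
        rate += positive_probability(p, ul) / un
    return rate


def ksg_cost(p: float, b: float, strategy: KSGStrategy) -> float:
    """Expected cost per individual of a kSG strategy.

    Perfect tests mean no false negatives; a healthy individual is a false
    positive exactly when some other member of its final subgroup is infected:
    D = b * (1 - p - (1-p)^{u_k}).  Only the final group size matters.
    """
    uk = strategy.final_size
    return b * (1.0 - p - (1.0 - p) ** uk)


def default_assignment(sub: Subpopulation) -> str:
    """Cost-optimal blanket status for untested individuals.

    'healthy' iff p*c <= (1-p)*b (expected cost of the healthy default does
    not exceed that of the infected default; ties go to healthy).
    """
    p = sub.prevalence
    return (
        "healthy" if p * sub.fn_cost <= (1.0 - p) * sub.fp_cost else "infected"
    )


def no_test_cost(sub: Subpopulation) -> float:
    """Expected cost per individual of the optimal no-test assignment:
    min(p*c, (1-p)*b)."""
    p = sub.prevalence
    return min(p * sub.fn_cost, (1.0 - p) * sub.fp_cost)


_STRATEGY_RE = re.compile(r"^(\d+)SG\((\d+(?:\s*,\s*\d+)*)\)$")


def parse_strategy(text: str) -> KSGStrategy | None:
    """Parse strategy notation: '1SG(33)', '2SG(66,22)', 'kSG(u1,...,uk)',
    'individual' (= 1SG(1)) or 'none' (no test, returned as None)."""
    text = text.strip()
    if text == "none":
        return None
    if text == "individual":
        return INDIVIDUAL
    m = _STRATEGY_RE.match(text)
    if m is None:
        raise ValueError(f"unrecognised strategy notation: {text!r}")
    k = int(m.group(1))
    sizes = tuple(int(u) for u in m.group(2).split(","))
    if k != len(sizes):
        raise ValueError(
            f"stage count {k} does not match the {len(sizes)} group sizes in {text!r}"
        )
    return KSGStrategy(sizes)


def format_strategy(strategy: KSGStrategy | None) -> str:
    """Inverse of :func:`parse_strategy` (bit-exact round trip)."""
    if strategy is None:
        return "none"
    if strategy.group_sizes == (1,):
        return "individual"
    us = strategy.group_sizes
    return f"{len(us)}SG({','.join(str(u) for u in us)})"
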