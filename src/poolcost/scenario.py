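"""Scenario configuration: schema, validation, packaged fixtures.

A scenario file (YAML or JSON) describes the subpopulations of a surveillance
campaign plus optional optimizer settings::

    name: austria_nov2020
    budget_tests: 103621
    max_stages: 2
    max_group: 100
    subpopulations:
      - name: healthcare_high_prevalence
        size: 1413
        prevalence: 0.196
        fp_cost: 6
        fn_cost: 33

Cost units are arbitrary but must be consistent across subpopulations within
a scenario: the heterogeneous lower bound and the optimizer sum b_i-scaled
terms, so mixing unit conventions silently skews the allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import yaml

from .strategies import Subpopulation

__all__ = [
    "Scenario",
    "load_scenario",
    "save_scenario",
    "austria_nov2020",
    "example_toy_scenario",
]

_SCENARIO_KEYS = {"name", "subpopulations", "budget_tests", "max_stages", "max_group", "seed"}
_SUB_KEYS = {"name", "size", "prevalence", "fp_cost", "fn_cost"}


@dataclass(frozen=True)
class Scenario:
    """A named population partition with optional budget and optimizer
    settings."""

    name: str
    subpopulations: tuple[Subpopulation, ...]
    budget_tests: int | None = None
    max_stages: int = 2
    max_group: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.subpopulations:
            raise ValueError("scenario needs at least one subpopulation")
        if self.budget_tests is not None and self.budget_tests < 0:
            raise ValueError("budget_tests must be non-negative")
        if self.max_stages < 1 or self.max_group < 1:
            raise ValueError("max_stages and max_group must be >= 1")

    @property
    def population(self) -> int:
        return sum(s.size for s in self.subpopulations)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "subpopulations": [
                {
                    "name": s.name,
                    "size": s.size,
                    "prevalence": s.prevalence,
                    "fp_cost": s.fp_cost,
                    "fn_cost": s.fn_cost,
                }
                for s in self.subpopulations
            ],
            "max_stages": self.max_stages,
            "max_group": self.max_group,
        }
        if self.budget_tests is not None:
            d["budget_tests"] = self.budget_tests
        if self.seed is not None:
            d["seed"] = self.seed
        return d


def _parse_subpopulation(raw: Any, index: int) -> Subpopulation:
    where = f"subpopulations[{index}]"
    if not isinstance(raw, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _SUB_KEYS
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    missing = _SUB_KEYS - set(raw)
    if missing:
        raise ValueError(f"{where}: missing keys {sorted(missing)}")
    try:
        return Subpopulation(
            name=str(raw["name"]),
            size=int(raw["size"]),
            prevalence=float(raw["prevalence"]),
            fp_cost=float(raw["fp_cost"]),
            fn_cost=float(raw["fn_cost"]),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: {exc}") from exc


def scenario_from_dict(raw: Any) -> Scenario:
    """Validate a parsed config mapping into a Scenario (unknown keys are
    rejected, all invariants enforced; errors name the offending field)."""
    if not isinstance(raw, dict):
        raise ValueError(f"scenario must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys {sorted(unknown)}")
    if "name" not in raw or "subpopulations" not in raw:
        raise ValueError("scenario requires 'name' and 'subpopulations'")
    subs_raw = raw["subpopulations"]
    if not isinstance(subs_raw, list):
        raise ValueError("'subpopulations' must be a list")
    subs = tuple(
        _parse_subpopulation(s, i) for i, s in enumerate(subs_raw)
    )
    return Scenario(
        name=str(raw["name"]),
        subpopulations=subs,
        budget_tests=(
            int(raw["budget_tests"]) if raw.get("budget_tests") is not None else None
        ),
        max_stages=int(raw.get("max_stages", 2)),
        max_group=int(raw.get("max_group", 100)),
        seed=int(raw["seed"]) if raw.get("seed") is not None else None,
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML; JSON is a YAML subset)."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: not valid YAML/JSON: {exc}") from exc
    try:
        return scenario_from_dict(raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as YAML (round-trips through load_scenario)."""
    Path(path).write_text(
        yaml.safe_dump(scenario.to_dict(), sort_keys=False)
    )


def austria_nov2020() -> Scenario:
    """The packaged four-subpopulation scenario for Austria, mid November
    2020: high/low-prevalence splits of the health-care workforce and the
    general population, with a test budget of 103 621 (the PCR tests actually
    used over three days)."""
    with resources.files("poolcost.data").joinpath("austria_nov2020.yaml").open() as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def example_toy_scenario(size: int = 1_000_000) -> Scenario:
    """Single-subpopulation toy scenario: prevalence 1%, a false negative
    fifty times worse than a false positive.  The no-test optimum is the
    blanket healthy assignment at cost 0.5 per individual."""
    return Scenario(
        name="toy_p01_a50",
        subpopulations=(
            Subpopulation(
                name="population",
                size=size,
                prevalence=0.01,
                fp_cost=1.0,
                fn_cost=50.0,
            ),
        ),
    )
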