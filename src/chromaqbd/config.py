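"""Structured run configuration (YAML/JSON) with eager validation.

A config file declares the factors with their natural ranges, the CMAs,
the desirability goals, the specification windows, and the Monte Carlo /
robustness settings, mirroring how such studies are set up in practice.
Validation happens on load; every error message names the offending
section and entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .designs import Factor
from .desirability import DesirabilityGoal
from .io import SchemaError, factors_from_records, goals_from_records, windows_from_records
from .modr import SpecWindow
from .monte_carlo import CMPDistribution

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    factors: list[Factor]
    cmas: list[str]
    goals: list[DesirabilityGoal] = field(default_factory=list)
    windows: list[SpecWindow] = field(default_factory=list)
    mc_distributions: list[CMPDistribution] = field(default_factory=list)
    mc_n_draws: int = 100_000
    mc_include_residual_noise: bool = True
    robustness_alpha: float = 0.05
    robustness_method: str = "regression_residual"
    seed: int = 0
    output_dir: str = "chromaqbd_out"
    verbosity: int = 1

    def __post_init__(self) -> None:
        names = {f.name for f in self.factors}
        if len(names) != len(self.factors):
            raise SchemaError("config: duplicate factor names")
        declared = set(self.cmas)
        for g in self.goals:
            if g.cma not in declared:
                raise SchemaError(f"config: goal references undeclared CMA {g.cma!r}")
        for w in self.windows:
            if w.cma not in declared:
                raise SchemaError(f"config: window references undeclared CMA {w.cma!r}")
        for d in self.mc_distributions:
            if d.name not in names:
                raise SchemaError(
                    f"config: Monte Carlo distribution for unknown factor {d.name!r}"
                )
        if not isinstance(self.seed, int):
            raise SchemaError("config: seed must be an integer")


def _mc_distributions(records: list[dict], factors: list[Factor]) -> list[CMPDistribution]:
    by_name = {f.name: f for f in factors}
    out = []
    for i, r in enumerate(records):
        try:
            name = str(r["name"])
            kind = str(r.get("kind", "uniform"))
            params = tuple(float(v) for v in r["params"])
            f = by_name.get(name)
            out.append(
                CMPDistribution(
                    name=name,
                    kind=kind,
                    params=params,
                    trunc_low=f.low if f is not None else None,
                    trunc_high=f.high if f is not None else None,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"monte_carlo distribution entry {i + 1}: {exc}") from exc
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    if "factors" not in raw:
        raise SchemaError(f"{path}: missing required section 'factors'")

    factors = factors_from_records(raw["factors"])
    cmas = [str(c) for c in raw.get("cmas", [])]
    mc = raw.get("monte_carlo", {}) or {}
    rob = raw.get("robustness", {}) or {}
    return RunConfig(
        factors=factors,
        cmas=cmas,
        goals=goals_from_records(raw.get("goals", []) or []),
        windows=windows_from_records(raw.get("windows", []) or []),
        mc_distributions=_mc_distributions(mc.get("distributions", []) or [], factors),
        mc_n_draws=int(mc.get("n_draws", 100_000)),
        mc_include_residual_noise=bool(mc.get("include_residual_noise", True)),
        robustness_alpha=float(rob.get("alpha", 0.05)),
        robustness_method=str(rob.get("method", "regression_residual")),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "chromaqbd_out")),
        verbosity=int(raw.get("verbosity", 1)),
    )
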