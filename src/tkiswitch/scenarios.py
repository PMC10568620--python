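"""Seeded synthetic scenario generation for property testing.

Draws random regimen parameter tables and initial tumor compositions that
obey the structural assumptions of the model:

* sign structure — under DrugA the W and Y populations decay while X and Z
  grow; under DrugB, W and X decay while Y and Z grow; under the
  combination, only Z grows;
* mutation rates are small, positive, and shared across regimens;
* initial compositions are dominated by Type-W with log-uniform resistant
  seeds, as for a newly detected tumor.

Randomness uses :func:`numpy.random.default_rng` (PCG64), which is
reproducible across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import (
    GROWTH_RATE_NAMES,
    MUTATION_RATE_NAMES,
    RegimenParameters,
    TumorState,
    default_parameter_table,
)

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "sample_regimen_parameters",
    "sample_initial_state",
    "sample_scenario",
    "generate_scenarios",
    "write_scenarios_jsonl",
    "read_scenarios_jsonl",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ranges for random scenario draws.

    Growth rates are drawn sign-preserving within ``growth_rate_spread``
    (default ±50%) of the published magnitudes; mutation rates log-uniform
    in ``mutation_rate_range``; resistant-cell fractions log-uniform in the
    per-type ranges, with Type-W absorbing the remainder of ``total_cells``.
    """

    seed: int | None = None
    growth_rate_spread: float = 0.5
    mutation_rate_range: tuple[float, float] = (1e-9, 1e-5)
    total_cells: float = 1e9
    x_fraction_range: tuple[float, float] = (1e-8, 1e-2)
    y_fraction_range: tuple[float, float] = (1e-8, 1e-2)
    z_fraction_range: tuple[float, float] = (1e-9, 1e-5)
    max_tries: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.growth_rate_spread < 1):
            raise ValueError("growth_rate_spread must lie in (0, 1)")
        for name in (
            "mutation_rate_range",
            "x_fraction_range",
            "y_fraction_range",
            "z_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        lo, hi = self.mutation_rate_range
        if hi >= 1e-3:
            raise ValueError("mutation rates above 1e-3/day are outside the model regime")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Scenario:
    params_table: dict[str, RegimenParameters]
    initial: TumorState


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_regimen_parameters(
    config: ScenarioConfig, rng: np.random.Generator
) -> dict[str, RegimenParameters]:
    """Draw a random rate table with the published sign structure.

    Magnitudes are uniform within ±``growth_rate_spread`` of the bundled
    defaults (signs preserved); one set of five mutation rates is drawn
    log-uniform and shared by all three regimens.  Draws whose growth rates
    nearly coincide (degenerate eigenvalues for the closed form) are
    rejected and redrawn, up to ``max_tries``.
    """
    base = default_parameter_table()
    lo_mut, hi_mut = config.mutation_rate_range
    for _ in range(config.max_tries):
        mutation = {
            name: _log_uniform(rng, lo_mut, hi_mut) for name in MUTATION_RATE_NAMES
        }
        table: dict[str, RegimenParameters] = {}
        for label, params in base.items():
            growth = {}
            for name in GROWTH_RATE_NAMES:
                default = getattr(params, name)
                factor = rng.uniform(
                    1 - config.growth_rate_spread, 1 + config.growth_rate_spread
                )
                growth[name] = default * factor
            table[label] = RegimenParameters(label=label, **growth, **mutation)
        if not any(p.is_degenerate() for p in table.values()):
            return table
    raise RuntimeError(
        f"rejection sampling exhausted after {config.max_tries} tries "
        "(degenerate growth-rate draws)"
    )


def sample_initial_state(
    config: ScenarioConfig, rng: np.random.Generator
) -> TumorState:
    """Draw a random initial composition; always valid (W dominates)."""
    fx = _log_uniform(rng, *config.x_fraction_range)
    fy = _log_uniform(rng, *config.y_fraction_range)
    fz = _log_uniform(rng, *config.z_fraction_range)
    total = config.total_cells
    x, y, z = fx * total, fy * total, fz * total
    return TumorState(w=total - (x + y + z), x=x, y=y, z=z, t=0.0)


def sample_scenario(config: ScenarioConfig, rng: np.random.Generator) -> Scenario:
    return Scenario(
        params_table=sample_regimen_parameters(config, rng),
        initial=sample_initial_state(config, rng),
    )


def generate_scenarios(
    n: int, config: ScenarioConfig | None = None, seed: int | None = None
) -> list[Scenario]:
    """Draw ``n`` scenarios; ``seed`` overrides the config's seed."""
    if config is None:
        config = ScenarioConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    return [sample_scenario(config, rng) for _ in range(n)]


def _scenario_to_dict(s: Scenario) -> dict:
    return {
        "params": {label: p.as_dict() for label, p in s.params_table.items()},
        "initial": {"w": s.initial.w, "x": s.initial.x, "y": s.initial.y, "z": s.initial.z},
    }


def _scenario_from_dict(d: dict) -> Scenario:
    table = {
        label: RegimenParameters.from_dict(label, rates)
        for label, rates in d["params"].items()
    }
    ini = d["initial"]
    return Scenario(
        params_table=table,
        initial=TumorState(w=ini["w"], x=ini["x"], y=ini["y"], z=ini["z"], t=0.0),
    )


def write_scenarios_jsonl(path, scenarios) -> None:
    """One JSON object per line: parameter table + initial state."""
    with open(path, "w") as fh:
        for s in scenarios:
            fh.write(json.dumps(_scenario_to_dict(s)) + "\n")


def read_scenarios_jsonl(path) -> list[Scenario]:
    with open(path) as fh:
        return [_scenario_from_dict(json.loads(line)) for line in fh if line.strip()]
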