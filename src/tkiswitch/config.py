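"""Run configuration: YAML/JSON loading, validation and defaults.

A :class:`RunConfig` bundles everything the end-to-end pipeline needs: the
per-regimen rate table, the initial tumor composition, the schedule
defaults (switch days, horizon) and the experiment grids.  Omitted fields
fall back to the bundled published defaults, so an empty config file
reproduces the standard study conditions exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .model import (
    RegimenParameters,
    TumorState,
    _load_bundled_defaults,
    standard_initial_state,
)

__all__ = [
    "SchemaViolationError",
    "InitialCondition",
    "ScheduleConfig",
    "GridConfig",
    "RunConfig",
    "default_config",
    "load_config",
    "save_config",
]


class SchemaViolationError(ValueError):
    """A config field that is unknown, mistyped or out of range."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass(frozen=True)
class InitialCondition:
    total: float = 1e9
    x0: float = 1e4
    y0: float = 1e4
    z0: float = 10.0

    def state(self) -> TumorState:
        return standard_initial_state(self.total, self.x0, self.y0, self.z0)


@dataclass(frozen=True)
class ScheduleConfig:
    switch_a_first: float = 307.0
    switch_b_first: float = 567.0
    horizon: float = 1000.0
    output_step: float = 1.0

    @property
    def switch_days(self) -> dict[str, float]:
        return {"A-first": self.switch_a_first, "B-first": self.switch_b_first}


@dataclass(frozen=True)
class GridConfig:
    """Experiment grid resolutions (all configurable; defaults balance the
    published axis ranges against run time)."""

    switch_day_start: int = 1
    switch_day_stop: int = 999
    switch_day_step: int = 1
    proportion_points_per_decade: int = 8
    xy_proportion_range: tuple[float, float] = (1e-8, 1e-1)
    z_proportion_range: tuple[float, float] = (1e-9, 1e-5)
    selection_map_size: int = 25
    area_map_size: int = 15
    growth_axis_halfwidth: float = 0.1
    growth_axis_points: int = 21
    mutation_axis_range: tuple[float, float] = (1e-9, 1e-5)
    mutation_axis_points: int = 17
    area_axis_points: int = 9
    #: Relative change below which a sweep counts as "unchanged".
    flat_threshold: float = 0.01

    def switch_days(self) -> np.ndarray:
        return np.arange(
            self.switch_day_start, self.switch_day_stop + 1, self.switch_day_step
        )

    def proportion_decades(self, lo: float, hi: float) -> np.ndarray:
        """Exact decade points plus log-spaced fill-in between them."""
        n_decades = int(round(np.log10(hi / lo)))
        n = n_decades * self.proportion_points_per_decade + 1
        fine = np.logspace(np.log10(lo), np.log10(hi), n)
        decades = np.logspace(np.log10(lo), np.log10(hi), n_decades + 1)
        return np.unique(np.concatenate([fine, decades]))


@dataclass(frozen=True)
class RunConfig:
    parameters: dict[str, RegimenParameters]
    initial: InitialCondition = InitialCondition()
    schedule: ScheduleConfig = ScheduleConfig()
    grids: GridConfig = GridConfig()
    out_dir: str = "tkiswitch-output"
    seed: int = 0

    def validate(self) -> "RunConfig":
        for label in ("A", "B", "C"):
            if label not in self.parameters:
                raise SchemaViolationError(
                    f"parameters.{label}", "regimen missing from table"
                )
        T = self.schedule.horizon
        for name in ("switch_a_first", "switch_b_first"):
            day = getattr(self.schedule, name)
            if not (0 <= day <= T):
                raise SchemaViolationError(
                    f"schedule.{name}", f"switch day {day} outside [0, {T}]"
                )
        if self.schedule.output_step <= 0:
            raise SchemaViolationError("schedule.output_step", "must be > 0")
        seeds = self.initial.x0 + self.initial.y0 + self.initial.z0
        if self.initial.total <= seeds:
            raise SchemaViolationError(
                "initial", f"resistant seeds {seeds} exhaust total {self.initial.total}"
            )
        return self


def _bundled_default_dict() -> dict:
    return _load_bundled_defaults()


def default_config() -> RunConfig:
    """The published study conditions."""
    raw = _bundled_default_dict()
    return _config_from_dict(raw)


_SECTION_FIELDS = {
    "initial": InitialCondition,
    "schedule": ScheduleConfig,
    "grids": GridConfig,
}
_TOP_LEVEL_SCALARS = ("out_dir", "seed")


def _coerce_section(name: str, cls, raw: dict):
    defaults = cls()
    known = set(defaults.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaViolationError(
            f"{name}.{sorted(unknown)[0]}", "unknown field"
        )
    kwargs = {}
    for key, value in raw.items():
        current = getattr(defaults, key)
        try:
            if isinstance(current, tuple):
                value = tuple(float(v) for v in value)
            elif isinstance(current, float):
                value = float(value)
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, str):
                value = str(value)
        except (TypeError, ValueError) as exc:
            raise SchemaViolationError(f"{name}.{key}", f"bad value {value!r}") from exc
        kwargs[key] = value
    return replace(defaults, **kwargs)


def _config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    known_keys = {"parameters", *_SECTION_FIELDS, *_TOP_LEVEL_SCALARS}
    unknown = set(raw) - known_keys
    if unknown:
        raise SchemaViolationError(sorted(unknown)[0], "unknown top-level field")

    defaults = _bundled_default_dict()
    table_raw = {
        label: dict(rates) for label, rates in defaults["parameters"].items()
    }
    for label, overrides in (raw.get("parameters") or {}).items():
        if label not in table_raw:
            raise SchemaViolationError(f"parameters.{label}", "unknown regimen")
        for rate, value in dict(overrides).items():
            if rate not in table_raw[label]:
                raise SchemaViolationError(
                    f"parameters.{label}.{rate}", "unknown rate name"
                )
            table_raw[label][rate] = float(value)
    try:
        parameters = {
            label: RegimenParameters.from_dict(label, rates)
            for label, rates in table_raw.items()
        }
    except ValueError as exc:
        raise SchemaViolationError("parameters", str(exc)) from exc

    sections = {}
    for name, cls in _SECTION_FIELDS.items():
        merged = dict(defaults.get(name, {}))
        merged.update(raw.get(name) or {})
        sections[name] = _coerce_section(name, cls, merged)

    config = RunConfig(
        parameters=parameters,
        initial=sections["initial"],
        schedule=sections["schedule"],
        grids=sections["grids"],
        out_dir=str(raw.get("out_dir", "tkiswitch-output")),
        seed=int(raw.get("seed", 0)),
    )
    return config.validate()


def load_config(path=None) -> RunConfig:
    """Load a YAML (or JSON) config; omitted fields take published defaults.

    ``path=None`` or an empty file yields the full default configuration.
    """
    if path is None:
        return default_config()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaViolationError("<root>", "config must be a mapping")
    return _config_from_dict(raw)


def _config_to_dict(config: RunConfig) -> dict:
    return {
        "parameters": {
            label: p.as_dict() for label, p in sorted(config.parameters.items())
        },
        "initial": asdict(config.initial),
        "schedule": asdict(config.schedule),
        "grids": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(config.grids).items()
        },
        "out_dir": config.out_dir,
        "seed": config.seed,
    }


def save_config(config: RunConfig, path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
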