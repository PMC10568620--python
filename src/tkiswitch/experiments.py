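"""The five computational experiments on the four-genotype therapy model.

* switch-time sweep — day-1000 burden as a function of the drug-switch day;
* initial-proportion sweep — sensitivity of the final burden to the initial
  fraction of each resistant genotype;
* therapy-selection map — best strategy over a grid of initial Type-X /
  Type-Y fractions;
* parameter-sensitivity grid — final burden as one rate constant varies
  under the first-line / second-line regimens (2-D) or the combination
  regimen (1-D);
* selection-area composition — how the map's strategy areas shift as one
  rate constant is perturbed.

Every experiment is a pure function of (parameters, initial state, grids):
repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    GROWTH_RATE_NAMES,
    MUTATION_RATE_NAMES,
    RATE_NAMES,
    RegimenParameters,
    TumorState,
    standard_initial_state,
)
from .therapy import (
    DEFAULT_HORIZON,
    DEFAULT_SWITCH_DAYS,
    STRATEGIES,
    TreatmentSchedule,
    final_total,
    standard_schedules,
    strategy_schedule,
)

__all__ = [
    "UnknownParameterError",
    "SwitchSweepResult",
    "ProportionSweepResult",
    "SelectionMap",
    "SensitivityGrid",
    "AreaComposition",
    "sweep_switch_time",
    "sweep_initial_proportion",
    "build_selection_map",
    "parameter_sensitivity_grid",
    "selection_area_composition",
    "default_axis_values",
    "default_map_fractions",
    "STANDARD_TOTAL",
    "STANDARD_SEEDS",
    "TIE_RELATIVE_TOLERANCE",
    "TIE_PRECEDENCE",
]

#: Standard initial tumor size and resistant seeds (X0, Y0, Z0).
STANDARD_TOTAL = 1e9
STANDARD_SEEDS = {"X": 1e4, "Y": 1e4, "Z": 10.0}

#: Finals within this relative distance of the minimum count as tied;
#: ties are resolved by a fixed (documented, arbitrary) precedence.
TIE_RELATIVE_TOLERANCE = 1e-9
TIE_PRECEDENCE = ("B-first", "A-first", "C")


class UnknownParameterError(ValueError):
    """A rate-constant name outside {a, b, c, f, g, h, k, p, q}."""


def _check_parameter_name(name: str) -> None:
    if name not in RATE_NAMES:
        raise UnknownParameterError(
            f"unknown parameter {name!r}; expected one of {RATE_NAMES}"
        )


def _initial_from_counts(x0: float, y0: float, z0: float, total: float) -> TumorState:
    return standard_initial_state(total=total, x0=x0, y0=y0, z0=z0)


# ---------------------------------------------------------------------------
# switch-time sweep

@dataclass(frozen=True)
class SwitchSweepResult:
    """Day-``horizon`` total burden for each tested drug-switch day."""

    strategy: str
    switch_days: np.ndarray
    finals: np.ndarray

    @property
    def min_final(self) -> float:
        return float(self.finals.min())

    @property
    def argmin_day(self) -> float:
        return float(self.switch_days[int(np.argmin(self.finals))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "switch_day": self.switch_days,
                "final_total": self.finals,
            }
        )


def sweep_switch_time(
    strategy: str,
    switch_days,
    params_table: dict[str, RegimenParameters],
    initial: TumorState | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> SwitchSweepResult:
    """Final burden of a two-phase schedule for each candidate switch day."""
    if strategy not in ("A-first", "B-first"):
        raise ValueError(f"switch sweep needs a sequential strategy, got {strategy!r}")
    if initial is None:
        initial = standard_initial_state()
    days = np.asarray(switch_days, dtype=float)
    if days.size and (days.min() < 0 or days.max() > horizon):
        raise ValueError(f"switch days must lie within [0, {horizon}]")
    finals = np.array(
        [
            final_total(initial, strategy_schedule(strategy, s, horizon), params_table)
            for s in days
        ]
    )
    return SwitchSweepResult(strategy=strategy, switch_days=days, finals=finals)


# ---------------------------------------------------------------------------
# initial-proportion sweep

@dataclass(frozen=True)
class ProportionSweepResult:
    """Final burden vs the initial fraction of one resistant genotype."""

    varied_type: str
    proportions: np.ndarray
    finals_per_strategy: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "varied_type": self.varied_type,
                    "proportion": self.proportions,
                    "strategy": strategy,
                    "final_total": finals,
                }
            )
            for strategy, finals in self.finals_per_strategy.items()
        ]
        return pd.concat(frames, ignore_index=True)


def sweep_initial_proportion(
    varied_type: str,
    proportions,
    strategies=STRATEGIES,
    params_table: dict[str, RegimenParameters] | None = None,
    total: float = STANDARD_TOTAL,
    switch_days: dict[str, float] = DEFAULT_SWITCH_DAYS,
    horizon: float = DEFAULT_HORIZON,
) -> ProportionSweepResult:
    """Vary one resistant genotype's initial fraction, others standard.

    The varied type's initial count is ``proportion * total``; the other two
    resistant types keep their standard seeds (X0 = Y0 = 1e4, Z0 = 10) and
    Type-W absorbs the remainder.
    """
    if varied_type not in ("X", "Y", "Z"):
        raise ValueError(f"varied_type must be X, Y or Z, got {varied_type!r}")
    if params_table is None:
        from .model import default_parameter_table

        params_table = default_parameter_table()
    props = np.asarray(proportions, dtype=float)
    if props.size == 0 or np.any(np.diff(props) <= 0):
        raise ValueError("proportions must be non-empty and strictly increasing")
    if props.min() <= 0 or props.max() >= 1:
        raise ValueError("proportions must lie in (0, 1)")

    schedules = standard_schedules(
        sta=switch_days.get("A-first", DEFAULT_SWITCH_DAYS["A-first"]),
        stb=switch_days.get("B-first", DEFAULT_SWITCH_DAYS["B-first"]),
        horizon=horizon,
    )
    finals: dict[str, np.ndarray] = {s: np.empty(props.size) for s in strategies}
    for i, prop in enumerate(props):
        counts = dict(STANDARD_SEEDS)
        counts[varied_type] = prop * total
        initial = _initial_from_counts(counts["X"], counts["Y"], counts["Z"], total)
        for s in strategies:
            finals[s][i] = final_total(initial, schedules[s], params_table)
    return ProportionSweepResult(
        varied_type=varied_type, proportions=props, finals_per_strategy=finals
    )


# ---------------------------------------------------------------------------
# therapy-selection map

@dataclass(frozen=True)
class SelectionMap:
    """Best strategy per cell of an initial (X, Y)-fraction grid.

    ``finals`` has shape (len(x_props), len(y_props), 3) with the last axis
    ordered as :data:`~tkiswitch.therapy.STRATEGIES` (A-first, B-first, C).
    ``best`` labels the argmin under the tie-break precedence; ``tied``
    flags cells where two strategies agree within the tie tolerance.
    """

    x_props: np.ndarray
    y_props: np.ndarray
    finals: np.ndarray
    best: np.ndarray
    tied: np.ndarray

    def best_at(self, x_prop: float, y_prop: float) -> str:
        i = int(np.argmin(np.abs(self.x_props - x_prop)))
        j = int(np.argmin(np.abs(self.y_props - y_prop)))
        return str(self.best[i, j])

    def area_fractions(self) -> dict[str, float]:
        n = self.best.size
        return {s: float(np.sum(self.best == s)) / n for s in STRATEGIES}

    def to_frame(self) -> pd.DataFrame:
        xi, yj = np.meshgrid(
            np.arange(self.x_props.size), np.arange(self.y_props.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "x_prop": self.x_props[xi.ravel()],
                "y_prop": self.y_props[yj.ravel()],
                "final_A_first": self.finals[:, :, 0].ravel(),
                "final_B_first": self.finals[:, :, 1].ravel(),
                "final_C": self.finals[:, :, 2].ravel(),
                "best": self.best.ravel(),
            }
        )


def _argmin_with_precedence(finals: np.ndarray) -> tuple[str, bool]:
    """Pick the smallest final; near-equal finals go to the fixed precedence."""
    fmin = finals.min()
    tied_mask = finals <= fmin * (1 + TIE_RELATIVE_TOLERANCE)
    candidates = [s for s, m in zip(STRATEGIES, tied_mask) if m]
    if len(candidates) == 1:
        return candidates[0], False
    for s in TIE_PRECEDENCE:
        if s in candidates:
            return s, True
    raise AssertionError("unreachable")


def default_map_fractions(n: int = 25, lo: float = 1e-8, hi: float = 1e-1) -> np.ndarray:
    """Log-spaced fraction grid used for the selection map axes."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def build_selection_map(
    x_props,
    y_props,
    params_table: dict[str, RegimenParameters] | None = None,
    z0: float = 10.0,
    switch_days: dict[str, float] = DEFAULT_SWITCH_DAYS,
    total: float = STANDARD_TOTAL,
    horizon: float = DEFAULT_HORIZON,
) -> SelectionMap:
    """Label, per (X, Y)-fraction cell, the strategy minimising final burden.

    Type-Z stays fixed at ``z0`` cells (default 10) across the whole map.
    """
    if params_table is None:
        from .model import default_parameter_table

        params_table = default_parameter_table()
    xs = np.asarray(x_props, dtype=float)
    ys = np.asarray(y_props, dtype=float)
    if xs.min() <= 0 or xs.max() >= 1 or ys.min() <= 0 or ys.max() >= 1:
        raise ValueError("fraction grids must lie in (0, 1)")

    schedules = standard_schedules(
        sta=switch_days.get("A-first", DEFAULT_SWITCH_DAYS["A-first"]),
        stb=switch_days.get("B-first", DEFAULT_SWITCH_DAYS["B-first"]),
        horizon=horizon,
    )
    finals = np.empty((xs.size, ys.size, len(STRATEGIES)))
    best = np.empty((xs.size, ys.size), dtype=object)
    tied = np.zeros((xs.size, ys.size), dtype=bool)
    for i, xp in enumerate(xs):
        for j, yp in enumerate(ys):
            initial = _initial_from_counts(xp * total, yp * total, z0, total)
            cell = np.array(
                [final_total(initial, schedules[s], params_table) for s in STRATEGIES]
            )
            finals[i, j] = cell
            best[i, j], tied[i, j] = _argmin_with_precedence(cell)
    return SelectionMap(x_props=xs, y_props=ys, finals=finals, best=best, tied=tied)


# ---------------------------------------------------------------------------
# parameter sensitivity

@dataclass(frozen=True)
class SensitivityGrid:
    """Final burden as one rate constant varies under a strategy.

    For the sequential strategies the grid is 2-D: ``axis1`` holds the
    parameter's values under the first-line regimen (rows of ``finals``)
    and ``axis2`` under the second-line regimen (columns).  For combination
    therapy ``axis2`` is ``None`` and ``finals`` is 1-D over values under
    regimen C.
    """

    parameter_name: str
    strategy: str
    axis1: np.ndarray
    axis2: np.ndarray | None
    finals: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        if self.axis2 is None:
            return pd.DataFrame(
                {
                    "parameter": self.parameter_name,
                    "strategy": self.strategy,
                    "value_first": self.axis1,
                    "value_second": np.nan,
                    "final_total": self.finals,
                }
            )
        ii, jj = np.meshgrid(
            np.arange(self.axis1.size), np.arange(self.axis2.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "parameter": self.parameter_name,
                "strategy": self.strategy,
                "value_first": self.axis1[ii.ravel()],
                "value_second": self.axis2[jj.ravel()],
                "final_total": self.finals.ravel(),
            }
        )


def default_axis_values(parameter_name: str, default_value: float) -> np.ndarray:
    """Default sweep axis: growth rates span default ± 0.1/day on a 21-point
    linear grid (crossing the sign change); mutation rates span the
    biologically plausible 1e-9…1e-5/day on a 17-point log grid."""
    _check_parameter_name(parameter_name)
    if parameter_name in GROWTH_RATE_NAMES:
        return np.linspace(default_value - 0.1, default_value + 0.1, 21)
    return np.logspace(-9, -5, 17)


def _strategy_regimens(strategy: str) -> tuple[str, ...]:
    if strategy == "A-first":
        return ("A", "B")
    if strategy == "B-first":
        return ("B", "A")
    if strategy == "C":
        return ("C",)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def parameter_sensitivity_grid(
    parameter_name: str,
    axis_values,
    params_table: dict[str, RegimenParameters] | None = None,
    strategy: str = "A-first",
    initial: TumorState | None = None,
    switch_days: dict[str, float] = DEFAULT_SWITCH_DAYS,
    horizon: float = DEFAULT_HORIZON,
) -> SensitivityGrid:
    """Sweep one rate constant, all other rates fixed at their defaults.

    ``axis_values`` is a 1-D array applied to both axes of the 2-D grid (or
    a pair ``(first_line_values, second_line_values)``); for combination
    therapy a single 1-D array.
    """
    _check_parameter_name(parameter_name)
    if params_table is None:
        from .model import default_parameter_table

        params_table = default_parameter_table()
    if initial is None:
        initial = standard_initial_state()
    regimens = _strategy_regimens(strategy)

    if strategy == "C":
        values = np.asarray(axis_values, dtype=float)
        schedule = strategy_schedule("C", horizon=horizon)
        finals = np.empty(values.size)
        for i, v in enumerate(values):
            table = dict(params_table)
            table["C"] = table["C"].replace(**{parameter_name: float(v)})
            finals[i] = final_total(initial, schedule, table)
        return SensitivityGrid(
            parameter_name=parameter_name,
            strategy=strategy,
            axis1=values,
            axis2=None,
            finals=finals,
        )

    if (
        isinstance(axis_values, (tuple, list))
        and len(axis_values) == 2
        and np.ndim(axis_values[0]) == 1
    ):
        axis1 = np.asarray(axis_values[0], dtype=float)
        axis2 = np.asarray(axis_values[1], dtype=float)
    else:
        axis1 = np.asarray(axis_values, dtype=float)
        axis2 = axis1.copy()

    first, second = regimens
    sw = switch_days.get(strategy, DEFAULT_SWITCH_DAYS[strategy])
    schedule = strategy_schedule(strategy, sw, horizon)
    finals = np.empty((axis1.size, axis2.size))
    for i, v1 in enumerate(axis1):
        for j, v2 in enumerate(axis2):
            table = dict(params_table)
            table[first] = table[first].replace(**{parameter_name: float(v1)})
            table[second] = table[second].replace(**{parameter_name: float(v2)})
            finals[i, j] = final_total(initial, schedule, table)
    return SensitivityGrid(
        parameter_name=parameter_name,
        strategy=strategy,
        axis1=axis1,
        axis2=axis2,
        finals=finals,
    )


# ---------------------------------------------------------------------------
# selection-map area composition

@dataclass(frozen=True)
class AreaComposition:
    """Strategy area fractions of the selection map vs one rate constant.

    ``parameter_name`` names the rate and the regimen it is perturbed under,
    e.g. ``"a_B"`` for Type-W's growth rate under osimertinib.
    """

    parameter_name: str
    parameter_values: np.ndarray
    fractions: tuple[dict[str, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter_name,
                "value": self.parameter_values,
                "frac_A_first": [f["A-first"] for f in self.fractions],
                "frac_B_first": [f["B-first"] for f in self.fractions],
                "frac_C": [f["C"] for f in self.fractions],
            }
        )


def _parse_regimen_parameter(name: str) -> tuple[str, str]:
    try:
        rate, regimen = name.split("_")
    except ValueError:
        raise UnknownParameterError(
            f"expected '<rate>_<regimen>' (e.g. 'a_B'), got {name!r}"
        ) from None
    _check_parameter_name(rate)
    if regimen not in ("A", "B", "C"):
        raise UnknownParameterError(f"unknown regimen {regimen!r} in {name!r}")
    return rate, regimen


def selection_area_composition(
    parameter_name: str,
    parameter_values,
    params_table: dict[str, RegimenParameters] | None = None,
    x_props=None,
    y_props=None,
    z0: float = 10.0,
    switch_days: dict[str, float] = DEFAULT_SWITCH_DAYS,
    total: float = STANDARD_TOTAL,
    horizon: float = DEFAULT_HORIZON,
) -> AreaComposition:
    """Rebuild the selection map for each value of one perturbed rate and
    report each strategy's fraction of the map area.

    Defaults to a coarser 15×15 fraction grid than the standalone map, since
    one composition point requires a full map rebuild.
    """
    rate, regimen = _parse_regimen_parameter(parameter_name)
    if params_table is None:
        from .model import default_parameter_table

        params_table = default_parameter_table()
    if x_props is None:
        x_props = default_map_fractions(15)
    if y_props is None:
        y_props = default_map_fractions(15)
    values = np.asarray(parameter_values, dtype=float)

    fractions = []
    for v in values:
        table = dict(params_table)
        table[regimen] = table[regimen].replace(**{rate: float(v)})
        sel = build_selection_map(
            x_props,
            y_props,
            table,
            z0=z0,
            switch_days=switch_days,
            total=total,
            horizon=horizon,
        )
        fractions.append(sel.area_fractions())
    return AreaComposition(
        parameter_name=parameter_name,
        parameter_values=values,
        fractions=tuple(fractions),
    )
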