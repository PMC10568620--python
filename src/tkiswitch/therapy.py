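"""Piecewise therapy scheduling: sequential / combination regimens over time.

A :class:`TreatmentSchedule` is an ordered, contiguous list of phases, each
running one drug regimen between two days.  Within a phase the dynamics are
exact (closed form from the phase-start state — no step-to-step error
accumulation); the phase-end state seeds the next phase.

The three strategies studied throughout the package are:

* ``"A-first"`` — erlotinib-class first, switch to osimertinib at ``sta``
  (default day 307, the erlotinib median progression-free survival);
* ``"B-first"`` — osimertinib first, switch at ``stb`` (default day 567);
* ``"C"``       — combination (erlotinib + osimertinib) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RegimenParameters, TumorState, closed_form_state

__all__ = [
    "InvalidScheduleError",
    "TreatmentPhase",
    "TreatmentSchedule",
    "Trajectory",
    "STRATEGIES",
    "DEFAULT_SWITCH_DAYS",
    "DEFAULT_HORIZON",
    "strategy_schedule",
    "standard_schedules",
    "simulate_schedule",
    "final_total",
    "recurrence_time",
]

STRATEGIES = ("A-first", "B-first", "C")
DEFAULT_SWITCH_DAYS = {"A-first": 307.0, "B-first": 567.0}
DEFAULT_HORIZON = 1000.0

TYPE_LABELS = ("W", "X", "Y", "Z")


class InvalidScheduleError(ValueError):
    """Phases that are out of order, non-contiguous or do not start at day 0."""


@dataclass(frozen=True)
class TreatmentPhase:
    regimen: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise InvalidScheduleError(
                f"phase must satisfy 0 <= start <= end, got [{self.start}, {self.end}]"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TreatmentSchedule:
    """Contiguous drug phases covering [0, horizon]."""

    phases: tuple[TreatmentPhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise InvalidScheduleError("schedule needs at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))
        if self.phases[0].start != 0:
            raise InvalidScheduleError(
                f"first phase must start at day 0, got {self.phases[0].start}"
            )
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if nxt.start != prev.end:
                raise InvalidScheduleError(
                    f"phases are not contiguous: {prev.end} != {nxt.start}"
                )

    @property
    def horizon(self) -> float:
        return self.phases[-1].end

    @classmethod
    def monotherapy(cls, regimen: str, horizon: float = DEFAULT_HORIZON) -> "TreatmentSchedule":
        return cls((TreatmentPhase(regimen, 0.0, float(horizon)),))

    @classmethod
    def sequential(
        cls,
        first: str,
        second: str,
        switch_day: float,
        horizon: float = DEFAULT_HORIZON,
    ) -> "TreatmentSchedule":
        switch_day = float(switch_day)
        if not (0 <= switch_day <= horizon):
            raise InvalidScheduleError(
                f"switch day {switch_day} outside [0, {horizon}]"
            )
        return cls(
            (
                TreatmentPhase(first, 0.0, switch_day),
                TreatmentPhase(second, switch_day, float(horizon)),
            )
        )


def strategy_schedule(
    strategy: str,
    switch_day: float | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> TreatmentSchedule:
    """Build the schedule for one named strategy.

    ``switch_day`` defaults to the clinically motivated value for the
    monotherapy strategies and is ignored for combination therapy.
    """
    if strategy == "A-first":
        sw = DEFAULT_SWITCH_DAYS["A-first"] if switch_day is None else switch_day
        return TreatmentSchedule.sequential("A", "B", sw, horizon)
    if strategy == "B-first":
        sw = DEFAULT_SWITCH_DAYS["B-first"] if switch_day is None else switch_day
        return TreatmentSchedule.sequential("B", "A", sw, horizon)
    if strategy == "C":
        return TreatmentSchedule.monotherapy("C", horizon)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def standard_schedules(
    sta: float = DEFAULT_SWITCH_DAYS["A-first"],
    stb: float = DEFAULT_SWITCH_DAYS["B-first"],
    horizon: float = DEFAULT_HORIZON,
) -> dict[str, TreatmentSchedule]:
    """The three standard strategy schedules keyed by strategy label."""
    return {
        "A-first": strategy_schedule("A-first", sta, horizon),
        "B-first": strategy_schedule("B-first", stb, horizon),
        "C": strategy_schedule("C", horizon=horizon),
    }


@dataclass(frozen=True)
class Trajectory:
    """Per-type and total cell counts on a time grid.

    ``counts`` has one row per time point and columns (w, x, y, z).
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (times.size, 4):
            raise ValueError(f"counts shape {counts.shape} mismatches {times.size} times")
        if times.size and times[0] != 0:
            raise ValueError("trajectory must start at day 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    @property
    def w(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def x(self) -> np.ndarray:
        return self.counts[:, 1]

    @property
    def y(self) -> np.ndarray:
        return self.counts[:, 2]

    @property
    def z(self) -> np.ndarray:
        return self.counts[:, 3]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def states(self) -> list[TumorState]:
        return [
            TumorState.from_array(row, t=t) for t, row in zip(self.times, self.counts)
        ]

    @property
    def final_total(self) -> float:
        return float(self.totals[-1])

    def dominant_types(self) -> np.ndarray:
        """Label of the largest genotype at each time point."""
        return np.array(TYPE_LABELS)[np.argmax(self.counts, axis=1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.times,
                "w": self.w,
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "total": self.totals,
            }
        )


def _output_grid(schedule: TreatmentSchedule, output_step: float) -> np.ndarray:
    horizon = schedule.horizon
    pts = np.arange(0.0, horizon, output_step)
    boundaries = [ph.start for ph in schedule.phases] + [horizon]
    grid = np.unique(np.concatenate([pts, np.asarray(boundaries, dtype=float)]))
    return grid


def simulate_schedule(
    initial: TumorState,
    schedule: TreatmentSchedule,
    params_table: dict[str, RegimenParameters],
    output_step: float = 1.0,
) -> Trajectory:
    """Simulate a schedule; exact within each phase.

    The output grid is {0, step, 2·step, …, horizon} plus every phase
    boundary.  Every point inside a phase is computed by the closed form
    directly from the phase-start state, so accuracy does not depend on the
    output step.
    """
    if output_step <= 0:
        raise ValueError(f"output_step must be > 0, got {output_step}")
    for phase in schedule.phases:
        if phase.regimen not in params_table:
            raise KeyError(f"regimen {phase.regimen!r} missing from parameter table")

    grid = _output_grid(schedule, output_step)
    times: list[float] = [0.0]
    rows: list[np.ndarray] = [initial.as_array()]

    state = initial
    for phase in schedule.phases:
        params = params_table[phase.regimen]
        phase_pts = grid[(grid > phase.start) & (grid <= phase.end)]
        end_state = state
        for t in phase_pts:
            end_state = closed_form_state(state, params, t - phase.start)
            times.append(float(t))
            rows.append(end_state.as_array())
        if phase_pts.size == 0 or phase_pts[-1] != phase.end:
            # zero-length phase (or degenerate grid): still advance exactly
            end_state = closed_form_state(state, params, phase.duration)
        state = end_state

    return Trajectory(np.asarray(times), np.vstack(rows))


def final_total(
    initial: TumorState,
    schedule: TreatmentSchedule,
    params_table: dict[str, RegimenParameters],
) -> float:
    """Total cell count at the schedule horizon (phase-exact, no grid)."""
    state = initial
    for phase in schedule.phases:
        state = closed_form_state(state, params_table[phase.regimen], phase.duration)
    return state.total()


def recurrence_time(traj: Trajectory) -> float | None:
    """First day the total burden regrows to its initial value after a nadir.

    Clinically: the tumor shrinks under therapy and later recurs to baseline
    size.  Returns the linearly interpolated crossing day, or ``None`` when
    the burden never falls strictly below baseline or never returns to it
    within the horizon.
    """
    totals = traj.totals
    if totals.size == 0:
        raise ValueError("empty trajectory")
    baseline = totals[0]
    dipped = False
    for i in range(1, totals.size):
        if totals[i] < baseline:
            dipped = True
        elif dipped:
            t0, t1 = traj.times[i - 1], traj.times[i]
            f0, f1 = totals[i - 1], totals[i]
            return float(t0 + (baseline - f0) / (f1 - f0) * (t1 - t0))
    return None
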