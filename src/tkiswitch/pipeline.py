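"""End-to-end pipeline: run every simulation and experiment, write outputs.

:func:`run_all` executes the three reference time-course simulations and
the five experiments under one :class:`~tkiswitch.config.RunConfig`,
writes CSVs, PNG figures and a JSON summary into the output directory, and
returns a manifest mapping output names to file paths.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import experiments as xp
from . import model, plotting, therapy
from .config import RunConfig, default_config
from .io import write_frame_csv, write_trajectory_csv

logger = logging.getLogger(__name__)

__all__ = ["run_all"]

#: Fig-7-style area-composition panels: each perturbs one rate under one
#: regimen (growth of W and Z, and the W→Z mutation rate).
AREA_COMPOSITION_PANELS = tuple(
    f"{rate}_{regimen}" for rate in ("a", "f", "k") for regimen in ("A", "B", "C")
)


def _stage(name: str):
    logger.info("stage %s: starting", name)
    return time.perf_counter()


def run_all(config: RunConfig | None = None) -> dict[str, str]:
    """Run everything; returns {output name: file path}."""
    if config is None:
        config = default_config()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = config.parameters
    initial = config.initial.state()
    sched_cfg = config.schedule
    grids = config.grids
    switch_days = sched_cfg.switch_days
    horizon = sched_cfg.horizon
    schedules = therapy.standard_schedules(
        sta=sched_cfg.switch_a_first, stb=sched_cfg.switch_b_first, horizon=horizon
    )

    model.reset_degeneracy_fallback_count()
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}

    # --- reference time courses -------------------------------------------
    t0 = _stage("time-courses")
    headline_totals: dict[str, float] = {}
    recurrence_days: dict[str, float | None] = {}
    for strategy, schedule in schedules.items():
        traj = therapy.simulate_schedule(
            initial, schedule, table, output_step=sched_cfg.output_step
        )
        headline_totals[strategy] = traj.final_total
        rec = therapy.recurrence_time(traj)
        recurrence_days[strategy] = rec
        slug = strategy.lower().replace("-", "_")
        path = out / f"trajectory_{slug}.csv"
        write_trajectory_csv(traj, path)
        manifest[f"trajectory_{slug}"] = str(path)
        png = out / f"trajectory_{slug}.png"
        plotting.plot_trajectory(traj, png, title=strategy)
        manifest[f"trajectory_{slug}_png"] = str(png)
        logger.debug(
            "strategy %s: day-%g total %.4g, recurrence %s",
            strategy, horizon, traj.final_total, rec,
        )
    timings["time_courses"] = time.perf_counter() - t0

    # --- switch-time sweep -------------------------------------------------
    t0 = _stage("switch-sweep")
    days = grids.switch_days()
    logger.info("switch sweep over %d days per strategy", days.size)
    sweeps = [
        xp.sweep_switch_time(s, days, table, initial, horizon=horizon)
        for s in ("A-first", "B-first")
    ]
    import pandas as pd

    path = out / "switch_sweep.csv"
    write_frame_csv(pd.concat([s.to_frame() for s in sweeps], ignore_index=True), path)
    manifest["switch_sweep"] = str(path)
    png = out / "switch_sweep.png"
    plotting.plot_switch_sweep(sweeps, png)
    manifest["switch_sweep_png"] = str(png)
    sweep_minima = {s.strategy: s.min_final for s in sweeps}
    sweep_argmin = {s.strategy: s.argmin_day for s in sweeps}
    timings["switch_sweep"] = time.perf_counter() - t0

    # --- initial-proportion sweeps ----------------------------------------
    t0 = _stage("proportion-sweep")
    frames = []
    for varied, (lo, hi) in (
        ("X", grids.xy_proportion_range),
        ("Y", grids.xy_proportion_range),
        ("Z", grids.z_proportion_range),
    ):
        props = grids.proportion_decades(lo, hi)
        res = xp.sweep_initial_proportion(
            varied, props, params_table=table, total=config.initial.total,
            switch_days=switch_days, horizon=horizon,
        )
        frames.append(res.to_frame())
    path = out / "proportion_sweep.csv"
    write_frame_csv(pd.concat(frames, ignore_index=True), path)
    manifest["proportion_sweep"] = str(path)
    timings["proportion_sweep"] = time.perf_counter() - t0

    # --- therapy-selection map --------------------------------------------
    t0 = _stage("selection-map")
    fracs = xp.default_map_fractions(grids.selection_map_size)
    logger.info("selection map on a %dx%d grid", fracs.size, fracs.size)
    sel = xp.build_selection_map(
        fracs, fracs, table, z0=config.initial.z0, switch_days=switch_days,
        total=config.initial.total, horizon=horizon,
    )
    path = out / "selection_map.csv"
    write_frame_csv(sel.to_frame(), path)
    manifest["selection_map"] = str(path)
    png = out / "selection_map.png"
    plotting.plot_selection_map(sel, png)
    manifest["selection_map_png"] = str(png)
    timings["selection_map"] = time.perf_counter() - t0

    # --- parameter sensitivity --------------------------------------------
    t0 = _stage("sensitivity")

    def axis_for(name: str, default_value: float) -> np.ndarray:
        if name in model.GROWTH_RATE_NAMES:
            hw = grids.growth_axis_halfwidth
            return np.linspace(
                default_value - hw, default_value + hw, grids.growth_axis_points
            )
        lo, hi = grids.mutation_axis_range
        return np.logspace(np.log10(lo), np.log10(hi), grids.mutation_axis_points)

    sens_frames = []
    for name in model.RATE_NAMES:
        for strategy in therapy.STRATEGIES:
            regimen = xp._strategy_regimens(strategy)[0]
            axis = axis_for(name, getattr(table[regimen], name))
            grid = xp.parameter_sensitivity_grid(
                name, axis, table, strategy=strategy, initial=initial,
                switch_days=switch_days, horizon=horizon,
            )
            sens_frames.append(grid.to_frame())
    path = out / "sensitivity.csv"
    write_frame_csv(pd.concat(sens_frames, ignore_index=True), path)
    manifest["sensitivity"] = str(path)
    timings["sensitivity"] = time.perf_counter() - t0

    # --- selection-area composition ---------------------------------------
    t0 = _stage("area-composition")
    area_frames = []
    area_fracs = xp.default_map_fractions(grids.area_map_size)
    for panel in AREA_COMPOSITION_PANELS:
        rate, regimen = panel.split("_")
        full_axis = axis_for(rate, getattr(table[regimen], rate))
        idx = np.linspace(0, full_axis.size - 1, grids.area_axis_points).round().astype(int)
        values = full_axis[np.unique(idx)]
        comp = xp.selection_area_composition(
            panel, values, table, x_props=area_fracs, y_props=area_fracs,
            z0=config.initial.z0, switch_days=switch_days,
            total=config.initial.total, horizon=horizon,
        )
        area_frames.append(comp.to_frame())
        png = out / f"area_composition_{panel}.png"
        plotting.plot_area_composition(comp, png)
        manifest[f"area_composition_{panel}_png"] = str(png)
    path = out / "area_composition.csv"
    write_frame_csv(pd.concat(area_frames, ignore_index=True), path)
    manifest["area_composition"] = str(path)
    timings["area_composition"] = time.perf_counter() - t0

    # --- summary ------------------------------------------------------------
    # timings go to the log only, keeping the summary byte-deterministic
    summary = {
        "final_totals": headline_totals,
        "recurrence_days": recurrence_days,
        "switch_sweep_min": sweep_minima,
        "switch_sweep_argmin_day": sweep_argmin,
        "degeneracy_fallbacks": model.degeneracy_fallback_count(),
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["summary"] = str(path)
    logger.info("degeneracy fallbacks: %d", model.degeneracy_fallback_count())
    for stage, secs in timings.items():
        logger.info("stage %s finished in %.2fs", stage, secs)
    return manifest
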