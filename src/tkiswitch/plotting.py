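"""Minimal matplotlib views of the simulation and experiment outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .experiments import AreaComposition, SelectionMap, SwitchSweepResult
from .therapy import STRATEGIES, Trajectory

__all__ = [
    "plot_trajectory",
    "plot_switch_sweep",
    "plot_selection_map",
    "plot_area_composition",
]

_TYPE_COLORS = {"w": "tab:blue", "x": "tab:orange", "y": "gold", "z": "tab:green"}


def plot_trajectory(traj: Trajectory, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for name in ("w", "x", "y", "z"):
        ax.semilogy(traj.times, getattr(traj, name), label=f"Type-{name.upper()}",
                    color=_TYPE_COLORS[name])
    ax.semilogy(traj.times, traj.totals, label="total", color="purple", lw=2)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cell number")
    ax.set_ylim(bottom=1.0)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_switch_sweep(results: list[SwitchSweepResult], path) -> None:
    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4))
    for ax, res in zip(np.atleast_1d(axes), results):
        ax.semilogy(res.switch_days, res.finals)
        ax.set_xlabel("drug-switch day")
        ax.set_ylabel("total cells at horizon")
        ax.set_title(res.strategy)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selection_map(sel: SelectionMap, path) -> None:
    codes = np.zeros(sel.best.shape, dtype=int)
    for idx, s in enumerate(STRATEGIES):
        codes[sel.best == s] = idx
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        sel.x_props, sel.y_props, codes.T, cmap=plt.get_cmap("viridis", 3),
        vmin=-0.5, vmax=2.5,
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("initial Type-X fraction")
    ax.set_ylabel("initial Type-Y fraction")
    cbar = fig.colorbar(mesh, ticks=[0, 1, 2])
    cbar.ax.set_yticklabels(STRATEGIES)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_area_composition(comp: AreaComposition, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for s, color in zip(STRATEGIES, ("gold", "tab:blue", "tab:red")):
        ax.plot(
            comp.parameter_values,
            [f[s] for f in comp.fractions],
            label=s,
            color=color,
        )
    if comp.parameter_values.min() > 0 and comp.parameter_values.max() / max(
        comp.parameter_values.min(), 1e-300
    ) > 100:
        ax.set_xscale("log")
    ax.set_xlabel(comp.parameter_name)
    ax.set_ylabel("fraction of map area")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
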