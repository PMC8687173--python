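"""Trajectory and RMSE figure output.

Panels group the states physiologically (gastro-intestinal, glucose,
beta-cell response, insulin masses, insulin concentrations/action), with
the meal doses as bars on a secondary axis.  Plotting is optional: if no
matplotlib backend is importable the functions return an empty list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .parameters import STATE_NAMES

__all__ = ["plot_trajectories", "plot_rmse", "plot_outputs"]

_PANELS = (
    ("gastric", ("Qsto1", "Qsto2", "Qgut")),
    ("glucose", ("Gp", "Gt")),
    ("beta_cell", ("Y", "Ipo")),
    ("insulin_masses", ("Il", "Ip")),
    ("insulin_signals", ("I1", "Id", "X")),
)


def _pyplot():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        return plt
    except Exception:
        return None


def _meal_bars(ax, schedule, horizon):
    if schedule is None or not schedule.events:
        return
    ax2 = ax.twinx()
    starts = [e.start for e in schedule.events]
    doses = [e.dose / 1000.0 for e in schedule.events]
    widths = [e.end - e.start for e in schedule.events]
    ax2.bar(starts, doses, width=widths, align="edge", alpha=0.25, color="grey")
    ax2.set_ylabel("meal, g")
    ax2.set_ylim(0, max(doses) * 4)


def plot_trajectories(truth, estimate=None, schedule=None, out_dir=".", prefix="trajectory"):
    """Write one figure per physiological state group; returns the paths."""
    plt = _pyplot()
    if plt is None:
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    t_truth = truth.times
    for group, names in _PANELS:
        fig, axes = plt.subplots(len(names), 1, figsize=(8, 2.4 * len(names)),
                                 sharex=True, squeeze=False)
        for ax, name in zip(axes[:, 0], names):
            idx = STATE_NAMES.index(name)
            ax.plot(t_truth, truth.states[:, idx], label="truth", lw=1.0)
            if estimate is not None:
                ax.plot(estimate.times, estimate.means[:, idx], "--",
                        label="estimate", lw=1.0)
            ax.set_ylabel(name)
            _meal_bars(ax, schedule, t_truth[-1])
        axes[0, 0].legend(loc="upper right", fontsize=8)
        axes[-1, 0].set_xlabel("time, min")
        path = out_dir / f"{prefix}_{group}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_rmse(rmse_by_flavour, out_dir=".", prefix="rmse"):
    """One RMSE figure per filter flavour, all 12 states."""
    plt = _pyplot()
    if plt is None:
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for flavour, series in rmse_by_flavour.items():
        fig, axes = plt.subplots(4, 3, figsize=(11, 9), sharex=True)
        for i, name in enumerate(STATE_NAMES):
            ax = axes.flat[i]
            ax.plot(series.times, series.values[:, i], lw=0.9)
            ax.set_title(name, fontsize=9)
        for ax in axes[-1]:
            ax.set_xlabel("time, min")
        fig.suptitle(f"RMSE, {flavour.upper()} ({series.mc_runs} MC runs)")
        fig.tight_layout()
        path = out_dir / f"{prefix}_{flavour}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_outputs(truth=None, estimate=None, schedule=None, rmse=None, out_dir="."):
    """Convenience wrapper: trajectory panels plus RMSE panels."""
    written = []
    if truth is not None:
        written += plot_trajectories(truth, estimate, schedule, out_dir)
    if rmse:
        written += plot_rmse(rmse, out_dir)
    return written
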