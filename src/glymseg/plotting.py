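"""Time-series plots of pooled tracer signals with the fitted model.

Each panel shows the raw pooled observations, the fitted plateau-then-slope
line, and a horizontal point interval at the baseline level marking the
breakpoint with its confidence interval — the estimated time of first
tracer appearance.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_region_fit(series, model, ax=None, color="tab:blue"):
    """One (cohort, region) panel: points, piecewise line, breakpoint interval."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = series.time_h
    grid = np.linspace(t.min(), t.max(), 200)
    ax.scatter(t, series.signal, s=12, alpha=0.5, color=color, label=f"{series.cohort} data")
    ax.plot(grid, model.predict(grid), color=color, lw=2, label="fitted model")
    lo, hi = model.ci_psi_
    ax.errorbar(
        [model.psi_], [model.beta0_],
        xerr=[[model.psi_ - lo], [hi - model.psi_]],
        fmt="o", color="black", capsize=4, lw=2, label="breakpoint (95% CI)",
    )
    ax.set_xlabel("time since injection (h)")
    ax.set_ylabel("normalized T1 signal")
    ax.set_title(f"{series.region} — {series.cohort}")
    ax.legend(fontsize=7)
    return ax


def plot_joint_fit(series_ref, series_iih, model, ax=None):
    """Two-cohort overlay for the shared-baseline joint model."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    colors = ("tab:blue", "tab:orange")
    for k, (series, color) in enumerate(zip((series_ref, series_iih), colors)):
        t = series.time_h
        grid = np.linspace(t.min(), t.max(), 200)
        mu = model.beta0_ + model.beta1_[k] * np.maximum(grid - model.psi_[k], 0.0)
        ax.scatter(t, series.signal, s=12, alpha=0.4, color=color, label=f"{series.cohort} data")
        ax.plot(grid, mu, color=color, lw=2, label=f"{series.cohort} fit")
        ax.axvline(model.psi_[k], color=color, ls=":", lw=1)
    ax.set_xlabel("time since injection (h)")
    ax.set_ylabel("normalized T1 signal")
    ax.set_title(f"{series_ref.region} — joint two-group model")
    ax.legend(fontsize=7)
    return ax


def save_figure(ax, path):
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
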