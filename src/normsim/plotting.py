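"""Static figures: per-group trait histograms and sweep heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import PopulationState, Trajectory

__all__ = ["plot_trait_histograms", "plot_sweep_heatmaps"]

HIST_BIN_WIDTH = 0.25  # trait units


def _bins(*states: PopulationState) -> np.ndarray:
    lo = min(s.traits.min() for s in states)
    hi = max(s.traits.max() for s in states)
    lo = np.floor(lo / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
    hi = np.ceil(hi / HIST_BIN_WIDTH) * HIST_BIN_WIDTH + HIST_BIN_WIDTH
    return np.arange(lo, hi, HIST_BIN_WIDTH)


def plot_trait_histograms(traj: Trajectory, path: str | Path) -> Path:
    """Initial vs final trait distributions, one overlaid histogram per group."""
    initial, final = traj.initial_state, traj.final_state
    bins = _bins(initial, final)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, state, title in ((axes[0], initial, "initial"), (axes[1], final, "final")):
        for g in range(state.n_groups):
            ax.hist(
                state.traits[state.members(g)],
                bins=bins,
                alpha=0.6,
                label=f"group {g + 1}",
            )
        ax.set_title(f"{title} (t={state.t})")
        ax.set_xlabel("trait value")
    axes[0].set_ylabel("agents")
    axes[0].legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sweep_heatmaps(table: pd.DataFrame, path: str | Path) -> Path:
    """Mean delta trait median over (alpha, beta), one panel per (r, rho)."""
    r_values = np.sort(table["r"].unique())
    rho_values = np.sort(table["rho"].unique())
    alpha_values = np.sort(table["alpha"].unique())
    beta_values = np.sort(table["beta"].unique())
    vmax = table["mean_delta_median"].max()
    fig, axes = plt.subplots(
        len(r_values),
        len(rho_values),
        figsize=(2.6 * len(rho_values) + 1.5, 2.4 * len(r_values) + 1),
        squeeze=False,
    )
    for i, r in enumerate(r_values):
        for j, rho in enumerate(rho_values):
            sub = table[(table["r"] == r) & (table["rho"] == rho)]
            grid = (
                sub.pivot(index="alpha", columns="beta", values="mean_delta_median")
                .reindex(index=alpha_values, columns=beta_values)
                .to_numpy()
            )
            ax = axes[i, j]
            im = ax.imshow(grid, origin="lower", aspect="auto", vmin=0, vmax=vmax, cmap="viridis")
            ax.set_title(f"r={r:g}, ρ={rho:g}", fontsize=9)
            ax.set_xticks(range(len(beta_values)), [f"{b:g}" for b in beta_values], fontsize=7)
            ax.set_yticks(range(len(alpha_values)), [f"{a:g}" for a in alpha_values], fontsize=7)
            if i == len(r_values) - 1:
                ax.set_xlabel("β")
            if j == 0:
                ax.set_ylabel("α")
    fig.colorbar(im, ax=axes, label="mean Δ trait median", shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
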