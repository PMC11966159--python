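"""Replicate execution and parameter sweeps.

A sweep runs the model over a grid of (alpha, beta, r, rho) cells with a
fixed number of replicate runs per cell (30 by default) and reports the
replicate-averaged delta trait median per cell — the quantity plotted as a
heatmap to map the convergence/divergence regimes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import DEFAULT_SPREAD_TOL, RunSummary, convergence_summary
from .model import SimulationParams, run_simulation

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_replicates",
    "run_sweep",
    "summarize_trends",
    "cell_seed",
]

logger = logging.getLogger("normsim")

# Default grids bracketing the two regime-defining alpha values (0.02, 0.06)
# and the (r, rho) = (0.5, 0.75) reference condition.
DEFAULT_ALPHA_GRID = (0.0, 0.01, 0.02, 0.04, 0.06)
DEFAULT_BETA_GRID = (0.1, 0.5, 1.0)
DEFAULT_R_GRID = (0.0, 0.5, 1.0)
DEFAULT_RHO_GRID = (0.0, 0.5, 0.75, 1.0)

SWEEP_COLUMNS = [
    "alpha",
    "beta",
    "r",
    "rho",
    "mean_delta_median",
    "sd_delta_median",
    "fraction_converged",
    "n_replicates",
]


@dataclass(frozen=True)
class SweepSpec:
    """A parameter grid plus replication settings."""

    base_params: SimulationParams = field(default_factory=SimulationParams)
    alpha_values: tuple[float, ...] = DEFAULT_ALPHA_GRID
    beta_values: tuple[float, ...] = DEFAULT_BETA_GRID
    r_values: tuple[float, ...] = DEFAULT_R_GRID
    rho_values: tuple[float, ...] = DEFAULT_RHO_GRID
    n_replicates: int = 30
    root_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_values", "beta_values", "r_values", "rho_values"):
            values = tuple(float(v) for v in getattr(self, name))
            if not values:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, values)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return (
            len(self.alpha_values)
            * len(self.beta_values)
            * len(self.r_values)
            * len(self.rho_values)
        )

    def cells(self):
        """Grid cells in deterministic row order."""
        return product(self.alpha_values, self.beta_values, self.r_values, self.rho_values)


@dataclass
class SweepResult:
    """Tidy per-cell table of replicate-averaged outcomes."""

    spec: SweepSpec
    table: pd.DataFrame


def run_replicates(params: SimulationParams, n: int, root_seed: int) -> list[RunSummary]:
    """Run ``n`` independent replicates with seeds ``root_seed .. root_seed+n-1``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    summaries = []
    for k in range(n):
        traj = run_simulation(replace(params, seed=root_seed + k))
        summaries.append(convergence_summary(traj))
    return summaries


def cell_seed(root_seed: int, alpha: float, beta: float, r: float, rho: float) -> int:
    """Stable per-cell seed from the root seed and the cell's own coordinates.

    Depends only on the cell, not on the rest of the grid, so a cell's result
    is unchanged by adding or removing other cells.
    """
    key = f"{int(root_seed)}|{float(alpha)!r}|{float(beta)!r}|{float(r)!r}|{float(rho)!r}"
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") & 0x3FFFFFFF


def _aggregate(alpha, beta, r, rho, summaries: list[RunSummary]) -> dict:
    deltas = np.array([s.final_delta_median for s in summaries])
    return {
        "alpha": alpha,
        "beta": beta,
        "r": r,
        "rho": rho,
        "mean_delta_median": float(deltas.mean()),
        "sd_delta_median": float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0,
        "fraction_converged": float(np.mean([s.converged for s in summaries])),
        "n_replicates": len(summaries),
    }


def run_sweep(
    spec: SweepSpec,
    checkpoint_path: str | Path | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run every grid cell and aggregate replicate outcomes.

    If ``checkpoint_path`` is given, each completed cell row is appended to
    that CSV immediately, so partial results survive an interruption.
    """
    rows = []
    checkpoint = Path(checkpoint_path) if checkpoint_path else None
    if checkpoint is not None:
        checkpoint.write_text(",".join(SWEEP_COLUMNS) + "\n")
    for i, (alpha, beta, r, rho) in enumerate(spec.cells()):
        params = replace(spec.base_params, alpha=alpha, beta=beta, r=r, rho=rho)
        seed = cell_seed(spec.root_seed, alpha, beta, r, rho)
        summaries = run_replicates(params, spec.n_replicates, seed)
        row = _aggregate(alpha, beta, r, rho, summaries)
        rows.append(row)
        if checkpoint is not None:
            pd.DataFrame([row]).to_csv(
                checkpoint, mode="a", header=False, index=False, float_format="%.12g"
            )
        if progress:
            logger.info("sweep cell %d/%d done", i + 1, spec.n_cells)
    return SweepResult(spec=spec, table=pd.DataFrame(rows, columns=SWEEP_COLUMNS))


def summarize_trends(result: SweepResult) -> pd.DataFrame:
    """Per-axis monotone-trend summary of the mean delta trait median.

    For each swept parameter with at least two levels, the cell means are
    marginalized (simple mean over the other axes) and a least-squares slope
    of marginal mean against the parameter value is reported, along with its
    sign (``trend``) and the range of the marginal means.  Single-level axes
    are skipped with a log note.
    """
    table = result.table
    rows = []
    for axis in ("alpha", "beta", "r", "rho"):
        levels = np.sort(table[axis].unique())
        if levels.size < 2:
            logger.info("axis %s has a single level; skipped in trend summary", axis)
            continue
        marginal = table.groupby(axis)["mean_delta_median"].mean().sort_index()
        slope = float(np.polyfit(marginal.index.to_numpy(), marginal.to_numpy(), 1)[0])
        scale = max(1.0, float(np.abs(marginal).max()))
        if abs(slope) < 1e-9 * scale:  # numerically flat axis
            slope = 0.0
        rows.append(
            {
                "parameter": axis,
                "n_levels": int(levels.size),
                "slope": slope,
                "trend": int(np.sign(slope)),
                "marginal_range": float(marginal.max() - marginal.min()),
            }
        )
    return pd.DataFrame(rows, columns=["parameter", "n_levels", "slope", "trend", "marginal_range"])
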