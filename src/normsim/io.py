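"""CSV output with embedded provenance.

Every file starts with ``#``-prefixed header lines carrying the full resolved
parameter set and seed as JSON, sufficient to regenerate the file exactly.
Floats are written with 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import params_dict
from .experiments import SweepResult
from .model import PopulationState, Trajectory

__all__ = [
    "trajectory_frame",
    "write_trajectory_csv",
    "write_final_state_csv",
    "write_sweep_csv",
]

FLOAT_FORMAT = "%.12g"


def _write_with_header(df: pd.DataFrame, path: Path, meta: dict) -> None:
    header = "# normsim " + json.dumps(meta, sort_keys=True) + "\n"
    path.write_text(header + df.to_csv(index=False, float_format=FLOAT_FORMAT))


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-step, per-group summary: t, group, median/mean/sd trait."""
    n_steps, n_groups = traj.per_step_group_medians.shape
    rows = []
    for t in range(n_steps):
        for g in range(n_groups):
            rows.append(
                {
                    "t": t,
                    "group": g,
                    "median_trait": traj.per_step_group_medians[t, g],
                    "mean_trait": traj.per_step_group_means[t, g],
                    "sd_trait": traj.per_step_group_sds[t, g],
                }
            )
    return pd.DataFrame(rows)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    _write_with_header(trajectory_frame(traj), path, params_dict(traj.params))
    return path


def write_final_state_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    state: PopulationState = traj.final_state
    df = pd.DataFrame(
        {"agent_id": range(state.n), "group": state.groups, "trait": state.traits}
    )
    _write_with_header(df, path, params_dict(traj.params))
    return path


def write_sweep_csv(result: SweepResult, path: str | Path) -> Path:
    path = Path(path)
    spec = result.spec
    meta = params_dict(spec.base_params)
    meta.update(
        alpha_values=list(spec.alpha_values),
        beta_values=list(spec.beta_values),
        r_values=list(spec.r_values),
        rho_values=list(spec.rho_values),
        n_replicates=spec.n_replicates,
        root_seed=spec.root_seed,
    )
    _write_with_header(result.table, path, meta)
    return path
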