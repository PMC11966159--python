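"""Summary statistics over population states and trajectories.

The central quantity is the *delta trait median*: the absolute difference
between the two groups' median trait values.  Values near zero indicate
convergence to a single population-wide norm; large values indicate
group-specific norms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import PopulationState, SimulationParams, Trajectory

__all__ = [
    "RunSummary",
    "group_medians",
    "delta_trait_median",
    "trait_spread",
    "convergence_summary",
]

#: Default population-spread threshold (trait units) below which a final
#: state is flagged as converged; well below the initial between-group
#: separation of 1.
DEFAULT_SPREAD_TOL = 0.1


@dataclass
class RunSummary:
    """Final-state summary of one simulation run."""

    params: SimulationParams
    final_delta_median: float
    final_group_medians: tuple[float, ...]
    final_population_median: float
    final_spread: float
    converged: bool

    def to_row(self, run_id: int | None = None) -> dict:
        """Flatten to one tidy record (for CSV serialization)."""
        p = self.params
        return {
            "run_id": run_id,
            "seed": p.seed,
            "alpha": p.alpha,
            "beta": p.beta,
            "gamma": p.gamma,
            "r": p.r,
            "rho": p.rho,
            "final_delta_median": self.final_delta_median,
            "final_population_median": self.final_population_median,
            "converged": self.converged,
        }


def group_medians(state: PopulationState) -> np.ndarray:
    """Median trait value of each group (even counts use the central midpoint)."""
    n_groups = state.n_groups
    out = np.empty(n_groups)
    for g in range(n_groups):
        members = state.members(g)
        if members.size == 0:
            raise ValueError(f"group {g} is empty; median undefined")
        out[g] = np.median(state.traits[members])
    return out


def delta_trait_median(state: PopulationState) -> float:
    """Absolute difference between the groups' trait medians.

    For two groups this is ``|median(group 0) - median(group 1)|``; with more
    groups, the maximum pairwise absolute difference.
    """
    med = group_medians(state)
    if med.size == 2:
        return float(abs(med[0] - med[1]))
    return float(max(abs(a - b) for a, b in combinations(med, 2)))


def trait_spread(state: PopulationState) -> float:
    """Population trait range (max minus min)."""
    return float(state.traits.max() - state.traits.min())


def convergence_summary(traj: Trajectory, spread_tol: float = DEFAULT_SPREAD_TOL) -> RunSummary:
    """Summarise the final state of a completed trajectory.

    A run is flagged converged when the final population spread (max - min
    trait) is below ``spread_tol``.
    """
    final = traj.final_state
    med = group_medians(final)
    spread = trait_spread(final)
    return RunSummary(
        params=traj.params,
        final_delta_median=delta_trait_median(final),
        final_group_medians=tuple(float(v) for v in med),
        final_population_median=float(np.median(final.traits)),
        final_spread=spread,
        converged=bool(spread < spread_tol),
    )
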