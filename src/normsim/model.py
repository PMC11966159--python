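"""Core agent-based model of continuous norm evolution.

A population of ``N`` agents, each holding a real-valued trait ``x_i`` and a
fixed group label, evolves in discrete time steps.  Each step has two stages:

* **interaction** — every agent picks a partner (from its own group with
  probability ``r``, otherwise from the whole population) and receives payoff

  .. math::

     V_i = e^{-\\alpha (x_i-\\theta)^2} e^{-\\beta (x_i-x_j)^2}
           + \\left(1 - e^{-\\gamma (x_i-\\bar x_{out})^2}\\right)

  where ``theta`` is the objectively optimal trait value and
  ``x_out`` is the mean trait of all agents outside the focal agent's group.
  The three weights trade off functional optimality (``alpha``), coordination
  with the interaction partner (``beta``) and differentiation from the
  outgroup (``gamma``).

* **imitation** — every agent copies the trait of a target chosen with
  probability proportional to the target's payoff from this step; with
  probability ``rho`` the candidate pool is restricted to the agent's own
  group.

Both stages are synchronous by default: payoffs and outgroup means are
computed from the start-of-step state, and all trait adoptions are applied
simultaneously.  An agent-sequential update order is available as a
sensitivity switch (``synchronous=False``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "SimulationParams",
    "PopulationState",
    "PayoffVector",
    "Trajectory",
    "init_population",
    "outgroup_mean",
    "compute_payoff",
    "select_partner",
    "interaction_stage",
    "select_imitation_target",
    "imitation_stage",
    "run_simulation",
]

logger = logging.getLogger("normsim")


class ConfigurationError(ValueError):
    """Raised when a parameter set is internally inconsistent."""


def _as_tuple(value, n: int, name: str) -> tuple[float, ...]:
    """Broadcast a scalar to ``n`` values, or validate a length-``n`` sequence."""
    if np.isscalar(value):
        return (float(value),) * n
    values = tuple(float(v) for v in value)
    if len(values) != n:
        raise ConfigurationError(f"{name} must have length {n}, got {len(values)}")
    return values


@dataclass(frozen=True)
class SimulationParams:
    """All model constants for a single run.

    Parameters
    ----------
    n_agents : int
        Population size ``N``.
    n_groups : int
        Number of groups ``M`` (at least 2).
    p : float or sequence of float
        Proportion of agents in group 0 (two-group case).  For more than two
        groups, a sequence of per-group proportions summing to one.
    group_means : sequence of float
        Initial trait mean per group.
    init_sd : float
        Standard deviation of initial trait values within each group.
    theta : float or sequence of float
        Objective optimal trait value, shared or per group.
    alpha, beta, gamma : float
        Non-negative weights of the objective value, partner similarity and
        outgroup dissimilarity payoff components.
    r : float
        Probability that an interaction partner is drawn from the focal
        agent's own group (coalitional assortment).
    rho : float
        Probability that the imitation candidate pool is restricted to the
        focal agent's own group (coalitional copying).
    t_max : int
        Number of time steps.
    copy_noise_sd : float
        Standard deviation of Gaussian noise added to copied trait values
        (0 = exact copying, the default).
    seed : int
        Seed of the run's random stream.
    synchronous : bool
        If False, imitation is applied agent-by-agent in random order using
        live trait values (sensitivity switch).
    imitate_self : bool
        Whether the focal agent itself is a valid imitation target, letting
        high-payoff agents retain their own trait.
    """

    n_agents: int = 100
    n_groups: int = 2
    p: float | tuple[float, ...] = 0.5
    group_means: tuple[float, ...] = (0.0, 1.0)
    init_sd: float = 1.0
    theta: float | tuple[float, ...] = 0.0
    alpha: float = 0.02
    beta: float = 0.5
    gamma: float = 0.05
    r: float = 0.5
    rho: float = 0.75
    t_max: int = 100
    copy_noise_sd: float = 0.0
    seed: int = 0
    synchronous: bool = True
    imitate_self: bool = True

    def __post_init__(self) -> None:
        if int(self.n_agents) != self.n_agents or self.n_agents < 2:
            raise ConfigurationError("n_agents must be an integer >= 2")
        if int(self.n_groups) != self.n_groups or self.n_groups < 2:
            raise ConfigurationError("n_groups must be an integer >= 2")
        object.__setattr__(self, "n_agents", int(self.n_agents))
        object.__setattr__(self, "n_groups", int(self.n_groups))
        if not np.isscalar(self.p):
            props = _as_tuple(self.p, self.n_groups, "p")
            if any(q < 0 for q in props):
                raise ConfigurationError("p entries must be non-negative")
            if not math.isclose(sum(props), 1.0, abs_tol=1e-9):
                raise ConfigurationError("p entries must sum to 1")
            object.__setattr__(self, "p", props)
        elif not 0.0 <= self.p <= 1.0:
            raise ConfigurationError("p must be in [0, 1]")
        for name in ("r", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("alpha", "beta", "gamma", "init_sd", "copy_noise_sd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0.0):
                raise ConfigurationError(f"{name} must be a finite value >= 0")
        object.__setattr__(
            self, "group_means", _as_tuple(self.group_means, self.n_groups, "group_means")
        )
        if not np.isscalar(self.theta):
            object.__setattr__(self, "theta", _as_tuple(self.theta, self.n_groups, "theta"))
        else:
            object.__setattr__(self, "theta", float(self.theta))
        if int(self.t_max) != self.t_max or self.t_max < 0:
            raise ConfigurationError("t_max must be an integer >= 0")
        object.__setattr__(self, "t_max", int(self.t_max))
        object.__setattr__(self, "seed", int(self.seed))
        sizes = self.group_sizes()
        for g, size in enumerate(sizes):
            if size < 1:
                raise ConfigurationError(
                    f"group {g} would receive 0 agents (n_agents={self.n_agents}, p={self.p})"
                )

    def proportions(self) -> tuple[float, ...]:
        if np.isscalar(self.p):
            if self.n_groups != 2:
                raise ConfigurationError("scalar p requires n_groups=2; pass a proportion list")
            return (float(self.p), 1.0 - float(self.p))
        return self.p  # type: ignore[return-value]

    def group_sizes(self) -> tuple[int, ...]:
        """Deterministic allocation of agents to groups.

        Two groups with scalar ``p``: exactly ``floor(p*N)`` agents in group 0.
        Otherwise a largest-remainder apportionment of ``N`` over the
        proportion list.
        """
        n = self.n_agents
        if np.isscalar(self.p) and self.n_groups == 2:
            n0 = int(math.floor(float(self.p) * n))
            return (n0, n - n0)
        quotas = np.asarray(self.proportions(), dtype=float) * n
        base = np.floor(quotas).astype(int)
        remainder = n - int(base.sum())
        order = np.argsort(-(quotas - base), kind="stable")
        for g in order[:remainder]:
            base[g] += 1
        return tuple(int(b) for b in base)

    def theta_per_group(self) -> np.ndarray:
        return np.asarray(_as_tuple(self.theta, self.n_groups, "theta"), dtype=float)


@dataclass
class PopulationState:
    """Trait values and group labels of all agents at one time step."""

    traits: np.ndarray
    groups: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.traits = np.asarray(self.traits, dtype=float)
        self.groups = np.asarray(self.groups, dtype=np.int64)
        if self.traits.shape != self.groups.shape or self.traits.ndim != 1:
            raise ValueError("traits and groups must be 1-d arrays of equal length")

    @property
    def n(self) -> int:
        return self.traits.size

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1

    def members(self, group: int) -> np.ndarray:
        """Indices of all agents in ``group``."""
        return np.flatnonzero(self.groups == group)


@dataclass
class PayoffVector:
    """Per-agent payoffs from one interaction stage.

    Each entry is strictly inside ``(0, 2)``: the product of two Gaussians is
    in ``(0, 1]`` and the outgroup-dissimilarity term is in ``[0, 1)``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("payoffs must be finite")
        if np.any(self.values <= 0.0) or np.any(self.values >= 2.0):
            raise ValueError("payoffs must lie strictly in (0, 2)")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Trajectory:
    """Time-indexed record of one simulation run.

    ``per_step_group_medians`` (and the mean/sd companions) have one row per
    recorded step including the initial state, so ``t_max + 1`` rows, and one
    column per group.  Full per-step states are kept only when the run was
    executed with ``record_states=True``; the initial and final states are
    always retained.
    """

    params: SimulationParams
    per_step_group_medians: np.ndarray
    per_step_group_means: np.ndarray
    per_step_group_sds: np.ndarray
    initial_state: PopulationState
    final_state: PopulationState
    states: list[PopulationState] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.per_step_group_medians.shape[0] - 1


# ---------------------------------------------------------------------------
# initialization


def init_population(params: SimulationParams, rng: np.random.Generator | None = None) -> PopulationState:
    """Draw the initial population.

    Group sizes are allocated deterministically from ``p`` (see
    :meth:`SimulationParams.group_sizes`); each agent's trait is drawn
    independently from ``Normal(group_means[g], init_sd)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sizes = params.group_sizes()
    groups = np.repeat(np.arange(params.n_groups), sizes)
    means = np.asarray(params.group_means, dtype=float)[groups]
    traits = rng.normal(means, params.init_sd)
    return PopulationState(traits=traits, groups=groups, t=0)


# ---------------------------------------------------------------------------
# payoff (Eq. components)


def outgroup_mean(state: PopulationState, group: int) -> float:
    """Mean trait of every agent outside ``group`` (start-of-step values)."""
    mask = state.groups != group
    if not mask.any():
        raise ValueError(f"group {group} has no outgroup; outgroup mean is undefined")
    return float(state.traits[mask].mean())


def compute_payoff(x_i, x_j, x_out, theta, alpha, beta, gamma):
    """Payoff of a focal agent with trait ``x_i`` meeting partner ``x_j``.

    Accepts scalars or broadcastable arrays; returns values strictly in
    ``(0, 2)`` for finite inputs.
    """
    args = [np.asarray(a, dtype=float) for a in (x_i, x_j, x_out, theta, alpha, beta, gamma)]
    if any(not np.all(np.isfinite(a)) for a in args):
        raise ValueError("compute_payoff requires finite inputs")
    x_i, x_j, x_out, theta, alpha, beta, gamma = args
    if np.any(alpha < 0) or np.any(beta < 0) or np.any(gamma < 0):
        raise ValueError("payoff weights must be non-negative")
    value = (
        np.exp(-alpha * (x_i - theta) ** 2) * np.exp(-beta * (x_i - x_j) ** 2)
        + (1.0 - np.exp(-gamma * (x_i - x_out) ** 2))
    )
    return value if value.ndim else float(value)


# ---------------------------------------------------------------------------
# partner / target selection


def select_partner(state: PopulationState, focal: int, r: float, rng: np.random.Generator) -> int:
    """Pick an interaction partner for ``focal``.

    With probability ``r`` the partner is uniform over the focal agent's
    ingroup (excluding the focal agent); otherwise uniform over the whole
    population excluding the focal agent.  If the focal agent is the sole
    member of its group, the ingroup branch falls back to a population-wide
    draw (logged).
    """
    n = state.n
    if n < 2:
        raise ValueError("need at least two agents to select a partner")
    if rng.random() < r:
        members = state.members(int(state.groups[focal]))
        if members.size > 1:
            k = int(rng.integers(members.size - 1))
            pos = int(np.searchsorted(members, focal))
            if k >= pos:
                k += 1
            return int(members[k])
        logger.warning(
            "agent %d is the sole member of group %d; falling back to population-wide partner draw",
            focal,
            int(state.groups[focal]),
        )
    k = int(rng.integers(n - 1))
    if k >= focal:
        k += 1
    return k


def select_imitation_target(
    payoffs: PayoffVector,
    state: PopulationState,
    focal: int,
    rho: float,
    rng: np.random.Generator,
    include_self: bool = True,
) -> int:
    """Pick an imitation target with probability proportional to payoff.

    With probability ``rho`` the candidate set is the focal agent's ingroup;
    otherwise the whole population.  The focal agent is itself a candidate
    unless ``include_self`` is False.
    """
    if rng.random() < rho:
        candidates = state.members(int(state.groups[focal]))
    else:
        candidates = np.arange(state.n)
    if not include_self:
        candidates = candidates[candidates != focal]
        if candidates.size == 0:
            raise ValueError(f"agent {focal} has no imitation candidates")
    weights = payoffs.values[candidates]
    total = weights.sum()
    if total <= 0.0:
        raise ValueError("candidate payoffs sum to zero; cannot normalize")
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
    return int(candidates[min(idx, candidates.size - 1)])


# ---------------------------------------------------------------------------
# stages

# Group membership is fixed for a whole run, so the per-group index arrays are
# built once and threaded through the vectorised stages.


@dataclass
class _GroupIndex:
    members: list[np.ndarray]   # agent indices per group, ascending
    sizes: np.ndarray           # group size, per group
    size_of: np.ndarray         # group size, per agent
    pos: np.ndarray             # agent's position within its group's members
    offsets: np.ndarray         # start of each group's slice in `flat`
    flat: np.ndarray            # members arrays concatenated in group order


def _build_group_index(groups: np.ndarray, n_groups: int) -> _GroupIndex:
    members = [np.flatnonzero(groups == g) for g in range(n_groups)]
    sizes = np.array([m.size for m in members], dtype=np.int64)
    pos = np.empty(groups.size, dtype=np.int64)
    for m in members:
        pos[m] = np.arange(m.size)
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    return _GroupIndex(
        members=members,
        sizes=sizes,
        size_of=sizes[groups],
        pos=pos,
        offsets=offsets,
        flat=np.concatenate(members),
    )


def _outgroup_means(traits: np.ndarray, gi: _GroupIndex) -> np.ndarray:
    """Per-group mean trait of all agents outside the group."""
    total = traits.sum()
    group_sums = np.array([traits[m].sum() for m in gi.members])
    out_counts = traits.size - gi.sizes
    if np.any(out_counts == 0):
        raise ValueError("every group must have a non-empty outgroup")
    return (total - group_sums) / out_counts


def interaction_stage(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    _group_index: _GroupIndex | None = None,
) -> PayoffVector:
    """Select one partner per agent and compute every agent's payoff.

    All quantities (partner traits, outgroup means) are taken from the
    start-of-step state.  Partner selection is vectorised over agents but
    draws from exactly the distribution of :func:`select_partner`.
    """
    gi = _group_index or _build_group_index(state.groups, params.n_groups)
    n = state.n
    traits = state.traits
    arange = np.arange(n)

    take_ingroup = rng.random(n) < params.r
    # population-wide draw excluding the focal agent
    k_glob = rng.integers(0, n - 1, size=n)
    partner_glob = k_glob + (k_glob >= arange)
    # ingroup draw excluding the focal agent (sizes vary per agent)
    k_in = rng.integers(0, np.maximum(gi.size_of - 1, 1), size=n)
    k_in = k_in + (k_in >= gi.pos)
    partner_in = gi.flat[gi.offsets[state.groups] + k_in]

    singleton = gi.size_of == 1
    if np.any(take_ingroup & singleton):
        logger.warning(
            "%d agent(s) are sole members of their group; using population-wide partner draw",
            int(np.count_nonzero(take_ingroup & singleton)),
        )
    partners = np.where(take_ingroup & ~singleton, partner_in, partner_glob)

    theta = params.theta_per_group()[state.groups]
    x_out = _outgroup_means(traits, gi)[state.groups]
    values = (
        np.exp(-params.alpha * (traits - theta) ** 2)
        * np.exp(-params.beta * (traits - traits[partners]) ** 2)
        + (1.0 - np.exp(-params.gamma * (traits - x_out) ** 2))
    )
    return PayoffVector(values=values)


def imitation_stage(
    state: PopulationState,
    payoffs: PayoffVector,
    params: SimulationParams,
    rng: np.random.Generator,
    _group_index: _GroupIndex | None = None,
) -> PopulationState:
    """Every agent adopts the trait of a payoff-proportionally chosen target.

    Synchronous by default: all agents copy start-of-step trait values and the
    adoptions are applied simultaneously.  Group labels never change; ``t`` is
    incremented.
    """
    gi = _group_index or _build_group_index(state.groups, params.n_groups)
    n = state.n

    if not params.synchronous or not params.imitate_self:
        # agent-sequential fallback; with synchronous=False agents copy live
        # trait values in a random order
        order = rng.permutation(n) if not params.synchronous else np.arange(n)
        traits = state.traits.copy()
        live = PopulationState(traits=traits, groups=state.groups, t=state.t)
        source = traits if not params.synchronous else state.traits
        for i in order:
            target = select_imitation_target(
                payoffs, live, int(i), params.rho, rng, include_self=params.imitate_self
            )
            traits[i] = source[target]
            if params.copy_noise_sd > 0:
                traits[i] += rng.normal(0.0, params.copy_noise_sd)
        return PopulationState(traits=traits, groups=state.groups.copy(), t=state.t + 1)

    restrict = rng.random(n) < params.rho
    draws = rng.random(n)
    w = payoffs.values

    cum_all = np.cumsum(w)
    targets = np.searchsorted(cum_all, draws * cum_all[-1], side="right")
    np.clip(targets, 0, n - 1, out=targets)
    for g, members in enumerate(gi.members):
        sel = restrict & (state.groups == g)
        if not sel.any():
            continue
        cum_g = np.cumsum(w[members])
        idx = np.searchsorted(cum_g, draws[sel] * cum_g[-1], side="right")
        np.clip(idx, 0, members.size - 1, out=idx)
        targets[sel] = members[idx]

    new_traits = state.traits[targets]
    if params.copy_noise_sd > 0:
        new_traits = new_traits + rng.normal(0.0, params.copy_noise_sd, size=n)
    return PopulationState(traits=new_traits, groups=state.groups.copy(), t=state.t + 1)


# ---------------------------------------------------------------------------
# runner


def _record(traits: np.ndarray, gi: _GroupIndex, row: int, med, mean, sd) -> None:
    for g, m in enumerate(gi.members):
        x = traits[m]
        med[row, g] = np.median(x)
        mean[row, g] = x.mean()
        sd[row, g] = x.std()


def run_simulation(params: SimulationParams, record_states: bool = False) -> Trajectory:
    """Run a full simulation: initialise, then ``t_max`` interaction/imitation steps.

    Returns a :class:`Trajectory` with per-step group medians, means and
    standard deviations (rows ``0..t_max``).  Fully reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    state = init_population(params, rng)
    gi = _build_group_index(state.groups, params.n_groups)
    m = params.n_groups
    shape = (params.t_max + 1, m)
    med = np.empty(shape)
    mean = np.empty(shape)
    sd = np.empty(shape)
    _record(state.traits, gi, 0, med, mean, sd)
    initial = PopulationState(state.traits.copy(), state.groups.copy(), 0)
    states = [initial] if record_states else []
    for step in range(params.t_max):
        payoffs = interaction_stage(state, params, rng, _group_index=gi)
        state = imitation_stage(state, payoffs, params, rng, _group_index=gi)
        _record(state.traits, gi, step + 1, med, mean, sd)
        if record_states:
            states.append(PopulationState(state.traits.copy(), state.groups.copy(), state.t))
    return Trajectory(
        params=params,
        per_step_group_medians=med,
        per_step_group_means=mean,
        per_step_group_sds=sd,
        initial_state=initial,
        final_state=state,
        states=states,
    )
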