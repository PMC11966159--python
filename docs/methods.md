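# Methods

## Model

`normsim` simulates the cultural evolution of a single continuous behavioural
trait in a group-structured population. The population holds `N` agents
(default 100) in `M ≥ 2` fixed groups; group membership never changes during
a run. Agent `i`'s state is one real number `x_i`. Trait values are
unbounded and unitless ("trait units"); the initial configuration fixes the
scale, with group means separated by 1 and within-group standard deviation 1.

Each time step applies two stages to the whole population.

**Interaction stage.** Every agent is focal exactly once. The focal agent
draws one partner: with probability `r` uniformly from its own group
(excluding itself), otherwise uniformly from the whole population (excluding
itself). Its payoff is

    V_i = exp(-alpha (x_i - theta)^2) * exp(-beta (x_i - x_j)^2)
          + (1 - exp(-gamma (x_i - xbar_out)^2))

with `xbar_out` the mean trait of all agents outside `i`'s group, computed
once per step from start-of-step traits. The product of the two Gaussian
factors lies in (0, 1] and the dissimilarity term in [0, 1), so payoffs are
strictly inside (0, 2) for finite traits; this is asserted on every stage.

**Imitation stage.** Every agent chooses a target with probability
proportional to the target's payoff from this step's interaction stage. With
probability `rho` the candidate set is the agent's own group, otherwise the
whole population; in both cases the focal agent is itself a candidate, so
high-payoff agents can retain their trait (switchable via
`imitate_self=False`). The agent adopts the target's start-of-step trait
value exactly; optional Gaussian copy noise (`copy_noise_sd`, default 0) can
be added as an extension. All adoptions are applied simultaneously
(synchronous update). An agent-sequential mode (`synchronous=False`), in
which imitations are applied in random order against live trait values, is
provided for sensitivity checks only.

## Parameters

| name | meaning | default |
| --- | --- | --- |
| `n_agents` | population size N | 100 |
| `n_groups` | number of groups M | 2 |
| `p` | proportion of agents in group 0 (list of proportions for M > 2) | 0.5 |
| `group_means` | initial trait mean per group | (0, 1) |
| `init_sd` | initial within-group trait SD | 1 |
| `theta` | objective optimal trait value (scalar or per group) | 0 |
| `alpha` | weight of the objective-value payoff term | 0.02 |
| `beta` | weight of partner similarity | 0.5 |
| `gamma` | weight of outgroup dissimilarity | 0.05 |
| `r` | coalitional assortment (P(partner is ingroup)) | 0.5 |
| `rho` | coalitional copying (P(imitation pool is ingroup)) | 0.75 |
| `t_max` | number of steps | 100 |
| `copy_noise_sd` | SD of copy noise | 0 |

The defaults are the reference study condition: equal group sizes, a shared
objective optimum at 0, weak objective pressure, moderate partner-similarity
pressure, a small differentiation incentive, and moderately coalitional
interaction and copying, run for 100 steps (long enough for the group
medians to stop moving at the default population size). `N = 100` keeps
medians stable while a full parameter sweep stays near-instant. Per-group
`theta` values model groups facing different functional optima; this variant
is supported but not exercised by the default experiments.

## Regime structure

The model has two locally stable configurations. If every agent holds (or
nearly holds) one common value, deviation is penalised by the partner
similarity and objective terms while the dissimilarity reward grows only
quadratically from zero — the merged state is an attractor. If the two
groups hold tight clusters separated by a distance D, a focal agent gains
roughly `2*gamma*D` per unit of movement away from the outgroup versus
`beta*(1-r)*D` of partner-similarity pull toward it (only the fraction
`(1-r)/2` of partners are outgroup members), plus mixing through the
`(1-rho)` population-wide imitation pool; for large D the Gaussian
similarity factor vanishes faster than the dissimilarity gradient, so
sufficiently separated clusters repel and the split state is
self-sustaining. Which basin the default initial condition (separation 1,
SD 1) falls into depends on the weights: at `alpha=0.02, beta=0.5, r=0.5,
rho=0.75` the run converges for `gamma = 0.05` and diverges far beyond the
initial separation for `gamma = 0.15` (see the README example). Larger `r`
and `rho` shrink both cross-group couplings and move the boundary toward
smaller `gamma`; larger `alpha` pulls both groups onto `theta` and moves it
the other way. The replicate-averaged Δ trait median over the sweep grid
reflects exactly these directions (falling in `alpha`, rising in `r` and
`rho`, comparatively flat in `beta`).

Because noiseless copying can only reuse existing trait values, the set of
distinct values shrinks monotonically and every run eventually freezes on a
few values. Coalitional copying purges cross-copied minority values from
each group, which makes near-split states metastable: a minority of runs at
`gamma = 0` still carry two values a few tenths of a trait unit apart at
step 100 even though the medians agree to < 0.01 (the asymptotic fate is a
single value).

## Numerical and design choices

- **Group allocation** is deterministic: `floor(p*N)` agents in group 0 for
  two groups (largest-remainder apportionment for more), guaranteeing
  non-empty groups and removing binomial variance from the group sizes.
  A group allocated zero agents is a configuration error naming the group.
- **Payoff-proportional choice** uses cumulative-sum inversion of a single
  uniform draw. Payoff positivity makes the normalisation safe; exact ties
  have probability zero for continuous traits.
- **Singleton ingroup** in partner selection falls back to a
  population-wide draw and logs a warning rather than deadlocking at
  extreme `p`.
- **Stages are vectorised** over agents. The per-agent functions
  `select_partner` and `select_imitation_target` define the sampling
  distributions and serve the unit tests and the asynchronous mode; the
  vectorised stages draw from identical distributions but consume the RNG
  stream in a different order, so the two modes match statistically, not
  draw-for-draw.
- **RNG discipline:** one `numpy` PCG64 generator per run, seeded from
  `params.seed`, covers initialisation and all steps. Replicate `k` of a
  condition uses `root_seed + k`. Sweep cells derive their root seed from a
  stable hash of the global root seed and the cell's own `(alpha, beta, r,
  rho)` coordinates, so a cell's result is independent of the rest of the
  grid.
- **Δ trait median** is the absolute difference of the two group medians
  (maximum pairwise difference for M > 2), taken per run *before* averaging
  across replicates, so runs diverging in opposite directions cannot
  cancel. Even-sized groups use the midpoint-of-central-pair median.
- **Convergence flag:** final population spread (max − min trait) below
  0.1 trait units, well under the initial between-group separation of 1.
- **Sweep grid defaults:** `alpha ∈ {0, 0.01, 0.02, 0.04, 0.06}`,
  `beta ∈ {0.1, 0.5, 1}`, `r ∈ {0, 0.5, 1}`, `rho ∈ {0, 0.5, 0.75, 1}`,
  30 replicates per cell — brackets the two regime-defining `alpha` values
  and the reference `(r, rho)` condition; 180 cells run in under two
  minutes on one core. Axis trends are summarised by the sign of the
  least-squares slope of the marginal means (slopes below 1e-9, relative to
  the marginal scale, are reported as flat).

## What the simulations do and do not show

All inputs are generated internally; there is no empirical data path. The
initial conditions emulate two communities whose norm distributions overlap
heavily but differ noticeably in central tendency. Passing tests therefore
demonstrate the internal logic of the mechanism — the direction of each
force, the bistability, reproducibility — not that any real cultural trait
follows these dynamics. Real norms are multidimensional, group membership
changes and subdivides over time, innovation continually injects new trait
values (here excluded by default to preserve the value-conservation
invariant), and interaction is structured by networks rather than uniform
mixing within/between groups. None of these are modelled.

## Known limitations

- Exactly where the convergence/divergence boundary falls is sensitive to
  implementation details of the update rule (update order, self-inclusion,
  selection scheme); conclusions should rest on the qualitative regime
  structure and trend directions, not on boundary coordinates.
- With `imitate_self=False` and `rho > 0`, a singleton group would have an
  empty imitation pool; this raises an error rather than silently falling
  back.
- Metastable near-split states mean "fraction converged" at a finite
  horizon understates asymptotic convergence, especially at small `gamma`.
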