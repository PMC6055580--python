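"""Asynchronous individual-based optimization of vertical habitat choice.

Each virtual animal occupies one sector of the column.  Within a time step
the agents are visited in a fresh random order; each compares the perceived
fitness (growth-to-mortality ratio) of staying with that of the two
adjacent sectors and moves to the strict maximizer, breaking ties uniformly
at random.  Occupancy updates immediately within the sweep, so later agents
face the situation left by earlier movers.  Perception is imperfect: food
or light differences smaller than a relative detection threshold are
invisible, in which case the candidate sector is assessed at the current
sector's conditions.  A candidate sector's density includes the prospective
mover (the agent evaluates the world as it would be after moving).

Demography is frozen: mortality enters only through the fitness
denominator; the number and age of agents never changes during a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .column import EnvironmentProfile, SectorColumn, treatment_environment
from .rates import (
    ADULT,
    GrowthParams,
    MortalityParams,
    PerceptionParams,
    RDParams,
    attack_rate,
    reaction_distance,
)

__all__ = [
    "AgeClassParams",
    "ModelParams",
    "SimulationConfig",
    "SimulationState",
    "OccupancyResult",
    "default_params",
    "perceived_fitness",
    "step",
    "run_simulation",
    "run_replicates",
    "equilibrium_check",
    "occupancy_to_frame",
]

try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class InvalidMoveError(ValueError):
    """Raised when a non-adjacent candidate sector is evaluated."""


@dataclass(frozen=True)
class AgeClassParams:
    """Everything age-specific: growth and reaction-distance coefficients,
    perception thresholds and the type III foraging-initiation threshold."""

    growth: GrowthParams
    rd: RDParams
    perception: PerceptionParams
    gamma: float


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the habitat-choice model."""

    juvenile: AgeClassParams
    adult: AgeClassParams
    mortality: MortalityParams = field(default_factory=MortalityParams)
    handling: float = 1e-8
    n_exponent: float = 2.0

    def for_age(self, age: str) -> AgeClassParams:
        return self.adult if age == ADULT else self.juvenile


def default_params() -> ModelParams:
    """Default parameterization.

    The type III thresholds are the fitted juvenile value 3.4158 ind/L and
    its two-order-of-magnitude reduction 0.0342 ind/L for adults; food
    detection thresholds are 0.19 (juvenile) and 0.08 (adult).
    """
    return ModelParams(
        juvenile=AgeClassParams(
            growth=GrowthParams(),
            rd=RDParams(),
            perception=PerceptionParams(ae_food=0.19),
            gamma=3.4158,
        ),
        adult=AgeClassParams(
            growth=GrowthParams(),
            rd=RDParams(),
            perception=PerceptionParams(ae_food=0.08),
            gamma=0.0342,
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol settings for one simulation batch.

    Defaults follow the published protocol: agents released in the fifth
    sector from the top, 200 steps with the first 100 discarded as burn-in,
    100 replicates.
    """

    n_individuals: int
    age: str = "juvenile"
    treatment: str = "none"
    response_type: str = "III"
    n_steps: int = 200
    burn_in: int = 100
    n_replicates: int = 100
    seed: int = 0
    initial_sector: int = 4

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not self.burn_in < self.n_steps:
            raise ValueError("burn_in must be < n_steps")
        if self.response_type not in ("II", "III"):
            raise ValueError("response_type must be 'II' or 'III'")


@dataclass
class SimulationState:
    """Agent sector indices and the derived per-sector occupancy."""

    agent_sectors: np.ndarray
    occupancy: np.ndarray
    step: int = 0

    @classmethod
    def initial(cls, n_individuals: int, sector: int, n_sectors: int) -> "SimulationState":
        agents = np.full(n_individuals, sector, dtype=np.int64)
        occ = np.bincount(agents, minlength=n_sectors).astype(np.int64)
        return cls(agent_sectors=agents, occupancy=occ, step=0)


@dataclass(frozen=True)
class OccupancyResult:
    """Replicate-averaged outcome of a simulation batch."""

    mean_distribution: np.ndarray
    per_replicate_mean_depth: np.ndarray
    grand_mean_depth: float
    final_states: list = field(default_factory=list, repr=False)
    trajectory: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Precomputed per-sector tables
#
# The static parts of the fitness landscape are tabulated once per run:
# for each sector i and each option d (0 = up, 1 = stay, 2 = down) the
# growth rate excluding the density term (``g_tab``) and the attack rate
# (``a_tab``), both under the focal agent's *perceived* food and light.
# Only the density-dependent terms remain to be evaluated in the sweep.
# ---------------------------------------------------------------------------


def _perceived(value_candidate: float, value_current: float, threshold: float) -> float:
    """Candidate-sector value as perceived from the current sector."""
    if abs(value_candidate - value_current) < threshold * value_current:
        return value_current
    return value_candidate


def _build_tables(env: EnvironmentProfile, age: str, params: ModelParams,
                  response_type: str):
    ap = params.for_age(age)
    g, rd, pc = ap.growth, ap.rd, ap.perception
    col = env.column
    n = col.n_sectors
    risk_on = env.kairomone

    def growth_static(food: float, light: float) -> float:
        light_cost = (g.c + (g.u if age == ADULT else 0.0)) * np.log10(1.0 + light)
        return (
            g.g0
            + g.a1 * food / (g.a2 + food)
            - light_cost
            - (g.kappa if risk_on else 0.0)
        )

    g_tab = np.full((n, 3), -np.inf)
    a_tab = np.zeros((n, 3))
    valid = np.zeros((n, 3), dtype=np.bool_)
    for i in range(n):
        for d, j in ((0, i - 1), (1, i), (2, i + 1)):
            if j < 0 or j >= n:
                continue
            valid[i, d] = True
            if j == i:
                food, light = env.food[i], env.light[i]
            else:
                food = _perceived(env.food[j], env.food[i], pc.ae_food)
                light = _perceived(env.light[j], env.light[i], pc.ae_light)
            g_tab[i, d] = growth_static(food, light)
            if risk_on:
                a_tab[i, d] = attack_rate(
                    reaction_distance(light, env.band_weights[j], age, rd),
                    params.mortality.swim_speed,
                )

    gamma = ap.gamma if response_type == "III" else 0.0
    nexp = params.n_exponent if response_type == "III" else 1.0
    pred = params.mortality.predator_density if risk_on else 0.0
    scalars = dict(
        b=g.b,
        volume=col.sector_volume,
        predator=pred,
        handling=params.handling,
        gamma=gamma,
        nexp=nexp,
        inv_longevity=1.0 / params.mortality.longevity,
        longevity=params.mortality.longevity,
    )
    return g_tab, a_tab, valid, scalars


def _option_fitness(occ_target, moving, g_static, a_rate, b, volume, predator,
                    handling, gamma, nexp, inv_longevity, longevity):
    """Fitness of one stay/move option; shared by both sweep backends."""
    dens = (occ_target + (1 if moving else 0)) / volume
    gr = g_static - b * dens
    mu = 0.0
    if predator > 0.0:
        M = dens - gamma
        if M > 0.0:
            Mn = M**nexp
            mu = predator * a_rate * Mn / (dens * (1.0 + a_rate * handling * Mn))
    mort = mu + inv_longevity
    if gr > 0.0:
        return gr / mort
    return gr * longevity


def _sweep_impl(agents, occ, g_tab, a_tab, valid, b, volume, predator, handling,
                gamma, nexp, inv_longevity, longevity, perm, tie_u):
    """One full sweep over all agents in the given order (in place)."""
    n_sectors = occ.shape[0]
    fits = np.empty(3)
    opts = np.empty(3, dtype=np.int64)
    ties = np.empty(3, dtype=np.int64)
    for a_idx in perm:
        cur = agents[a_idx]
        n_opts = 0
        for d in range(3):
            if not valid[cur, d]:
                continue
            j = cur + d - 1
            moving = j != cur
            dens = (occ[j] + (1 if moving else 0)) / volume
            gr = g_tab[cur, d] - b * dens
            mu = 0.0
            if predator > 0.0:
                M = dens - gamma
                if M > 0.0:
                    Mn = M**nexp
                    ar = a_tab[cur, d]
                    mu = predator * ar * Mn / (dens * (1.0 + ar * handling * Mn))
            mort = mu + inv_longevity
            if gr > 0.0:
                fit = gr / mort
            else:
                fit = gr * longevity
            fits[n_opts] = fit
            opts[n_opts] = j
            n_opts += 1
        best = fits[0]
        for k in range(1, n_opts):
            if fits[k] > best:
                best = fits[k]
        tol = 1e-12 * (abs(best) if abs(best) > 1.0 else 1.0)
        n_ties = 0
        for k in range(n_opts):
            if best - fits[k] <= tol:
                ties[n_ties] = opts[k]
                n_ties += 1
        choice = ties[int(tie_u[a_idx] * n_ties)]
        if choice != cur:
            occ[cur] -= 1
            occ[choice] += 1
            agents[a_idx] = choice
    return n_sectors


_sweep_python = _sweep_impl
if _HAVE_NUMBA:
    _sweep_fast = _njit(_sweep_impl)
else:  # pragma: no cover
    _sweep_fast = _sweep_impl


def perceived_fitness(
    agent_sector: int,
    candidate_sector: int,
    state: SimulationState,
    env: EnvironmentProfile,
    params: ModelParams,
    age: str = "juvenile",
    response_type: str = "III",
) -> float:
    """Fitness of one candidate sector as perceived by an agent.

    The candidate must be the agent's own sector or an adjacent one.  For a
    move, the candidate's density counts the mover itself; for staying, the
    occupancy already includes the agent.
    """
    if abs(candidate_sector - agent_sector) > 1:
        raise InvalidMoveError(
            f"sector {candidate_sector} is not adjacent to {agent_sector}"
        )
    if not (0 <= candidate_sector < env.column.n_sectors):
        raise InvalidMoveError(f"sector {candidate_sector} outside the column")
    g_tab, a_tab, valid, sc = _build_tables(env, age, params, response_type)
    d = candidate_sector - agent_sector + 1
    return _option_fitness(
        state.occupancy[candidate_sector],
        candidate_sector != agent_sector,
        g_tab[agent_sector, d],
        a_tab[agent_sector, d],
        **sc,
    )


def step(
    state: SimulationState,
    env: EnvironmentProfile,
    params: ModelParams,
    rng: np.random.Generator,
    age: str = "juvenile",
    response_type: str = "III",
    _tables=None,
    _backend=None,
) -> SimulationState:
    """Advance the state by one full sweep (all agents, random order)."""
    tables = _tables if _tables is not None else _build_tables(
        env, age, params, response_type
    )
    g_tab, a_tab, valid, sc = tables
    sweep = _backend if _backend is not None else _sweep_fast
    n = len(state.agent_sectors)
    perm = rng.permutation(n)
    tie_u = rng.random(n)
    sweep(
        state.agent_sectors, state.occupancy, g_tab, a_tab, valid,
        sc["b"], sc["volume"], sc["predator"], sc["handling"], sc["gamma"],
        sc["nexp"], sc["inv_longevity"], sc["longevity"], perm, tie_u,
    )
    state.step += 1
    return state


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate stream: SeedSequence((root, replicate))."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


def run_simulation(
    config: SimulationConfig,
    env: EnvironmentProfile | None = None,
    params: ModelParams | None = None,
    replicate: int = 0,
    record_trajectory: bool = False,
    backend: str = "fast",
) -> OccupancyResult:
    """Run a single replicate and average the post-burn-in occupancy.

    The replicate stream is derived from ``(config.seed, replicate)``; the
    mean distribution averages the ``n_steps - burn_in`` post-burn-in
    sweeps, and mean depth weights sector midpoints by those fractions.
    """
    env = env if env is not None else treatment_environment(config.treatment)
    params = params if params is not None else default_params()
    col = env.column
    rng = _replicate_rng(config.seed, replicate)
    state = SimulationState.initial(
        config.n_individuals, config.initial_sector, col.n_sectors
    )
    tables = _build_tables(env, config.age, params, config.response_type)
    sweep = _sweep_python if backend == "python" else _sweep_fast
    accum = np.zeros(col.n_sectors)
    traj = [] if record_trajectory else None
    for _ in range(config.n_steps):
        step(state, env, params, rng, config.age, config.response_type,
             _tables=tables, _backend=sweep)
        if record_trajectory:
            traj.append(state.occupancy.copy())
        if state.step > config.burn_in:
            accum += state.occupancy
    n_recorded = config.n_steps - config.burn_in
    dist = accum / (n_recorded * config.n_individuals)
    depth = float(dist @ col.midpoints)
    return OccupancyResult(
        mean_distribution=dist,
        per_replicate_mean_depth=np.array([depth]),
        grand_mean_depth=depth,
        final_states=[state],
        trajectory=np.array(traj) if record_trajectory else None,
    )


def run_replicates(
    config: SimulationConfig,
    env: EnvironmentProfile | None = None,
    params: ModelParams | None = None,
    keep_final_states: bool = False,
    backend: str = "fast",
) -> OccupancyResult:
    """Run ``config.n_replicates`` independent replicates and pool them."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    env = env if env is not None else treatment_environment(config.treatment)
    params = params if params is not None else default_params()
    dists = []
    depths = []
    finals = []
    for r in range(config.n_replicates):
        res = run_simulation(config, env, params, replicate=r, backend=backend)
        dists.append(res.mean_distribution)
        depths.append(res.grand_mean_depth)
        if keep_final_states:
            finals.append(res.final_states[0])
    mean_dist = np.mean(dists, axis=0)
    depths = np.asarray(depths)
    return OccupancyResult(
        mean_distribution=mean_dist,
        per_replicate_mean_depth=depths,
        grand_mean_depth=float(depths.mean()),
        final_states=finals,
    )


def equilibrium_check(
    state: SimulationState,
    env: EnvironmentProfile,
    params: ModelParams,
    age: str = "juvenile",
    response_type: str = "III",
) -> float:
    """Maximum perceivable unilateral fitness gain over all agents.

    A value <= 0 means no agent perceives a better adjacent sector: the
    configuration is a (perceived) ideal-free / Nash state.
    """
    g_tab, a_tab, valid, sc = _build_tables(env, age, params, response_type)
    n_sectors = env.column.n_sectors
    # one evaluation per occupied sector suffices: agents are interchangeable
    max_gain = -np.inf
    for i in range(n_sectors):
        if state.occupancy[i] == 0:
            continue
        stay = _option_fitness(
            state.occupancy[i], False, g_tab[i, 1], a_tab[i, 1], **sc
        )
        best_move = -np.inf
        for d, j in ((0, i - 1), (2, i + 1)):
            if not valid[i, d]:
                continue
            best_move = max(
                best_move,
                _option_fitness(
                    state.occupancy[j], True, g_tab[i, d], a_tab[i, d], **sc
                ),
            )
        max_gain = max(max_gain, best_move - stay)
    return float(max_gain)


def occupancy_to_frame(result: OccupancyResult, column: SectorColumn) -> pd.DataFrame:
    """Summary table: one row per sector with the pooled mean fraction."""
    return pd.DataFrame(
        {
            "sector_index": np.arange(column.n_sectors),
            "depth_m": column.midpoints,
            "mean_fraction": result.mean_distribution,
        }
    )
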