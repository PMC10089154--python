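"""Stochastic stage-structured individual-based spread model.

Each day, in order: adults reproduce, non-juveniles disperse, everyone is
exposed to mortality and the survivors age (and may advance a size stage).
Dispersal follows the kernel: an individual at node j visits its neighbours
in a fresh uniformly random order and moves to the first neighbour k whose
uniform draw falls at or below D(j,k) — at most one move per individual per
day, with age and stage untouched by the move.

Individuals are held as parallel numpy arrays (age, stage, node), so all
demographic and dispersal draws are vectorised; a day costs a handful of
array operations per node rather than a Python loop over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import DispersalKernel, dispersal_probability
from .networks import SpatialHabitatNetwork

__all__ = [
    "DemographicParams",
    "PopulationState",
    "SimulationResult",
    "initialize",
    "reproduce_step",
    "disperse_step",
    "mortality_and_aging_step",
    "simulate",
]


@dataclass(frozen=True)
class DemographicParams:
    """Per-day vital rates of the stage-structured population.

    Defaults give a springtail-like life history: four size stages, only the
    largest reproducing, Poisson clutches, uniform background mortality, and
    a per-node recruitment ceiling that saturates a source patch within a few
    weeks.  Individuals at or below ``juvenile_age_threshold`` days never
    disperse.
    """

    n_stages: int = 4
    stage_advance_prob: float = 0.1
    repro_prob: float = 0.15
    clutch_size_mean: float = 5.0
    mortality_prob: float | tuple[float, ...] = 0.02
    density_ceiling: int | None = 300
    juvenile_age_threshold: int = 7

    def __post_init__(self):
        probs = [self.stage_advance_prob, self.repro_prob] + list(
            np.atleast_1d(self.mortality_prob)
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all rates must be probabilities in [0, 1]")
        if self.n_stages < 1:
            raise ValueError("need at least one stage")
        if self.density_ceiling is not None and self.density_ceiling < 1:
            raise ValueError("density_ceiling must be >= 1 (or None)")
        if self.juvenile_age_threshold < 0:
            raise ValueError("juvenile_age_threshold must be >= 0")
        if self.clutch_size_mean < 0:
            raise ValueError("clutch_size_mean must be >= 0")

    def mortality_by_stage(self) -> np.ndarray:
        m = np.atleast_1d(np.asarray(self.mortality_prob, dtype=float))
        if m.size == 1:
            m = np.repeat(m, self.n_stages)
        if m.size != self.n_stages:
            raise ValueError("mortality_prob must be scalar or one value per stage")
        return m


@dataclass
class PopulationState:
    """Roster of individuals as parallel arrays."""

    day: int
    age: np.ndarray  # days, int
    stage: np.ndarray  # 1..n_stages, int
    node: np.ndarray  # node id, int
    n_nodes: int

    @property
    def size(self) -> int:
        return self.age.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.node, minlength=self.n_nodes)

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.day, self.age.copy(), self.stage.copy(), self.node.copy(), self.n_nodes
        )


@dataclass
class SimulationResult:
    """Daily counts plus colonization and occupancy summaries.

    ``counts`` has one row per recorded day (row d = end of day d; row 0 is
    the initial state) and one column per node.  ``colonization_day[j]`` is
    the first day node j held at least one individual (−1 if never);
    ``occupancy_day`` is the first day every node held at least one
    individual simultaneously, or None when the run is censored at the
    horizon.
    """

    counts: np.ndarray
    colonization_day: np.ndarray
    occupancy_day: int | None
    censored: bool
    duration: int
    seed: int | None
    topology_id: str
    move_ages: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    @property
    def occupancy_or_horizon(self) -> float:
        """Occupancy day with censored runs entered at the horizon."""
        return float(self.duration if self.occupancy_day is None else self.occupancy_day)


def initialize(
    net: SpatialHabitatNetwork,
    source: int,
    n0: int,
    rng: np.random.Generator,
    params: DemographicParams | None = None,
    stages: np.ndarray | None = None,
) -> PopulationState:
    """Introduce ``n0`` individuals at the source node.

    Stages are drawn uniformly from the size classes unless given explicitly;
    initial age is stage×7 days, so stage-1 individuals start as juveniles
    while larger stages can disperse immediately.
    """
    params = params or DemographicParams()
    if not 0 <= source < net.n_nodes:
        raise ValueError(f"source node {source} not in network")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if stages is None:
        stages = rng.integers(1, params.n_stages + 1, size=n0)
    else:
        stages = np.asarray(stages, dtype=np.int64)
        if stages.size != n0 or np.any((stages < 1) | (stages > params.n_stages)):
            raise ValueError("invalid explicit stage assignment")
    age = stages * params.juvenile_age_threshold
    return PopulationState(
        day=0,
        age=age.astype(np.int64),
        stage=stages.astype(np.int64),
        node=np.full(n0, source, dtype=np.int64),
        n_nodes=net.n_nodes,
    )


def reproduce_step(
    state: PopulationState, params: DemographicParams, rng: np.random.Generator
) -> PopulationState:
    """Adults reproduce; recruits enter stage 1 at age 0 in the parent's node.

    Recruitment is truncated so no node exceeds the density ceiling.
    """
    adults = state.stage == params.n_stages
    n_adults = int(adults.sum())
    if n_adults == 0 or params.repro_prob == 0.0:
        return state
    reproducing = rng.random(n_adults) <= params.repro_prob
    if not reproducing.any():
        return state
    parent_nodes = state.node[adults][reproducing]
    clutches = rng.poisson(params.clutch_size_mean, size=parent_nodes.size)
    recruits = np.bincount(parent_nodes, weights=clutches, minlength=state.n_nodes)
    recruits = recruits.astype(np.int64)
    if params.density_ceiling is not None:
        room = np.maximum(params.density_ceiling - state.counts(), 0)
        recruits = np.minimum(recruits, room)
    total = int(recruits.sum())
    if total == 0:
        return state
    new_nodes = np.repeat(np.arange(state.n_nodes), recruits)
    return PopulationState(
        day=state.day,
        age=np.concatenate([state.age, np.zeros(total, dtype=np.int64)]),
        stage=np.concatenate([state.stage, np.ones(total, dtype=np.int64)]),
        node=np.concatenate([state.node, new_nodes]),
        n_nodes=state.n_nodes,
    )


def _dispersal_table(
    net: SpatialHabitatNetwork, kernel: DispersalKernel
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-node (neighbour ids, per-day crossing probabilities)."""
    nbr_lists = net.neighbor_lists()
    table = []
    for j, nbrs in enumerate(nbr_lists):
        if nbrs.size:
            lengths = np.array([net.length_of(j, int(k)) for k in nbrs])
            probs = np.asarray(dispersal_probability(kernel, lengths), dtype=float)
        else:
            probs = np.empty(0)
        table.append((nbrs, probs))
    return table


def disperse_step(
    state: PopulationState,
    net: SpatialHabitatNetwork,
    kernel: DispersalKernel,
    params: DemographicParams,
    rng: np.random.Generator,
    table: list[tuple[np.ndarray, np.ndarray]] | None = None,
    collect_move_ages: bool = False,
):
    """One day of dispersal; conserves the total population exactly.

    Destinations are computed against a snapshot of the day's start, so an
    individual moves at most once per day.  Returns the new state, or
    ``(state, ages_of_movers)`` when ``collect_move_ages`` is set.
    """
    if table is None:
        table = _dispersal_table(net, kernel)
    eligible = state.age > params.juvenile_age_threshold
    new_node = state.node.copy()
    moved_mask = np.zeros(state.size, dtype=bool)
    for j in range(state.n_nodes):
        nbrs, probs = table[j]
        if nbrs.size == 0 or not probs.any():
            continue
        idx = np.nonzero(eligible & (state.node == j))[0]
        m = idx.size
        if m == 0:
            continue
        d = nbrs.size
        order = rng.random((m, d)).argsort(axis=1)  # fresh random neighbour order
        u = rng.random((m, d))
        success = u <= probs[order]
        hit = success.any(axis=1)
        if not hit.any():
            continue
        first = success.argmax(axis=1)
        dest = nbrs[order[np.arange(m), first]]
        new_node[idx[hit]] = dest[hit]
        moved_mask[idx[hit]] = True
    out = PopulationState(state.day, state.age, state.stage, new_node, state.n_nodes)
    if collect_move_ages:
        return out, state.age[moved_mask].copy()
    return out


def mortality_and_aging_step(
    state: PopulationState, params: DemographicParams, rng: np.random.Generator
) -> PopulationState:
    """Stage-specific mortality, then survivors age one day and may advance."""
    if state.size == 0:
        return state
    mort = params.mortality_by_stage()
    dies = rng.random(state.size) <= mort[state.stage - 1]
    # p=0 must never kill: random() can return exactly 0.0
    if np.all(mort == 0.0):
        dies[:] = False
    keep = ~dies
    age = state.age[keep] + 1
    stage = state.stage[keep].copy()
    if params.stage_advance_prob > 0 and stage.size:
        advance = (rng.random(stage.size) <= params.stage_advance_prob) & (
            stage < params.n_stages
        )
        stage[advance] += 1
    return PopulationState(state.day, age, stage, state.node[keep], state.n_nodes)


def simulate(
    net: SpatialHabitatNetwork,
    params: DemographicParams,
    kernel: DispersalKernel,
    duration: int = 200,
    seed: int | np.random.SeedSequence | None = None,
    source: int = 0,
    n0: int = 200,
    init_state: PopulationState | None = None,
    stop_when_occupied: bool = False,
    collect_move_ages: bool = False,
) -> SimulationResult:
    """Run the daily reproduce → disperse → die loop on a habitat network.

    Fully reproducible given ``seed``.  With ``stop_when_occupied`` the run
    ends on the day full occupancy is reached and the counts table is
    truncated there (used by large sweeps); otherwise counts cover every day
    0..duration.
    """
    if duration < 1:
        raise ValueError("duration must be >= 1")
    rng = np.random.default_rng(seed)
    state = init_state.copy() if init_state is not None else initialize(net, source, n0, rng, params)
    n = net.n_nodes
    counts = np.zeros((duration + 1, n), dtype=np.int64)
    counts[0] = state.counts()
    colonization = np.where(counts[0] > 0, 0, -1)
    occupancy_day: int | None = 0 if bool((counts[0] > 0).all()) else None
    table = _dispersal_table(net, kernel)
    move_ages: list[np.ndarray] = []
    last_day = duration
    for day in range(1, duration + 1):
        if occupancy_day is not None and stop_when_occupied:
            last_day = day - 1
            break
        state = reproduce_step(state, params, rng)
        if collect_move_ages:
            state, ages = disperse_step(state, net, kernel, params, rng, table, True)
            move_ages.append(ages)
        else:
            state = disperse_step(state, net, kernel, params, rng, table)
        state = mortality_and_aging_step(state, params, rng)
        state.day = day
        c = state.counts()
        counts[day] = c
        newly = (c > 0) & (colonization < 0)
        colonization[newly] = day
        if occupancy_day is None and bool((c > 0).all()):
            occupancy_day = day
    return SimulationResult(
        counts=counts[: last_day + 1],
        colonization_day=colonization,
        occupancy_day=occupancy_day,
        censored=occupancy_day is None,
        duration=duration,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        topology_id=net.topology_id,
        move_ages=np.concatenate(move_ages) if move_ages else (np.empty(0, dtype=np.int64) if collect_move_ages else None),
        config={
            "kernel": {"a": kernel.a, "b": kernel.b, "mode": kernel.mode},
            "n0": n0,
            "source": source,
        },
    )
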