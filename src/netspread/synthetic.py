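"""Synthetic data with the structure of the laboratory experiment.

The emulated experiment follows springtail populations on physical habitat
networks for 182 days: each node receives food according to an independent
two-state Markov regime, nodes are photographed every 1–2 (at most 5) days,
and image-based counting misses a fraction of individuals.  These generators
produce data with that structure — Markov food series, irregular observation
schedules, binomially thinned counts, and binomial dispersal trials for
kernel fitting — so every analysis stage can be exercised without the
original dataset.  Default transition and detection rates are placeholders
for testing analysis robustness, not biological estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kernel import DispersalKernel, dispersal_probability
from .simulate import SimulationResult

__all__ = [
    "FOOD_ADDED",
    "NO_FOOD",
    "make_food_regime",
    "make_schedule",
    "observe",
    "occupancy_from_observations",
    "dispersal_trials",
]

FOOD_ADDED = "food_added"
NO_FOOD = "no_food"

DEFAULT_GAP_PROBS = {1: 0.5, 2: 0.45, 5: 0.05}


def make_food_regime(
    n_nodes: int,
    horizon: int,
    p_on_off: float,
    p_off_on: float,
    seed: int | np.random.SeedSequence | None = None,
    start_state: str = FOOD_ADDED,
) -> pd.DataFrame:
    """Independent two-state ('food added' / 'no food') Markov series per node.

    Long-run food fraction tends to p_off_on / (p_on_off + p_off_on).
    Returns rows (node_id, day, state) for days 0..horizon.
    """
    for p in (p_on_off, p_off_on):
        if not 0.0 <= p <= 1.0:
            raise ValueError("transition probabilities must be in [0, 1]")
    if start_state not in (FOOD_ADDED, NO_FOOD):
        raise ValueError(f"unknown start state {start_state!r}")
    rng = np.random.default_rng(seed)
    on = np.empty((horizon + 1, n_nodes), dtype=bool)
    on[0] = start_state == FOOD_ADDED
    u = rng.random((horizon, n_nodes))
    for t in range(1, horizon + 1):
        prev = on[t - 1]
        on[t] = np.where(prev, u[t - 1] >= p_on_off, u[t - 1] < p_off_on)
    days, nodes = np.meshgrid(np.arange(horizon + 1), np.arange(n_nodes), indexing="ij")
    return pd.DataFrame(
        {
            "node_id": nodes.ravel(),
            "day": days.ravel(),
            "state": np.where(on.ravel(), FOOD_ADDED, NO_FOOD),
        }
    )


def make_schedule(
    horizon: int = 182,
    gap_probs: dict[int, float] | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Observation days: day 0, then i.i.d. gaps drawn from ``gap_probs``.

    Gaps must be supported on 1..5 days (photography happened every 1–2,
    at most 5, days).
    """
    gap_probs = DEFAULT_GAP_PROBS if gap_probs is None else gap_probs
    gaps = np.array(sorted(gap_probs))
    if np.any((gaps < 1) | (gaps > 5)):
        raise ValueError("observation gaps must lie in 1..5 days")
    p = np.array([gap_probs[g] for g in gaps], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("gap probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    days = [0]
    while days[-1] < horizon:
        step = int(rng.choice(gaps, p=p))
        if days[-1] + step > horizon:
            break
        days.append(days[-1] + step)
    return np.array(days, dtype=int)


def observe(
    result: SimulationResult,
    schedule: np.ndarray,
    detect_prob: float,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Imperfect observation of a simulation: scheduled days, binomial thinning.

    Each individual present on an observation day is detected independently
    with ``detect_prob``.  First-detection (apparent colonization) days can
    only be later than the truth, since thinning and schedule gaps delay the
    first observed individual.
    """
    if not 0.0 < detect_prob <= 1.0:
        raise ValueError("detect_prob must be in (0, 1]")
    schedule = np.asarray(schedule, dtype=int)
    last = result.counts.shape[0] - 1
    schedule = schedule[schedule <= last]
    rng = np.random.default_rng(seed)
    truth = result.counts[schedule]
    if detect_prob == 1.0:
        obs = truth
    else:
        obs = rng.binomial(truth, detect_prob)
    days, nodes = np.meshgrid(schedule, np.arange(truth.shape[1]), indexing="ij")
    return pd.DataFrame(
        {"day": days.ravel(), "node_id": nodes.ravel(), "count": obs.ravel()}
    )


def occupancy_from_observations(obs: pd.DataFrame) -> int | None:
    """Apparent time to full occupancy from an observed counts table."""
    wide = obs.pivot(index="day", columns="node_id", values="count")
    full = (wide >= 1).all(axis=1)
    hits = full[full].index
    return int(hits[0]) if len(hits) else None


def dispersal_trials(
    kernel: DispersalKernel,
    distances,
    n_per_distance: int,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Binomial dispersal trials at each corridor length, for kernel fitting.

    At distance d, ``n_per_distance`` release trials each succeed with the
    kernel probability at d.  Returns rows (distance_mm, n_trials,
    n_success, proportion) suitable for :func:`netspread.kernel.fit_kernel`.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("need at least one distance")
    if n_per_distance < 1:
        raise ValueError("need at least one trial per distance")
    rng = np.random.default_rng(seed)
    p = np.atleast_1d(dispersal_probability(kernel, distances))
    succ = rng.binomial(n_per_distance, p)
    return pd.DataFrame(
        {
            "distance_mm": distances,
            "n_trials": n_per_distance,
            "n_success": succ,
            "proportion": succ / n_per_distance,
        }
    )
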