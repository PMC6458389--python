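"""Discrete-time engine: migrant entry, Schelling-style movement, breach census.

Each iteration ``t``:

1. **Entry phase** — ``Mig(t) = round(g * P(t-1))`` migrants attempt entry
   (zero once ``P(t-1)`` has reached the population cap). Each attempt draws
   one cell uniformly at random and succeeds with probability
   ``exp(-beta_in * resident_fraction)``; a failed attempt is discarded.
   Admissions take effect immediately (sequential update).
2. **Movement phase** — ``P(t)`` agents are drawn uniformly at random with
   replacement. A drawn agent whose tolerance is breached in its current
   cell picks one other cell uniformly and moves there iff it would be
   satisfied with itself included; otherwise it stays. A resident found
   breached when drawn is flagged with the current iteration (first breach).
3. **Record** — all observables are censused at iteration end. With
   ``params.breach_census`` every resident sitting in a currently breached
   cell is additionally flagged before the record is taken.

Iterations are 1-indexed in outputs; ``t = 0`` is the initial census.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .core import NO_BREACH, CityState, ModelParams, init_city
from .metrics import (
    MetricsRecord,
    Trajectory,
    csi,
    current_breach_fraction,
    ever_breached_fraction,
)

__all__ = [
    "EntryPhaseStats",
    "attempted_migrants",
    "entry_probability",
    "entry_phase",
    "attempt_move",
    "movement_phase",
    "step",
    "run",
]


@dataclass(frozen=True)
class EntryPhaseStats:
    """Bookkeeping of one iteration's entry phase."""

    attempted: int
    admitted: int
    entry_probabilities: list[float]

    def __post_init__(self) -> None:
        if not 0 <= self.admitted <= self.attempted:
            raise ValueError("admitted must lie in [0, attempted]")


def attempted_migrants(
    prev_population: int, initial_population: int, params: ModelParams
) -> int:
    """Number of migrants attempting entry this iteration, ``Mig(t)``.

    Zero once the previous population has reached
    ``max_pop_factor * P(0)``; otherwise ``g * P(t-1)`` rounded half-up.
    """
    if prev_population >= params.max_pop_factor * initial_population:
        return 0
    return int(math.floor(params.g * prev_population + 0.5))


def entry_probability(resident_fraction: float, beta_in: float) -> float:
    """Probability that an entry attempt into a cell succeeds.

    ``exp(-beta_in * resident_fraction)``: full resident cells resist entry,
    emptier or migrant-heavy cells admit more readily. With ``beta_in = 0``
    every attempt succeeds.
    """
    if not 0.0 <= resident_fraction <= 1.0:
        raise ValueError("resident_fraction must lie in [0, 1]")
    if beta_in < 0:
        raise ValueError(f"beta_in must be >= 0, got {beta_in}")
    return math.exp(-beta_in * resident_fraction)


def entry_phase(
    state: CityState, params: ModelParams, rng: random.Random
) -> EntryPhaseStats:
    """Run one iteration's migrant entry; admitted migrants are added in place."""
    attempts = attempted_migrants(state.population, state.initial_population, params)
    res = state.resident_count
    mig = state.migrant_count
    M = params.M
    beta = params.beta_in
    probs: list[float] = []
    admitted = 0
    for _ in range(attempts):
        i = rng.randrange(M)
        total = res[i] + mig[i]
        frac = res[i] / total if total else 0.0
        p = math.exp(-beta * frac)
        probs.append(p)
        if rng.random() < p:
            mig[i] += 1
            admitted += 1
    stats = EntryPhaseStats(attempts, admitted, probs)
    state.entry_log.append((attempts, admitted, probs))
    return stats


def attempt_move(
    state: CityState,
    agent: tuple[str, int],
    params: ModelParams,
    rng: random.Random,
) -> bool:
    """Process one movement attempt for ``agent``; returns True if it moved.

    ``agent`` is ``("resident", resident_id)`` or ``("migrant", cell_index)``
    (migrants are interchangeable within a cell). A satisfied agent does
    nothing. A breached agent draws one candidate cell uniformly among the
    other ``M - 1`` and moves iff it would be satisfied there with itself
    counted; a breached resident is flagged with the state's current
    iteration either way.
    """
    kind, idx = agent
    res = state.resident_count
    mig = state.migrant_count
    M = params.M
    if kind == "resident":
        i = state.resident_cell[idx]
        if mig[i] <= params.tau_res * (res[i] + mig[i]):
            return False
        if state.first_breach[idx] == NO_BREACH:
            state.first_breach[idx] = state.t
        j = rng.randrange(M - 1)
        if j >= i:
            j += 1
        if mig[j] <= params.tau_res * (res[j] + mig[j] + 1):
            res[i] -= 1
            res[j] += 1
            state.resident_cell[idx] = j
            return True
        return False
    elif kind == "migrant":
        i = idx
        if mig[i] < 1:
            raise ValueError(f"no migrant in cell {i}")
        if res[i] <= params.tau_mig * (res[i] + mig[i]):
            return False
        j = rng.randrange(M - 1)
        if j >= i:
            j += 1
        if res[j] <= params.tau_mig * (res[j] + mig[j] + 1):
            mig[i] -= 1
            mig[j] += 1
            return True
        return False
    raise ValueError(f"unknown agent kind {kind!r}")


def _any_breached_agent(state: CityState, params: ModelParams) -> bool:
    """Whether any agent anywhere is currently breached (movement can occur)."""
    tau_r, tau_m = params.tau_res, params.tau_mig
    for res, mig in zip(state.resident_count, state.migrant_count):
        total = res + mig
        if total == 0:
            continue
        if res > 0 and mig > tau_r * total:
            return True
        if mig > 0 and res > tau_m * total:
            return True
    return False


def movement_phase(
    state: CityState, params: ModelParams, rng: random.Random
) -> int:
    """Run one iteration's movement phase; returns the number of moves.

    Default: ``P(t)`` draws uniformly at random with replacement, processed
    sequentially with immediate state updates. With
    ``params.move_without_replacement`` a random permutation of every agent
    is processed once instead.
    """
    if params.move_without_replacement:
        return _movement_phase_permutation(state, params, rng)
    P = state.population
    if not _any_breached_agent(state, params):
        return 0  # nobody can move; the draws would all be no-ops
    # local aliases: this loop dominates runtime
    res = state.resident_count
    mig = state.migrant_count
    res_cell = state.resident_cell
    first_breach = state.first_breach
    N = state.n_residents
    M = params.M
    tau_r = params.tau_res
    tau_m = params.tau_mig
    t = state.t
    randrange = rng.randrange
    moves = 0
    for _ in range(P):
        k = randrange(P)
        if k < N:  # resident k
            i = res_cell[k]
            total = res[i] + mig[i]
            if mig[i] <= tau_r * total:
                continue
            if first_breach[k] == NO_BREACH:
                first_breach[k] = t
            j = randrange(M - 1)
            if j >= i:
                j += 1
            if mig[j] <= tau_r * (res[j] + mig[j] + 1):
                res[i] -= 1
                res[j] += 1
                res_cell[k] = j
                moves += 1
        else:  # migrant: k - N indexes the per-cell migrant blocks
            k -= N
            i = 0
            while k >= mig[i]:
                k -= mig[i]
                i += 1
            total = res[i] + mig[i]
            if res[i] <= tau_m * total:
                continue
            j = randrange(M - 1)
            if j >= i:
                j += 1
            if res[j] <= tau_m * (res[j] + mig[j] + 1):
                mig[i] -= 1
                mig[j] += 1
                moves += 1
    return moves


def _movement_phase_permutation(
    state: CityState, params: ModelParams, rng: random.Random
) -> int:
    """Variant: every agent attempts exactly once, in random order."""
    mig_home = [i for i, m in enumerate(state.migrant_count) for _ in range(m)]
    N = state.n_residents
    order = list(range(N + len(mig_home)))
    rng.shuffle(order)
    res = state.resident_count
    mig = state.migrant_count
    moves = 0
    for k in order:
        if k < N:
            moves += attempt_move(state, ("resident", k), params, rng)
        else:
            i = mig_home[k - N]
            # the migrant that entered the phase in cell i may have moved;
            # process a migrant currently in that cell if any remains
            if mig[i] > 0:
                if attempt_move(state, ("migrant", i), params, rng):
                    moves += 1
    return moves


def step(state: CityState, params: ModelParams, rng: random.Random) -> MetricsRecord:
    """Advance one iteration: entry, movement, end-of-iteration census."""
    prev_pop = state.population
    state.t += 1
    stats = entry_phase(state, params, rng)
    moves = movement_phase(state, params, rng)
    if params.breach_census:
        _census_flag_breached(state, params)
    pop = state.population
    return MetricsRecord(
        t=state.t,
        population=pop,
        migrants=state.n_migrants,
        attempted=stats.attempted,
        admitted=stats.admitted,
        mean_entry_prob=(
            sum(stats.entry_probabilities) / stats.attempted
            if stats.attempted
            else None
        ),
        B_c=current_breach_fraction(state),
        B_f=ever_breached_fraction(state),
        CSI=csi(state),
        growth_rate=(pop - prev_pop) / prev_pop,
        moves=moves,
    )


def _census_flag_breached(state: CityState, params: ModelParams) -> None:
    """Flag every resident currently sitting in a breached cell."""
    tau_r = params.tau_res
    breached = [
        mig > tau_r * (res + mig)
        for res, mig in zip(state.resident_count, state.migrant_count)
    ]
    if not any(breached):
        return
    t = state.t
    first_breach = state.first_breach
    res_cell = state.resident_cell
    for r in range(state.n_residents):
        if first_breach[r] == NO_BREACH and breached[res_cell[r]]:
            first_breach[r] = t


def run(params: ModelParams) -> Trajectory:
    """Simulate a full run and return its trajectory.

    Deterministic: the same ``params`` (including seed) reproduce the
    trajectory bit-for-bit.
    """
    rng = random.Random(params.seed)
    state = init_city(params)
    records = [
        MetricsRecord(
            t=0,
            population=state.population,
            migrants=0,
            attempted=0,
            admitted=0,
            mean_entry_prob=None,
            B_c=current_breach_fraction(state),
            B_f=ever_breached_fraction(state),
            CSI=csi(state),
            growth_rate=math.nan,
            moves=0,
        )
    ]
    for _ in range(params.n_iterations):
        records.append(step(state, params, rng))
    return Trajectory(
        params, records, np.asarray(state.first_breach, dtype=np.int64), state
    )
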