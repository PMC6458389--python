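"""Domain types and elementary predicates of the city model.

The model is a Schelling-type city of ``M`` neighbourhoods ("cells").
Residents carry a tolerance ``tau_res``: the maximum fraction of migrants
they accept in their cell. Migrants carry ``tau_mig``, the maximum fraction
of residents they accept. An agent whose opposite-type fraction strictly
exceeds its tolerance is "breached" and will attempt to relocate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterator, Literal, Optional

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "Agent",
    "CityState",
    "init_city",
    "cell_composition",
    "is_satisfied",
]

NO_BREACH = -1  # sentinel in the per-resident first-breach array


@dataclass(frozen=True)
class ModelParams:
    """Full scenario configuration of the stochastic city model.

    Parameters
    ----------
    M : int
        Number of neighbourhoods (cells).
    n_residents : int
        Initial resident population, split equally across cells; must be
        divisible by ``M``.
    tau_res : float
        Resident tolerance: maximum migrant fraction a resident accepts.
    tau_mig : float
        Migrant tolerance: maximum resident fraction a migrant accepts.
    g : float
        Entry rate: fraction of the current population attempting entry
        per iteration, ``Mig(t) = g * P(t-1)``.
    beta_in : float
        Entry friction; attempt succeeds with probability
        ``exp(-beta_in * resident_fraction)`` of the target cell.
    max_pop_factor : float
        Population cap as a multiple of the initial population; once
        ``P(t-1)`` reaches it, no further migrants attempt entry.
    n_iterations : int
        Number of discrete time steps to simulate.
    seed : int
        Seed of the run's random stream.
    move_without_replacement : bool
        If True the movement phase processes a random permutation of all
        agents instead of ``P(t)`` draws with replacement (non-default
        variant; see the methods note).
    breach_census : bool
        If True an end-of-iteration census additionally flags every
        resident currently sitting in a breached cell. By default breaches
        are recorded only when a sampled agent evaluates its cell during
        the movement phase (agent-centric detection); the census variant
        stamps a whole cell at its breach iteration and guarantees
        ``B_c(t) <= B_f(t)``.
    """

    M: int = 20
    n_residents: int = 1000
    tau_res: float = 0.25
    tau_mig: float = 0.75
    g: float = 0.005
    beta_in: float = 1.0
    max_pop_factor: float = 1.5
    n_iterations: int = 200
    seed: int = 0
    move_without_replacement: bool = False
    breach_census: bool = False

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be a positive integer, got {self.M}")
        if self.n_residents < 1:
            raise ValueError("n_residents must be positive")
        if self.n_residents % self.M != 0:
            raise ValueError(
                f"n_residents={self.n_residents} is not divisible by M={self.M}; "
                "initial cells must be equal"
            )
        if not 0.0 <= self.tau_res <= 1.0:
            raise ValueError(f"tau_res must lie in [0, 1], got {self.tau_res}")
        if not 0.0 <= self.tau_mig <= 1.0:
            raise ValueError(f"tau_mig must lie in [0, 1], got {self.tau_mig}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if self.beta_in < 0:
            raise ValueError(f"beta_in must be >= 0, got {self.beta_in}")
        if self.max_pop_factor < 1:
            raise ValueError(f"max_pop_factor must be >= 1, got {self.max_pop_factor}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")

    @property
    def residents_per_cell(self) -> int:
        """Initial residents per cell, ``p = n_residents / M`` (derived)."""
        return self.n_residents // self.M

    # --- flat-mapping (YAML/JSON) round trip -------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass
class Agent:
    """Read-only record view of one agent (residents carry breach history)."""

    agent_type: Literal["resident", "migrant"]
    cell_index: int
    ever_breached: bool = False
    first_breach_iteration: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ever_breached != (self.first_breach_iteration is not None):
            raise ValueError(
                "first_breach_iteration must be set iff ever_breached is true"
            )


class CityState:
    """Mutable state of the city at one time step.

    Residents are tracked individually: ``resident_cell[r]`` is the cell of
    resident ``r`` and ``first_breach[r]`` its first-breach iteration
    (``NO_BREACH`` while unbreached). Migrants are interchangeable once
    inside the city, so only per-cell counts are kept.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        M = params.M
        p = params.residents_per_cell
        self.t = 0
        # plain lists: the engine's inner loop does scalar access only
        self.resident_cell = [i for i in range(M) for _ in range(p)]
        self.first_breach = [NO_BREACH] * params.n_residents
        self.resident_count = [p] * M
        self.migrant_count = [0] * M
        self.initial_population = params.n_residents
        # per-iteration entry log: (attempted, admitted, [p_entry per attempt])
        self.entry_log: list[tuple[int, int, list[float]]] = []

    # --- aggregates --------------------------------------------------------

    @property
    def n_residents(self) -> int:
        return self.params.n_residents

    @property
    def n_migrants(self) -> int:
        return sum(self.migrant_count)

    @property
    def population(self) -> int:
        return self.n_residents + self.n_migrants

    def cell_population(self, i: int) -> int:
        return self.resident_count[i] + self.migrant_count[i]

    def iter_agents(self) -> Iterator[Agent]:
        """Materialise per-agent records (for inspection, not the hot path)."""
        for r in range(self.n_residents):
            fb = int(self.first_breach[r])
            yield Agent(
                "resident",
                int(self.resident_cell[r]),
                ever_breached=fb != NO_BREACH,
                first_breach_iteration=None if fb == NO_BREACH else fb,
            )
        for i, m in enumerate(self.migrant_count):
            for _ in range(m):
                yield Agent("migrant", i)

    def validate(self) -> None:
        """Internal consistency check (tests and debugging)."""
        counts = np.bincount(np.asarray(self.resident_cell), minlength=self.params.M)
        if list(counts) != self.resident_count:
            raise AssertionError("resident_count out of sync with resident_cell")
        if self.n_residents != self.params.n_residents:
            raise AssertionError("resident conservation violated")
        if any(m < 0 for m in self.migrant_count):
            raise AssertionError("negative migrant count")


def init_city(params: ModelParams) -> CityState:
    """Build the initial city: M equal all-resident cells, nobody breached.

    Raises
    ------
    ValueError
        If ``n_residents`` is not divisible by ``M`` (raised by
        :class:`ModelParams` itself).
    """
    return CityState(params)


def cell_composition(state: CityState, i: int) -> tuple[int, int, float, float]:
    """Counts and fractions ``(n_res, n_mig, f_res, f_mig)`` of cell ``i``.

    Fractions are over all agents in the cell; an empty cell reports
    ``(0, 0, 0.0, 0.0)`` by convention, so it is always an acceptable
    destination.
    """
    if not 0 <= i < state.params.M:
        raise IndexError(f"cell index {i} out of range [0, {state.params.M})")
    n_res = state.resident_count[i]
    n_mig = state.migrant_count[i]
    total = n_res + n_mig
    if total == 0:
        return 0, 0, 0.0, 0.0
    return n_res, n_mig, n_res / total, n_mig / total


def is_satisfied(
    agent_type: Literal["resident", "migrant"],
    opposite_fraction: float,
    params: ModelParams,
) -> bool:
    """Whether an agent tolerates the given opposite-type fraction.

    The tolerance is the *maximum* opposite-type fraction the agent is
    willing to accept, so equality counts as satisfied; a breach is strict
    exceedance.
    """
    if not 0.0 <= opposite_fraction <= 1.0:
        raise ValueError(f"opposite_fraction must lie in [0, 1], got {opposite_fraction}")
    if agent_type == "resident":
        return opposite_fraction <= params.tau_res
    if agent_type == "migrant":
        return opposite_fraction <= params.tau_mig
    raise ValueError(f"unknown agent_type {agent_type!r}")
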