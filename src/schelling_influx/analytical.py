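"""Closed-form deterministic approximation of the breach cascade.

A city of ``M`` sequenced neighbourhoods ``C_1..C_M`` holds ``N`` residents,
``N/M`` per cell. Every iteration ``x`` migrants arrive in every cell.
Resident tolerance is expressed through the threshold ``j``: a cell's
residents are breached once its migrants reach ``tau_r`` times its resident
count (``tau_r = j / (N/M)``, so the first breach needs ``j`` migrants).
When cell ``C_u`` breaches, its residents are redistributed equally over
the cells after it in sequence, raising their thresholds; migrants never
move. This yields a strict breach order ``C_1, C_2, ...`` with closed
forms:

* incremental migrants  ``I_1 = j``, ``I_u = M j / ((M-u+1)(M-u+2))`` for u >= 2
* cumulative migrants per cell at the u-th breach  ``j M / (M-u+1)``
* breach times  ``T_u = (sum of I_1..I_u) / x``
* breach fraction  ``B_u = u / M``

All quantities are real-valued: this is a continuum approximation. The last
cell has no destination cells, so the cascade stops at ``u = M - 1`` and
``B`` is capped at ``(M-1)/M``.

:func:`discrete_oracle` simulates the same rules step by step in discrete
time and serves as an independent cross-check of the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnalyticalParams",
    "BreachSchedule",
    "breach_threshold",
    "incremental_migrants",
    "cumulative_migrants",
    "breach_time",
    "breach_fraction",
    "mean_breach_time",
    "breach_schedule",
    "breach_trajectory",
    "population_increase_at",
    "discrete_oracle",
]


@dataclass(frozen=True)
class AnalyticalParams:
    """Configuration of the deterministic cascade model.

    ``tau_m`` is carried for fidelity with the stochastic model but does not
    enter any formula (migrants are fully tolerant and never move).
    """

    M: int = 20
    N: int = 5000
    tau_r: float = 0.33
    tau_m: float = 1.0
    x: float = 1.0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError(f"M must be >= 2, got {self.M}")
        if self.N < 1:
            raise ValueError("N must be positive")
        if self.x <= 0:
            raise ValueError(f"x must be > 0, got {self.x}")
        if self.tau_r * self.N / self.M <= 0:
            raise ValueError(
                f"breach threshold j = tau_r*N/M must be > 0, got "
                f"{self.tau_r * self.N / self.M}"
            )


@dataclass
class BreachSchedule:
    """Per-breach records (u, I_u, cumulative migrants per cell, T_u, B_u)."""

    params: AnalyticalParams
    u: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    I_u: np.ndarray = field(default_factory=lambda: np.array([]))
    cumulative: np.ndarray = field(default_factory=lambda: np.array([]))
    T_u: np.ndarray = field(default_factory=lambda: np.array([]))
    B_u: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u": self.u,
                "I_u": self.I_u,
                "cumulative": self.cumulative,
                "T_u": self.T_u,
                "B_u": self.B_u,
            }
        )


def breach_threshold(params: AnalyticalParams) -> float:
    """Migrants needed in a pristine cell for its residents to breach, ``j``."""
    return params.tau_r * params.N / params.M


def _check_u(u: int, params: AnalyticalParams, upper: int) -> None:
    if not 1 <= u <= upper:
        raise ValueError(f"breach index u={u} outside [1, {upper}]")


def incremental_migrants(u: int, params: AnalyticalParams) -> float:
    """Additional migrants per cell between the (u-1)-th and u-th breach.

    Piecewise: ``I_1 = j`` exactly; for ``u >= 2``,
    ``I_u = M j / ((M-u+1)(M-u+2))`` (the general formula does not reduce to
    ``j`` at u = 1, so the first step is special-cased).
    """
    _check_u(u, params, params.M - 1)
    j = breach_threshold(params)
    if u == 1:
        return j
    M = params.M
    return M * j / ((M - u + 1) * (M - u + 2))


def cumulative_migrants(u: int, params: AnalyticalParams) -> float:
    """Total migrants per cell at the u-th breach: ``j M / (M-u+1)``.

    Equal to the telescoping sum of ``I_1..I_u``.
    """
    _check_u(u, params, params.M - 1)
    return breach_threshold(params) * params.M / (params.M - u + 1)


def breach_time(u: int, params: AnalyticalParams) -> float:
    """Continuous-time iteration of the u-th breach, ``T_u = (Σ I_q) / x``."""
    _check_u(u, params, params.M - 1)
    return cumulative_migrants(u, params) / params.x


def breach_fraction(u: int, params: AnalyticalParams) -> float:
    """Fraction of residents breached after the u-th breach, ``B_u = u / M``."""
    _check_u(u, params, params.M)
    return u / params.M


def mean_breach_time(S: int, params: AnalyticalParams) -> float:
    """Average breach time over the first S breaches, paired with B = S/M."""
    _check_u(S, params, params.M - 1)
    return sum(breach_time(u, params) for u in range(1, S + 1)) / S


def population_increase_at(u: int, params: AnalyticalParams) -> float:
    """City-wide population increase (fraction of N) at the u-th breach.

    ``M * cumulative_migrants(u) / N``; independent of the arrival rate x.
    """
    _check_u(u, params, params.M - 1)
    return params.M * cumulative_migrants(u, params) / params.N


def breach_schedule(params: AnalyticalParams) -> BreachSchedule:
    """Closed-form schedule for all breaches u = 1 .. M-1."""
    us = np.arange(1, params.M)
    return BreachSchedule(
        params=params,
        u=us,
        I_u=np.array([incremental_migrants(int(u), params) for u in us]),
        cumulative=np.array([cumulative_migrants(int(u), params) for u in us]),
        T_u=np.array([breach_time(int(u), params) for u in us]),
        B_u=np.array([breach_fraction(int(u), params) for u in us]),
    )


def breach_trajectory(params: AnalyticalParams, t_max: float) -> pd.DataFrame:
    """Step function B(t) on [0, t_max]: B = u/M for T_u <= t < T_{u+1}.

    Returns one row per step edge (t, B); B is 0 before T_1 and capped at
    (M-1)/M once the cascade ends.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    sched = breach_schedule(params)
    rows = [{"t": 0.0, "B": 0.0}]
    for T, B in zip(sched.T_u, sched.B_u):
        if T > t_max:
            break
        rows.append({"t": float(T), "B": float(B)})
    return pd.DataFrame(rows)


def discrete_oracle(params: AnalyticalParams, t_max: int) -> BreachSchedule:
    """Simulate the cascade rules literally in discrete time.

    Each iteration adds ``x`` migrant mass to every cell, then sweeps the
    cells in sequence: a cell whose migrant mass has reached ``tau_r`` times
    its resident mass (equality breaches) redistributes its residents
    equally over the cells after it and empties. Breach times are the
    integer iterations at which each breach occurred, so they sit within
    one iteration above the continuous closed-form times.
    """
    M = params.M
    tau_r = params.tau_r
    residents = [params.N / M] * M
    migrants = [0.0] * M
    breached = [False] * M
    events: list[tuple[int, int, float, float]] = []  # (u, t, I_cum, B)
    n_breached = 0
    for t in range(1, t_max + 1):
        for i in range(M):
            migrants[i] += params.x
        for i in range(M - 1):  # the last cell has no destinations
            if breached[i] or residents[i] <= 0:
                continue
            thresh = tau_r * residents[i]
            if migrants[i] >= thresh:
                share = residents[i] / (M - 1 - i)
                for k in range(i + 1, M):
                    residents[k] += share
                residents[i] = 0.0
                breached[i] = True
                n_breached += 1
                # record the trigger level, not the (possibly overshot) mass
                events.append((n_breached, t, thresh, n_breached / M))
        if n_breached >= M - 1:
            break
    if events:
        u, times, cum, B = map(np.array, zip(*events))
    else:
        u = times = cum = B = np.array([])
    return BreachSchedule(
        params=params,
        u=u.astype(int) if u.size else u,
        I_u=np.diff(cum, prepend=0.0) if cum.size else cum,
        cumulative=cum,
        T_u=times.astype(float) if times.size else times,
        B_u=B,
    )
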