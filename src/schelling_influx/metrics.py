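"""Observables of the city dynamics.

Per-iteration state metrics:

* ``B_c(t)`` — current breach fraction: share of residents whose cell's
  migrant fraction strictly exceeds ``tau_res`` right now.
* ``B_f(t)`` — ever-breached fraction: share of residents breached at any
  point so far; monotone nondecreasing.
* ``T_tau`` — mean first-breach iteration over all residents ever breached
  at the end of a run.
* ``CSI`` — cell segregation indicator: mean over non-empty cells of
  ``|f_r - f_m| / (f_r + f_m)`` where ``f_r`` (``f_m``) is the cell's share
  of the city-wide resident (migrant) total. 1 = fully segregated,
  0 = proportionally mixed.

Trajectory-level curves: periodic growth rates, time to reach each whole
percent of ``B_f``, and ``B_f`` versus population increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import NO_BREACH, CityState

__all__ = [
    "MetricsRecord",
    "Trajectory",
    "current_breach_fraction",
    "ever_breached_fraction",
    "mean_time_to_first_breach",
    "csi",
    "periodic_growth_rate",
    "last_admitting_iteration",
    "time_per_breach_percent",
    "breach_vs_population_curve",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Observables censused at the end of one iteration."""

    t: int
    population: int
    migrants: int
    attempted: int
    admitted: int
    mean_entry_prob: Optional[float]
    B_c: float
    B_f: float
    CSI: float
    growth_rate: float
    moves: int = 0


class Trajectory:
    """One run's per-iteration records plus the final per-resident breach table."""

    def __init__(
        self,
        params,
        records: list[MetricsRecord],
        first_breach: np.ndarray,
        final_state: CityState,
    ):
        self.params = params
        self.records = records
        self.first_breach = first_breach  # NO_BREACH where never breached
        self.final_state = final_state

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame, one row per iteration (t = 0 is the initial census)."""
        df = pd.DataFrame([vars(r) if not hasattr(r, "__dict__") else r.__dict__
                           for r in self.records])
        if df.empty:
            df = pd.DataFrame(
                columns=["t", "population", "migrants", "attempted", "admitted",
                         "mean_entry_prob", "B_c", "B_f", "CSI", "growth_rate",
                         "moves"]
            )
        df["mean_entry_prob"] = pd.to_numeric(df["mean_entry_prob"])  # None -> NaN
        df["seed"] = self.params.seed
        df["g"] = self.params.g
        return df

    def breach_table(self) -> pd.DataFrame:
        """(agent_id, first_breach_iteration) for residents ever breached."""
        idx = np.flatnonzero(self.first_breach != NO_BREACH)
        return pd.DataFrame(
            {"agent_id": idx, "first_breach_iteration": self.first_breach[idx]}
        )

    # --- scalar summaries --------------------------------------------------

    @property
    def final_B_f(self) -> float:
        return self.records[-1].B_f

    @property
    def first_breach_time(self) -> float:
        """First iteration with any resident ever breached; nan if none."""
        times = self.first_breach[self.first_breach != NO_BREACH]
        return float(times.min()) if times.size else math.nan

    @property
    def mean_time_to_first_breach(self) -> float:
        """T_tau of this run; nan if no resident was ever breached."""
        times = self.first_breach[self.first_breach != NO_BREACH]
        return float(times.mean()) if times.size else math.nan


# --- state-level metrics ---------------------------------------------------


def _breached_cells(state: CityState) -> list[bool]:
    """Cells whose migrant fraction strictly exceeds tau_res."""
    tau = state.params.tau_res
    out = []
    for res, mig in zip(state.resident_count, state.migrant_count):
        total = res + mig
        out.append(total > 0 and mig > tau * total)
    return out


def current_breach_fraction(state: CityState) -> float:
    """B_c: fraction of residents currently breached, over residents only."""
    breached = _breached_cells(state)
    n_breached = sum(
        res for res, b in zip(state.resident_count, breached) if b
    )
    return n_breached / state.n_residents


def ever_breached_fraction(state: CityState) -> float:
    """B_f: fraction of residents ever breached (flag-based, monotone)."""
    n = sum(1 for fb in state.first_breach if fb != NO_BREACH)
    return n / state.n_residents


def mean_time_to_first_breach(breach_table: Sequence[int] | pd.DataFrame) -> float:
    """T_tau: mean first-breach iteration over breached residents.

    Raises
    ------
    ValueError
        If no resident was ever breached (the mean is undefined, not 0).
    """
    if isinstance(breach_table, pd.DataFrame):
        times = breach_table["first_breach_iteration"].to_numpy()
    else:
        times = np.asarray(list(breach_table), dtype=float)
    if times.size == 0:
        raise ValueError("T_tau is undefined: no resident was ever breached")
    return float(times.mean())


def csi(state: CityState) -> float:
    """Cell segregation indicator over non-empty cells.

    With zero migrants city-wide every migrant share is taken as 0, so the
    indicator is 1 from t = 0 (all-resident cells are fully homogeneous).
    """
    n_res_tot = state.n_residents
    n_mig_tot = state.n_migrants
    terms = []
    for res, mig in zip(state.resident_count, state.migrant_count):
        if res + mig == 0:
            continue
        f_r = res / n_res_tot if n_res_tot else 0.0
        f_m = mig / n_mig_tot if n_mig_tot else 0.0
        terms.append(abs(f_r - f_m) / (f_r + f_m))
    if not terms:
        raise ValueError("CSI is undefined: all cells are empty")
    return sum(terms) / len(terms)


# --- trajectory-level curves -----------------------------------------------


def _mean_frame(trajectory_or_frame) -> pd.DataFrame:
    """Accept a Trajectory, a tidy frame, or an already-aggregated frame."""
    if isinstance(trajectory_or_frame, Trajectory):
        return trajectory_or_frame.to_frame()
    df = trajectory_or_frame
    if "seed" in df.columns and df["seed"].nunique() > 1:
        df = df.groupby("t", as_index=False).mean(numeric_only=True)
    return df.sort_values("t")


def periodic_growth_rate(
    trajectory_or_frame, window: Optional[tuple[int, int]] = None
) -> pd.Series | float:
    """Per-iteration population growth rate (P(t) - P(t-1)) / P(t-1).

    With ``window=(t0, t1)`` returns the mean rate over that inclusive
    iteration range instead of the full series.
    """
    df = _mean_frame(trajectory_or_frame)
    pop = df.set_index("t")["population"]
    rate = pop.diff() / pop.shift(1)
    rate = rate.dropna()
    if window is not None:
        t0, t1 = window
        return float(rate.loc[t0:t1].mean())
    return rate


def last_admitting_iteration(trajectory_or_frame) -> float:
    """Last iteration with nonzero admissions: the end of the pre-cap window.

    ``nan`` if nothing was ever admitted.
    """
    df = _mean_frame(trajectory_or_frame)
    admitting = df.loc[df["admitted"] > 0, "t"]
    return float(admitting.max()) if len(admitting) else math.nan


def time_per_breach_percent(trajectory_or_frame) -> pd.DataFrame:
    """First iteration at which (ensemble-mean) B_f reaches each whole percent.

    Level 0 is the first iteration with B_f > 0, i.e. the first-breach time
    of the mean curve. Levels never attained are absent.
    """
    df = _mean_frame(trajectory_or_frame)
    t = df["t"].to_numpy()
    bf = df["B_f"].to_numpy()
    rows = []
    hit = np.flatnonzero(bf > 0)
    if hit.size:
        rows.append({"level_pct": 0, "t_first": int(t[hit[0]])})
    max_pct = int(math.floor(bf.max() * 100 + 1e-9))
    for level in range(1, max_pct + 1):
        hit = np.flatnonzero(bf >= level / 100 - 1e-12)
        if hit.size:
            rows.append({"level_pct": level, "t_first": int(t[hit[0]])})
    return pd.DataFrame(rows, columns=["level_pct", "t_first"])


def breach_vs_population_curve(trajectory_or_frame) -> pd.DataFrame:
    """Population increase (fraction of P(0)) when B_f first reaches each percent.

    For each whole-percent level of (ensemble-mean) B_f attained, reports
    ``(P(t*) - P(0)) / P(0)`` at the first iteration ``t*`` where the mean
    B_f reaches that level. Level 0 maps to increase 0 at t = 0.
    """
    df = _mean_frame(trajectory_or_frame)
    df = df.sort_values("t")
    pop = df["population"].to_numpy()
    p0 = pop[0]
    timing = time_per_breach_percent(df)
    t_index = df.set_index("t")["population"]
    rows = [{"level_pct": 0, "t_first": int(df["t"].iloc[0]), "pop_increase": 0.0}]
    for _, row in timing.iterrows():
        if row["level_pct"] == 0:
            continue
        p_star = t_index.loc[row["t_first"]]
        rows.append(
            {
                "level_pct": int(row["level_pct"]),
                "t_first": int(row["t_first"]),
                "pop_increase": float((p_star - p0) / p0),
            }
        )
    return pd.DataFrame(rows, columns=["level_pct", "t_first", "pop_increase"])
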