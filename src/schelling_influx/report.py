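"""Artifact plumbing: CSV/JSON export of runs, ensembles and cascade schedules.

Every file is plain text; the manifest records parameters and seeds so a
scenario can be re-run to identical bytes.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .analytical import AnalyticalParams, breach_schedule, breach_trajectory
from .ensemble import EnsembleResult, frontier
from .metrics import Trajectory

__all__ = ["write_trajectory", "write_ensemble", "write_analytical", "report"]

TRAJECTORY_COLUMNS = [
    "run_id", "seed", "g", "t", "population", "migrants", "attempted",
    "admitted", "mean_entry_prob", "B_c", "B_f", "CSI", "growth_rate",
]


def write_trajectory(tr: Trajectory, out_dir: Path, stem: str = "run") -> list[Path]:
    """One run: per-iteration CSV, final breach table CSV, summary JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = tr.to_frame()
    df["run_id"] = 0
    traj_path = out_dir / f"{stem}_trajectory.csv"
    df[TRAJECTORY_COLUMNS].to_csv(traj_path, index=False)
    breach_path = out_dir / f"{stem}_breach_table.csv"
    tr.breach_table().to_csv(breach_path, index=False)
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "params": tr.params.to_dict(),
                "final_B_f": tr.final_B_f,
                "first_breach_time": tr.first_breach_time,
                "T_tau": tr.mean_time_to_first_breach,
                "final_population": tr.records[-1].population,
            },
            indent=2,
            default=float,
        )
    )
    return [traj_path, breach_path, summary_path]


def write_ensemble(ens: EnsembleResult, out_dir: Path, stem: str) -> list[Path]:
    """One ensemble: tidy per-run CSV, per-iteration aggregate CSV, summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    tidy_path = out_dir / f"{stem}_trajectories.csv"
    ens.tidy[TRAJECTORY_COLUMNS].to_csv(tidy_path, index=False)
    paths.append(tidy_path)
    agg = ens.mean.melt(id_vars="t", var_name="metric", value_name="mean").merge(
        ens.sd.melt(id_vars="t", var_name="metric", value_name="sd"),
        on=["t", "metric"],
    )
    agg["g"] = ens.params.g
    agg["n"] = ens.n_runs
    agg_path = out_dir / f"{stem}_aggregates.csv"
    agg[["g", "t", "metric", "mean", "sd", "n"]].to_csv(agg_path, index=False)
    paths.append(agg_path)
    summary_path = out_dir / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(ens.summary(), indent=2, default=float))
    paths.append(summary_path)
    return paths


def write_analytical(
    params: AnalyticalParams, out_dir: Path, stem: str, t_max: float = 500.0
) -> list[Path]:
    """Cascade schedule and B(t) step function for one arrival rate x."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sched_path = out_dir / f"{stem}_schedule.csv"
    breach_schedule(params).to_frame().to_csv(sched_path, index=False)
    traj_path = out_dir / f"{stem}_trajectory.csv"
    breach_trajectory(params, t_max).to_csv(traj_path, index=False)
    return [sched_path, traj_path]


def report(
    ensembles: list[EnsembleResult],
    analytical: list[AnalyticalParams],
    out_dir: Path,
    plots: bool = False,
) -> dict:
    """Write every artifact for a set of results and return the manifest.

    Always writes ``manifest.json``; per-scenario CSVs and the frontier when
    results are present; optional overview figures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for ens in ensembles:
        stem = f"g{ens.params.g:g}".replace(".", "p")
        files += [str(p.name) for p in write_ensemble(ens, out_dir, stem)]
    if len(ensembles) >= 2:
        fr_path = out_dir / "frontier.csv"
        frontier(ensembles).to_csv(fr_path, index=False)
        files.append(fr_path.name)
    for ap in analytical:
        stem = f"x{ap.x:g}".replace(".", "p")
        files += [str(p.name) for p in write_analytical(ap, out_dir, stem)]
    if plots and ensembles:
        files += [p.name for p in _overview_plots(ensembles, out_dir)]
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "scenarios": [
            {
                "params": ens.params.to_dict(),
                "n_runs": ens.n_runs,
                "base_seed": ens.base_seed,
            }
            for ens in ensembles
        ],
        "analytical": [
            {"M": a.M, "N": a.N, "tau_r": a.tau_r, "tau_m": a.tau_m, "x": a.x}
            for a in analytical
        ],
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _overview_plots(ensembles: list[EnsembleResult], out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("growth_rate", "periodic growth rate"),
        ("B_c", "current breach fraction"),
        ("B_f", "ever-breached fraction"),
        ("CSI", "cell segregation indicator"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, (col, label) in zip(axes.ravel(), panels):
        for ens in ensembles:
            ax.plot(ens.mean["t"], ens.mean[col], label=f"g={ens.params.g:g}")
        ax.set_ylabel(label)
        ax.set_xlabel("iteration")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    path = Path(out_dir) / "overview.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]
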