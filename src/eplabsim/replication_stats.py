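"""Replication batches, output summaries, validation statistics and export.

A batch runs a scenario ``n_reps`` times, each replication seeded from a
documented split of the master seed (``SeedSequence([master_seed, r])``),
so batches are bit-reproducible and different scenarios can share common
random numbers by sharing the master seed.  Totals are summarized as mean
and sample SD over replications; the daily-discharge statistics pool every
observation day of every replication, matching how a single long record of
daily ward output would be summarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import engine
from .input_model import ModelConfig
from .scenarios import ScenarioSpec, resolve_config

__all__ = [
    "BatchSummary",
    "run_batch",
    "percent_difference",
    "mann_whitney_daily",
    "export_batch",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = (
    "scenario", "n_reps", "mean_total", "sd_total",
    "mean_daily", "sd_daily", "pct_diff_vs_base",
)


@dataclass
class BatchSummary:
    """Mean/SD of per-replication totals and pooled daily discharges."""

    scenario_name: str
    n_reps: int
    mean_total: float
    sd_total: float
    mean_daily: float
    sd_daily: float
    per_replication_totals: np.ndarray
    mean_daily_per_rep: np.ndarray = field(default=None, repr=False)
    percent_diff_vs_base: float | None = None

    def __post_init__(self) -> None:
        assert self.n_reps == len(self.per_replication_totals)


def _sd(values: np.ndarray) -> float:
    # sample SD; a single replication has no spread by convention
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def run_batch(
    config: ModelConfig,
    scenario: ScenarioSpec,
    n_reps: int,
    master_seed: int,
) -> BatchSummary:
    """Run ``n_reps`` replications of a scenario and summarize the outputs."""
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    compiled = engine.CompiledInputs(resolve_config(config, scenario))
    totals = np.empty(n_reps, dtype=np.int64)
    daily_all = []
    for r in range(n_reps):
        result = engine.run_replication(
            config,
            scenario,
            seed=np.random.SeedSequence([master_seed, r]),
            compiled=compiled,
        )
        totals[r] = result.total_tep_discharges
        daily_all.append(result.daily_discharges)
    daily = np.concatenate(daily_all)
    return BatchSummary(
        scenario_name=scenario.name,
        n_reps=n_reps,
        mean_total=float(totals.mean()),
        sd_total=_sd(totals),
        mean_daily=float(daily.mean()),
        sd_daily=_sd(daily),
        per_replication_totals=totals,
        mean_daily_per_rep=np.array([d.mean() for d in daily_all]),
    )


def percent_difference(test: BatchSummary, base: BatchSummary) -> float:
    """Throughput change of ``test`` relative to ``base``, in percent
    (one decimal, as reported)."""
    if base.mean_total == 0:
        raise ValueError("base scenario has zero mean total discharges")
    return round(100.0 * (test.mean_total - base.mean_total) / base.mean_total, 1)


def mann_whitney_daily(sim_daily, ref_daily) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two daily-discharge records.

    Uses the rank-sum statistic with tie correction (exact method for small
    tie-free samples, normal approximation otherwise).  Fully tied input --
    every value identical across both samples -- gives (n1*n2/2, 1.0) by
    convention.
    """
    x = np.asarray(sim_daily, dtype=float)
    y = np.asarray(ref_daily, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both daily-discharge vectors must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return x.size * y.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def export_batch(
    summary: BatchSummary,
    out_dir: str | Path,
    base: BatchSummary | None = None,
    plot: bool = False,
) -> dict[str, Path]:
    """Write a batch's summary row and per-replication totals as CSV.

    Returns the written paths keyed by kind (``summary``, ``totals`` and,
    with ``plot=True``, a histogram of per-replication totals).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slug = summary.scenario_name.replace("/", "-")
    pct = summary.percent_diff_vs_base
    if pct is None and base is not None:
        pct = percent_difference(summary, base)
    row = pd.DataFrame(
        [
            {
                "scenario": summary.scenario_name,
                "n_reps": summary.n_reps,
                "mean_total": summary.mean_total,
                "sd_total": summary.sd_total,
                "mean_daily": summary.mean_daily,
                "sd_daily": summary.sd_daily,
                "pct_diff_vs_base": pct,
            }
        ],
        columns=list(SUMMARY_COLUMNS),
    )
    paths = {
        "summary": out_dir / f"{slug}_summary.csv",
        "totals": out_dir / f"{slug}_replications.csv",
    }
    row.to_csv(paths["summary"], index=False)
    pd.DataFrame(
        {
            "replication": np.arange(summary.n_reps),
            "total_tep_discharges": summary.per_replication_totals,
        }
    ).to_csv(paths["totals"], index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(summary.per_replication_totals, bins=30, color="steelblue")
        ax.set_xlabel("total TEP discharges per replication")
        ax.set_ylabel("replications")
        ax.set_title(summary.scenario_name)
        paths["plot"] = out_dir / f"{slug}_hist.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)
    return paths
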