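"""Evaluation metrics and report tables for simulation results.

The headline metric is the time-to-target: the smallest campaign-end week at
which the population-mean meat consumption has fallen by at least the target
fraction relative to baseline.  Attainment is only recorded at campaign ends,
the cadence at which the external entity observes the network.  A run that
never attains the target returns the explicit :data:`NOT_REACHED` sentinel.

Also computed: scaled average and per-agent relative changes in meat
consumption, the adopters fraction (agents strictly below the target energy
ceiling; vegetarians always count), and a sex-stratified consumption/impact
report mirroring the structure of a baseline-vs-target summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import SubstituteShares, kcal_to_grams, opinion_to_consumption
from .dynamics import SimulationResult
from .impacts import METRICS, impacts_of, per_agent_impacts, relative_impact_change
from .population import FOOD_GROUPS
from .scenarios import Scenario

__all__ = [
    "NOT_REACHED",
    "target_ceiling",
    "avg_relative_change",
    "individual_relative_changes",
    "time_to_target",
    "adopters",
    "adopters_series",
    "MetricsReport",
    "build_report",
    "plot_trajectories",
]


class _NotReached:
    """Sentinel for a target not attained within the simulated horizon."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NOT_REACHED"

    def __bool__(self) -> bool:
        return False


NOT_REACHED = _NotReached()


def target_ceiling(
    baseline_mean_kcal: float, reduction: float, meat_kcal_per_g: float = 1.87
) -> tuple[float, float]:
    """Desired maximum mean meat consumption implied by a reduction target.

    Returns (kcal/d, g/d): the CCC-style percentage reduction applied to the
    baseline population-mean meat energy, with grams via the meat energy
    density.  E.g. a 35% reduction of a 202 kcal/d baseline gives a ceiling of
    about 131 kcal/d, i.e. about 70 g/d.
    """
    if baseline_mean_kcal <= 0 or not 0 <= reduction < 1:
        raise ValueError("need a positive baseline and a reduction in [0, 1)")
    kcal = (1.0 - reduction) * baseline_mean_kcal
    return kcal, kcal / meat_kcal_per_g


def avg_relative_change(mean_series: np.ndarray) -> np.ndarray:
    """Relative change of a population-mean series versus its baseline value."""
    mean_series = np.asarray(mean_series, dtype=float)
    if mean_series.size == 0 or mean_series[0] <= 0:
        raise ValueError("baseline mean must be positive")
    return (mean_series - mean_series[0]) / mean_series[0]


def individual_relative_changes(opinions: np.ndarray, E: np.ndarray) -> pd.DataFrame:
    """Per-agent relative meat-energy change series, excluding zero-baseline agents."""
    opinions = np.asarray(opinions, dtype=float)
    E = np.asarray(E, dtype=float)
    kcal = opinions * E[None, :]
    base = kcal[0]
    keep = base > 0
    rel = (kcal[:, keep] - base[keep][None, :]) / base[keep][None, :]
    cols = np.flatnonzero(keep)
    return pd.DataFrame(rel, columns=cols)


def time_to_target(result: SimulationResult, target: float | None = None):
    """Smallest campaign-end week with relative change <= -target.

    ``target`` defaults to the scenario's own target.  A zero target is
    satisfied at baseline (week 0).  Returns :data:`NOT_REACHED` when no
    campaign end attains the target within the horizon.
    """
    if target is None:
        target = result.scenario.target
    if target < 0:
        raise ValueError("target must be nonnegative")
    r = avg_relative_change(result.mean_meat_kcal)
    if target == 0:
        return 0
    for week in result.campaign_end_weeks:
        if r[week] <= -target:
            return int(week)
    return NOT_REACHED


def adopters(x: np.ndarray, E: np.ndarray, target_kcal: float) -> float:
    """Fraction of agents consuming strictly less meat energy than the ceiling."""
    if target_kcal <= 0:
        raise ValueError("target_kcal must be positive")
    x = np.asarray(x, dtype=float)
    E = np.asarray(E, dtype=float)
    return float(np.mean(x * E < target_kcal))


def adopters_series(result: SimulationResult, E: np.ndarray) -> np.ndarray:
    """Adopters fraction per recorded week (requires recorded opinions)."""
    if result.opinions is None:
        raise ValueError("opinions were not recorded for this run")
    kcal = result.opinions * np.asarray(E, dtype=float)[None, :]
    return (kcal < result.target_kcal).mean(axis=1)


@dataclass
class MetricsReport:
    """Summary of a simulation run against its target."""

    target: float
    time_to_target_weeks: object
    adopters_fraction_at_target: float | None
    consumption: pd.DataFrame
    group_changes: pd.DataFrame
    impact_changes: pd.Series | None
    avg_relative_change: np.ndarray
    summary: dict = field(default_factory=dict)

    def to_summary_frame(self) -> pd.DataFrame:
        rows = dict(self.summary)
        rows["target"] = self.target
        rows["time_to_target_weeks"] = (
            "not_reached"
            if self.time_to_target_weeks is NOT_REACHED
            else self.time_to_target_weeks
        )
        if self.adopters_fraction_at_target is not None:
            rows["adopters_fraction_at_target"] = self.adopters_fraction_at_target
        return pd.DataFrame({"key": list(rows), "value": [rows[k] for k in rows]})


def _stratified_consumption(grams: dict, roster: pd.DataFrame, label: str) -> pd.DataFrame:
    rows = []
    sex = roster["sex"].to_numpy()
    for group in FOOD_GROUPS:
        g = np.asarray(grams[group], dtype=float)
        for s in ("male", "female"):
            sel = sex == s
            rows.append(
                {
                    "when": label,
                    "group": group,
                    "sex": s,
                    "mean_g": float(g[sel].mean()),
                    "sd_g": float(g[sel].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def build_report(
    result: SimulationResult,
    roster: pd.DataFrame,
    shares: SubstituteShares,
    impact_table: pd.DataFrame | None = None,
    scenario: Scenario | None = None,
    density_table: dict | None = None,
) -> MetricsReport:
    """Assemble the evaluation report for one run.

    Sex-stratified consumption at baseline and at the time-to-target,
    population percent changes per group (kcal and grams, computed on
    totals), impact percent changes, and the adopters fraction at target.
    """
    scenario = scenario or result.scenario
    E = roster["E"].to_numpy(dtype=float)
    ttt = time_to_target(result, scenario.target)
    r = avg_relative_change(result.mean_meat_kcal)

    base_kcal = opinion_to_consumption(roster["x0"].to_numpy(), roster, shares)
    base_grams = kcal_to_grams(base_kcal, roster, density_table)
    consumption = [_stratified_consumption(base_grams, roster, "baseline")]

    group_changes = pd.DataFrame()
    impact_changes = None
    adopters_at_target = None
    if ttt is not NOT_REACHED and result.opinions is not None:
        x_t = result.opinion_at_week(ttt)
        kcal_t = opinion_to_consumption(x_t, roster, shares)
        grams_t = kcal_to_grams(kcal_t, roster, density_table)
        consumption.append(_stratified_consumption(grams_t, roster, f"week_{ttt}"))

        rows = []
        for group in FOOD_GROUPS:
            kb, kt = np.sum(base_kcal[group]), np.sum(kcal_t[group])
            gb, gt = np.sum(base_grams[group]), np.sum(grams_t[group])
            rows.append(
                {
                    "group": group,
                    "kcal_pct_change": relative_impact_change(kt, kb),
                    "grams_pct_change": relative_impact_change(gt, gb),
                }
            )
        group_changes = pd.DataFrame(rows).set_index("group")

        base_totals = impacts_of(base_grams, impact_table)
        target_totals = impacts_of(grams_t, impact_table)
        impact_changes = pd.Series(
            {m: relative_impact_change(target_totals[m], base_totals[m]) for m in METRICS}
        )
        adopters_at_target = adopters(x_t, E, result.target_kcal)

    summary = {
        "baseline_mean_meat_kcal": result.baseline_mean_meat_kcal,
        "target_kcal": result.target_kcal,
        "final_relative_change": float(r[-1]),
        "n_campaigns": result.n_campaigns,
    }
    return MetricsReport(
        target=scenario.target,
        time_to_target_weeks=ttt,
        adopters_fraction_at_target=adopters_at_target,
        consumption=pd.concat(consumption, ignore_index=True),
        group_changes=group_changes,
        impact_changes=impact_changes,
        avg_relative_change=r,
        summary=summary,
    )


def plot_trajectories(result: SimulationResult, E: np.ndarray, path=None, max_agents: int = 200):
    """Opinion and mean-consumption panels for a recorded run (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    weeks = result.weeks
    if result.opinions is not None:
        step = max(1, result.opinions.shape[1] // max_agents)
        axes[0].plot(weeks, result.opinions[:, ::step], color="0.8", lw=0.5)
    axes[0].plot(weeks, result.mean_opinion, color="k", lw=2, label="mean opinion")
    axes[0].set(xlabel="week", ylabel="meat opinion", ylim=(0, 1))
    axes[0].legend()
    axes[1].plot(weeks, result.mean_meat_kcal, color="k", lw=2)
    axes[1].axhline(result.target_kcal, ls="--", color="tab:red", label="target ceiling")
    axes[1].set(xlabel="week", ylabel="mean meat kcal/d")
    axes[1].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
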