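"""End-to-end orchestration: roster -> network -> campaigns -> report -> sweep.

A single master seed is expanded into independent substreams (population,
effort sampling, replicate index) via :class:`numpy.random.SeedSequence`, so
each stage is independently reproducible and the full pipeline is a pure
function of (config, seed).  Output files embed a hash of their configuration
for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .allocation import substitute_shares
from .dynamics import CampaignPropagator, SimulationResult, run_scenario
from .metrics import NOT_REACHED, MetricsReport, build_report, time_to_target
from .network import KernelParams, SocialNetwork, build_network
from .population import PopulationConfig, generate_population
from .scenarios import Scenario, build_gamma, with_overrides

__all__ = [
    "config_hash",
    "simulate",
    "sweep_time_to_target",
    "sweep_medians",
    "write_result",
]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(*configs) -> str:
    """Short stable hash of one or more dataclass/dict configurations."""
    payload = json.dumps([_jsonable(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def simulate(
    roster: pd.DataFrame,
    scenario: Scenario,
    kernel: KernelParams = KernelParams(),
    network: SocialNetwork | None = None,
    propagator: CampaignPropagator | None = None,
    substitution_mode: str = "baseline_flexible",
    impact_table: pd.DataFrame | None = None,
    density_table: dict | None = None,
    record_opinions: bool = True,
) -> tuple[SimulationResult, MetricsReport]:
    """Run one scenario end to end and build its metrics report."""
    if network is None:
        network = build_network(roster, kernel)
    result = run_scenario(
        roster, network, scenario, propagator=propagator, record_opinions=record_opinions
    )
    shares = substitute_shares(roster, mode=substitution_mode)
    report = build_report(
        result, roster, shares, impact_table=impact_table, density_table=density_table
    )
    return result, report


def sweep_time_to_target(
    roster: pd.DataFrame,
    network: SocialNetwork,
    base_scenario: Scenario,
    mu_values,
    modes=("trunc_normal",),
    replicates: int = 5,
    master_seed: int = 0,
    propagator: CampaignPropagator | None = None,
) -> pd.DataFrame:
    """Time-to-target over a (mode, mu, replicate) grid of influence draws.

    One row per cell; the not-reached sentinel is encoded as ``inf`` so that
    medians remain order-preserving.  Rows come out in deterministic grid
    order regardless of execution strategy.
    """
    lam = roster["lambda"].to_numpy(dtype=float)
    if propagator is None:
        propagator = CampaignPropagator(network.A, lam, dt=base_scenario.dt)
    root = np.random.SeedSequence(master_seed)
    mu_values = list(mu_values)
    modes = list(modes)
    children = root.spawn(len(modes) * len(mu_values) * replicates)
    rows = []
    idx = 0
    for mode in modes:
        for mu in mu_values:
            for rep in range(replicates):
                seed = int(children[idx].generate_state(1)[0] % (2**31))
                idx += 1
                scenario = with_overrides(base_scenario, mode=mode, mu=float(mu), seed=seed)
                gamma = build_gamma(scenario, roster, seed=seed)
                result = run_scenario(
                    roster,
                    network,
                    scenario,
                    gamma=gamma,
                    propagator=propagator,
                    record_opinions=False,
                )
                ttt = time_to_target(result)
                rows.append(
                    {
                        "mode": mode,
                        "mu": float(mu),
                        "replicate": rep,
                        "seed": seed,
                        "time_to_target_weeks": float("inf") if ttt is NOT_REACHED else float(ttt),
                    }
                )
    return pd.DataFrame(rows)


def sweep_medians(sweep: pd.DataFrame) -> pd.DataFrame:
    """Median time-to-target per (mode, mu) cell."""
    return (
        sweep.groupby(["mode", "mu"], sort=True)["time_to_target_weeks"]
        .median()
        .reset_index()
        .rename(columns={"time_to_target_weeks": "median_weeks"})
    )


def write_result(result: SimulationResult, path, extra_configs=(), opinions_path=None) -> None:
    """Write the weekly series as delimited text with a config-echo header.

    ``opinions_path`` additionally writes the full weeks x agents opinion
    matrix (one column per agent) when the run recorded it.
    """
    digest = config_hash(result.scenario, *extra_configs)
    frame = result.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {digest}\n")
        for key, value in asdict(result.scenario).items():
            fh.write(f"# scenario.{key}: {value}\n")
        frame.to_csv(fh, index=False)
    if opinions_path is not None:
        if result.opinions is None:
            raise ValueError("opinions were not recorded for this run")
        wide = pd.DataFrame(result.opinions, columns=range(result.opinions.shape[1]))
        wide.insert(0, "week", result.weeks)
        with open(opinions_path, "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash: {digest}\n")
            wide.to_csv(fh, index=False)
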