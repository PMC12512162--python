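"""Concatenated continuous-time Friedkin-Johnsen opinion dynamics.

Within a campaign, each agent's meat opinion x_i(t) in [0, 1] evolves as

    dx_i/dt = lambda_i * sum_j A_ij (x_j - x_i) + (1 - lambda_i) * (u_i - x_i)

where A is the row-normalized social-influence matrix, lambda_i the agent's
susceptibility to peers, and u_i the prejudice.  The first term is the social
(consensus-seeking) cost, the second the inertia cost anchoring the agent to
its prejudice; lambda = 0 is full stubbornness.  The box [0, 1]^n is forward
invariant because each rate is a convex pull towards points inside the box.

The external entity acts between campaigns: once the network is stationary it
refreshes prejudices as a trade-off between the agent's reference opinion and
the external opinion s_i,

    u_i = (1 - gamma_i) * x_ref_i + gamma_i * s_i,

with x_ref the initial opinion x(0) in campaign 1 and the prejudice carried
out of the previous campaign thereafter, so prejudices compound geometrically
towards s at per-campaign rate gamma (the concatenated construction).
Chaining the prejudices — rather than re-anchoring them at the previous
stationary opinions — keeps gamma = 0 agents anchored to their baseline
habits indefinitely (the no-influence network then simply sits at its FJ
equilibrium) and preserves opinion heterogeneity across campaigns; re-anchoring
at stationary opinions would instead let partially stubborn agents forget
their baselines and collapse the population onto the fully stubborn agents
even with no external influence at all.  The run stops when the population-mean
meat energy falls to (1 - target) of baseline — checked at campaign ends, the
cadence at which a policymaker would observe the network — or at the horizon.

Integration uses the classical fixed-step RK4 scheme with dt = 0.25 week.
Because the within-campaign dynamics is linear time-invariant, the RK4 step is
a fixed affine map, so one week of integration is precomputed as a dense
propagator pair (P_week, S_week); stepping a week is then a single mat-vec and
bitwise-equivalent to naive RK4 stepping up to float roundoff.  The propagator
depends only on (A, lambda, dt) and is reused across campaigns and scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SocialNetwork
from .scenarios import Scenario, build_gamma

__all__ = [
    "fj_rate",
    "fj_fixed_point",
    "compute_prejudice",
    "external_opinion",
    "CampaignPropagator",
    "run_campaign",
    "run_scenario",
    "SimulationResult",
]


def fj_rate(x: np.ndarray, A: np.ndarray, lam: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Instantaneous FJ rate dx/dt."""
    x = np.asarray(x, float)
    lam = np.asarray(lam, float)
    u = np.asarray(u, float)
    if not (x.shape == lam.shape == u.shape and A.shape == (x.size, x.size)):
        raise ValueError("dimension mismatch between x, lambda, u and A")
    return lam * (A @ x - x) + (1.0 - lam) * (u - x)


def fj_fixed_point(A: np.ndarray, lam: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Closed-form stationary opinions: solve (I - diag(lam) A) x = (I - diag(lam)) u.

    Requires the system matrix to be nonsingular (guaranteed whenever every
    agent has lambda < 1 or is connected to one that does).
    """
    lam = np.asarray(lam, float)
    n = lam.size
    B = np.eye(n) - lam[:, None] * A
    return np.linalg.solve(B, (1.0 - lam) * u)


def compute_prejudice(x_ref: np.ndarray, gamma: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Blend reference opinions with the external opinion: u = (1-g) x_ref + g s."""
    x_ref = np.asarray(x_ref, float)
    gamma = np.asarray(gamma, float)
    s = np.asarray(s, float)
    if not (x_ref.shape == gamma.shape == s.shape):
        raise ValueError("x_ref, gamma and s must have equal length")
    for name, v in (("x_ref", x_ref), ("gamma", gamma), ("s", s)):
        if (v < 0).any() or (v > 1).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    return (1.0 - gamma) * x_ref + gamma * s


def external_opinion(E: np.ndarray, target_kcal: float, mode: str = "per_agent_ceiling") -> np.ndarray:
    """External entity's opinion s_i per agent.

    ``per_agent_ceiling``: the opinion corresponding to consuming at most the
    population target ceiling, s_i = min(1, target_kcal / E_i).
    ``global_zero``: push towards zero meat (limit-case testing).
    """
    E = np.asarray(E, float)
    if (E <= 0).any():
        raise ValueError("all agents must have positive baseline energy")
    if mode == "per_agent_ceiling":
        if target_kcal <= 0:
            raise ValueError("target_kcal must be positive")
        return np.minimum(1.0, target_kcal / E)
    if mode == "global_zero":
        return np.zeros_like(E)
    raise ValueError(f"unknown external opinion mode {mode!r}")


class CampaignPropagator:
    """One-week affine RK4 propagator of the linear FJ dynamics.

    For dx/dt = M x + c with M = diag(lam) A - I and c = (I - diag(lam)) u,
    a single RK4 step of size h is x+ = P x + S c with
    P = sum_{k=0..4} (hM)^k / k!  and  S = sum_{k=0..3} h^{k+1} M^k / (k+1)!.
    One week is m = 1/dt such steps, collapsed into (P_week, S_week).
    """

    def __init__(self, A: np.ndarray, lam: np.ndarray, dt: float = 0.25):
        if dt <= 0:
            raise ValueError("dt must be positive")
        m = round(1.0 / dt)
        if m < 1 or abs(m * dt - 1.0) > 1e-9:
            raise ValueError("dt must divide 1 week evenly")
        lam = np.asarray(lam, float)
        n = lam.size
        if A.shape != (n, n):
            raise ValueError("A and lambda sizes disagree")
        self.lam = lam
        self.dt = dt
        M = lam[:, None] * A - np.eye(n)
        h = dt
        P = np.eye(n)
        S = np.zeros((n, n))
        hM_pow = np.eye(n)  # (hM)^k / k!
        for k in range(1, 5):
            S += hM_pow * (h / k)  # h^k M^(k-1) / k!
            hM_pow = hM_pow @ (h * M) / k
            P += hM_pow
        P_week = np.eye(n)
        S_week = np.zeros((n, n))
        for _ in range(m):
            S_week = P @ S_week + S
            P_week = P @ P_week
        self.P_week = P_week
        self.S_week = S_week

    def step_week(self, x: np.ndarray, c: np.ndarray) -> np.ndarray:
        return self.P_week @ x + self.S_week @ c


def run_campaign(
    x: np.ndarray,
    u: np.ndarray,
    propagator: CampaignPropagator,
    tol: float = 1e-4,
    max_weeks: int = 1560,
):
    """Integrate one campaign until weekly stationarity or the week budget.

    Returns ``(trajectory, converged)``: ``trajectory`` holds the weekly
    opinion vectors after each of the simulated weeks (shape weeks x n), and
    ``converged`` is False when the sup-norm weekly change never fell below
    ``tol`` within ``max_weeks`` (flagged, not fatal).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    c = (1.0 - propagator.lam) * u
    traj = []
    converged = False
    for _ in range(max_weeks):
        x_new = np.clip(propagator.step_week(x, c), 0.0, 1.0)
        traj.append(x_new)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            converged = True
            break
        x = x_new
    return np.array(traj), converged


@dataclass
class SimulationResult:
    """Weekly trajectories of a multi-campaign run.

    ``weeks`` runs 0..T; ``mean_meat_kcal`` and ``mean_opinion`` are aligned
    with it; ``campaign_of_week`` gives the campaign index (0 at baseline).
    ``opinions`` is the full weeks x n matrix when recorded.
    """

    weeks: np.ndarray
    mean_meat_kcal: np.ndarray
    mean_opinion: np.ndarray
    campaign_of_week: np.ndarray
    campaign_end_weeks: list
    baseline_mean_meat_kcal: float
    target_kcal: float
    reached: bool
    scenario: Scenario
    opinions: np.ndarray | None = None
    final_opinions: np.ndarray | None = None
    gamma: np.ndarray | None = None
    unconverged_campaigns: list = field(default_factory=list)

    @property
    def n_campaigns(self) -> int:
        return len(self.campaign_end_weeks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.weeks,
                "campaign": self.campaign_of_week,
                "mean_meat_kcal": self.mean_meat_kcal,
                "mean_opinion": self.mean_opinion,
            }
        )

    def opinion_at_week(self, week: int) -> np.ndarray:
        if self.opinions is None:
            raise ValueError("opinions were not recorded for this run")
        return self.opinions[int(week)]


def run_scenario(
    roster: pd.DataFrame,
    network: SocialNetwork,
    scenario: Scenario,
    gamma: np.ndarray | None = None,
    propagator: CampaignPropagator | None = None,
    record_opinions: bool = True,
) -> SimulationResult:
    """Run repeated influence campaigns until the meat target is met.

    Alternates prejudice refresh and campaign integration, stopping when the
    population-mean meat energy at a campaign end is at most
    ``(1 - target) * baseline mean`` or when ``scenario.max_weeks`` is
    exhausted.  Deterministic given (roster, network, scenario).  Passing a
    prebuilt ``propagator`` (which depends only on roster and network) avoids
    recomputing it across scenarios; ``gamma`` may be supplied to reuse a
    sampled effort vector.
    """
    scenario.validate()
    lam = roster["lambda"].to_numpy(dtype=float)
    E = roster["E"].to_numpy(dtype=float)
    x0 = roster["x0"].to_numpy(dtype=float)
    if gamma is None:
        gamma = build_gamma(scenario, roster)
    if propagator is None:
        propagator = CampaignPropagator(network.A, lam, dt=scenario.dt)

    baseline_mean = float(np.mean(x0 * E))
    target_kcal = (1.0 - scenario.target) * baseline_mean
    s = external_opinion(E, max(target_kcal, np.finfo(float).tiny), scenario.external_opinion_mode)

    states = [x0]
    campaign_idx = [0]
    campaign_end_weeks: list[int] = []
    unconverged: list[int] = []
    x = x0
    u_ref = x0  # prejudice chain: campaign 1 blends x(0), later ones the carried prejudice
    week = 0
    reached = baseline_mean <= target_kcal
    k = 0
    while not reached and week < scenario.max_weeks:
        k += 1
        u = compute_prejudice(u_ref, gamma, s)
        u_ref = u
        traj, converged = run_campaign(
            x, u, propagator, tol=scenario.tol, max_weeks=scenario.max_weeks - week
        )
        if traj.size == 0:
            break
        states.extend(traj)
        campaign_idx.extend([k] * len(traj))
        x = traj[-1]
        week += len(traj)
        campaign_end_weeks.append(week)
        if not converged:
            unconverged.append(k)
        if float(np.mean(x * E)) <= target_kcal:
            reached = True

    X = np.vstack(states)
    mean_meat = X @ E / len(E)
    return SimulationResult(
        weeks=np.arange(X.shape[0]),
        mean_meat_kcal=mean_meat,
        mean_opinion=X.mean(axis=1),
        campaign_of_week=np.array(campaign_idx),
        campaign_end_weeks=campaign_end_weeks,
        baseline_mean_meat_kcal=baseline_mean,
        target_kcal=target_kcal,
        reached=reached,
        scenario=scenario,
        opinions=X if record_opinions else None,
        final_opinions=x,
        gamma=gamma,
        unconverged_campaigns=unconverged,
    )
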