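"""External-influence scenarios: the effort vector gamma.

A virtual external entity (government / policymaker) is connected to every
agent and exerts an effort gamma_i in [0, gamma_bar] on agent i, where
gamma_bar is the maximum influence agents tolerate.  Four assignment modes
are supported:

* ``broadcast`` — equal effort gamma_i = gamma_bar (universal policy; the
  high- and low-influence settings use gamma_bar = 0.025 and 0.0125),
* ``uniform_random`` — gamma_i ~ U[0, gamma_bar],
* ``trunc_normal`` — gamma_i ~ N_[0, gamma_bar](mu, sigma),
* ``trunc_normal_sorted`` — the same truncated-normal sample, assigned by rank
  of baseline meat opinion (largest effort to the heaviest meat eaters under
  ``high_meat_first``, or the reverse).

Vegetarians are fully stubborn towards external influence as well: their
gamma is forced to zero after assignment.  Truncated-normal draws use the
inverse CDF on the truncated support, so sampling is exact and seedable even
for means far into a tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Scenario",
    "InvalidScenarioError",
    "assign_broadcast",
    "sample_uniform_gamma",
    "sample_truncnorm_gamma",
    "sort_gamma_by_baseline",
    "build_gamma",
    "load_scenario",
    "save_scenario",
]

MODES = ("broadcast", "uniform_random", "trunc_normal", "trunc_normal_sorted")
SORT_DIRECTIONS = ("high_meat_first", "low_meat_first")
EXTERNAL_OPINION_MODES = ("per_agent_ceiling", "global_zero")


class InvalidScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """One simulated policy setting.

    ``target`` is the desired fractional reduction of population-mean meat
    consumption (0.35 or 0.50 for the CCC goals); ``gamma_bar`` the maximum
    tolerated external effort; ``mu``/``sigma`` parametrize the truncated
    normal in the heterogeneous modes.  ``max_weeks`` caps the simulated
    horizon (default 1560 weeks = 30 y).
    """

    mode: str = "broadcast"
    gamma_bar: float = 0.025
    mu: float | None = None
    sigma: float = 0.2 * 0.025
    sort_direction: str = "high_meat_first"
    target: float = 0.35
    external_opinion_mode: str = "per_agent_ceiling"
    seed: int = 0
    max_weeks: int = 1560
    replicates: int = 1
    tol: float = 1e-4
    dt: float = 0.25

    def validate(self) -> None:
        if self.mode not in MODES:
            raise InvalidScenarioError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.gamma_bar <= 1.0:
            raise InvalidScenarioError("gamma_bar must lie in (0, 1]")
        if not 0.0 < self.target < 1.0:
            raise InvalidScenarioError("target must lie in (0, 1)")
        if self.mode in ("trunc_normal", "trunc_normal_sorted"):
            if self.mu is None or not 0.0 <= self.mu <= self.gamma_bar:
                raise InvalidScenarioError("mu must lie in [0, gamma_bar]")
            if self.sigma <= 0:
                raise InvalidScenarioError("sigma must be positive")
        if self.sort_direction not in SORT_DIRECTIONS:
            raise InvalidScenarioError(f"unknown sort_direction {self.sort_direction!r}")
        if self.external_opinion_mode not in EXTERNAL_OPINION_MODES:
            raise InvalidScenarioError(
                f"unknown external_opinion_mode {self.external_opinion_mode!r}"
            )
        if self.max_weeks < 1 or self.replicates < 1:
            raise InvalidScenarioError("max_weeks and replicates must be >= 1")
        if self.tol <= 0 or self.dt <= 0:
            raise InvalidScenarioError("tol and dt must be positive")


def assign_broadcast(n: int, gamma_bar: float) -> np.ndarray:
    """Equal effort for every agent: gamma_i = gamma_bar."""
    if n < 1:
        raise InvalidScenarioError("n must be >= 1")
    if not 0.0 < gamma_bar <= 1.0:
        raise InvalidScenarioError("gamma_bar must lie in (0, 1]")
    return np.full(n, gamma_bar, dtype=float)


def sample_uniform_gamma(n: int, lo: float, hi: float, seed) -> np.ndarray:
    """i.i.d. uniform efforts on [lo, hi], reproducible by seed."""
    if not 0.0 <= lo < hi:
        raise InvalidScenarioError("need 0 <= lo < hi")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n)


def sample_truncnorm_gamma(
    n: int, mu: float, sigma: float, lo: float, hi: float, seed
) -> np.ndarray:
    """Truncated-normal efforts via inverse CDF on the truncated support."""
    if not 0.0 <= lo < hi:
        raise InvalidScenarioError("need 0 <= lo < hi")
    if sigma <= 0:
        raise InvalidScenarioError("sigma must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    draws = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    return np.clip(draws, lo, hi)


def sort_gamma_by_baseline(
    gamma: np.ndarray, x0: np.ndarray, direction: str, ids: np.ndarray | None = None
) -> np.ndarray:
    """Assign sampled efforts by rank of baseline meat opinion.

    Under ``high_meat_first`` the agent with the k-th largest x0 receives the
    k-th largest gamma; ``low_meat_first`` reverses the pairing.  Ties in x0
    are broken by ascending agent id.  The multiset of efforts is preserved.
    """
    gamma = np.asarray(gamma, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if gamma.shape != x0.shape:
        raise InvalidScenarioError("gamma and x0 must have equal length")
    if direction not in SORT_DIRECTIONS:
        raise InvalidScenarioError(f"unknown sort_direction {direction!r}")
    if ids is None:
        ids = np.arange(x0.size)
    key = -x0 if direction == "high_meat_first" else x0
    order = np.lexsort((np.asarray(ids), key))  # primary key, ties by id
    out = np.empty_like(gamma)
    out[order] = np.sort(gamma)[::-1]
    return out


def build_gamma(scenario: Scenario, roster: pd.DataFrame, seed=None) -> np.ndarray:
    """Construct the effort vector for a roster under a scenario.

    Vegetarians' efforts are forced to zero (fully stubborn to external
    influence); all entries lie in [0, gamma_bar].
    """
    scenario.validate()
    n = len(roster)
    seed = scenario.seed if seed is None else seed
    if scenario.mode == "broadcast":
        gamma = assign_broadcast(n, scenario.gamma_bar)
    elif scenario.mode == "uniform_random":
        gamma = sample_uniform_gamma(n, 0.0, scenario.gamma_bar, seed)
    else:
        gamma = sample_truncnorm_gamma(
            n, scenario.mu, scenario.sigma, 0.0, scenario.gamma_bar, seed
        )
        if scenario.mode == "trunc_normal_sorted":
            gamma = sort_gamma_by_baseline(
                gamma,
                roster["x0"].to_numpy(),
                scenario.sort_direction,
                ids=roster["id"].to_numpy(),
            )
    gamma = gamma.copy()
    gamma[(roster["diet_class"] == "vegetarian").to_numpy()] = 0.0
    return np.clip(gamma, 0.0, scenario.gamma_bar)


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(scenario), fh, sort_keys=False)


def load_scenario(path, **overrides) -> Scenario:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(Scenario.__dataclass_fields__)
    if unknown:
        raise InvalidScenarioError(f"unknown scenario keys {sorted(unknown)}")
    data.update(overrides)
    scenario = Scenario(**data)
    scenario.validate()
    return scenario


def with_overrides(scenario: Scenario, **kwargs) -> Scenario:
    return replace(scenario, **kwargs)
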