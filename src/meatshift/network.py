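"""Weighted undirected social network from age/SES similarity.

Peers who are close in age and socioeconomic status influence each other more
strongly.  The edge weight between distinct agents i and j is a separable
exponential kernel on ordinal attribute distances,

    w_ij = exp(-alpha * |a_i - a_j| - beta * |s_i - s_j|),

where a is the age-bin index (0..4) and s the SES rank (0..2).  The kernel is
symmetric, bounded in (0, 1], equals 1 at zero distance, and is strictly
decreasing in each distance; with positive decay rates the graph is complete
and therefore connected.  The dynamics consume the row-normalized influence
matrix A (rows sum to 1 for agents with at least one neighbour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import AGE_GROUPS, SES_LEVELS

__all__ = ["KernelParams", "SocialNetwork", "similarity_weight", "build_network"]

_AGE_INDEX = {a: i for i, a in enumerate(AGE_GROUPS)}
_SES_INDEX = {s: i for i, s in enumerate(SES_LEVELS)}


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class KernelParams:
    """Decay rates of the similarity kernel (per ordinal bin)."""

    alpha: float = 1.0  # age
    beta: float = 1.0  # SES

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise NetworkError("kernel decay rates must be strictly positive")


@dataclass
class SocialNetwork:
    """Symmetric nonnegative weights W (zero diagonal) and row-normalized A."""

    W: np.ndarray
    A: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def to_edge_list(self) -> pd.DataFrame:
        """Upper-triangle edges as an ``i,j,weight`` frame for inspection."""
        i, j = np.triu_indices(self.n, k=1)
        return pd.DataFrame({"i": i, "j": j, "weight": self.W[i, j]})

    def to_networkx(self):
        import networkx as nx

        return nx.from_numpy_array(self.W)


def _attr_indices(agent):
    """Accept an Agent-like row (Series, namedtuple, dict) or (age, ses)."""
    if isinstance(agent, dict):
        age, ses = agent["age_group"], agent["ses"]
    else:
        age, ses = agent.age_group, agent.ses
    return _AGE_INDEX[age], _SES_INDEX[ses]


def similarity_weight(agent_i, agent_j, params: KernelParams = KernelParams()) -> float:
    """Kernel weight between two distinct agents; symmetric in its arguments."""
    params.validate()
    id_i = getattr(agent_i, "id", None) if not isinstance(agent_i, dict) else agent_i.get("id")
    id_j = getattr(agent_j, "id", None) if not isinstance(agent_j, dict) else agent_j.get("id")
    if id_i is not None and id_i == id_j:
        raise NetworkError("self-edges are not defined")
    ai, si = _attr_indices(agent_i)
    aj, sj = _attr_indices(agent_j)
    return float(np.exp(-params.alpha * abs(ai - aj) - params.beta * abs(si - sj)))


def build_network(roster: pd.DataFrame, params: KernelParams = KernelParams()) -> SocialNetwork:
    """Build the dense complete similarity graph over a roster (n >= 2)."""
    params.validate()
    n = len(roster)
    if n < 2:
        raise NetworkError("a social network needs at least 2 agents")
    age = roster["age_group"].map(_AGE_INDEX).to_numpy()
    ses = roster["ses"].map(_SES_INDEX).to_numpy()
    if np.isnan(age.astype(float)).any() or np.isnan(ses.astype(float)).any():
        raise NetworkError("roster contains unknown age/SES labels")
    d_age = np.abs(age[:, None] - age[None, :])
    d_ses = np.abs(ses[:, None] - ses[None, :])
    W = np.exp(-params.alpha * d_age - params.beta * d_ses)
    np.fill_diagonal(W, 0.0)
    degree = W.sum(axis=1)
    A = np.divide(W, degree[:, None], out=np.zeros_like(W), where=degree[:, None] > 0)
    return SocialNetwork(W=W, A=A)
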