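"""Map opinion trajectories to food-group consumption under substitution rules.

An agent's opinion x_i is its desired share of meat energy within the
four-group basket (meat, meat alternatives, pulses, vegetables), so meat
energy is x_i * E_i.  Energy freed by a meat reduction, (x0_i - x_i) * E_i,
is reallocated to the three substitute groups in fixed per-agent shares, so
the basket energy E_i is conserved exactly at every time point.

Two share rules are provided.  ``baseline_strict`` allocates proportionally to
the agent's baseline substitute energy (agents consuming only meat at baseline
send all freed energy to vegetables).  ``baseline_flexible`` treats agents who
reported no meat alternatives and no pulses at baseline as still able to adopt
some: their shares default to the population-mean substitute composition among
agents who did report substitutes, acknowledging that a short diet diary can
miss foods eaten at weekly or monthly cadence.  The two modes agree exactly
for agents with positive baseline alternatives-plus-pulses.

Opinion increases (meat gain) are clamped at baseline and flagged; the
modelled campaigns only push meat downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import DEFAULT_ENERGY_DENSITY, FOOD_GROUPS

__all__ = [
    "SubstituteShares",
    "substitute_shares",
    "opinion_to_consumption",
    "kcal_to_grams",
    "read_density_table",
    "write_density_table",
]

SUBSTITUTE_GROUPS = ("alt", "pulses", "veg")
MODES = ("baseline_flexible", "baseline_strict")


@dataclass
class SubstituteShares:
    """Per-agent allocation of freed meat energy across substitutes.

    ``shares`` has shape (n, 3), columns ordered (alt, pulses, veg); each row
    is nonnegative and sums to 1.
    """

    shares: np.ndarray
    mode: str

    def validate(self) -> None:
        if (self.shares < 0).any() or not np.allclose(self.shares.sum(axis=1), 1.0):
            raise ValueError("shares must be nonnegative and sum to 1 per agent")


def substitute_shares(
    roster: pd.DataFrame,
    mode: str = "baseline_flexible",
    default_shares: tuple | None = None,
) -> SubstituteShares:
    """Compute each agent's substitute shares from baseline energy.

    ``default_shares`` overrides the flexible-mode blend for zero-substitute
    agents; by default it is the population-mean composition of substitute
    energy among agents with positive alternatives-plus-pulses.
    """
    if mode not in MODES:
        raise ValueError(f"unknown substitution mode {mode!r}")
    sub_kcal = roster[[f"{g}_kcal" for g in SUBSTITUTE_GROUPS]].to_numpy(dtype=float)
    totals = sub_kcal.sum(axis=1)
    shares = np.zeros_like(sub_kcal)
    positive = totals > 0
    shares[positive] = sub_kcal[positive] / totals[positive, None]
    shares[~positive] = [0.0, 0.0, 1.0]  # carnivores: all freed energy to vegetables

    if mode == "baseline_flexible":
        zero_sub = (sub_kcal[:, 0] == 0) & (sub_kcal[:, 1] == 0)
        if default_shares is None:
            reporters = ~zero_sub
            if reporters.any():
                pooled = sub_kcal[reporters].sum(axis=0)
                default = pooled / pooled.sum()
            else:
                default = np.array([0.0, 0.0, 1.0])
        else:
            default = np.asarray(default_shares, dtype=float)
            if default.shape != (3,) or (default < 0).any() or not np.isclose(default.sum(), 1.0):
                raise ValueError("default_shares must be 3 nonnegative values summing to 1")
        shares[zero_sub] = default
    result = SubstituteShares(shares=shares, mode=mode)
    result.validate()
    return result


def opinion_to_consumption(
    x: np.ndarray, roster: pd.DataFrame, shares: SubstituteShares
) -> dict:
    """Energy per food group for opinions ``x`` (shape (n,) or (T, n)).

    Returns a dict group -> kcal array of the same leading shape, plus a
    ``"clamped"`` boolean mask flagging entries where an opinion increase was
    clamped at baseline.  The four groups sum exactly to E per agent.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    E = roster["E"].to_numpy(dtype=float)
    x0 = roster["x0"].to_numpy(dtype=float)
    if x.shape[1] != E.size:
        raise ValueError("opinion matrix width must equal roster size")
    if (x < 0).any() or (x > 1).any():
        raise ValueError("opinions must lie in [0, 1]")

    clamped = x > x0[None, :]
    x_eff = np.minimum(x, x0[None, :])
    freed = (x0[None, :] - x_eff) * E[None, :]
    out = {"meat": x_eff * E[None, :]}
    for k, group in enumerate(SUBSTITUTE_GROUPS):
        base = roster[f"{group}_kcal"].to_numpy(dtype=float)
        out[group] = base[None, :] + freed * shares.shares[:, k][None, :]
    out["clamped"] = clamped
    if x.shape[0] == 1:
        out = {k: v[0] for k, v in out.items()}
    return out


def kcal_to_grams(
    kcal: dict, roster: pd.DataFrame, density_table: dict | None = None
) -> dict:
    """Convert per-group energy to grams via per-agent baseline densities.

    Each agent's own baseline kcal-per-gram is used for groups it consumed at
    baseline; groups with zero baseline grams fall back to the population
    density table (kcal per gram, default :data:`DEFAULT_ENERGY_DENSITY`).
    """
    table = dict(DEFAULT_ENERGY_DENSITY if density_table is None else density_table)
    for group in FOOD_GROUPS:
        if group not in table:
            raise ValueError(f"density table is missing group {group!r}")
        if table[group] <= 0:
            raise ValueError(f"density for {group!r} must be positive")
    grams = {}
    for group in FOOD_GROUPS:
        base_g = roster[f"{group}_g"].to_numpy(dtype=float)
        base_kcal = roster[f"{group}_kcal"].to_numpy(dtype=float)
        density = np.where(base_g > 0, np.divide(base_kcal, base_g, out=np.full_like(base_g, table[group]), where=base_g > 0), table[group])
        density = np.where(density > 0, density, table[group])
        grams[group] = np.asarray(kcal[group], dtype=float) / density
    return grams


def consumption_series_frame(
    opinions: np.ndarray,
    weeks: np.ndarray,
    roster: pd.DataFrame,
    shares: SubstituteShares,
    density_table: dict | None = None,
) -> pd.DataFrame:
    """Long-format consumption time series: week, agent_id, group, kcal, grams."""
    kcal = opinion_to_consumption(opinions, roster, shares)
    grams = kcal_to_grams(kcal, roster, density_table)
    ids = roster["id"].to_numpy()
    frames = []
    for group in FOOD_GROUPS:
        k = np.atleast_2d(kcal[group])
        g = np.atleast_2d(grams[group])
        frames.append(
            pd.DataFrame(
                {
                    "week": np.repeat(np.asarray(weeks), len(ids)),
                    "agent_id": np.tile(ids, k.shape[0]),
                    "group": group,
                    "kcal": k.ravel(),
                    "grams": g.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["week", "agent_id", "group"], kind="stable", ignore_index=True
    )


def read_density_table(path) -> dict:
    df = pd.read_csv(path)
    if not {"group", "kcal_per_gram"} <= set(df.columns):
        raise ValueError("density table needs columns group,kcal_per_gram")
    table = dict(zip(df["group"], df["kcal_per_gram"].astype(float)))
    missing = set(FOOD_GROUPS) - set(table)
    if missing:
        raise ValueError(f"density table is missing groups {sorted(missing)}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("densities must be positive")
    return table


def write_density_table(table: dict, path) -> None:
    pd.DataFrame(
        {"group": list(FOOD_GROUPS), "kcal_per_gram": [table[g] for g in FOOD_GROUPS]}
    ).to_csv(path, index=False)
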