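"""Environmental footprint accounting for the four food groups.

Consumption in grams is converted to four metrics — greenhouse gas emissions
(kg CO2-eq), land use (m^2), blue-water use (L) and scarcity-weighted water
(L) — via a per-100 g impact-factor table, one row per food group:

    metric_m = sum_g grams_g / 100 * factor_{g,m}

Impacts are exactly linear in consumption.  Population-level relative changes
are computed on population totals, not means of per-agent ratios.

The shipped default table is SYNTHETIC: literature-plausible per-100 g factors
for UK retail meat (red/processed plus poultry), meat alternatives, pulses and
non-starchy vegetables, chosen so baseline per-capita impacts of a typical
adult diary fall in the right range and so the meat footprint dominates per
gram on every metric (most strongly for greenhouse gases and land, least for
blue water, where vegetables and pulses also carry sizeable irrigation
demand).  Substantive analyses should supply a table derived from a
life-cycle-assessment database.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population import FOOD_GROUPS

__all__ = [
    "METRICS",
    "DEFAULT_IMPACT_TABLE",
    "impacts_of",
    "per_agent_impacts",
    "relative_impact_change",
    "read_impact_table",
    "write_impact_table",
]

METRICS = (
    "co2_kg_per_100g",
    "land_m2_per_100g",
    "water_L_per_100g",
    "swater_L_per_100g",
)


def _default_table() -> pd.DataFrame:
    data = {
        #            co2    land    water  scarcity-weighted water
        "meat":   (2.20, 4.50, 123.0, 3645.0),
        "alt":    (0.35, 0.80,  30.0,  400.0),
        "pulses": (0.25, 1.20,  18.0, 1059.0),
        "veg":    (0.20, 0.30,  26.0,  161.0),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(METRICS)).rename_axis("group")


#: Synthetic default factors (see module docstring); per 100 g of product.
DEFAULT_IMPACT_TABLE = _default_table()


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing_groups = set(FOOD_GROUPS) - set(table.index)
    if missing_groups:
        raise ValueError(f"impact table is missing groups {sorted(missing_groups)}")
    missing_metrics = set(METRICS) - set(table.columns)
    if missing_metrics:
        raise ValueError(f"impact table is missing metrics {sorted(missing_metrics)}")
    table = table.loc[list(FOOD_GROUPS), list(METRICS)].astype(float)
    if (table.to_numpy() < 0).any():
        raise ValueError("impact factors must be nonnegative")
    return table


def impacts_of(grams: dict, table: pd.DataFrame | None = None) -> pd.Series:
    """Total impacts of a consumption vector (grams per group, scalars or arrays).

    Array-valued groups are summed over agents/time first, so the result is
    the population total for each metric.
    """
    table = _validate_table(DEFAULT_IMPACT_TABLE if table is None else table)
    totals = {}
    for metric in METRICS:
        acc = 0.0
        for group in FOOD_GROUPS:
            g = np.asarray(grams[group], dtype=float)
            if (g < 0).any():
                raise ValueError(f"negative grams for group {group!r}")
            acc += g.sum() / 100.0 * table.loc[group, metric]
        totals[metric] = float(acc)
    return pd.Series(totals)


def per_agent_impacts(grams: dict, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-agent impacts (rows follow the grams arrays) for stratified reports."""
    table = _validate_table(DEFAULT_IMPACT_TABLE if table is None else table)
    out = {}
    for metric in METRICS:
        acc = None
        for group in FOOD_GROUPS:
            contrib = np.asarray(grams[group], dtype=float) / 100.0 * table.loc[group, metric]
            acc = contrib if acc is None else acc + contrib
        out[metric] = acc
    return pd.DataFrame(out)


def relative_impact_change(value, baseline) -> float:
    """Percent change 100 * (value - baseline) / baseline; baseline must be > 0."""
    value = np.asarray(value, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if (baseline <= 0).any():
        raise ValueError("relative change is undefined for a nonpositive baseline")
    out = 100.0 * (value - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def read_impact_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "group" not in df.columns:
        raise ValueError("impact table needs a 'group' column")
    return _validate_table(df.set_index("group"))


def write_impact_table(table: pd.DataFrame, path) -> None:
    _validate_table(table).rename_axis("group").reset_index().to_csv(path, index=False)
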