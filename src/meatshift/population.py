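"""Synthetic consumer rosters emulating the NDNS 2019 adult sample.

The simulator operates on a roster of agents, each carrying sociodemographic
attributes (sex, age group, socioeconomic status), baseline daily consumption
of the four modelled food groups (meat, meat alternatives, pulses, vegetables)
in grams and kilocalories, and the derived opinion-dynamics quantities:

* ``E`` — total baseline energy from the four groups (kcal/d),
* ``x0`` — the initial meat opinion, the fraction of that energy coming from
  meat, in [0, 1],
* ``diet_class`` — vegetarian (x0 = 0), carnivore (x0 = 1) or omnivore,
* ``lambda`` — susceptibility to social influence (0 for vegetarians and
  carnivores, who are fully stubborn towards peers).

Rosters are plain :class:`pandas.DataFrame` objects with one row per agent and
a documented delimited-text serialisation, so externally supplied survey
extracts can be used in place of synthetic ones.

The generator draws attributes independently from configured marginals and
intakes from sex-stratified zero-inflated gamma distributions moment-matched
to configured marginal means/SDs.  Diet classes (vegetarian / carnivore /
"zero-substitute" meat-and-vegetables-only omnivores) are drawn first and
impose the structural zeros; the positive parts are then moment-matched so the
marginal targets are met in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_GROUPS",
    "AGE_GROUPS",
    "SES_LEVELS",
    "SEXES",
    "ROSTER_COLUMNS",
    "DEFAULT_ENERGY_DENSITY",
    "IntakeParams",
    "PopulationConfig",
    "InvalidConfigError",
    "RosterValidationError",
    "classify_agent",
    "generate_population",
    "derive_opinion_columns",
    "read_roster",
    "write_roster",
]

FOOD_GROUPS = ("meat", "alt", "pulses", "veg")
AGE_GROUPS = ("19-29", "30-39", "40-55", "56-64", "65-85")
SES_LEVELS = ("low", "medium", "high")
SEXES = ("male", "female")

GRAM_COLUMNS = tuple(f"{g}_g" for g in FOOD_GROUPS)
KCAL_COLUMNS = tuple(f"{g}_kcal" for g in FOOD_GROUPS)
ROSTER_COLUMNS = ("id", "sex", "age_group", "ses") + GRAM_COLUMNS + KCAL_COLUMNS

#: Default energy densities (kcal per gram).  The meat density 1.87 kcal/g is
#: the value implied by the CCC target ceilings quoted in kcal and grams
#: (131 kcal = 70 g, 101 kcal = 54 g); the others are typical as-consumed
#: densities for cooked pulses, meat alternatives and non-starchy vegetables.
DEFAULT_ENERGY_DENSITY = {"meat": 1.87, "alt": 1.50, "pulses": 1.10, "veg": 0.35}


class InvalidConfigError(ValueError):
    """Raised when a population configuration cannot produce a valid roster."""


class RosterValidationError(ValueError):
    """Raised when a roster file violates the documented contract."""


@dataclass(frozen=True)
class IntakeParams:
    """Marginal (zero-inclusive) mean and SD of daily intake in grams."""

    mean: float
    sd: float


def _default_intakes() -> dict:
    # Sex-stratified marginal means/SDs in g/d for the four food groups.
    return {
        ("male", "meat"): IntakeParams(129.9, 84.5),
        ("female", "meat"): IntakeParams(91.6, 64.9),
        ("male", "alt"): IntakeParams(2.6, 12.3),
        ("female", "alt"): IntakeParams(2.7, 13.6),
        ("male", "pulses"): IntakeParams(41.7, 51.5),
        ("female", "pulses"): IntakeParams(33.0, 39.3),
        ("male", "veg"): IntakeParams(135.6, 110.5),
        ("female", "veg"): IntakeParams(143.9, 113.7),
    }


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the synthetic-roster generator.

    Defaults emulate the NDNS 2019 adult extract used as the simulator's
    baseline population: n = 1841 agents, 129 vegetarians, 31 carnivores and
    436 agents consuming no meat alternatives and no pulses at baseline
    ("zero-substitute" agents, a superset of the carnivores).
    """

    n: int = 1841
    sex_props: dict = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    age_props: dict = field(
        default_factory=lambda: {
            "19-29": 0.18,
            "30-39": 0.18,
            "40-55": 0.27,
            "56-64": 0.15,
            "65-85": 0.22,
        }
    )
    ses_props: dict = field(
        default_factory=lambda: {"low": 0.30, "medium": 0.40, "high": 0.30}
    )
    vegetarian_rate: float = 129 / 1841
    carnivore_rate: float = 31 / 1841
    zero_substitute_rate: float = 436 / 1841
    intakes: dict = field(default_factory=_default_intakes)
    #: probability that an *eligible* agent nevertheless consumes none of the
    #: group (within-class zero inflation)
    zero_inflation: dict = field(
        default_factory=lambda: {"alt": 0.90, "pulses": 0.30, "veg": 0.05}
    )
    energy_density: dict = field(default_factory=lambda: dict(DEFAULT_ENERGY_DENSITY))
    lambda_omnivore: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise InvalidConfigError("n must be >= 1")
        for name, props, levels in (
            ("sex_props", self.sex_props, SEXES),
            ("age_props", self.age_props, AGE_GROUPS),
            ("ses_props", self.ses_props, SES_LEVELS),
        ):
            if set(props) != set(levels):
                raise InvalidConfigError(f"{name} must have keys {levels}")
            vals = np.array([props[k] for k in levels], dtype=float)
            if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise InvalidConfigError(f"{name} must be nonnegative and sum to 1")
        for rate in (self.vegetarian_rate, self.carnivore_rate, self.zero_substitute_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidConfigError("class rates must lie in [0, 1]")
        if self.vegetarian_rate + self.carnivore_rate > 1.0:
            raise InvalidConfigError("vegetarian_rate + carnivore_rate must be <= 1")
        if self.zero_substitute_rate < self.carnivore_rate:
            raise InvalidConfigError(
                "zero_substitute_rate includes carnivores and cannot be smaller "
                "than carnivore_rate"
            )
        for key, p in self.zero_inflation.items():
            if not 0.0 <= p < 1.0:
                raise InvalidConfigError(f"zero_inflation[{key}] must lie in [0, 1)")
        for (sex, group), params in self.intakes.items():
            if params.mean <= 0 or params.sd <= 0:
                raise InvalidConfigError(
                    f"intake mean/sd for ({sex}, {group}) must be positive"
                )
        for group, d in self.energy_density.items():
            if d <= 0:
                raise InvalidConfigError(f"energy density for {group} must be positive")
        if not 0.0 <= self.lambda_omnivore <= 1.0:
            raise InvalidConfigError("lambda_omnivore must lie in [0, 1]")


def classify_agent(kcal_by_group) -> str:
    """Classify an agent from its baseline energy per food group.

    Vegetarian iff meat energy is zero, carnivore iff *all* energy comes from
    meat, omnivore otherwise.  ``kcal_by_group`` is a mapping or sequence
    ordered (meat, alternatives, pulses, vegetables).
    """
    if isinstance(kcal_by_group, dict):
        vals = np.array([kcal_by_group[g] for g in FOOD_GROUPS], dtype=float)
    else:
        vals = np.asarray(kcal_by_group, dtype=float)
    if vals.shape != (len(FOOD_GROUPS),):
        raise ValueError("expected one energy value per food group")
    if (vals < 0).any():
        raise ValueError("energies must be nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("degenerate agent: total baseline energy is zero")
    meat = vals[0]
    if meat == 0:
        return "vegetarian"
    if meat == total:
        return "carnivore"
    return "omnivore"


def _positive_gamma_params(mean: float, sd: float, p_pos: float):
    """Moment-match the positive part of a zero-inflated gamma.

    Given the marginal mean/SD (zeros included) and the positivity probability,
    return (shape, scale) for the positive draws so the marginal moments are
    matched; falls back to unit coefficient of variation when the implied
    positive-part variance is not attainable.
    """
    if p_pos <= 0:
        return None
    mu_pos = mean / p_pos
    var_pos = (sd**2 + mean**2) / p_pos - mu_pos**2
    if var_pos <= 0:
        var_pos = mu_pos**2  # CV = 1 fallback
    shape = mu_pos**2 / var_pos
    scale = var_pos / mu_pos
    return shape, scale


def _class_probabilities(cfg: PopulationConfig):
    vr, cr = cfg.vegetarian_rate, cfg.carnivore_rate
    z_om = max(cfg.zero_substitute_rate - cr, 0.0)  # meat+veg-only omnivores
    reg = 1.0 - vr - cr - z_om
    if reg < 0:
        raise InvalidConfigError("class rates exceed 1 in total")
    return np.array([vr, cr, z_om, reg])


def _positivity_probabilities(cfg: PopulationConfig):
    """Marginal P(group intake > 0) implied by classes and zero inflation."""
    vr, cr, z_om, reg = _class_probabilities(cfg)
    q_alt = 1.0 - cfg.zero_inflation["alt"]
    q_pul = 1.0 - cfg.zero_inflation["pulses"]
    q_veg = 1.0 - cfg.zero_inflation["veg"]
    # regular omnivores are conditioned on (alt > 0) OR (pulses > 0)
    p_or = 1.0 - (1.0 - q_alt) * (1.0 - q_pul)
    p_alt_reg = q_alt / p_or if p_or > 0 else 0.0
    p_pul_reg = q_pul / p_or if p_or > 0 else 0.0
    return {
        "meat": 1.0 - vr,
        "alt": reg * p_alt_reg + vr * q_alt,
        "pulses": reg * p_pul_reg + vr * q_pul,
        "veg": z_om + (vr + reg) * q_veg,
    }


def _draw_positive_masks(cfg: PopulationConfig, classes: np.ndarray, rng) -> dict:
    """Per-group boolean masks of agents with positive intake."""
    n = classes.size
    q_alt = 1.0 - cfg.zero_inflation["alt"]
    q_pul = 1.0 - cfg.zero_inflation["pulses"]
    q_veg = 1.0 - cfg.zero_inflation["veg"]

    is_veg = classes == 0
    is_carn = classes == 1
    is_zsub = classes == 2
    is_reg = classes == 3

    masks = {g: np.zeros(n, dtype=bool) for g in FOOD_GROUPS}
    masks["meat"] = ~is_veg

    # regular omnivores: (alt, pulses) jointly, conditioned on at least one
    p10 = q_alt * (1 - q_pul)
    p01 = (1 - q_alt) * q_pul
    p11 = q_alt * q_pul
    tot = p10 + p01 + p11
    if tot <= 0:
        raise InvalidConfigError("zero_inflation leaves omnivores with no substitutes")
    joint = rng.choice(3, size=n, p=[p10 / tot, p01 / tot, p11 / tot])
    masks["alt"][is_reg] = (joint[is_reg] != 1)
    masks["pulses"][is_reg] = (joint[is_reg] != 0)
    masks["veg"][is_reg] = rng.random(n)[is_reg] < q_veg

    # vegetarians: independent zero inflation, redrawn until E > 0
    u = rng.random((n, 3))
    masks["alt"][is_veg] = u[is_veg, 0] < q_alt
    masks["pulses"][is_veg] = u[is_veg, 1] < q_pul
    masks["veg"][is_veg] = u[is_veg, 2] < q_veg
    empty = is_veg & ~(masks["alt"] | masks["pulses"] | masks["veg"])
    while empty.any():
        u = rng.random((n, 3))
        masks["alt"][empty] = u[empty, 0] < q_alt
        masks["pulses"][empty] = u[empty, 1] < q_pul
        masks["veg"][empty] = u[empty, 2] < q_veg
        empty = is_veg & ~(masks["alt"] | masks["pulses"] | masks["veg"])

    # meat-and-vegetables-only agents always have vegetables; carnivores none
    masks["veg"][is_zsub] = True
    for g in ("alt", "pulses", "veg"):
        masks[g][is_carn] = False
    return masks


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate a synthetic agent roster.

    Deterministic given ``config`` (including its seed).  The returned frame
    has the serialisable :data:`ROSTER_COLUMNS` plus the derived columns
    ``E``, ``x0``, ``diet_class`` and ``lambda``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = rng.choice(SEXES, size=n, p=[config.sex_props[s] for s in SEXES])
    age = rng.choice(AGE_GROUPS, size=n, p=[config.age_props[a] for a in AGE_GROUPS])
    ses = rng.choice(SES_LEVELS, size=n, p=[config.ses_props[s] for s in SES_LEVELS])
    classes = rng.choice(4, size=n, p=_class_probabilities(config))
    masks = _draw_positive_masks(config, classes, rng)

    p_pos = _positivity_probabilities(config)
    grams = {g: np.zeros(n) for g in FOOD_GROUPS}
    for group in FOOD_GROUPS:
        for s in SEXES:
            sel = (sex == s) & masks[group]
            if not sel.any():
                continue
            params = config.intakes[(s, group)]
            matched = _positive_gamma_params(params.mean, params.sd, p_pos[group])
            if matched is None:
                continue
            shape, scale = matched
            grams[group][sel] = rng.gamma(shape, scale, size=sel.sum())

    data = {"id": np.arange(n), "sex": sex, "age_group": age, "ses": ses}
    for group in FOOD_GROUPS:
        data[f"{group}_g"] = grams[group]
    for group in FOOD_GROUPS:
        data[f"{group}_kcal"] = grams[group] * config.energy_density[group]
    roster = pd.DataFrame(data)
    return derive_opinion_columns(roster, lambda_omnivore=config.lambda_omnivore)


def derive_opinion_columns(
    roster: pd.DataFrame, lambda_omnivore: float = 0.5
) -> pd.DataFrame:
    """Attach E, x0, diet_class and lambda to a roster of baseline intakes."""
    roster = roster.copy()
    kcal = roster[list(KCAL_COLUMNS)].to_numpy(dtype=float)
    E = kcal.sum(axis=1)
    if (E <= 0).any():
        bad = roster.index[E <= 0].tolist()
        raise RosterValidationError(
            f"agents with zero total baseline energy (rows {bad}); exclude upstream"
        )
    x0 = kcal[:, 0] / E
    diet_class = np.where(x0 == 0, "vegetarian", np.where(x0 == 1, "carnivore", "omnivore"))
    lam = np.where(diet_class == "omnivore", lambda_omnivore, 0.0)
    roster["E"] = E
    roster["x0"] = x0
    roster["diet_class"] = diet_class
    roster["lambda"] = lam
    return roster


def write_roster(roster: pd.DataFrame, path) -> None:
    """Write the serialisable roster columns as comma-delimited UTF-8 text."""
    roster.loc[:, list(ROSTER_COLUMNS)].to_csv(path, index=False)


def read_roster(path, lambda_omnivore: float = 0.5) -> pd.DataFrame:
    """Read and validate a roster file.

    Rows with missing sex/age/SES or zero total energy are rejected (dropped
    with a warning naming the rows), mirroring the survey exclusion rules;
    negative intakes or unknown category labels raise
    :class:`RosterValidationError` listing the offending rows.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RosterValidationError(f"roster is missing columns {missing_cols}")

    numeric = df[list(GRAM_COLUMNS + KCAL_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad_numeric = (numeric.isna() & df[list(GRAM_COLUMNS + KCAL_COLUMNS)].notna()).any(axis=1)
    negative = (numeric < 0).any(axis=1)
    if negative.any():
        rows = df.index[negative].tolist()
        raise RosterValidationError(f"negative intakes in rows {rows}")
    if bad_numeric.any():
        rows = df.index[bad_numeric].tolist()
        raise RosterValidationError(f"non-numeric intakes in rows {rows}")

    unknown = (
        ~df["sex"].isin(SEXES) & df["sex"].notna()
        | ~df["age_group"].isin(AGE_GROUPS) & df["age_group"].notna()
        | ~df["ses"].isin(SES_LEVELS) & df["ses"].notna()
    )
    if unknown.any():
        rows = df.index[unknown].tolist()
        raise RosterValidationError(f"unknown category labels in rows {rows}")

    incomplete = df[["sex", "age_group", "ses"]].isna().any(axis=1)
    zero_energy = numeric[list(KCAL_COLUMNS)].fillna(0).sum(axis=1) <= 0
    reject = incomplete | zero_energy
    if reject.any():
        rows = df.index[reject].tolist()
        warnings.warn(
            f"rejected {len(rows)} agent(s) with missing attributes or zero "
            f"baseline energy (rows {rows})",
            stacklevel=2,
        )
        df = df.loc[~reject].reset_index(drop=True)
    if df.empty:
        raise RosterValidationError("no valid agents remain after exclusions")
    df[list(GRAM_COLUMNS + KCAL_COLUMNS)] = df[list(GRAM_COLUMNS + KCAL_COLUMNS)].astype(float)
    return derive_opinion_columns(df, lambda_omnivore=lambda_omnivore)


def with_seed(config: PopulationConfig, seed: int) -> PopulationConfig:
    """Return a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
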