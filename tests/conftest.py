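import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import meatshift as ms
from meatshift.population import derive_opinion_columns

settings.register_profile("default", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("default")


def make_roster(rows) -> pd.DataFrame:
    """Build a roster frame from (sex, age, ses, meat_g, alt_g, pulses_g, veg_g) rows.

    Energies use the package's default densities so x0 and E are consistent.
    """
    from meatshift.population import DEFAULT_ENERGY_DENSITY, FOOD_GROUPS

    records = []
    for i, (sex, age, ses, meat, alt, pulses, veg) in enumerate(rows):
        rec = {"id": i, "sex": sex, "age_group": age, "ses": ses}
        for g, v in zip(FOOD_GROUPS, (meat, alt, pulses, veg)):
            rec[f"{g}_g"] = float(v)
            rec[f"{g}_kcal"] = float(v) * DEFAULT_ENERGY_DENSITY[g]
        records.append(rec)
    return derive_opinion_columns(pd.DataFrame(records))


@pytest.fixture
def small_roster() -> pd.DataFrame:
    """Six agents: one vegetarian, one carnivore, four omnivores."""
    return make_roster(
        [
            ("male", "19-29", "low", 0.0, 10.0, 20.0, 50.0),  # vegetarian
            ("female", "30-39", "medium", 300.0, 0.0, 0.0, 0.0),  # carnivore
            ("male", "40-55", "high", 150.0, 5.0, 20.0, 40.0),
            ("female", "56-64", "low", 80.0, 0.0, 30.0, 120.0),
            ("male", "65-85", "medium", 200.0, 0.0, 0.0, 60.0),  # meat+veg only
            ("female", "19-29", "high", 50.0, 20.0, 40.0, 200.0),
        ]
    )


def random_instance(rng: np.random.Generator, n: int, lam_max: float = 0.85):
    """Random row-normalized influence matrix plus bounded FJ parameters."""
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    A = W / W.sum(axis=1, keepdims=True)
    lam = rng.uniform(0.0, lam_max, size=n)
    u = rng.random(n)
    x = rng.random(n)
    return A, lam, u, x


@pytest.fixture(scope="session")
def calibrated_roster() -> pd.DataFrame:
    """The default survey-calibrated synthetic roster (n = 1841, fixed seed)."""
    return ms.generate_population(ms.PopulationConfig(seed=1))


@pytest.fixture(scope="session")
def calibrated_network(calibrated_roster):
    return ms.build_network(calibrated_roster)


@pytest.fixture(scope="session")
def calibrated_propagator(calibrated_roster, calibrated_network):
    return ms.CampaignPropagator(
        calibrated_network.A, calibrated_roster["lambda"].to_numpy()
    )
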