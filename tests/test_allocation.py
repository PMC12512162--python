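import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_roster
from meatshift.allocation import (
    kcal_to_grams,
    opinion_to_consumption,
    read_density_table,
    substitute_shares,
    write_density_table,
)
from meatshift.population import DEFAULT_ENERGY_DENSITY, FOOD_GROUPS, PopulationConfig, generate_population


def roster_one(meat, alt, pulses, veg, kcal=None):
    """Single-agent roster with explicit kcal values when given."""
    if kcal is not None and (meat, alt, pulses, veg) == (0, 0, 0, 0):
        meat, alt, pulses, veg = kcal  # reuse energies as grams placeholders
    r = make_roster([("male", "30-39", "medium", meat, alt, pulses, veg)])
    if kcal is not None:
        for g, v in zip(FOOD_GROUPS, kcal):
            r[f"{g}_kcal"] = float(v)
        from meatshift.population import derive_opinion_columns

        r = derive_opinion_columns(r.drop(columns=["E", "x0", "diet_class", "lambda"]))
    return r


class TestSubstituteShares:
    def test_strict_proportional_to_baseline(self):
        r = roster_one(100, 10, 10, 10, kcal=(100, 20, 30, 50))
        s = substitute_shares(r, mode="baseline_strict")
        np.testing.assert_allclose(s.shares[0], [0.2, 0.3, 0.5])

    def test_meat_and_veg_only_strict_goes_to_vegetables(self):
        r = roster_one(100, 0, 0, 50)
        s = substitute_shares(r, mode="baseline_strict")
        np.testing.assert_allclose(s.shares[0], [0.0, 0.0, 1.0])

    def test_flexible_default_passthrough(self):
        r = roster_one(100, 0, 0, 50)
        s = substitute_shares(r, mode="baseline_flexible", default_shares=(0.05, 0.15, 0.80))
        np.testing.assert_allclose(s.shares[0], [0.05, 0.15, 0.80])

    def test_flexible_defaults_to_population_composition(self):
        roster = make_roster(
            [
                ("male", "19-29", "low", 100, 10, 20, 50),
                ("female", "30-39", "low", 100, 0, 0, 50),  # zero-substitute
            ]
        )
        s = substitute_shares(roster, mode="baseline_flexible")
        sub_kcal = roster.loc[0, ["alt_kcal", "pulses_kcal", "veg_kcal"]].to_numpy(float)
        np.testing.assert_allclose(s.shares[1], sub_kcal / sub_kcal.sum())

    def test_modes_agree_for_substitute_reporters(self):
        roster = make_roster([("male", "19-29", "low", 100, 10, 20, 50)])
        a = substitute_shares(roster, "baseline_strict").shares
        b = substitute_shares(roster, "baseline_flexible").shares
        np.testing.assert_allclose(a, b)

    def test_carnivore_flexible_gets_default_blend(self):
        roster = make_roster(
            [
                ("male", "19-29", "low", 100, 10, 20, 50),
                ("female", "30-39", "low", 300, 0, 0, 0),  # carnivore
            ]
        )
        s = substitute_shares(roster, "baseline_flexible")
        assert s.shares[1, 0] > 0 and s.shares[1, 1] > 0


class TestOpinionToConsumption:
    def test_identity_at_baseline_opinion(self, small_roster):
        shares = substitute_shares(small_roster, "baseline_strict")
        out = opinion_to_consumption(small_roster["x0"].to_numpy(), small_roster, shares)
        for g in FOOD_GROUPS:
            np.testing.assert_allclose(out[g], small_roster[f"{g}_kcal"], atol=1e-9)
        assert not out["clamped"].any()

    def test_worked_reduction_example(self):
        r = roster_one(0, 0, 0, 0, kcal=(200, 40, 60, 100))  # E=400, x0=0.5
        shares = substitute_shares(r, "baseline_strict")
        np.testing.assert_allclose(shares.shares[0], [0.2, 0.3, 0.5])
        out = opinion_to_consumption(np.array([0.3]), r, shares)
        assert out["meat"][0] == pytest.approx(120.0)
        np.testing.assert_allclose(
            [out["alt"][0], out["pulses"][0], out["veg"][0]], [56.0, 84.0, 140.0]
        )
        total = sum(out[g][0] for g in FOOD_GROUPS)
        assert total == pytest.approx(400.0)

    def test_vegetarian_unchanged(self, small_roster):
        shares = substitute_shares(small_roster, "baseline_flexible")
        out = opinion_to_consumption(small_roster["x0"].to_numpy(), small_roster, shares)
        veg = small_roster.index[small_roster["diet_class"] == "vegetarian"][0]
        for g in FOOD_GROUPS:
            assert out[g][veg] == pytest.approx(small_roster.loc[veg, f"{g}_kcal"])

    def test_opinion_increase_clamped_and_flagged(self):
        r = roster_one(0, 0, 0, 0, kcal=(200, 40, 60, 100))
        shares = substitute_shares(r, "baseline_strict")
        out = opinion_to_consumption(np.array([0.9]), r, shares)
        assert out["clamped"][0]
        assert out["meat"][0] == pytest.approx(200.0)  # clamped at baseline

    @given(st.integers(0, 10_000))
    def test_energy_conserved_and_substitution_monotone(self, seed):
        rng = np.random.default_rng(seed)
        roster = generate_population(PopulationConfig(n=30, seed=seed % 997))
        shares = substitute_shares(roster, "baseline_flexible")
        x0 = roster["x0"].to_numpy()
        x1 = x0 * rng.uniform(0, 1, size=len(roster))
        x = np.vstack([x0, x1, x1 * 0.5])  # nested reductions
        out = opinion_to_consumption(x, roster, shares)
        total = sum(np.asarray(out[g]) for g in FOOD_GROUPS)
        np.testing.assert_allclose(total, np.tile(roster["E"], (3, 1)), rtol=1e-12)
        # weakly larger substitute intake at the lower opinion, per positive share
        for k, g in enumerate(("alt", "pulses", "veg")):
            has_share = shares.shares[:, k] > 0
            assert (np.asarray(out[g])[2, has_share] >= np.asarray(out[g])[1, has_share] - 1e-9).all()


class TestConsumptionSeries:
    def test_long_format_conserves_energy_per_week(self, small_roster):
        from meatshift.allocation import consumption_series_frame

        shares = substitute_shares(small_roster)
        x0 = small_roster["x0"].to_numpy()
        opinions = np.vstack([x0, x0 * 0.8])
        frame = consumption_series_frame(opinions, np.array([0, 1]), small_roster, shares)
        assert list(frame.columns) == ["week", "agent_id", "group", "kcal", "grams"]
        assert len(frame) == 2 * len(small_roster) * 4
        totals = frame.groupby(["week", "agent_id"])["kcal"].sum()
        for (_, agent_id), total in totals.items():
            expected = small_roster.set_index("id").loc[agent_id, "E"]
            assert total == pytest.approx(expected)


class TestKcalToGrams:
    def test_agent_density_used_when_baseline_positive(self):
        r = roster_one(100, 0, 0, 0, kcal=(200, 0, 0, 1))
        grams = kcal_to_grams({g: np.array([150.0 if g == "meat" else 0.0]) for g in FOOD_GROUPS}, r)
        assert grams["meat"][0] == pytest.approx(75.0)  # density 2.0 kcal/g

    def test_zero_baseline_falls_back_to_table(self):
        r = roster_one(100, 0, 10, 10)
        kcal = {g: np.array([30.0]) for g in FOOD_GROUPS}
        grams = kcal_to_grams(kcal, r)
        assert grams["alt"][0] == pytest.approx(30.0 / DEFAULT_ENERGY_DENSITY["alt"])

    def test_zero_kcal_gives_zero_grams(self, small_roster):
        kcal = {g: np.zeros(len(small_roster)) for g in FOOD_GROUPS}
        grams = kcal_to_grams(kcal, small_roster)
        for g in FOOD_GROUPS:
            np.testing.assert_array_equal(grams[g], 0.0)

    def test_bad_density_table_rejected(self, small_roster):
        kcal = {g: np.zeros(len(small_roster)) for g in FOOD_GROUPS}
        with pytest.raises(ValueError):
            kcal_to_grams(kcal, small_roster, {"meat": 0.0, "alt": 1, "pulses": 1, "veg": 1})

    def test_density_table_roundtrip(self, tmp_path):
        path = tmp_path / "density.csv"
        write_density_table(DEFAULT_ENERGY_DENSITY, path)
        assert read_density_table(path) == pytest.approx(DEFAULT_ENERGY_DENSITY)
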