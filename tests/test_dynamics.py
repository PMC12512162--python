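import numpy as np
import pytest
from hypothesis import given, strategies as st

import meatshift as ms
from conftest import make_roster, random_instance
from meatshift.dynamics import (
    CampaignPropagator,
    compute_prejudice,
    external_opinion,
    fj_fixed_point,
    fj_rate,
    run_campaign,
    run_scenario,
)
from meatshift.scenarios import Scenario


def naive_rk4(x, A, lam, u, dt, weeks):
    """Reference fixed-step RK4 integration of the FJ rate, one week at a time."""
    traj = []
    steps = round(1 / dt)
    for _ in range(weeks):
        for _ in range(steps):
            k1 = fj_rate(x, A, lam, u)
            k2 = fj_rate(x + dt / 2 * k1, A, lam, u)
            k3 = fj_rate(x + dt / 2 * k2, A, lam, u)
            k4 = fj_rate(x + dt * k3, A, lam, u)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj.append(x)
    return np.array(traj)


class TestFJRate:
    def test_fully_stubborn_at_prejudice_is_stationary(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        rate = fj_rate(np.array([0.4, 0.9]), A, np.zeros(2), np.array([0.4, 0.9]))
        np.testing.assert_allclose(rate, 0.0)

    def test_two_agent_consensus_pull(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        rate = fj_rate(np.array([0.0, 1.0]), A, np.ones(2), np.zeros(2))
        np.testing.assert_allclose(rate, [1.0, -1.0])

    def test_inertia_pull_towards_prejudice(self):
        A = np.zeros((1, 1))
        rate = fj_rate(np.array([0.9]), A, np.zeros(1), np.array([0.3]))
        assert rate[0] == pytest.approx(-0.6)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fj_rate(np.zeros(3), np.zeros((2, 2)), np.zeros(3), np.zeros(3))


class TestPrejudice:
    def test_no_influence_keeps_reference(self):
        u = compute_prejudice(np.array([0.7]), np.array([0.0]), np.array([0.1]))
        assert u[0] == 0.7

    def test_full_influence_adopts_external(self):
        u = compute_prejudice(np.array([0.7]), np.array([1.0]), np.array([0.2]))
        assert u[0] == pytest.approx(0.2)

    def test_midpoint_blend(self):
        u = compute_prejudice(np.array([0.8]), np.array([0.5]), np.array([0.2]))
        assert u[0] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_prejudice(np.array([1.2]), np.array([0.5]), np.array([0.2]))


class TestExternalOpinion:
    def test_per_agent_ceiling_quotient(self):
        s = external_opinion(np.array([400.0]), 131.0)
        assert s[0] == pytest.approx(131.0 / 400.0)  # 0.3275

    def test_ceiling_capped_at_one(self):
        assert external_opinion(np.array([100.0]), 131.0)[0] == 1.0

    def test_global_zero(self):
        np.testing.assert_array_equal(
            external_opinion(np.array([100.0, 400.0]), 131.0, "global_zero"), 0.0
        )


class TestPropagator:
    @given(st.integers(0, 10_000))
    def test_matches_naive_rk4(self, seed):
        """The precomputed weekly propagator reproduces step-by-step RK4."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        A, lam, u, x = random_instance(rng, n)
        prop = CampaignPropagator(A, lam, dt=0.25)
        expected = naive_rk4(x, A, lam, u, 0.25, weeks=8)
        got = [x]
        c = (1 - lam) * u
        for _ in range(8):
            got.append(prop.step_week(got[-1], c))
        np.testing.assert_allclose(np.array(got[1:]), expected, atol=1e-12)

    def test_bad_dt_rejected(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            CampaignPropagator(A, np.zeros(2), dt=0.3)


class TestRunCampaign:
    def test_starts_at_fixed_point_ends_immediately(self):
        rng = np.random.default_rng(0)
        A, lam, u, _ = random_instance(rng, 5)
        xstar = fj_fixed_point(A, lam, u)
        prop = CampaignPropagator(A, lam)
        traj, converged = run_campaign(xstar, u, prop)
        assert converged and len(traj) == 1
        np.testing.assert_allclose(traj[0], xstar, atol=1e-9)

    def test_all_susceptible_reach_consensus(self):
        """lambda = 1 on a connected symmetric graph recovers consensus
        dynamics; the final spread falls below the stationarity tolerance."""
        n, tol = 4, 1e-4
        A = (np.ones((n, n)) - np.eye(n)) / (n - 1)
        prop = CampaignPropagator(A, np.ones(n))
        x0 = np.array([0.0, 1.0, 0.2, 0.9])
        traj, converged = run_campaign(x0, np.zeros(n), prop, tol=tol, max_weeks=500)
        assert converged
        assert traj[-1].max() - traj[-1].min() < tol
        assert traj[-1].mean() == pytest.approx(x0.mean(), abs=1e-6)

    @given(st.integers(0, 10_000))
    def test_stationary_state_matches_linear_solve(self, seed):
        """Campaign-end opinions agree with the closed-form FJ fixed point."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        A, lam, u, x = random_instance(rng, n)
        tol = 1e-4
        prop = CampaignPropagator(A, lam)
        traj, converged = run_campaign(x, u, prop, tol=tol, max_weeks=2000)
        assert converged
        np.testing.assert_allclose(traj[-1], fj_fixed_point(A, lam, u), atol=10 * tol)

    def test_nonconvergence_flagged_not_fatal(self):
        rng = np.random.default_rng(1)
        A, lam, u, x = random_instance(rng, 4)
        traj, converged = run_campaign(x, u, CampaignPropagator(A, lam), tol=1e-12, max_weeks=3)
        assert not converged and len(traj) == 3


class TestRunScenario:
    def test_vegetarian_conservation_and_box_invariance(self, small_roster):
        net = ms.build_network(small_roster)
        res = run_scenario(small_roster, net, Scenario(target=0.35, max_weeks=400))
        assert (res.opinions >= 0).all() and (res.opinions <= 1).all()
        veg = (small_roster["diet_class"] == "vegetarian").to_numpy()
        assert (res.opinions[:, veg] == 0).all()

    def test_no_external_influence_never_reaches(self, small_roster):
        """gamma = 0: the network settles at the no-external FJ equilibrium
        and the mean never falls below it, so the target stays unreached."""
        net = ms.build_network(small_roster)
        sc = Scenario(target=0.35, max_weeks=200)
        res = run_scenario(small_roster, net, sc, gamma=np.zeros(len(small_roster)))
        assert not res.reached
        lam = small_roster["lambda"].to_numpy()
        E = small_roster["E"].to_numpy()
        eq = fj_fixed_point(net.A, lam, small_roster["x0"].to_numpy())
        eq_mean = (eq * E).mean()
        assert res.mean_meat_kcal.min() >= eq_mean - 1e-6

    def test_full_effort_towards_zero_reaches_any_target(self):
        roster = make_roster(
            [
                ("male", "19-29", "low", 150, 5, 20, 40),
                ("female", "30-39", "medium", 80, 10, 30, 120),
                ("male", "40-55", "high", 200, 5, 10, 60),
            ]
        )
        net = ms.build_network(roster)
        sc = Scenario(gamma_bar=1.0, target=0.9, external_opinion_mode="global_zero", max_weeks=400)
        res = run_scenario(roster, net, sc)
        assert res.reached
        assert res.mean_meat_kcal[-1] <= 0.1 * res.baseline_mean_meat_kcal

    def test_monotone_forcing_across_campaign_ends(self, small_roster):
        net = ms.build_network(small_roster)
        res = run_scenario(small_roster, net, Scenario(target=0.5, max_weeks=600))
        ends = res.mean_meat_kcal[res.campaign_end_weeks]
        assert (np.diff(ends) <= 1e-9).all()

    def test_determinism(self, small_roster):
        net = ms.build_network(small_roster)
        sc = Scenario(mode="uniform_random", seed=3, target=0.35, max_weeks=300)
        a = run_scenario(small_roster, net, sc)
        b = run_scenario(small_roster, net, sc)
        np.testing.assert_array_equal(a.opinions, b.opinions)

    @pytest.mark.parametrize("factor", [0.5, 0.25])
    def test_scaling_gamma_down_never_speeds_up(self, factor):
        rosters = [
            make_roster(
                [
                    ("male", "19-29", "low", 150, 5, 20, 40),
                    ("female", "30-39", "medium", 80, 10, 30, 120),
                    ("male", "40-55", "high", 200, 5, 10, 60),
                    ("female", "56-64", "low", 120, 0, 15, 90),
                    ("male", "65-85", "medium", 90, 5, 25, 80),
                ]
            )
        ]
        for roster in rosters:
            net = ms.build_network(roster)
            sc = Scenario(target=0.35, max_weeks=2000)
            gamma = ms.build_gamma(sc, roster)
            t_full = ms.time_to_target(run_scenario(roster, net, sc, gamma=gamma))
            t_scaled = ms.time_to_target(run_scenario(roster, net, sc, gamma=factor * gamma))
            t_full = np.inf if t_full is ms.NOT_REACHED else t_full
            t_scaled = np.inf if t_scaled is ms.NOT_REACHED else t_scaled
            assert t_scaled >= t_full
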