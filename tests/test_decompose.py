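"""Learning/noise decomposition, learning fraction, and cohort summaries."""

import numpy as np
import pandas as pd
import pytest

from pglearn import (Curriculum, PGParams, cumulative_accuracy, decompose,
                     learning_fraction, learning_rollout, noise_consistency,
                     preferred_relabel, rate_trend_summary, reward_after_error,
                     simulate_pg, update_residuals)
from pglearn.models import vector_pg_drift
from pglearn.trials import build_regressors


@pytest.fixture(scope="module")
def noiseless_sim():
    params = PGParams(variant="vector_pg", alpha=0.05, beta=-0.2, qdiag=0.01,
                      sigma=0.0, sigma_day=0.0, w1_sd=0.0)
    cur = Curriculum(n_sessions=2, trials_per_session=150)
    return simulate_pg(params, cur, seed=17)


class TestRollout:
    def test_no_learning_constant_trajectory(self, small_sim):
        p = PGParams(variant="noise_only", alpha=0.0, qdiag=0.0)
        w0 = np.array([0.5, -1.0, 1.0, 0.0, 0.2])
        traj = learning_rollout(p, small_sim.trials, w0)
        assert np.all(traj == w0)

    def test_matches_noiseless_simulation(self, noiseless_sim):
        traj = learning_rollout(noiseless_sim.params, noiseless_sim.trials,
                                noiseless_sim.true_weights[0])
        assert np.allclose(traj, noiseless_sim.true_weights, atol=1e-10)

    def test_deterministic(self, small_sim):
        p = PGParams(variant="vector_pg", alpha=0.1, beta=-0.3)
        w0 = np.zeros(5)
        a = learning_rollout(p, small_sim.trials, w0)
        b = learning_rollout(p, small_sim.trials, w0)
        assert np.array_equal(a, b)

    def test_rate_traj_length_checked(self, small_sim):
        p = PGParams(variant="vector_pg", alpha=0.1)
        with pytest.raises(ValueError, match="length"):
            learning_rollout(p, small_sim.trials, np.zeros(5),
                             rate_traj=np.ones(3))


class TestResiduals:
    def test_noise_only_residuals_are_full_updates(self, small_sim):
        p = PGParams(variant="noise_only", alpha=0.0, qdiag=0.0)
        inferred = np.cumsum(np.ones((50, 5)) * 0.01, axis=0)
        dl, res = update_residuals(inferred, p, small_sim.trials.iloc[:50])
        assert np.all(dl == 0)
        assert np.allclose(res, np.diff(inferred, axis=0))

    def test_noiseless_rollout_has_zero_residuals(self, noiseless_sim):
        dl, res = update_residuals(noiseless_sim.true_weights,
                                   noiseless_sim.params, noiseless_sim.trials)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_three_trial_hand_example(self):
        # hand-checkable: T=3, drift evaluated at the inferred weights
        trials = pd.DataFrame({
            "session": [1, 1, 1], "trial": [0, 1, 2],
            "contrast_left": [0.0, 1.0, 0.0],
            "contrast_right": [1.0, 0.0, 1.0],
            "correct_side": ["R", "L", "R"],
            "choice": ["R", "L", "L"],
            "reward": [1.0, 1.0, 0.0]})
        p = PGParams(variant="vector_pg", alpha=0.1, beta=-0.5, qdiag=0.0)
        inferred = np.array([[0.0] * 5, [0.1] * 5, [0.3] * 5])
        x = build_regressors(trials).x
        y = np.array([1, -1, -1])
        r = np.array([1.0, 1.0, 0.0])
        expected_dl = np.array([
            vector_pg_drift(inferred[0], x[0], y[0], r[0], p),
            vector_pg_drift(inferred[1], x[1], y[1], r[1], p)])
        dl, res = update_residuals(inferred, p, trials)
        assert np.allclose(dl, expected_dl)
        assert np.allclose(res, np.diff(inferred, axis=0) - expected_dl)

    def test_reconstruction_consistency(self, small_sim):
        p = PGParams(variant="vector_pg", alpha=0.08, beta=-0.2, qdiag=0.01)
        rng = np.random.default_rng(0)
        inferred = np.cumsum(rng.normal(0, 0.05, (len(small_sim.trials), 5)),
                             axis=0)
        dl, res = update_residuals(inferred, p, small_sim.trials)
        rebuilt = inferred[0] + np.cumsum(dl + res, axis=0)
        assert np.allclose(rebuilt, inferred[1:], atol=1e-10)

    def test_too_short_rejected(self, small_sim):
        p = PGParams(variant="vector_pg")
        with pytest.raises(ValueError):
            update_residuals(np.zeros((1, 5)), p, small_sim.trials.iloc[:1])


class TestLearningFraction:
    def test_pure_noise_fraction_exactly_zero(self, small_sim):
        p = PGParams(variant="noise_only", alpha=0.0, qdiag=0.0)
        rng = np.random.default_rng(1)
        inferred = np.cumsum(rng.normal(0, 0.1, (200, 5)), axis=0)
        d = decompose(inferred, p, small_sim.trials.iloc[:200])
        assert d.learning_fraction == 0.0

    def test_pure_learning_fraction_exactly_one(self, noiseless_sim):
        d = decompose(noiseless_sim.true_weights, noiseless_sim.params,
                      noiseless_sim.trials)
        assert d.learning_fraction == 1.0
        assert np.allclose(d.residual_traj, 0.0, atol=1e-9)

    def test_fraction_bounded_and_monotone_in_noise(self):
        # same learning rate, increasing noise: fraction should not rise
        cur = Curriculum(n_sessions=2, trials_per_session=150)
        fracs = []
        for sigma in (0.02, 0.08, 0.3):
            fs = []
            for seed in range(10):
                p = PGParams(variant="vector_pg", alpha=0.1, sigma=sigma,
                             sigma_day=sigma)
                sim = simulate_pg(p, cur, seed=seed)
                d = decompose(sim.true_weights, p, sim.trials)
                fs.append(d.learning_fraction)
                assert 0.0 <= d.learning_fraction <= 1.0
            fracs.append(np.mean(fs))
        assert fracs[0] > fracs[1] > fracs[2]

    def test_ratio_of_sums_variant(self, noiseless_sim):
        dl, res = update_residuals(noiseless_sim.true_weights,
                                   noiseless_sim.params, noiseless_sim.trials)
        frac, _ = learning_fraction(dl, res, ratio_of_sums=True)
        assert frac == 1.0

    def test_projection_and_cosine_on_noiseless(self, noiseless_sim):
        d = decompose(noiseless_sim.true_weights, noiseless_sim.params,
                      noiseless_sim.trials)
        assert d.projection_fraction == pytest.approx(1.0)
        assert d.mean_cosine == pytest.approx(1.0)


class TestRewardAfterError:
    def test_hand_enumerated_sequence(self):
        # rewards 1,0,0,0,1: pairs after an error -> (0,0),(0,0),(0,1)
        trials = pd.DataFrame({
            "session": [1] * 5, "trial": range(5),
            "contrast_left": [0.0] * 5, "contrast_right": [1.0] * 5,
            "correct_side": ["R"] * 5,
            "choice": ["R", "L", "L", "L", "R"],
            "reward": [1.0, 0.0, 0.0, 0.0, 1.0]})
        cond, shuf = reward_after_error(trials)
        assert cond == pytest.approx(1 / 3)
        assert shuf == pytest.approx(2 / 5)

    def test_iid_rewards_show_no_effect(self, rng):
        n = 100_000
        r = (rng.random(n) < 0.6).astype(float)
        trials = pd.DataFrame({
            "session": [1] * n, "trial": range(n),
            "contrast_left": [0.0] * n, "contrast_right": [1.0] * n,
            "correct_side": ["R"] * n,
            "choice": np.where(r > 0, "R", "L"),
            "reward": r})
        cond, shuf = reward_after_error(trials)
        se = np.sqrt(0.6 * 0.4 / (r == 0).sum())
        assert abs(cond - shuf) < 3 * se

    def test_session_boundary_pairs_excluded(self):
        trials = pd.DataFrame({
            "session": [1, 1, 2, 2], "trial": range(4),
            "contrast_left": [0.0] * 4, "contrast_right": [1.0] * 4,
            "correct_side": ["R"] * 4,
            "choice": ["L", "L", "R", "R"],
            "reward": [0.0, 0.0, 1.0, 1.0]})
        cond, _ = reward_after_error(trials)
        # only the within-session pair (t=0 -> t=1) counts: r=0
        assert cond == 0.0

    def test_side_relabeling_invariance(self, small_sim):
        t = small_sim.trials.copy()
        cond1, shuf1 = reward_after_error(t)
        swap = {"L": "R", "R": "L"}
        t["choice"] = t["choice"].map(swap)
        t["correct_side"] = t["correct_side"].map(swap)
        cl, cr = t["contrast_left"].copy(), t["contrast_right"].copy()
        t["contrast_left"], t["contrast_right"] = cr, cl
        cond2, shuf2 = reward_after_error(t)
        assert cond1 == cond2 and shuf1 == shuf2

    def test_no_errors_rejected(self):
        trials = pd.DataFrame({
            "session": [1, 1], "trial": [0, 1],
            "contrast_left": [0.0] * 2, "contrast_right": [1.0] * 2,
            "correct_side": ["R"] * 2, "choice": ["R", "R"],
            "reward": [1.0, 1.0]})
        with pytest.raises(ValueError):
            reward_after_error(trials)

    def test_error_reinforcing_updates_depress_reward_after_error(self):
        # negative baseline: errors beget errors, so E[r | after error] drops
        cur = Curriculum(n_sessions=4, trials_per_session=250)
        worse = 0
        for seed in range(6):
            p = PGParams(variant="vector_pg", alpha=0.3, beta=-0.5,
                         sigma=0.02, sigma_day=0.02)
            sim = simulate_pg(p, cur, seed=seed)
            cond, shuf = reward_after_error(sim.trials)
            worse += cond < shuf
        assert worse >= 4


class TestCohortSummaries:
    def test_preferred_relabel_identity_control(self):
        rng = np.random.default_rng(3)
        alphas = np.array([[0.2, 0.05], [0.01, 0.3], [0.1, 0.15]])
        weights = [rng.normal(size=(50, 2)), rng.normal(size=(80, 2)),
                   rng.normal(size=(60, 2))]
        pref, nonpref, cp, cn = preferred_relabel(
            alphas, weights, grid_size=20, permutation=np.arange(3))
        assert np.allclose(pref, cp)
        assert np.allclose(nonpref, cn)

    def test_asymmetric_cohort_preferred_exceeds_shuffled(self):
        # animals with strongly asymmetric rates and matching weight growth
        rng = np.random.default_rng(5)
        n = 8
        alphas, weights = [], []
        for i in range(n):
            pref_side = i % 2
            a = [0.02, 0.02]
            a[pref_side] = 0.3
            alphas.append(a)
            w = np.zeros((100, 2))
            w[:, pref_side] = np.linspace(0, 3, 100)
            w[:, 1 - pref_side] = np.linspace(0, 0.3, 100)
            weights.append(w + rng.normal(0, 0.05, (100, 2)))
        pref, nonpref, cp, _ = preferred_relabel(np.array(alphas), weights,
                                                 grid_size=30, seed=1)
        assert pref[-10:].mean() > nonpref[-10:].mean()
        assert pref[-10:].mean() > cp[-10:].mean()

    def test_symmetric_cohort_indistinguishable_from_shuffle(self):
        # alpha_left == alpha_right: preference labels are arbitrary, so
        # the preferred average and the shuffled control should agree
        # within cohort noise
        rng = np.random.default_rng(11)
        n, T = 12, 80
        alphas = np.tile([0.1, 0.1], (n, 1)) + rng.normal(0, 1e-6, (n, 2))
        weights = [np.abs(rng.normal(1.0, 0.3, (T, 2))) for _ in range(n)]
        pref, nonpref, cp, cn = preferred_relabel(alphas, weights,
                                                  grid_size=25, seed=4)
        spread = np.concatenate([w.ravel() for w in weights]).std() / np.sqrt(n)
        assert np.all(np.abs(pref - cp) < 2 * spread)
        assert np.all(np.abs(nonpref - cn) < 2 * spread)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            preferred_relabel(np.array([[0.1, 0.2]]),
                              [np.zeros((10, 2))], grid_size=5)

    def test_noise_consistency_positive_on_spread_cohort(self):
        rng = np.random.default_rng(7)
        sigmas = rng.uniform(0.02, 0.3, size=20)
        resid = sigmas * rng.uniform(0.9, 1.1, size=20)
        rho, r2 = noise_consistency(resid, sigmas)
        assert rho > 0.5
        assert r2 == pytest.approx(rho ** 2)

    def test_noise_consistency_degenerate_rejected(self):
        with pytest.raises(ValueError):
            noise_consistency([0.1, 0.1, 0.1], [0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            noise_consistency([0.1, 0.2], [0.3, 0.4])

    def test_cumulative_accuracy_all_correct_is_one(self):
        trials = pd.DataFrame({
            "session": [1] * 4, "trial": range(4),
            "contrast_left": [0.0] * 4, "contrast_right": [1.0] * 4,
            "correct_side": ["R"] * 4, "choice": ["R"] * 4,
            "reward": [1.0] * 4})
        assert np.all(cumulative_accuracy(trials) == 1.0)

    def test_rate_trend_static_truth_centers_on_zero(self):
        rng = np.random.default_rng(9)
        cur = Curriculum(n_sessions=2, trials_per_session=100)
        trials = [simulate_pg(PGParams(variant="noise_only", sigma=0.1,
                                       sigma_day=0.1), cur, seed=s).trials
                  for s in range(6)]
        rates = [np.exp(rng.normal(0, 0.05, 200)) for _ in range(6)]
        out = rate_trend_summary(rates, trials, grid_size=30)
        band = np.abs(out["delta_log_rate_mean"]) - 2 * out["delta_log_rate_se"]
        assert (band < 0).mean() > 0.9

    def test_rate_trend_recovers_upward_ramp(self):
        cur = Curriculum(n_sessions=2, trials_per_session=100)
        trials = [simulate_pg(PGParams(variant="noise_only", sigma=0.1,
                                       sigma_day=0.1), cur, seed=s).trials
                  for s in range(5)]
        rates = [np.linspace(0.5, 2.0, 200) for _ in range(5)]
        out = rate_trend_summary(rates, trials, grid_size=30)
        assert out["delta_log_rate_mean"][-1] > 1.0  # log(4) ~ 1.39
        assert out["n_animals"] == 5
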