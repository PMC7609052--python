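"""Saccade-model likelihood, fitting, simulation, and stationary behavior."""

import numpy as np
import pytest

from plumewalk._pipeline import behavior_to_turn_data
from plumewalk.stopwalk_models import fitted_stop_spec, fitted_walk_spec
from plumewalk.synthetic_world import (EncounterTrainConfig,
                                       generate_encounter_train,
                                       simulate_ground_truth_behavior)
from plumewalk.turn_model import (OrientationTrace, TurnLikelihoodData,
                                  TurnModelParams, fit_turn_model,
                                  full_turn_rate,
                                  orientation_vs_frequency_curve,
                                  reflect_upwind, sigmoid_drive,
                                  simulate_turn_ensemble, simulate_turn_model,
                                  turn_log_likelihood,
                                  upwind_turn_probability)

DT = 1.0 / 90.0


class TestSigmoidAndRate:
    def test_probability_half_at_zero_drive_for_any_gain(self):
        for alpha in (-3.0, 0.0, 0.242, 7.0):
            assert upwind_turn_probability(0.0, alpha) == 0.5

    def test_zero_gain_is_half_everywhere(self):
        W = np.linspace(0, 10, 11)
        np.testing.assert_array_equal(upwind_turn_probability(W, 0.0), 0.5)

    def test_direct_evaluation_example(self):
        assert upwind_turn_probability(3.0, 0.242) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.726)))

    def test_symmetry_in_gain(self):
        W = np.linspace(0, 8, 17)
        total = upwind_turn_probability(W, 0.4) + upwind_turn_probability(W, -0.4)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_monotone_increasing_for_positive_gain(self):
        p = upwind_turn_probability(np.linspace(0, 10, 50), 0.242)
        assert np.all(np.diff(p) > 0) and np.all((p > 0) & (p < 1))

    def test_full_turn_rate_modulation_arithmetic(self):
        base = TurnModelParams(tau_T=0.75)
        assert full_turn_rate(base, 5.0, 3.0) == pytest.approx(4.0 / 3.0)
        mod = TurnModelParams(tau_T=0.75, tau_freq=10.0)  # 1/tau_freq = 0.1
        assert full_turn_rate(mod, 2.0, 0.0) == pytest.approx(4.0 / 3.0 + 0.2)
        with pytest.raises(ValueError):
            full_turn_rate(TurnModelParams(tau_T=0.75, tau_freq=-0.1), 100.0, 0.0)


def _single_step_data(dtheta, theta, W=0.0, turn=False):
    return TurnLikelihoodData(dtheta=np.array([dtheta]),
                              theta=np.array([theta]),
                              W_freq=np.array([W]), W_dur=np.array([0.0]),
                              turn_mask=np.array([turn]),
                              walking_mask=np.array([True]), time_step=DT)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def independent_log_likelihood(params, data):
    """Brute-force per-step product oracle, coded independently."""
    total = 0.0
    for i in range(len(data.dtheta)):
        if not data.walking_mask[i]:
            continue
        lam = 1.0 / params.tau_T
        if params.tau_freq is not None:
            lam += data.W_freq[i] / params.tau_freq
        if params.tau_dur is not None:
            lam += data.W_dur[i] / params.tau_dur
        if not data.turn_mask[i]:
            total += -DT * lam + _norm_logpdf(data.dtheta[i], 0.0,
                                              params.straight_jitter_sd)
            continue
        pT = 1.0 / (1.0 + np.exp(-params.alpha * params.filter_tau
                                 * data.W_freq[i]))
        th = data.theta[i] % 360.0
        mu_up = -params.turn_mean if 0 < th < 180 else params.turn_mean
        event = np.log(DT * lam) - DT * lam
        if th % 180.0 == 0.0:
            mix = 0.5 * np.exp(_norm_logpdf(data.dtheta[i], params.turn_mean,
                                            params.turn_sd)) \
                + 0.5 * np.exp(_norm_logpdf(data.dtheta[i], -params.turn_mean,
                                            params.turn_sd))
            total += event + np.log(mix)
        elif np.sign(data.dtheta[i]) == np.sign(mu_up):
            total += event + np.log(pT) + _norm_logpdf(data.dtheta[i], mu_up,
                                                       params.turn_sd)
        else:
            total += event + np.log(1 - pT) + _norm_logpdf(data.dtheta[i],
                                                           -mu_up,
                                                           params.turn_sd)
    return total


class TestTurnLikelihood:
    def test_empty_data_is_zero(self):
        data = _single_step_data(0.0, 10.0)
        data.walking_mask[:] = False
        assert turn_log_likelihood(TurnModelParams(), data) == 0.0

    def test_single_straight_step_hand_computation(self):
        params = TurnModelParams(tau_T=0.75)
        got = turn_log_likelihood(params, _single_step_data(0.0, 10.0))
        lam = 4.0 / 3.0
        expected = -DT * lam + _norm_logpdf(0.0, 0.0, 0.22)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_product_oracle(self):
        rng = np.random.default_rng(5)
        n = 120
        data = TurnLikelihoodData(
            dtheta=np.where(rng.random(n) < 0.1,
                            rng.normal(0, 35, n), rng.normal(0, 0.2, n)),
            theta=rng.uniform(0, 360, n),
            W_freq=rng.exponential(1.0, n),
            W_dur=rng.exponential(0.3, n),
            turn_mask=rng.random(n) < 0.1,
            walking_mask=rng.random(n) < 0.9,
            time_step=DT)
        for params in (TurnModelParams(),
                       TurnModelParams(alpha=-0.5, tau_T=0.4),
                       TurnModelParams(tau_freq=5.0, tau_dur=8.0)):
            got = turn_log_likelihood(params, data)
            want = independent_log_likelihood(params, data)
            assert got == pytest.approx(want, rel=1e-6)

    def test_reflection_boundary_step_is_finite_mixture(self):
        params = TurnModelParams()
        got = turn_log_likelihood(params, _single_step_data(31.0, 180.0,
                                                            W=2.0, turn=True))
        assert np.isfinite(got)
        # boundary term has no p_T dependence
        got2 = turn_log_likelihood(TurnModelParams(alpha=5.0),
                                   _single_step_data(31.0, 180.0, W=2.0,
                                                     turn=True))
        assert got == pytest.approx(got2)


@pytest.fixture(scope="module")
def turn_training_data():
    """120 trajectories x 60 s spanning onset rates 0-10 Hz."""
    rates = np.linspace(0.05, 10.0, 120)
    trains = [generate_encounter_train(EncounterTrainConfig(
        onset_rate=float(r), duration_sampler=("constant", {"value": 0.05}),
        total_time=60.0, seed=500 + i)) for i, r in enumerate(rates)]
    beh = simulate_ground_truth_behavior(
        TurnModelParams(), fitted_stop_spec(), fitted_walk_spec(),
        trains, 120, seed=41)
    return [behavior_to_turn_data(b) for b in beh]


class TestFitTurnModel:
    def test_gain_and_timescale_recovery(self, turn_training_data):
        fit = fit_turn_model(turn_training_data, n_subsets=100, seed=7)
        assert fit.medians["alpha"] == pytest.approx(0.242, rel=0.12)
        assert fit.medians["tau_T"] == pytest.approx(0.75, rel=0.08)
        assert fit.n_failed == 0

    def test_null_gain_recovery(self):
        rates = np.linspace(0.5, 8.0, 40)
        trains = [generate_encounter_train(EncounterTrainConfig(
            onset_rate=float(r), duration_sampler=("constant", {"value": 0.05}),
            total_time=60.0, seed=700 + i)) for i, r in enumerate(rates)]
        beh = simulate_ground_truth_behavior(
            TurnModelParams(alpha=0.0), fitted_stop_spec(), fitted_walk_spec(),
            trains, 40, seed=43)
        data = [behavior_to_turn_data(b) for b in beh]
        fit = fit_turn_model(data, n_subsets=60, seed=8)
        spread = fit.table.alpha.quantile([0.1, 0.9])
        assert spread.iloc[0] < 0.0 < spread.iloc[1]
        assert abs(fit.medians["alpha"]) < 0.05

    def test_modulation_terms_not_robust_on_unmodulated_data(self,
                                                             turn_training_data):
        fit = fit_turn_model(turn_training_data[:40], n_subsets=12, seed=9,
                             fit_modulation=True)
        q = fit.table.inv_tau_freq.quantile([0.1, 0.9])
        assert q.iloc[0] < 0.0 < q.iloc[1] or abs(fit.medians["inv_tau_freq"]) < 0.1

    def test_fast_path_matches_general_likelihood(self, turn_training_data):
        from plumewalk.turn_model import _stats_loglik, _sufficient_stats
        d = turn_training_data[3]
        params = TurnModelParams(alpha=0.3, tau_T=0.6)
        st = _sufficient_stats(d, params.filter_tau)
        fast = _stats_loglik(0.3, 1.0 / 0.6, st, DT)
        walk = d.walking_mask
        # subtract the parameter-independent angle densities
        turn = d.turn_mask & walk
        const = (_norm_logpdf(d.dtheta[walk & ~d.turn_mask], 0.0, 0.22).sum()
                 + sum(_norm_logpdf(abs(x), 30.0, 10.0)
                       for x in d.dtheta[turn]))
        full = turn_log_likelihood(params, d)
        assert fast + const == pytest.approx(full, rel=1e-9)

    def test_requires_ten_trajectories(self, turn_training_data):
        with pytest.raises(ValueError):
            fit_turn_model(turn_training_data[:5])


class TestSimulation:
    def test_unbiased_walk_has_uniform_reflected_orientation(self):
        tr = generate_encounter_train(EncounterTrainConfig(
            onset_rate=0.0, total_time=3000.0, seed=50))
        res = simulate_turn_model(TurnModelParams(alpha=0.0), tr, seed=51)
        assert res.theta_plus[2000:].mean() == pytest.approx(90.0, abs=5.0)

    def test_inter_turn_intervals_exponential_with_mean_tau(self):
        tr = generate_encounter_train(EncounterTrainConfig(
            onset_rate=0.0, total_time=3000.0, seed=52))
        res = simulate_turn_model(TurnModelParams(), tr, seed=53)
        iti = np.diff(res.turn_times)
        assert iti.mean() == pytest.approx(0.75, rel=0.05)
        assert iti.std() == pytest.approx(iti.mean(), rel=0.1)

    def test_seed_determinism(self):
        tr = generate_encounter_train(EncounterTrainConfig(
            onset_rate=2.0, total_time=30.0, seed=54))
        a = simulate_turn_model(TurnModelParams(), tr, seed=55)
        b = simulate_turn_model(TurnModelParams(), tr, seed=55)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_discrete_chain_stationary_oracle(self):
        """Analytic 7-state birth-death stationary mean versus a long
        package simulation at near-constant drive and lattice magnitudes."""
        params = TurnModelParams(turn_sd=1e-6, straight_jitter_sd=1e-6)
        rate = 2.0
        step = int(round(1.0 / rate / DT))
        n = int(1500.0 / DT)
        from plumewalk.signal_encounters import EncounterSeries
        train = EncounterSeries.from_intervals(
            [(i, i + 1) for i in range(0, n - 1, step)], n, DT)
        res = simulate_turn_model(params, train, initial_theta=90.0, seed=56)
        burn = int(30.0 / DT)
        drive = sigmoid_drive(params, res.W_freq[burn:]).mean()
        p = float(upwind_turn_probability(drive, params.alpha))
        # birth-death chain on theta+ in {0, 30, ..., 180}, reflecting ends
        pi = np.ones(7)
        pi[1] = pi[0] / p
        for k in range(1, 6):
            pi[k + 1] = pi[k] * (1 - p) / p
        pi[6] *= p  # end state entered only by downwind steps
        pi /= pi.sum()
        oracle = 30.0 * np.dot(np.arange(7), pi)
        sim = res.theta_plus[burn:].mean()
        assert sim == pytest.approx(oracle, abs=3.0)

    def test_ensemble_matches_single_statistics(self):
        tr = generate_encounter_train(EncounterTrainConfig(
            onset_rate=2.0, duration_sampler=("constant", {"value": 0.05}),
            total_time=400.0, seed=57))
        traces = simulate_turn_ensemble(TurnModelParams(), tr, 10, seed=58)
        burn = int(20.0 / DT)
        mean_ens = np.mean([t.theta_plus[burn:].mean() for t in traces])
        singles = [simulate_turn_model(TurnModelParams(), tr, seed=100 + k)
                   for k in range(10)]
        mean_sgl = np.mean([t.theta_plus[burn:].mean() for t in singles])
        assert mean_ens == pytest.approx(mean_sgl, abs=4.0)


class TestOrientationCurve:
    def test_unbiased_model_flat_with_ninety_intercept(self):
        tr = generate_encounter_train(EncounterTrainConfig(
            onset_rate=2.0, duration_sampler=("constant", {"value": 0.05}),
            total_time=1000.0, seed=60))
        traces = simulate_turn_ensemble(TurnModelParams(alpha=0.0), tr, 10,
                                        seed=61)
        tp = np.concatenate([t.theta_plus for t in traces])
        W = np.tile(traces[0].W_freq, 10)
        curve = orientation_vs_frequency_curve(tp, W)
        assert abs(curve.slope) < 2.5 * max(curve.slope_se, 0.5)
        assert curve.intercept == pytest.approx(90.0, abs=4.0)

    def test_biased_model_monotone_decreasing_binned_means(self):
        rng = np.random.default_rng(62)
        tps, Ws = [], []
        for i, r in enumerate(np.arange(0.5, 3.6, 0.5)):
            tr = generate_encounter_train(EncounterTrainConfig(
                onset_rate=float(r), duration_sampler=("constant", {"value": 0.05}),
                total_time=300.0, seed=63 + i))
            traces = simulate_turn_ensemble(TurnModelParams(), tr, 6, seed=64 + i)
            burn = int(20.0 / DT)
            tps.append(np.concatenate([t.theta_plus[burn:] for t in traces]))
            Ws.append(np.tile(traces[0].W_freq[burn:], 6))
        curve = orientation_vs_frequency_curve(np.concatenate(tps),
                                               np.concatenate(Ws),
                                               bins=np.arange(0, 3.75, 0.5))
        diffs = np.diff(curve.mean_theta_plus)
        assert (diffs < 3.0).all()           # non-increasing within noise
        assert curve.slope < -10.0
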