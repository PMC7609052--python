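"""Rate formulas, bout likelihoods, MLE recovery, and model statistics."""

import numpy as np
import pytest

from plumewalk._filters import causal_exp_filter
from plumewalk._pipeline import behaviors_to_bout_data
from plumewalk.signal_encounters import EncounterSeries
from plumewalk.stopwalk_models import (BoutData, RateModelSpec,
                                       bout_log_likelihood, classify_onsets,
                                       compare_models, fit_rate_model,
                                       fitted_stop_spec, fitted_walk_spec,
                                       generate_model_statistics, rate_trace,
                                       simulate_transitions)
from plumewalk.synthetic_world import (EncounterTrainConfig,
                                       generate_encounter_train,
                                       simulate_ground_truth_behavior)
from plumewalk.turn_model import TurnModelParams

DT = 1.0 / 90.0


def _train(rate=4.0, T=60.0, seed=0, dur=0.05):
    return generate_encounter_train(EncounterTrainConfig(
        onset_rate=rate, duration_sampler=("constant", {"value": dur}),
        total_time=T, seed=seed))


class TestRateTrace:
    def test_stop_rate_at_onset_is_017(self):
        tr = _train(seed=1)
        lam = rate_trace(fitted_stop_spec(), tr.w, tr.d, DT)
        onsets = np.flatnonzero(tr.w)
        np.testing.assert_allclose(lam[onsets], 0.17, atol=1e-12)

    def test_no_odor_limit_is_baseline_for_all_families(self):
        w = np.zeros(900)
        d = np.zeros(900)
        for spec, base in [
            (fitted_stop_spec(), 0.78),
            (fitted_walk_spec(), 0.29),
            (RateModelSpec("accumulated_evidence", "walk_to_stop",
                           dict(lam0=0.3, lam1=0.5, lam2=2.0, tau=0.3)),
             0.8),  # lam0 + lam1 at F=0
            (RateModelSpec("encounter_duration", "walk_to_stop",
                           dict(lam_enc=0.2, lam_blank=0.9)), 0.9),
        ]:
            np.testing.assert_allclose(rate_trace(spec, w, d, DT), base)

    def test_accumulated_walk_two_onsets_kernel_sum(self):
        spec = fitted_walk_spec()
        tau = spec.params["tau"]
        dlam = spec.params["dlam"]
        lam0 = spec.params["lam0"]
        n = 900
        gap = 9  # 0.1 s
        w = np.zeros(n)
        w[100] = 1
        w[100 + gap] = 1
        lam = rate_trace(spec, w, np.zeros(n), DT)
        i = 100 + gap
        expected = lam0 + dlam * (1.0 + np.exp(-gap * DT / tau))
        assert lam[i] == pytest.approx(expected, rel=1e-9)
        # single-onset comparison: the pair exceeds it by dlam*exp(-gap/tau)
        w1 = np.zeros(n)
        w1[100 + gap] = 1
        lam1 = rate_trace(spec, w1, np.zeros(n), DT)
        assert lam[i] - lam1[i] == pytest.approx(
            dlam * np.exp(-gap * DT / tau), rel=1e-9)

    def test_encounter_duration_switches_on_exposure(self):
        tr = _train(seed=2, dur=0.2)
        spec = RateModelSpec("encounter_duration", "walk_to_stop",
                             dict(lam_enc=0.2, lam_blank=0.9))
        lam = rate_trace(spec, tr.w, tr.d, DT)
        assert np.all(lam[tr.d == 1] == 0.2) and np.all(lam[tr.d == 0] == 0.9)

    def test_last_encounter_continuous_between_and_resets_at_onsets(self):
        tr = _train(seed=3, rate=1.0)
        lam = rate_trace(fitted_stop_spec(), tr.w, tr.d, DT)
        onsets = np.flatnonzero(tr.w)
        interior = np.setdiff1d(np.arange(1, lam.size), onsets)
        steps = np.abs(np.diff(lam))
        # between onsets the rate moves by < lam0*dt/tau per step
        assert steps[np.isin(np.arange(1, lam.size), interior)].max() < 0.78 * DT / 0.25 + 1e-9

    def test_nonpositive_rate_rejected(self):
        spec = RateModelSpec("last_encounter", "walk_to_stop",
                             dict(lam0=0.1, dlam=-0.2, tau=0.3))
        w = np.zeros(100)
        w[10] = 1
        with pytest.raises(ValueError):
            rate_trace(spec, w, np.zeros(100), DT)

    def test_unknown_family_and_missing_params_rejected(self):
        with pytest.raises(ValueError):
            RateModelSpec("magic", "walk_to_stop", {})
        with pytest.raises(ValueError):
            RateModelSpec("last_encounter", "walk_to_stop", dict(lam0=1.0))


class TestBoutLikelihood:
    def test_single_walk_bout_closed_form(self):
        n = 90
        walking = np.ones(n + 10, dtype=bool)
        walking[n:] = False
        spec = RateModelSpec("last_encounter", "walk_to_stop",
                             dict(lam0=0.5, dlam=0.0, tau=1.0))
        data = BoutData([dict(w=np.zeros(n + 10), d=np.zeros(n + 10),
                              walking=walking)], DT)
        got = bout_log_likelihood(spec, data)
        expected = -(n + 1) * DT * 0.5 + np.log(DT * 0.5)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_data_is_zero(self):
        assert bout_log_likelihood(fitted_stop_spec(), BoutData([], DT)) == 0.0

    def test_matches_independent_product_oracle(self):
        rng = np.random.default_rng(4)
        tr = _train(seed=5, T=30.0)
        walking = rng.random(tr.w.size) < 0.7
        data = BoutData([dict(w=tr.w, d=tr.d, walking=walking)], DT)
        for spec in (fitted_stop_spec(),
                     RateModelSpec("accumulated_evidence", "walk_to_stop",
                                   dict(lam0=0.3, lam1=0.5, lam2=2.0, tau=0.3)),
                     RateModelSpec("encounter_duration", "walk_to_stop",
                                   dict(lam_enc=0.2, lam_blank=0.9))):
            lam = rate_trace(spec, tr.w, tr.d, DT)
            oracle = 0.0
            for i in range(tr.w.size):
                if walking[i]:
                    oracle += -DT * lam[i]
                if i > 0 and walking[i - 1] and not walking[i]:
                    oracle += np.log(DT * lam[i]) - DT * lam[i]
            got = bout_log_likelihood(spec, data)
            assert got == pytest.approx(oracle, rel=1e-9)

    def test_rates_causal_so_future_signal_cannot_reach_back(self):
        """Signal recorded after a trajectory ends cannot change any rate --
        and hence any likelihood term -- before the end."""
        tr = _train(seed=6, T=20.0)
        w2, d2 = tr.w.copy(), tr.d.copy()
        w2[1200:] = 1
        d2[1200:] = 1
        for spec in (fitted_stop_spec(), fitted_walk_spec(),
                     RateModelSpec("encounter_duration", "walk_to_stop",
                                   dict(lam_enc=0.2, lam_blank=0.9))):
            a = rate_trace(spec, tr.w, tr.d, DT)[:1200]
            b = rate_trace(spec, w2, d2, DT)[:1200]
            np.testing.assert_array_equal(a, b)

    def test_censored_final_bout_contributes_survival_only(self):
        n = 90
        walking = np.ones(n, dtype=bool)  # ends mid-walk: censored
        spec = RateModelSpec("last_encounter", "walk_to_stop",
                             dict(lam0=0.5, dlam=0.0, tau=1.0))
        data = BoutData([dict(w=np.zeros(n), d=np.zeros(n), walking=walking)],
                        DT)
        assert bout_log_likelihood(spec, data) == pytest.approx(
            -n * DT * 0.5, rel=1e-12)

    def test_expected_transition_count_matches_rate_integral(self):
        rng = np.random.default_rng(7)
        tr = _train(seed=8, T=500.0, rate=3.0)
        stop = fitted_stop_spec()
        walk = fitted_walk_spec()
        counts, integrals = [], []
        for k in range(20):
            walking = simulate_transitions(stop, walk, tr.w, tr.d, DT, rng=rng)
            lam = rate_trace(stop, tr.w, tr.d, DT)
            counts.append(int((walking[:-1] & ~walking[1:]).sum()))
            integrals.append(lam[walking].sum() * DT)
        assert np.mean(counts) == pytest.approx(np.mean(integrals), rel=0.05)


@pytest.fixture(scope="module")
def recovery_bouts():
    """500 labeled sequences on 4 Hz trains, both fitted models generating."""
    trains = [_train(rate=4.0, T=60.0, seed=7000 + i) for i in range(500)]
    beh = simulate_ground_truth_behavior(TurnModelParams(), fitted_stop_spec(),
                                         fitted_walk_spec(), trains, 500,
                                         seed=77)
    return behaviors_to_bout_data(beh)


class TestFitRateModel:
    def test_stop_model_parameter_recovery(self, recovery_bouts):
        fit = fit_rate_model("last_encounter", "walk_to_stop", recovery_bouts,
                             n_subsets=20, subset_fraction=0.2, seed=11)
        assert fit.medians["lam0"] == pytest.approx(0.78, rel=0.10)
        assert fit.medians["tau"] == pytest.approx(0.25, rel=0.15)
        assert fit.medians["dlam"] == pytest.approx(-0.61, rel=0.15)

    def test_walk_model_parameter_recovery(self, recovery_bouts):
        fit = fit_rate_model("accumulated_evidence", "stop_to_walk",
                             recovery_bouts, n_subsets=20,
                             subset_fraction=0.2, seed=12)
        assert fit.medians["lam0"] == pytest.approx(0.29, rel=0.12)
        assert fit.medians["dlam"] == pytest.approx(0.41, rel=0.12)

    def test_too_few_transitions_rejected(self):
        tr = _train(seed=13, T=5.0)
        data = BoutData([dict(w=tr.w, d=tr.d,
                              walking=np.ones(tr.w.size, bool))], DT)
        with pytest.raises(ValueError):
            fit_rate_model("last_encounter", "walk_to_stop", data)

    def test_cross_family_fit_flags_nonrobust_estimates(self, recovery_bouts):
        """Fitting the accumulating family to reset-generated stop data:
        estimates spread widely and hug the imposed bounds."""
        small = BoutData(recovery_bouts.trajectories[:100], DT)
        fit = fit_rate_model("accumulated_evidence", "walk_to_stop", small,
                             n_subsets=12, subset_fraction=0.3, seed=14)
        own = fit_rate_model("last_encounter", "walk_to_stop", small,
                             n_subsets=12, subset_fraction=0.3, seed=15)
        assert fit.bound_hugging_fraction >= own.bound_hugging_fraction

    def test_seed_reproducibility(self, recovery_bouts):
        small = BoutData(recovery_bouts.trajectories[:60], DT)
        a = fit_rate_model("last_encounter", "walk_to_stop", small,
                           n_subsets=5, seed=16)
        b = fit_rate_model("last_encounter", "walk_to_stop", small,
                           n_subsets=5, seed=16)
        assert a.medians == b.medians


class TestClassifyOnsets:
    def test_isolated_and_clump_labels(self):
        t = np.array([0.0, 5.0, 5.3, 5.6, 9.0])
        labels = classify_onsets(t)
        np.testing.assert_array_equal(labels["isolated"],
                                      [True, False, False, False, True])
        np.testing.assert_array_equal(labels["clump"],
                                      [False, True, True, True, False])

    def test_windows_configurable(self):
        t = np.array([0.0, 1.5, 3.0])
        assert classify_onsets(t, isolation_window=2.0)["isolated"].sum() == 0
        assert classify_onsets(t, isolation_window=1.0)["isolated"].all()


class TestModelStatistics:
    def test_constant_rate_control_curves_coincide_with_baseline(self):
        const_stop = RateModelSpec("last_encounter", "walk_to_stop",
                                   dict(lam0=0.6, dlam=0.0, tau=1.0))
        const_walk = RateModelSpec("last_encounter", "stop_to_walk",
                                   dict(lam0=0.6, dlam=0.0, tau=1.0))
        trains = [_train(rate=2.0, T=200.0, seed=9000 + i) for i in range(4)]
        stats = generate_model_statistics(const_stop, const_walk, trains,
                                          seed=17, n_repeats=3)
        g = stats["grid"]
        sel = g <= 4.0
        post = stats["curves"][("stop", "all")]
        rand = stats["curves"][("stop", "random")]
        assert np.nanmax(np.abs(post[sel] - rand[sel])) < 0.06

    def test_reset_model_post_encounter_walks_outlast_baseline(self):
        # moderate rate: at saturating encounter rates the suppression is
        # ubiquitous and post-encounter conditioning loses contrast
        trains = [_train(rate=1.5, T=200.0, seed=9100 + i) for i in range(6)]
        stats = generate_model_statistics(fitted_stop_spec(), fitted_walk_spec(),
                                          trains, seed=18, n_repeats=4)
        g = stats["grid"]
        mid = (g > 0.5) & (g < 3.0)
        post = stats["curves"][("stop", "all")]
        rand = stats["curves"][("stop", "random")]
        assert np.nanmean(post[mid] - rand[mid]) > 0.025

    def test_encounter_duration_model_shows_no_post_encounter_excess(self):
        dur_stop = RateModelSpec("encounter_duration", "walk_to_stop",
                                 dict(lam_enc=0.17, lam_blank=0.78))
        trains = [_train(rate=1.5, T=200.0, seed=9100 + i, dur=0.05)
                  for i in range(6)]
        stats = generate_model_statistics(dur_stop, fitted_walk_spec(), trains,
                                          seed=19, n_repeats=4)
        g = stats["grid"]
        mid = (g > 0.5) & (g < 3.0)
        post = stats["curves"][("stop", "all")]
        rand = stats["curves"][("stop", "random")]
        reset = generate_model_statistics(fitted_stop_spec(), fitted_walk_spec(),
                                          trains, seed=18, n_repeats=4)
        excess_dur = np.nanmean(post[mid] - rand[mid])
        excess_reset = np.nanmean(reset["curves"][("stop", "all")][mid]
                                  - reset["curves"][("stop", "random")][mid])
        assert excess_dur < excess_reset / 2

    def test_identical_models_tie_reported(self, recovery_bouts):
        small = BoutData(recovery_bouts.trajectories[:40], DT)
        spec = fitted_stop_spec()
        comp = compare_models({"a": spec, "b": spec}, small, "walk_to_stop",
                              seed=20, compute_discrepancy=False)
        assert comp["tie"] and set(comp["winners"]) == {"a", "b"}

    def test_direction_mismatch_rejected(self, recovery_bouts):
        with pytest.raises(ValueError):
            compare_models({"a": fitted_walk_spec()},
                           BoutData(recovery_bouts.trajectories[:10], DT),
                           "walk_to_stop")
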