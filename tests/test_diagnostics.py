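"""Quality metrics: CCFs, artifact index, contamination, matching,
sensitivity, power law, scalar detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from binpursuit.diagnostics import (CCF, ccf_artifact_index, contamination_rate,
                                    cross_correlogram,
                                    detection_error_closed_form, fit_powerlaw,
                                    match_neurons, match_spikes,
                                    optimal_threshold, scalar_detection_sim,
                                    sensitivity_analysis, timing_rmse)


def poisson_train(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


class TestCCF:
    def test_independent_poisson_is_flat(self):
        rng = np.random.default_rng(0)
        dur = 200.0
        a = poisson_train(20, dur, rng)
        b = poisson_train(15, dur, rng)
        ccf = cross_correlogram(a, b, 10, 0.5, dur)
        # 3-sigma Poisson bands around the baseline rate per bin
        expected_counts = a.size * 15 * 0.5e-3
        band = 3 * np.sqrt(expected_counts) / (a.size * 0.5e-3)
        assert np.all(np.abs(ccf.rate - 15) < band)
        assert ccf.baseline == pytest.approx(15, rel=0.1)

    def test_shifted_train_gives_single_peak_at_lag(self):
        rng = np.random.default_rng(1)
        a = poisson_train(10, 100, rng)
        b = a + 2.2e-3  # strictly inside the [2.0, 2.5) ms lag bin
        ccf = cross_correlogram(a, b, 10, 0.5, 100.0)
        peak = ccf.lags_ms[np.argmax(ccf.rate)]
        assert peak == pytest.approx(2.25, abs=0.26)
        assert np.sum(ccf.rate > 0.5 * ccf.rate.max()) == 1

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(2)
        dur = 50.0
        a = poisson_train(12, dur, rng)
        b = poisson_train(30, dur, rng)
        ab = cross_correlogram(a, b, 10, 0.5, dur)
        ba = cross_correlogram(b, a, 10, 0.5, dur)
        # counts(a,b at lag L) == counts(b,a at -L); rates renormalize by
        # the reference-train size
        assert np.allclose(ab.rate * a.size, (ba.rate * b.size)[::-1])

    def test_empty_reference_is_well_defined(self):
        ccf = cross_correlogram([], [1.0, 2.0], 10, 0.5, 10.0)
        assert ccf.n_ref == 0
        assert np.all(ccf.rate == 0)

    def test_window_must_be_multiple_of_bin(self):
        with pytest.raises(ValueError):
            cross_correlogram([1.0], [1.0], 10.0, 0.7)


class TestArtifactIndex:
    def _flat(self, rate=10.0):
        lags = np.arange(-19, 20) * 0.5 + 0.25
        return CCF(lags, np.full(lags.size, rate), rate, 100, 0.5)

    def test_flat_ccf_has_zero_index(self):
        assert ccf_artifact_index(self._flat()) == pytest.approx(0.0)

    def test_constructed_half_depth_notch(self):
        ccf = self._flat(10.0)
        notch = np.abs(ccf.lags_ms) <= 1.0
        ccf.rate[notch] = 5.0  # central bins at half the flank rate
        assert ccf_artifact_index(ccf, 1.0, 5.0) == pytest.approx(0.5)

    def test_scale_invariance(self):
        ccf = self._flat(10.0)
        ccf.rate[np.abs(ccf.lags_ms) <= 1.0] = 4.0
        i1 = ccf_artifact_index(ccf)
        scaled = CCF(ccf.lags_ms, 3 * ccf.rate, 3 * ccf.baseline, 100, 0.5)
        assert ccf_artifact_index(scaled) == pytest.approx(i1)

    def test_zero_baseline_is_undefined(self):
        ccf = CCF(np.array([-0.25, 0.25]), np.zeros(2), 0.0, 10, 0.5)
        assert np.isnan(ccf_artifact_index(ccf, 0.3, 0.4))


def half_rate_train():
    """Deterministic train whose occupancy-corrected in-refractory spike
    rate is exactly half the out-of-window rate (1 ms window).

    100 base spikes at 3.5 ms spacing over 385 ms; the first 20 base
    spikes are followed by an extra spike at +0.5 ms.  Occupied time
    = 80 x 1 + 20 x 1.5 = 110 ms holding the 20 in-window spikes
    (rate 20/110); free time = 275 ms holding the 100 base spikes
    (rate 100/275 = 2 x 20/110).
    """
    base = np.arange(100) * 3.5e-3
    extra = base[:20] + 0.5e-3
    return np.sort(np.concatenate([base, extra])), 0.385


class TestContamination:
    def test_constructed_half_rate_train_reads_fifty_percent(self):
        t, dur = half_rate_train()
        assert contamination_rate(t, 1.0, dur) == pytest.approx(50.0)

    def test_all_long_intervals_give_zero(self):
        t = np.arange(50) * 10e-3
        assert contamination_rate(t, 1.0, 1.0) == 0.0

    def test_poisson_train_reads_about_hundred_percent(self):
        rng = np.random.default_rng(3)
        t = poisson_train(40, 500, rng)
        c = contamination_rate(t, 2.0, 500.0)
        assert c == pytest.approx(100.0, abs=10.0)

    def test_fewer_than_two_spikes_undefined(self):
        assert np.isnan(contamination_rate([0.5], 1.0, 1.0))


class TestMatching:
    def test_identical_trains_have_zero_error(self):
        t = np.array([10, 50, 90])
        rep = match_spikes(t, t, 2)
        assert rep["error_rate"] == 0 and rep["hits"] == 3

    def test_empty_estimate_is_all_misses(self):
        rep = match_spikes([], [10, 20], 2)
        assert rep["error_rate"] == 1.0
        assert rep["misses"] == 2 and rep["false_positives"] == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_matching_count_equals_hungarian_oracle(self, data):
        n_e = data.draw(st.integers(0, 15))
        n_t = data.draw(st.integers(0, 15))
        est = np.sort(data.draw(st.lists(
            st.integers(0, 200), min_size=n_e, max_size=n_e, unique=True)))
        tru = np.sort(data.draw(st.lists(
            st.integers(0, 200), min_size=n_t, max_size=n_t, unique=True)))
        tol = data.draw(st.integers(0, 10))
        hits = match_spikes(np.asarray(est, float), np.asarray(tru, float),
                            tol)["hits"]
        if len(est) and len(tru):
            ok = np.abs(np.subtract.outer(est, tru)) <= tol
            r, c = linear_sum_assignment(-ok.astype(float))
            oracle = int(ok[r, c].sum())
        else:
            oracle = 0
        assert hits == oracle

    def test_neuron_matching_resolves_identity_permutation(self):
        from binpursuit.events import SpikeEventSet
        tru = SpikeEventSet([0, 0, 1, 1], [100, 300, 200, 400],
                            n_neurons=2, n_bins=1000)
        est = SpikeEventSet([1, 1, 0, 0], [100, 300, 201, 401],
                            n_neurons=2, n_bins=1000)
        rep = match_neurons(est, tru, 2)
        assert rep["mapping"] == {0: 1, 1: 0}
        assert rep["error_rate"] == 0

    def test_timing_rmse_ignores_constant_registration_offset(self):
        from binpursuit.events import SpikeEventSet
        rng = np.random.default_rng(4)
        bins = np.sort(rng.choice(10_000, 50, replace=False)) + 20
        jitter = rng.normal(0, 0.1, 50)
        tru = SpikeEventSet(np.zeros(50, int), bins, n_neurons=1, n_bins=11_000)
        est = SpikeEventSet(np.zeros(50, int), bins + 3, jitter,
                            n_neurons=1, n_bins=11_000)
        rmse = timing_rmse(est, tru, 10)
        assert rmse == pytest.approx(np.sqrt(np.mean(
            (jitter - np.median(jitter)) ** 2)), rel=1e-6)


class TestSensitivity:
    def test_counts_recorded_and_slope_estimated(self):
        def count_fn(j, m):
            return int(round(1000 * m ** -2.0))
        curve = sensitivity_analysis(count_fn, 0, [0.3, 1.0, 3.2])
        assert curve.sensitivity == pytest.approx(2.0, rel=0.01)
        assert np.all(np.diff(curve.counts) <= 0)

    def test_zero_count_flagged_as_nan(self):
        curve = sensitivity_analysis(lambda j, m: 0, 0, [0.3, 1.0, 3.2])
        assert np.isnan(curve.sensitivity)

    def test_narrow_multiplier_range_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis(lambda j, m: 1, 0, [0.8, 1.2])


class TestPowerLaw:
    def test_exact_recovery(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        fit = fit_powerlaw(x, 2.0 * x ** 1.5)
        assert fit.exponent == pytest.approx(1.5, abs=1e-12)
        assert fit.prefactor == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_predictor_monotone_for_positive_exponent(self):
        fit = fit_powerlaw([1, 2, 4, 8], [1, 2.2, 3.9, 8.5])
        s = np.linspace(0.1, 10, 50)
        assert np.all(np.diff(fit.predict(s)) > 0)

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 5, 20)
        y = 3 * x ** 0.7 * np.exp(rng.normal(0, 0.2, 20))
        fit = fit_powerlaw(x, y)
        lx, ly = np.log(x), np.log(y)
        slope = (np.sum((lx - lx.mean()) * (ly - ly.mean()))
                 / np.sum((lx - lx.mean()) ** 2))
        intercept = ly.mean() - slope * lx.mean()
        assert fit.exponent == pytest.approx(slope, abs=1e-10)
        assert np.log(fit.prefactor) == pytest.approx(intercept, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw([1, 2], [1, 2])


class TestScalarDetection:
    def test_very_low_threshold_detects_everything(self):
        out = scalar_detection_sim(3.0, 0.1, [-50.0], n_trials=10_000, seed=6)
        assert out["detections"][0] == 1.0

    def test_optimal_threshold_matches_gaussian_log_odds(self):
        snr, p = 3.0, 0.05
        thr_star = optimal_threshold(snr, p)
        thresholds = np.linspace(thr_star - 1.5, thr_star + 1.5, 61)
        out = scalar_detection_sim(snr, p, thresholds, n_trials=200_000, seed=7)
        best = thresholds[np.argmin(out["errors"])]
        assert abs(best - thr_star) < 0.3
        # error at the closed-form optimum within 3 MC standard errors
        k = np.argmin(np.abs(thresholds - thr_star))
        exact = detection_error_closed_form(thresholds[k], snr, p)
        assert abs(out["errors"][k] - exact) < 3 * out["mc_se"][k]


class TestArtifactInjection:
    def test_deleting_synchronous_spikes_raises_index_monotonically(self):
        # start from two synchronized trains and delete a growing
        # fraction of the near-coincident partner spikes: the zero-lag
        # notch (and hence the index) must deepen monotonically
        rng = np.random.default_rng(8)
        dur = 300.0
        a = poisson_train(20, dur, rng)
        b = poisson_train(20, dur, rng)
        take = rng.random(a.size) < 0.3
        b = np.sort(np.concatenate([b, a[take] + rng.uniform(
            -5e-3, 5e-3, take.sum())]))
        near = np.min(np.abs(np.subtract.outer(b, a)), axis=1) < 1e-3
        near_idx = np.where(near)[0]
        indices = []
        for f in (0.0, 0.5, 1.0):
            kill = near_idx[: int(f * near_idx.size)]
            bb = np.delete(b, kill)
            ccf = cross_correlogram(a, bb, 10, 0.5, dur)
            indices.append(ccf_artifact_index(ccf))
        assert indices[0] < indices[1] < indices[2]
        assert indices[2] > 0.3
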