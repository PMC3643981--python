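"""Greedy binary pursuit: prior weights, gains, solver, correction, blocks."""

import numpy as np
import pytest

from binpursuit.events import SpikeEventSet
from binpursuit.pursuit import (PursuitConfig, PursuitEngine,
                                compute_prior_weights, delta_loglik,
                                greedy_solve, plan_blocks, process_blocks)
from binpursuit.simulate import render_recording
from binpursuit.waveforms import compute_derivatives


def objective(data, ws, events, theta):
    """Brute-force negative log-posterior: 1/2||V - W*X||^2 + sum theta."""
    from binpursuit.waveforms import predict
    resid = data - predict(ws, events, data.shape[1])
    return 0.5 * np.sum(resid ** 2) + np.sum(theta[events.neuron_id])


class TestPriorWeights:
    def test_even_odds_gives_zero_penalty(self):
        assert compute_prior_weights(0.5, 1.0)[0] == 0.0

    def test_one_in_five_hundred(self):
        # 40 sp/s at 20 kHz: one spike per 500 bins, theta = log(499)
        theta = compute_prior_weights(1 / 500, 1.0)[0]
        assert theta == pytest.approx(np.log(499), abs=1e-12)
        assert theta == pytest.approx(6.213, abs=5e-4)

    def test_multiplier_scales_linearly(self):
        assert (compute_prior_weights(0.01, 6.0)
                == pytest.approx(6 * compute_prior_weights(0.01, 1.0)))

    def test_strictly_decreasing_in_p(self):
        p = np.linspace(0.001, 0.499, 50)
        theta = compute_prior_weights(p, 1.0)
        assert np.all(np.diff(theta) < 0)

    @pytest.mark.parametrize("p", [0.0, -0.1, 0.6, 1.0])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            compute_prior_weights(p)


class TestDeltaLoglik:
    def test_perfect_match_gain_is_half_norm(self, tiny_templates):
        ws, _ = tiny_templates
        w = ws.templates[0]
        resid = np.zeros((8, 100))
        resid[:, 20:50] = w
        b = np.sum(w ** 2)
        assert delta_loglik(resid, w, 0.0, 20) == pytest.approx(b / 2)

    def test_zero_residual_gain_is_negative(self, tiny_templates):
        ws, _ = tiny_templates
        w = ws.templates[0]
        b = np.sum(w ** 2)
        g = delta_loglik(np.zeros((8, 100)), w, 3.0, 10)
        assert g == pytest.approx(-b / 2 - 3.0)

    def test_footprint_past_segment_rejected(self, tiny_templates):
        ws, _ = tiny_templates
        with pytest.raises(ValueError):
            delta_loglik(np.zeros((8, 100)), ws.templates[0], 0.0, 80)

    def test_matches_brute_force_objective_difference(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(0)
        data = rng.standard_normal((8, 200))
        theta = np.array([2.0, 3.0])
        without = SpikeEventSet.empty(2, 200)
        with_spike = SpikeEventSet([0], [60], n_neurons=2, n_bins=200)
        dl = delta_loglik(data, ws.templates[0], theta[0], 60)
        brute = objective(data, ws, without, theta) - objective(
            data, ws, with_spike, theta)
        assert dl == pytest.approx(brute, rel=1e-10)


class TestGreedySolve:
    def test_pure_noise_with_large_penalty_finds_nothing(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 2000))
        ev, _ = greedy_solve(data, ws, np.full(2, 1e4),
                             PursuitConfig(correction=()))
        assert len(ev) == 0

    def test_single_rendered_spike_recovered_exactly(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(2)
        truth = SpikeEventSet([0], [700], n_neurons=2, n_bins=2000)
        rec = render_recording(ws, truth, rng.standard_normal((8, 2000)),
                               20000.0)
        theta = compute_prior_weights(np.full(2, 1 / 2000), 6.0)
        ev, _ = greedy_solve(rec.data, ws, theta, PursuitConfig(correction=()))
        assert len(ev) == 1
        assert ev.neuron_id[0] == 0 and ev.bin[0] == 700

    def test_synchronous_pair_both_recovered(self, tiny_templates):
        # the central clustering failure case: two neurons firing in the
        # same bin must both be found from the superposed waveform
        ws, _ = tiny_templates
        rng = np.random.default_rng(3)
        truth = SpikeEventSet([0, 1], [700, 700], n_neurons=2, n_bins=2000)
        rec = render_recording(ws, truth, rng.standard_normal((8, 2000)),
                               20000.0)
        theta = compute_prior_weights(np.full(2, 1 / 2000), 6.0)
        ev, _ = greedy_solve(rec.data, ws, theta, PursuitConfig(correction=()))
        assert len(ev) == 2
        assert sorted(ev.neuron_id.tolist()) == [0, 1]
        assert np.all(np.abs(ev.bin - 700) <= 1)

    def test_non_finite_voltage_rejected(self, tiny_templates):
        ws, _ = tiny_templates
        data = np.zeros((8, 200))
        data[0, 50] = np.nan
        with pytest.raises(ValueError):
            greedy_solve(data, ws, np.ones(2))

    def test_incremental_gains_match_brute_force(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(4)
        truth_bins = [100, 130, 400, 405, 900]
        truth_ids = [0, 1, 0, 1, 0]
        truth = SpikeEventSet(truth_ids, truth_bins, n_neurons=2, n_bins=2000)
        rec = render_recording(ws, truth, rng.standard_normal((8, 2000)),
                               20000.0)
        theta = compute_prior_weights(np.full(2, 1 / 500), 1.0)
        ev, info = greedy_solve(rec.data, ws, theta,
                                PursuitConfig(correction=()),
                                track_history=True)
        # replay the flip history against from-scratch objective evaluation
        cur = SpikeEventSet.empty(2, 2000)
        obj = objective(rec.data, ws, cur, theta)
        for flip in info["history"]:
            key = (flip.neuron, flip.bin)
            have = set(zip(cur.neuron_id.tolist(), cur.bin.tolist()))
            if flip.insert:
                have.add(key)
            else:
                have.remove(key)
            ids, bins = zip(*sorted(have)) if have else ((), ())
            cur = SpikeEventSet(list(ids), list(bins), n_neurons=2,
                                n_bins=2000)
            new_obj = objective(rec.data, ws, cur, theta)
            assert flip.total_gain == pytest.approx(obj - new_obj, rel=1e-9,
                                                    abs=1e-9)
            obj = new_obj

    def test_local_optimality_at_termination(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(5)
        truth = SpikeEventSet([0, 1, 0], [100, 105, 600], n_neurons=2,
                              n_bins=1500)
        rec = render_recording(ws, truth, rng.standard_normal((8, 1500)),
                               20000.0)
        theta = compute_prior_weights(np.full(2, 1 / 500), 1.0)
        ev, _ = greedy_solve(rec.data, ws, theta, PursuitConfig(correction=()))
        base = objective(rec.data, ws, ev, theta)
        have = set(zip(ev.neuron_id.tolist(), ev.bin.tolist()))
        tol = 1e-9 * ws.norms_sq().max()
        for j in range(2):
            for i in range(1500 - 30 + 1):
                trial = set(have)
                if (j, i) in trial:
                    trial.remove((j, i))
                else:
                    trial.add((j, i))
                ids, bins = zip(*sorted(trial)) if trial else ((), ())
                alt = SpikeEventSet(list(ids), list(bins), n_neurons=2,
                                    n_bins=1500)
                assert objective(rec.data, ws, alt, theta) >= base - tol


class TestVariabilityCorrection:
    def test_exact_template_gives_zero_coefficients(self, tiny_templates):
        ws, _ = tiny_templates
        cfg = PursuitConfig(correction=("time", "amp", "width"),
                            gamma_factor=0.0)
        truth = SpikeEventSet([0], [500], n_neurons=2, n_bins=1500)
        rec = render_recording(ws, truth, np.zeros((8, 1500)), 20000.0)
        ev, _ = greedy_solve(rec.data, ws, np.full(2, 1.0), cfg)
        assert len(ev) == 1
        assert abs(ev.subbin_offset[0]) < 1e-8
        assert abs(ev.amp_coef[0]) < 1e-8
        assert abs(ev.width_coef[0]) < 1e-8

    def test_shifted_template_recovers_offset(self, tiny_templates):
        ws, _ = tiny_templates
        wsd = compute_derivatives(ws)
        tau = 0.3
        truth = SpikeEventSet([0], [500], [tau], n_neurons=2, n_bins=1500)
        rec = render_recording(wsd, truth, np.zeros((8, 1500)), 20000.0)
        ev, _ = greedy_solve(rec.data, wsd, np.full(2, 1.0),
                             PursuitConfig(correction=("time",),
                                           gamma_factor=0.0))
        assert len(ev) == 1
        assert ev.subbin_offset[0] == pytest.approx(tau, abs=0.05)

    def test_large_ridge_shrinks_coefficients_to_zero(self, tiny_templates):
        ws, _ = tiny_templates
        wsd = compute_derivatives(ws)
        truth = SpikeEventSet([0], [500], [0.3], n_neurons=2, n_bins=1500)
        rec = render_recording(wsd, truth, np.zeros((8, 1500)), 20000.0)
        ev, _ = greedy_solve(rec.data, wsd, np.full(2, 1.0),
                             PursuitConfig(correction=("time",),
                                           gamma_factor=1e9))
        assert abs(ev.subbin_offset[0]) < 1e-6

    def test_coefficients_match_dense_ridge_oracle(self, tiny_templates):
        ws, _ = tiny_templates
        wsd = compute_derivatives(ws)
        cfg = PursuitConfig(correction=("time", "amp", "width"),
                            gamma_factor=0.05, coef_clamp=10.0)
        rng = np.random.default_rng(6)
        noise = 0.1 * rng.standard_normal((8, 1500))
        truth = SpikeEventSet([0], [500], [0.2], [0.1], [-0.1],
                              n_neurons=2, n_bins=1500)
        rec = render_recording(wsd, truth, noise, 20000.0)
        ev, info = greedy_solve(rec.data, wsd, np.full(2, 1.0), cfg)
        assert len(ev) == 1
        i = ev.bin[0]
        # oracle: ridge regression of the post-subtraction residual onto D
        seg = (rec.data[:, i:i + 30] - wsd.templates[0]).ravel()
        D = np.stack([-wsd.d_time[0].ravel(), wsd.d_amp[0].ravel(),
                      wsd.d_width[0].ravel()], axis=1)
        gamma = cfg.gamma_factor * np.trace(D.T @ D) / 3
        beta = np.linalg.solve(D.T @ D + gamma * np.eye(3), D.T @ seg)
        assert ev.subbin_offset[0] == pytest.approx(beta[0], abs=1e-10)
        assert ev.amp_coef[0] == pytest.approx(beta[1], abs=1e-10)
        assert ev.width_coef[0] == pytest.approx(beta[2], abs=1e-10)

    def test_singular_design_with_zero_ridge_raises(self, tiny_templates):
        # duplicating a derivative column makes D'D singular
        ws, _ = tiny_templates
        wsd = compute_derivatives(ws)
        wsd.d_width = wsd.d_amp.copy()
        with pytest.raises(np.linalg.LinAlgError, match="gamma"):
            PursuitEngine(wsd, np.ones(2),
                          PursuitConfig(correction=("amp", "width"),
                                        gamma_factor=0.0))


class TestBlocks:
    def test_block_plan_matches_printed_vector_length(self):
        # 512 electrodes at 20 kHz in 1 s blocks: 10,240,000 samples/block
        blocks = plan_blocks(20_000 * 10, 20_000.0, 1.0, 30)
        start, stop, lo, hi = blocks[3]
        assert 512 * (stop - start) == 10_240_000
        assert lo == start - 30 and hi == stop + 30

    def test_empty_recording_gives_empty_result(self, tiny_templates):
        ws, _ = tiny_templates
        ev, _ = process_blocks(np.zeros((8, 50_000)), ws, np.ones(2), 20000.0,
                               PursuitConfig(block_s=1.0, correction=()))
        assert len(ev) == 0

    def test_boundary_spike_found_exactly_once(self, tiny_templates):
        ws, _ = tiny_templates
        rng = np.random.default_rng(7)
        fs, block = 20000.0, 1.0
        bins = [19_990, 20_010, 5_000, 33_000]  # two straddle the 1 s edge
        truth = SpikeEventSet([0, 1, 0, 1], bins, n_neurons=2, n_bins=40_000)
        rec = render_recording(ws, truth, rng.standard_normal((8, 40_000)), fs)
        theta = compute_prior_weights(np.full(2, 1 / 2000), 6.0)
        cfg = PursuitConfig(block_s=block, correction=())
        ev, _ = process_blocks(rec.data, ws, theta, fs, cfg)
        single, _ = greedy_solve(rec.data, ws, theta, cfg)
        assert sorted(ev.bin.tolist()) == sorted(truth.bin.tolist())
        assert sorted(ev.bin.tolist()) == sorted(single.bin.tolist())

    def test_too_short_block_rejected(self):
        with pytest.raises(ValueError):
            plan_blocks(10_000, 20000.0, 0.002, 30)

    def test_raising_multiplier_weakly_decreases_spike_count(self, small_sim):
        from binpursuit.whitening import whiten_pipeline
        cfg, rec, truth = small_sim
        data_w, ws_w, _ = whiten_pipeline(rec.data, truth.spikes, cfg.taps)
        p = np.clip(truth.spikes.rates(), 1e-9, 0.499)
        counts = []
        for mult in (1.0, 3.0, 6.0, 12.0, 24.0):
            theta = compute_prior_weights(p, mult)
            ev, _ = process_blocks(data_w, ws_w, theta, rec.sampling_rate_hz,
                                   PursuitConfig(correction=()))
            counts.append(len(ev))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
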