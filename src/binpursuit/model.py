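"""Model/Results interface tying the full sorting procedure together.

``SpikeSortingModel`` holds a recording plus an initial spike-train
estimate and exposes ``fit()``, which runs the coordinate-ascent MAP
procedure: template regression, subset-selection pruning, noise
estimation and two-stage whitening, plug-in Bernoulli priors, and greedy
binary pursuit in blocks, optionally iterating waveform/spike updates.
``fit`` returns a ``SpikeSortingResults`` carrying the spike events,
templates (raw and whitened space), noise model, objective trace and
per-neuron quality summary, with hooks for the prior-sensitivity
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diagnostics as dg
from .clustering import cluster_initialize
from .events import SpikeEventSet, write_spikes
from .io import Recording
from .pursuit import PursuitConfig, PursuitEngine, compute_prior_weights, process_blocks
from .waveforms import (WaveformSet, estimate_waveforms, noise_mad_scale,
                        prune_waveforms)
from .whitening import NoiseModel, compute_residual, whiten_pipeline


@dataclass
class FitConfig:
    """All tunables of the sorting procedure."""

    taps: int = 30
    prune_a: float = 1.0
    window_bins: int = 16
    prior_multiplier: float = 6.0
    rounds: int = 1
    refractory_ms: float = 1.5
    pursuit: PursuitConfig = field(default_factory=PursuitConfig)


class SpikeSortingModel:
    """MAP spike sorter for a multi-electrode recording.

    Parameters
    ----------
    recording : Recording
        The voltage data.
    init_events : SpikeEventSet
        Initial spike-train estimate (typically from the clustering
        initializer) defining the neuron count and seed spike times.
    config : FitConfig, optional
    """

    def __init__(self, recording: Recording, init_events: SpikeEventSet,
                 config: FitConfig | None = None, **kwargs):
        self.recording = recording
        self.init_events = init_events
        cfg = config or FitConfig()
        if kwargs:
            cfg = replace(cfg, **kwargs)
        self.config = cfg

    @classmethod
    def from_clustering(cls, recording: Recording, config: FitConfig | None = None,
                        seed: int = 0, k: int | None = None,
                        init_kwargs: dict | None = None, **kwargs):
        """Build the model with its initializer run internally."""
        init = cluster_initialize(recording, k=k, seed=seed,
                                  **(init_kwargs or {}))
        return cls(recording, init.events, config, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, rounds: int | None = None) -> "SpikeSortingResults":
        cfg = self.config
        rounds = cfg.rounds if rounds is None else rounds
        rec = self.recording
        data = np.asarray(rec.data, float)
        events = self.init_events
        trace: list[dict] = []

        # round 1: waveforms -> prune -> noise -> whiten -> priors -> pursuit
        ws_raw = estimate_waveforms(data, events, cfg.taps)
        resid = compute_residual(data, ws_raw, events)
        ws_raw = prune_waveforms(ws_raw, noise_mad_scale(resid), cfg.prune_a)
        data_w, ws_w, noise_model = whiten_pipeline(
            data, events, cfg.taps, window_bins=cfg.window_bins,
            prune_a=cfg.prune_a, ws=ws_raw)
        p = np.clip(events.rates(), 0.5 / events.n_bins, 0.499)
        theta = compute_prior_weights(p, cfg.prior_multiplier)
        events_hat, info = process_blocks(data_w, ws_w, theta,
                                          rec.sampling_rate_hz, cfg.pursuit)
        trace.append({"round": 1, "stage": "pursuit",
                      "objective": self._objective(data_w, ws_w, events_hat, theta),
                      "n_spikes": len(events_hat), "n_flips": info["n_flips"]})

        # later rounds: alternate waveform / spike updates with the noise
        # model and priors held fixed (pure coordinate descent)
        for rnd in range(2, rounds + 1):
            ws_w = self._refit_whitened(data_w, events_hat, ws_w, cfg)
            obj_w = self._objective(data_w, ws_w, events_hat, theta)
            trace.append({"round": rnd, "stage": "waveforms",
                          "objective": obj_w, "n_spikes": len(events_hat)})
            proposal, info = process_blocks(data_w, ws_w, theta,
                                            rec.sampling_rate_hz, cfg.pursuit)
            obj_p = self._objective(data_w, ws_w, proposal, theta)
            # greedy pursuit restarts from an empty spike train; accept its
            # local optimum only if it does not increase the objective over
            # the previous spike set, preserving coordinate descent
            if obj_p <= obj_w:
                events_hat = proposal
            else:
                obj_p = obj_w
            trace.append({"round": rnd, "stage": "pursuit",
                          "objective": obj_p, "n_spikes": len(events_hat),
                          "n_flips": info["n_flips"]})
        return SpikeSortingResults(self, events_hat, ws_raw, ws_w, noise_model,
                                   p, theta, trace, data_w)

    @staticmethod
    def _objective(data_w, ws_w, events, theta) -> float:
        """Whitened-space negative log-posterior (up to constants)."""
        resid = compute_residual(data_w, ws_w, events)
        return 0.5 * float(np.sum(resid ** 2)) + float(
            np.sum(theta[events.neuron_id]))

    @staticmethod
    def _refit_whitened(data_w, events, ws_prev, cfg) -> WaveformSet:
        """Re-estimate whitened templates on the round-1 support.

        The electrode support is held fixed (constrained least squares)
        rather than re-pruned, so the waveform update can only decrease
        the quadratic objective.  Neurons that lost all spikes keep
        their previous template (they contribute nothing anyway).
        """
        counts = events.counts()
        live = np.flatnonzero(counts > 0)
        if live.size == 0:
            return ws_prev
        remap = -np.ones(events.n_neurons, int)
        remap[live] = np.arange(live.size)
        sub = SpikeEventSet(remap[events.neuron_id], events.bin,
                            events.subbin_offset, events.amp_coef,
                            events.width_coef, n_neurons=live.size,
                            n_bins=events.n_bins)
        ws_sub = estimate_waveforms(data_w, sub, cfg.taps,
                                    support_mask=ws_prev.support_mask[live])
        out = ws_prev.copy()
        out.templates[live] = ws_sub.templates
        out.support_mask[live] = ws_sub.support_mask
        out.alignment_tap[live] = ws_sub.alignment_tap
        return WaveformSet(out.templates, out.alignment_tap, out.support_mask)


class SpikeSortingResults:
    """Fitted spike trains plus everything needed to assess them."""

    def __init__(self, model: SpikeSortingModel, events: SpikeEventSet,
                 waveforms_raw: WaveformSet, waveforms_whitened: WaveformSet,
                 noise_model: NoiseModel, p: np.ndarray, theta: np.ndarray,
                 objective_trace: list, data_whitened: np.ndarray):
        self.model = model
        self.events = events
        self.waveforms_raw = waveforms_raw
        self.waveforms_whitened = waveforms_whitened
        self.noise_model = noise_model
        self.p = p
        self.theta = theta
        self.objective_trace = objective_trace
        self._data_w = data_whitened

    # -- basic accessors -------------------------------------------------
    @property
    def sampling_rate_hz(self) -> float:
        return self.model.recording.sampling_rate_hz

    @property
    def n_neurons(self) -> int:
        return self.events.n_neurons

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]["objective"]

    def spike_times_s(self, neuron: int) -> np.ndarray:
        return self.events.times_s(self.sampling_rate_hz, neuron)

    # -- diagnostics -----------------------------------------------------
    def contamination(self, neuron: int,
                      refractory_ms: float | None = None) -> float:
        refractory_ms = refractory_ms or self.model.config.refractory_ms
        return dg.contamination_rate(self.spike_times_s(neuron), refractory_ms,
                                     self.model.recording.duration_s)

    def ccf(self, a: int, b: int, window_ms: float = 10.0,
            bin_ms: float = 0.5) -> dg.CCF:
        return dg.cross_correlogram(self.spike_times_s(a),
                                    self.spike_times_s(b), window_ms, bin_ms,
                                    self.model.recording.duration_s)

    def error_vs_truth(self, truth: SpikeEventSet,
                       tol_ms: float = 0.5) -> dict:
        tol_bins = tol_ms * 1e-3 * self.sampling_rate_hz
        return dg.match_neurons(self.events, truth, tol_bins)

    def respike_count(self, neuron: int, multiplier: float) -> int:
        """Spike count of one neuron after re-running binary pursuit with
        only that neuron's penalty scaled by ``multiplier``."""
        theta = self.theta.copy()
        theta[neuron] *= multiplier
        ev, _ = process_blocks(self._data_w, self.waveforms_whitened, theta,
                               self.sampling_rate_hz,
                               self.model.config.pursuit)
        return int(ev.counts()[neuron])

    def sensitivity(self, neuron: int, multipliers=None,
                    step: float = 2.0) -> dg.SensitivityCurve:
        """Prior-sensitivity curve (see the diagnostics module)."""
        if multipliers is None:
            multipliers = np.geomspace(1 / 3.2, 3.2, 5)
        return dg.sensitivity_analysis(self.respike_count, neuron,
                                       multipliers, 1.0, step)

    # -- presentation ----------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-neuron table: spike counts, rates, prior penalties and
        refractory contamination."""
        fs = self.sampling_rate_hz
        dur = self.model.recording.duration_s
        counts = self.events.counts()
        rows = []
        for j in range(self.n_neurons):
            rows.append({
                "neuron": j,
                "n_spikes": int(counts[j]),
                "rate_hz": counts[j] / dur,
                "p_init": self.p[j],
                "theta": self.theta[j],
                "template_norm": float(np.sqrt(
                    self.waveforms_whitened.norms_sq()[j])),
                "contamination_pct": self.contamination(j),
            })
        return pd.DataFrame(rows).set_index("neuron")

    def save(self, outdir) -> None:
        """Write spikes (TSV), templates and noise model (NPZ), and the
        objective trace (JSON) to a directory."""
        import json
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spikes(self.events.sorted(), outdir / "spikes.tsv")
        np.savez(outdir / "waveforms.npz",
                 templates=self.waveforms_raw.templates,
                 templates_whitened=self.waveforms_whitened.templates,
                 support_mask=self.waveforms_whitened.support_mask,
                 alignment_tap=self.waveforms_whitened.alignment_tap)
        self.noise_model.save(outdir / "noise_model.npz")
        (outdir / "objective_trace.json").write_text(
            json.dumps(self.objective_trace, indent=1))


def coordinate_ascent(recording: Recording, init_events: SpikeEventSet,
                      config: FitConfig | None = None,
                      **kwargs) -> SpikeSortingResults:
    """Functional entry point: build the model and fit it."""
    return SpikeSortingModel(recording, init_events, config, **kwargs).fit()
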