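"""Ground-truth simulator for multi-electrode extracellular recordings.

Generates recordings under exactly the generative model the sorter
assumes: each neuron contributes a fixed spatiotemporal waveform at every
spike, spikes are independent Bernoulli draws per sample bin (with
optional refractory enforcement and injected pairwise synchrony), and the
background is zero-mean Gaussian noise with separable space-time
correlation (AR(1) in time on each electrode, exponential-decay
correlation across electrodes).

The waveform forward model is a stand-in: the field does not prescribe
one, so templates are biphasic gamma-difference shapes whose amplitude
decays exponentially with electrode distance from the neuron.  Synchrony
is injected by copying spikes from a master train into a partner train
with uniform jitter; this reproduces the statistical signature (elevated
cross-correlation with a sub-millisecond coincident core) without
claiming a biophysical mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .events import SpikeEventSet
from .io import Recording
from .waveforms import WaveformSet, compute_derivatives, predict

_BURN_IN = 256


# ---------------------------------------------------------------------------
# geometry and waveform templates
# ---------------------------------------------------------------------------

def grid_geometry(n_rows: int, n_cols: int, spacing: float = 1.0,
                  kind: str = "square") -> np.ndarray:
    """Electrode coordinates for a square or hexagonal grid (E x 2)."""
    if kind not in ("square", "hex"):
        raise ValueError(f"unknown grid kind {kind!r}")
    coords = []
    row_h = spacing if kind == "square" else spacing * np.sqrt(3) / 2
    for r in range(n_rows):
        x0 = 0.0 if (kind == "square" or r % 2 == 0) else spacing / 2
        for c in range(n_cols):
            coords.append((x0 + c * spacing, r * row_h))
    return np.asarray(coords, dtype=float)


def biphasic_shape(taps: int = 30, peak_tap: float | None = None,
                   trough_peak_ratio: float = 0.4, width: float = 1.0) -> np.ndarray:
    """Unit biphasic action-potential shape (negative-going, min = -1).

    Difference of two gamma-shaped lobes: a fast depolarization trough at
    ``peak_tap`` followed by a slower repolarization bump whose height is
    ``trough_peak_ratio`` of the trough.  ``width`` dilates both lobes.
    """
    if taps < 4:
        raise ValueError("need at least 4 taps")
    if not np.all(np.isfinite([trough_peak_ratio, width])) or width <= 0:
        raise ValueError("non-finite or non-positive shape parameters")
    t = np.arange(taps, dtype=float)
    if peak_tap is None:
        peak_tap = taps / 3.0
    # high-order gamma lobes: a sharp ~0.2 ms depolarization trough
    # followed by a slower, broader repolarization bump
    k1, k2 = 36.0, 14.0
    th1 = width * peak_tap / (k1 - 1)
    th2 = width * (peak_tap + taps / 6.0) / (k2 - 1)

    def lobe(k, th):
        g = t ** (k - 1) * np.exp(-t / th)
        return g / g.max()

    shape = -lobe(k1, th1) + trough_peak_ratio * lobe(k2, th2)
    shape /= np.abs(shape.min())
    return shape


def make_waveform(geometry: np.ndarray, position, amplitude: float,
                  decay_lambda: float = 1.2, taps: int = 30,
                  **shape_params) -> np.ndarray:
    """Spatiotemporal waveform tensor (electrodes x taps) for one neuron.

    The biphasic shape is scaled on each electrode by
    ``exp(-dist(electrode, position) / decay_lambda)``; a neuron sitting
    on an electrode therefore reaches exactly ``-amplitude`` at its
    trough there.
    """
    geometry = np.atleast_2d(np.asarray(geometry, float))
    if geometry.size == 0:
        raise ValueError("geometry must be non-empty")
    position = np.asarray(position, float)
    if not (np.isfinite(amplitude) and np.all(np.isfinite(position))
            and np.isfinite(decay_lambda)):
        raise ValueError("non-finite waveform parameters")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    shape = biphasic_shape(taps=taps, **shape_params)
    dist = np.linalg.norm(geometry - position[None, :], axis=1)
    scale = amplitude * np.exp(-dist / decay_lambda)
    return scale[:, None] * shape[None, :]


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass
class SyncPair:
    """Injected pairwise synchrony: each spike of ``master`` is copied
    into ``partner`` with probability ``prob``, jittered uniformly by an
    integer in [-jitter_bins, +jitter_bins]."""

    master: int
    partner: int
    prob: float
    jitter_bins: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("coincidence probability must be in [0, 1]")
        if self.jitter_bins < 0:
            raise ValueError("jitter must be >= 0 bins")


def _enforce_refractory(bins: np.ndarray, refrac_bins: int) -> np.ndarray:
    """Delete the later spike of any pair closer than ``refrac_bins``."""
    if bins.size == 0 or refrac_bins <= 0:
        return bins
    keep = [int(bins[0])]
    for b in bins[1:]:
        if b - keep[-1] > refrac_bins:
            keep.append(int(b))
    return np.asarray(keep, dtype=np.int64)


def sample_spike_trains(
    rates,
    duration_s: float,
    sampling_rate_hz: float,
    refractory_ms: float = 1.5,
    sync_spec=(),
    seed: int = 0,
    n_waveform_taps: int = 30,
) -> SpikeEventSet:
    """Bernoulli spike trains with refractory enforcement and synchrony.

    Each bin of each neuron is an independent Bernoulli draw with
    ``p_j = rate_j / sampling_rate``; at 20 kHz a 40 sp/s neuron spikes on
    average once per 500 bins.  Refractory violations are resolved by
    deleting the later spike; synchrony is then injected per ``sync_spec``.
    Spike bins are restricted to [0, n_bins - n_waveform_taps] so a full
    waveform always fits in the recording.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if np.any(rates >= sampling_rate_hz):
        raise ValueError("rate must be below the sampling rate")
    if refractory_ms < 0:
        raise ValueError("refractory must be >= 0")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s * sampling_rate_hz))
    n_valid = n_bins - n_waveform_taps + 1
    if n_valid <= 0:
        raise ValueError("recording shorter than one waveform")
    refrac_bins = int(round(refractory_ms * 1e-3 * sampling_rate_hz))
    trains: list[np.ndarray] = []
    for p in rates / sampling_rate_hz:
        bins = np.flatnonzero(rng.random(n_valid) < p) if p > 0 else np.zeros(0, int)
        trains.append(_enforce_refractory(bins, refrac_bins))
    for pair in sync_spec:
        pair = pair if isinstance(pair, SyncPair) else SyncPair(*pair)
        master = trains[pair.master]
        take = rng.random(master.size) < pair.prob
        jit = (rng.integers(-pair.jitter_bins, pair.jitter_bins + 1, master.size)
               if pair.jitter_bins else np.zeros(master.size, int))
        injected = np.clip(master[take] + jit[take], 0, n_valid - 1)
        injected = np.unique(injected)
        # keep injected spikes; drop pre-existing partner spikes that fall
        # inside an injected spike's refractory window
        old = trains[pair.partner]
        if injected.size and old.size and refrac_bins > 0:
            d = np.abs(old[:, None] - injected[None, :]).min(axis=1)
            old = old[d > refrac_bins]
        merged = np.unique(np.concatenate([old, injected]))
        trains[pair.partner] = merged
    neuron_id = np.concatenate(
        [np.full(tr.size, j, dtype=np.int64) for j, tr in enumerate(trains)]
    ) if trains else np.zeros(0, int)
    bins = np.concatenate(trains) if trains else np.zeros(0, int)
    return SpikeEventSet(neuron_id, bins, n_neurons=rates.size, n_bins=n_bins)


def add_variability(events: SpikeEventSet, seed: int,
                    subbin: bool = True, amp_sd: float = 0.0,
                    width_sd: float = 0.0, clamp: float = 0.5) -> SpikeEventSet:
    """Attach ground-truth per-event Taylor coefficients.

    Sub-bin offsets are drawn uniform in (-0.5, 0.5) bins; amplitude and
    width coefficients are Gaussian with the given standard deviations,
    clamped to +-``clamp``.
    """
    rng = np.random.default_rng(seed)
    n = len(events)
    out = events.select(slice(None))
    if subbin:
        out.subbin_offset = rng.uniform(-0.5, 0.5, n)
    if amp_sd > 0:
        out.amp_coef = np.clip(rng.normal(0, amp_sd, n), -clamp, clamp)
    if width_sd > 0:
        out.width_coef = np.clip(rng.normal(0, width_sd, n), -clamp, clamp)
    return out


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Separable space-time Gaussian noise specification.

    ``ar_coeff``: AR(1) coefficient per electrode (scalar broadcast),
    strictly inside the unit circle.  ``spatial_scale``: correlation
    length of the exponential cross-electrode kernel in grid units
    (None or 0 for independent electrodes).  ``variance``: marginal
    per-sample variance in (voltage units)^2.
    """

    ar_coeff: float = 0.0
    spatial_scale: float | None = None
    variance: float = 1.0

    def __post_init__(self):
        ar = np.atleast_1d(np.asarray(self.ar_coeff, float))
        if np.any(np.abs(ar) >= 1.0):
            raise ValueError("AR coefficient must lie inside the unit circle")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.spatial_scale is not None and self.spatial_scale < 0:
            raise ValueError("spatial_scale must be >= 0")

    def spatial_corr(self, geometry: np.ndarray) -> np.ndarray:
        """Cross-electrode correlation matrix exp(-dist / spatial_scale)."""
        geometry = np.atleast_2d(geometry)
        n = geometry.shape[0]
        if not self.spatial_scale:
            return np.eye(n)
        d = np.linalg.norm(geometry[:, None] - geometry[None, :], axis=2)
        R = np.exp(-d / self.spatial_scale)
        if scipy.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("spatial correlation matrix is not positive definite")
        return R


def sample_noise(spec: NoiseSpec, n_electrodes: int, n_samples: int,
                 seed: int = 0, geometry: np.ndarray | None = None) -> np.ndarray:
    """Zero-mean Gaussian noise field with separable covariance.

    Temporal structure is generated by the AR(1) recursion with unit
    marginal variance; spatial structure by mixing electrodes with the
    symmetric square root of the exponential correlation matrix; the
    result is scaled to the requested variance.
    """
    rng = np.random.default_rng(seed)
    if spec.variance == 0:
        return np.zeros((n_electrodes, n_samples))
    ar = np.broadcast_to(np.atleast_1d(np.asarray(spec.ar_coeff, float)),
                         (n_electrodes,))
    z = rng.standard_normal((n_electrodes, n_samples + _BURN_IN))
    x = np.empty_like(z)
    for e in range(n_electrodes):
        phi = ar[e]
        x[e] = scipy.signal.lfilter([np.sqrt(1 - phi ** 2)], [1.0, -phi], z[e])
    x = x[:, _BURN_IN:]
    if spec.spatial_scale:
        if geometry is None:
            raise ValueError("geometry required for spatially correlated noise")
        R = spec.spatial_corr(geometry)
        evals, evecs = scipy.linalg.eigh(R)
        S = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
        x = S @ x
    return np.sqrt(spec.variance) * x


# ---------------------------------------------------------------------------
# rendering and full scenarios
# ---------------------------------------------------------------------------

def render_recording(ws: WaveformSet, events: SpikeEventSet,
                     noise: np.ndarray, sampling_rate_hz: float,
                     geometry: np.ndarray | None = None) -> Recording:
    """Superpose waveforms on the noise: V = sum_j sum_s W_j(t - t_s) + noise.

    Events with nonzero Taylor coefficients are rendered with the
    first-order corrected waveform (same expansion the sorter uses).
    """
    noise = np.atleast_2d(np.asarray(noise, float))
    if noise.shape[0] != ws.n_electrodes:
        raise ValueError("noise and waveforms disagree on electrode count")
    if len(events) and events.bin.max() + ws.n_taps > noise.shape[1]:
        raise ValueError("spike too close to the recording end to place a waveform")
    data = noise + predict(ws, events, noise.shape[1])
    return Recording(data, sampling_rate_hz, geometry)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the sorter must recover."""

    waveforms: WaveformSet
    spikes: SpikeEventSet
    rates: np.ndarray
    sync_spec: tuple
    refractory_ms: float
    noise: NoiseSpec
    snr: np.ndarray


@dataclass
class SimulationConfig:
    """Scenario description for :func:`simulate`.

    ``snr`` is the peak template amplitude on the neuron's home electrode
    divided by the noise standard deviation (scalar or per-neuron).
    """

    n_rows: int = 2
    n_cols: int = 4
    grid_kind: str = "square"
    spacing: float = 1.0
    n_neurons: int = 6
    duration_s: float = 60.0
    sampling_rate_hz: float = 20_000.0
    rate_hz: float = 10.0
    snr: float = 8.0
    taps: int = 30
    decay_lambda: float = 1.6
    refractory_ms: float = 1.5
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(
        ar_coeff=0.4, spatial_scale=0.7, variance=1.0))
    sync_spec: tuple = ()
    subbin_variability: bool = False
    amp_sd: float = 0.0
    width_sd: float = 0.0


def true_waveform_set(config: SimulationConfig) -> tuple[WaveformSet, np.ndarray]:
    """Deterministic per-neuron templates for a scenario.

    Neurons sit on electrodes (cycling through the grid) with shape
    parameters varied deterministically per neuron so no two templates
    are collinear.  Returns the waveform set and the geometry.
    """
    geometry = grid_geometry(config.n_rows, config.n_cols,
                             config.spacing, config.grid_kind)
    n_e = geometry.shape[0]
    snr = np.broadcast_to(np.atleast_1d(np.asarray(config.snr, float)),
                          (config.n_neurons,))
    sd = np.sqrt(config.noise.variance)
    templates = []
    stride = next(s for s in (3, 5, 7, 1) if np.gcd(s, n_e) == 1)
    for j in range(config.n_neurons):
        # strided placement (stride coprime to the electrode count) keeps
        # consecutively numbered neurons apart on the grid and gives every
        # neuron a distinct home electrode when n_neurons <= n_electrodes;
        # shape parameters vary deterministically per neuron
        pos = geometry[(stride * j) % n_e]
        templates.append(make_waveform(
            geometry, pos, amplitude=snr[j] * sd,
            decay_lambda=config.decay_lambda, taps=config.taps,
            trough_peak_ratio=0.45 + 0.3 * (j % 5) / 4.0,
            width=0.85 + 0.35 * ((2 * j) % 7) / 6.0,
            peak_tap=config.taps / 3.0 + (j % 3) - 1,
        ))
    ws = WaveformSet(np.stack(templates))
    return ws, geometry


def simulate(config: SimulationConfig, seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Generate a full recording plus its ground truth.

    All randomness flows from ``seed``; identical (config, seed) pairs
    produce bit-identical outputs.
    """
    ws, geometry = true_waveform_set(config)
    snr = np.broadcast_to(np.atleast_1d(np.asarray(config.snr, float)),
                          (config.n_neurons,))
    rates = np.broadcast_to(np.atleast_1d(np.asarray(config.rate_hz, float)),
                            (config.n_neurons,))
    ss = np.random.SeedSequence(seed)
    s_spk, s_noise, s_var = [int(s.generate_state(1)[0] % (2 ** 31))
                             for s in ss.spawn(3)]
    spikes = sample_spike_trains(
        rates, config.duration_s, config.sampling_rate_hz,
        refractory_ms=config.refractory_ms, sync_spec=config.sync_spec,
        seed=s_spk, n_waveform_taps=config.taps)
    if config.subbin_variability or config.amp_sd or config.width_sd:
        spikes = add_variability(spikes, s_var, subbin=config.subbin_variability,
                                 amp_sd=config.amp_sd, width_sd=config.width_sd)
        ws = compute_derivatives(ws)
    noise = sample_noise(config.noise, geometry.shape[0], spikes.n_bins,
                         seed=s_noise, geometry=geometry)
    rec = render_recording(ws, spikes, noise, config.sampling_rate_hz, geometry)
    truth = GroundTruth(ws, spikes, np.asarray(rates), tuple(config.sync_spec),
                        config.refractory_ms, config.noise, snr.copy())
    return rec, truth
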