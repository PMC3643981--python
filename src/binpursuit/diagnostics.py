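"""Spike-sorting quality metrics, with and without ground truth.

Ground-truth-free diagnostics exploit two measurable artifacts: missed
near-synchronous spikes carve a notch at zero lag into the
cross-correlogram between neighboring neurons (quantified by the
artifact index), and false positives violate the refractory period
(quantified by the contamination rate).  The prior-sensitivity analysis
measures how strongly a neuron's recovered spike count depends on its
Bernoulli prior penalty: well-isolated units are insensitive, and across
a population the sensitivity predicts the true error rate via a power
law that can be calibrated in simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm


# ---------------------------------------------------------------------------
# cross-correlograms
# ---------------------------------------------------------------------------

@dataclass
class CCF:
    """Cross-correlation function: conditional rate of train b around
    the spikes of train a.

    ``rate[k]`` is the firing rate (spikes/s) of the secondary train in
    lag bin ``lags_ms[k]`` relative to each primary spike; ``baseline``
    is the secondary train's mean rate.
    """

    lags_ms: np.ndarray
    rate: np.ndarray
    baseline: float
    n_ref: int
    bin_ms: float


def cross_correlogram(times_a, times_b, window_ms: float = 10.0,
                      bin_ms: float = 0.5,
                      duration_s: float | None = None) -> CCF:
    """Histogram of lags (t_b - t_a) normalized to a conditional rate.

    ``window_ms`` must be a whole multiple of ``bin_ms``.  The rate in
    each lag bin is the pair count divided by (number of reference
    spikes x bin duration); the baseline is the mean rate of the
    secondary train.  If the two arrays are the same object the zero-lag
    self-pairs are excluded (autocorrelogram convention).
    """
    n_half = window_ms / bin_ms
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("window_ms must be a multiple of bin_ms")
    n_half = int(round(n_half))
    ta = np.sort(np.asarray(times_a, float))
    tb = np.sort(np.asarray(times_b, float))
    auto = times_a is times_b
    if duration_s is None:
        duration_s = max(ta[-1] if ta.size else 0.0,
                         tb[-1] if tb.size else 0.0) + 1e-9
    edges_s = (np.arange(-n_half, n_half + 1) * bin_ms) * 1e-3
    centers = (edges_s[:-1] + edges_s[1:]) / 2 * 1e3
    counts = np.zeros(2 * n_half)
    if ta.size and tb.size:
        for t in ta:
            lo = np.searchsorted(tb, t + edges_s[0])
            hi = np.searchsorted(tb, t + edges_s[-1])
            lags = tb[lo:hi] - t
            if auto:
                lags = lags[lags != 0.0]
            counts += np.histogram(lags, bins=edges_s)[0]
    baseline = tb.size / duration_s
    if ta.size == 0:
        return CCF(centers, np.zeros(2 * n_half), baseline, 0, bin_ms)
    rate = counts / (ta.size * bin_ms * 1e-3)
    return CCF(centers, rate, baseline, int(ta.size), bin_ms)


def ccf_artifact_index(ccf: CCF, notch_ms: float = 1.0,
                       flank_ms: float = 5.0) -> float:
    """Depth of the zero-lag notch relative to the surrounding flanks.

    Index = (mean rate over notch_ms < |lag| <= flank_ms  -  mean rate
    over |lag| <= notch_ms) / baseline rate.  Zero for a flat CCF;
    positive when near-synchronous spikes are missing.  Returns nan when
    the baseline rate is zero (undefined).
    """
    if flank_ms <= notch_ms:
        raise ValueError("flank must exceed notch")
    if ccf.baseline <= 0 or ccf.n_ref == 0:
        return float("nan")
    lag = np.abs(ccf.lags_ms)
    notch = lag <= notch_ms
    flank = (lag > notch_ms) & (lag <= flank_ms)
    if not (notch.any() and flank.any()):
        raise ValueError("CCF window too narrow for the requested intervals")
    return float((ccf.rate[flank].mean() - ccf.rate[notch].mean()) / ccf.baseline)


# ---------------------------------------------------------------------------
# refractory contamination
# ---------------------------------------------------------------------------

def contamination_rate(times_s, refractory_ms: float,
                       duration_s: float | None = None) -> float:
    """Refractory contamination in percent (a false-positive proxy).

    The rate of spikes falling inside the refractory window opened by a
    preceding spike, divided by the rate of spikes outside all such
    windows, x 100, with both rates computed over the time each regime
    actually occupies.  100% means refractory structure is absent
    (e.g. a Poisson train); 50% means the in-window rate is half the
    out-of-window rate.  Undefined (nan) for fewer than 2 spikes.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory must be > 0")
    t = np.sort(np.asarray(times_s, float))
    if t.size < 2:
        return float("nan")
    if duration_s is None:
        duration_s = t[-1] + refractory_ms * 1e-3
    r = refractory_ms * 1e-3
    isi = np.diff(t)
    n_in = int(np.sum(isi <= r))
    occupied = float(np.sum(np.minimum(isi, r))) + min(r, duration_s - t[-1])
    n_out = t.size - n_in
    free = duration_s - occupied
    if free <= 0 or n_out == 0 or occupied <= 0:
        return float("inf")
    return 100.0 * (n_in / occupied) / (n_out / free)


# ---------------------------------------------------------------------------
# ground-truth matching
# ---------------------------------------------------------------------------

def match_spikes(estimated, truth, tol_bins: float) -> dict:
    """One-to-one matching of two spike-time sequences within a tolerance.

    Greedy two-pointer matching on the sorted sequences, which attains
    the maximum bipartite matching for interval (|a - b| <= tol)
    adjacency.  ``error_rate`` is (misses + false positives) / true
    count, as a fraction.
    """
    if tol_bins < 0:
        raise ValueError("tolerance must be >= 0")
    est = np.sort(np.asarray(estimated, float))
    tru = np.sort(np.asarray(truth, float))
    hits = 0
    i = j = 0
    while i < est.size and j < tru.size:
        d = est[i] - tru[j]
        if abs(d) <= tol_bins:
            hits += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    misses = tru.size - hits
    fps = est.size - hits
    err = (misses + fps) / tru.size if tru.size else float("nan")
    return {"hits": hits, "misses": misses, "false_positives": fps,
            "error_rate": err, "n_true": int(tru.size), "n_est": int(est.size)}


def match_neurons(estimated, truth, tol_bins: float) -> dict:
    """Match estimated neurons to true neurons and pool the error rates.

    Identities are resolved by the assignment (Hungarian) maximizing the
    total number of matched spikes between estimated and true trains.
    Returns the per-true-neuron reports, the mapping, and the pooled
    error rate (all misses + all false positives over all true spikes).
    """
    Je, Jt = estimated.n_neurons, truth.n_neurons
    est_trains = [estimated.train(j) for j in range(Je)]
    true_trains = [truth.train(j) for j in range(Jt)]
    hits = np.zeros((Je, Jt))
    for a in range(Je):
        for b in range(Jt):
            hits[a, b] = match_spikes(est_trains[a], true_trains[b],
                                      tol_bins)["hits"]
    rows, cols = linear_sum_assignment(-hits)
    mapping = {int(a): int(b) for a, b in zip(rows, cols)}
    per_neuron = {}
    total_hits = 0
    for a, b in mapping.items():
        rep = match_spikes(est_trains[a], true_trains[b], tol_bins)
        per_neuron[b] = rep
        total_hits += rep["hits"]
    n_true = sum(t.size for t in true_trains)
    n_est = sum(t.size for t in est_trains)
    error = ((n_true - total_hits) + (n_est - total_hits)) / n_true if n_true else float("nan")
    return {"mapping": mapping, "per_neuron": per_neuron,
            "error_rate": error, "n_true": n_true, "n_est": n_est,
            "hits": int(total_hits)}


def timing_rmse(estimated, truth, tol_bins: float) -> float:
    """Pooled RMSE (in bins) of recovered spike times against the truth.

    Neurons are matched as in :func:`match_neurons`; within each matched
    pair the spike-time differences (including sub-bin offsets) are
    computed over the matched spikes, the per-neuron median difference is
    subtracted -- an estimated template is only registered to the lattice
    up to a constant (possibly fractional) offset, which carries no
    timing information -- and the residuals are pooled into one RMSE.
    """
    rep = match_neurons(estimated, truth, tol_bins)
    pooled = []
    for a, b in rep["mapping"].items():
        sel_e = estimated.neuron_id == a
        sel_t = truth.neuron_id == b
        te = np.sort(estimated.bin[sel_e] + estimated.subbin_offset[sel_e])
        tt = np.sort(truth.bin[sel_t] + truth.subbin_offset[sel_t])
        i = j = 0
        d = []
        while i < te.size and j < tt.size:
            diff = te[i] - tt[j]
            if abs(diff) <= tol_bins:
                d.append(diff)
                i += 1
                j += 1
            elif diff < 0:
                i += 1
            else:
                j += 1
        if d:
            d = np.asarray(d)
            pooled.append(d - np.median(d))
    if not pooled:
        return float("nan")
    d = np.concatenate(pooled)
    return float(np.sqrt(np.mean(d ** 2)))


# ---------------------------------------------------------------------------
# prior sensitivity and power-law calibration
# ---------------------------------------------------------------------------

@dataclass
class SensitivityCurve:
    """Spike count of one neuron as a function of its prior multiplier.

    ``sensitivity`` is |d log(count) / d log(multiplier)| evaluated at
    the default multiplier by a central log-log finite difference.
    """

    neuron_id: int
    multipliers: np.ndarray
    counts: np.ndarray
    sensitivity: float
    default_multiplier: float


def sensitivity_analysis(count_fn, neuron_id: int, multipliers,
                         default_multiplier: float = 1.0,
                         step: float = 2.0) -> SensitivityCurve:
    """Prior-sensitivity curve for one neuron.

    ``count_fn(neuron_id, multiplier)`` must re-run spike estimation with
    only that neuron's penalty scaled by ``multiplier`` (relative to the
    fitted penalty) and return its spike count.  The sensitivity is the
    central finite difference of log count between
    ``default_multiplier * step`` and ``default_multiplier / step``.
    A zero count at the default leaves the sensitivity undefined (nan).
    """
    multipliers = np.sort(np.asarray(multipliers, float))
    if multipliers.size and multipliers.max() / multipliers.min() < 10:
        raise ValueError("multipliers should span at least one decade")
    counts = np.array([count_fn(neuron_id, m) for m in multipliers], float)
    c_def = count_fn(neuron_id, default_multiplier)
    c_lo = count_fn(neuron_id, default_multiplier / step)
    c_hi = count_fn(neuron_id, default_multiplier * step)
    if c_def <= 0 or c_lo <= 0:
        sens = float("nan")
    else:
        # probe counts of zero are floored at one half (continuity
        # correction) so a count collapsing to zero still yields a
        # finite, large slope rather than an undefined one
        sens = abs(np.log(max(c_hi, 0.5)) - np.log(c_lo)) / (2 * np.log(step))
    return SensitivityCurve(neuron_id, multipliers, counts, float(sens),
                            default_multiplier)


@dataclass
class PowerLawFit:
    """y = prefactor * x ** exponent, fitted by OLS on (log x, log y)."""

    exponent: float
    prefactor: float
    r_squared: float

    def predict(self, x):
        return self.prefactor * np.asarray(x, float) ** self.exponent


def fit_powerlaw(x, y) -> PowerLawFit:
    """Least-squares power law through positive (x, y) pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive data")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(slope), float(np.exp(intercept)), float(r2))


# ---------------------------------------------------------------------------
# scalar signal-detection simulation
# ---------------------------------------------------------------------------

def optimal_threshold(snr: float, prior_p: float) -> float:
    """Error-minimizing threshold for detecting a Gaussian-shifted scalar:
    mu/2 + log((1-p)/p)/mu, the Gaussian log-odds crossing point."""
    return snr / 2.0 + np.log((1 - prior_p) / prior_p) / snr


def detection_error_closed_form(threshold, snr: float, prior_p: float):
    """Expected miss + false-positive fraction at a threshold."""
    thr = np.asarray(threshold, float)
    return (1 - prior_p) * norm.sf(thr) + prior_p * norm.cdf(thr - snr)


def scalar_detection_sim(snr: float, prior_p: float, thresholds,
                         n_trials: int = 100_000, seed: int = 0) -> dict:
    """Monte-Carlo detection of a scalar signal in unit Gaussian noise.

    Each trial is signal-present with probability ``prior_p`` (mean
    ``snr``) else noise (mean 0); a detection is a sample above the
    threshold.  Returns detection and error fractions per threshold plus
    Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    thresholds = np.asarray(thresholds, float)
    present = rng.random(n_trials) < prior_p
    x = rng.standard_normal(n_trials) + snr * present
    above = x[None, :] > thresholds[:, None]
    detections = above.mean(axis=1)
    errors = np.mean(above ^ present[None, :], axis=1)
    se = np.sqrt(np.maximum(errors * (1 - errors), 1e-12) / n_trials)
    return {"thresholds": thresholds, "detections": detections,
            "errors": errors, "mc_se": se, "n_trials": n_trials}
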