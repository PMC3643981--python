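# Methods

## Generative model

Voltage on an array of `E` electrodes sampled at rate `f_s` (default
20 kHz) is modelled as

    V(t) = Σ_j Σ_τ W_j(τ) X_j(t − τ) + ε(t),

with binary spike indicators `X_j(t)`, per-neuron templates `W_j`
spanning `N_w` taps (default 30, ≈1.5 ms), and zero-mean Gaussian noise
`ε` whose covariance is assumed separable in space and time. Spikes are
a priori independent Bernoulli events with probability `p_j` per bin;
`p_j` is small (a 40 sp/s neuron at 20 kHz has `p = 1/500`). The
negative log-posterior is a quadratic form in the residual (weighted by
the inverse noise covariance) plus a per-spike penalty
`θ_j = log((1 − p_j)/p_j)`.

All estimation is coordinate ascent on this posterior: templates by
linear regression given spikes, spikes by greedy binary optimization
given templates, with the noise model estimated from the residuals in
between. Each stage can only decrease the objective, so the procedure
converges to a local optimum; because the spike stage is greedy and the
objective non-convex, no global-optimality claim is made.

## Template estimation and pruning

Given an event table, all templates are estimated **jointly**: the
design matrix is the bank of shifted spike-indicator trains, so the
normal equations (shared across electrodes, solved with a diagonal
jitter of 1e-10 × the mean diagonal) resolve temporally overlapping
spikes of different neurons exactly rather than averaging them into
each other. Two neurons with identical spike trains make the design
singular and raise an error naming them. An optional support mask turns
the fit into exact constrained least squares (used when re-fitting in
later rounds, where the electrode support is frozen so the update
cannot increase the objective).

Pruning zeroes a neuron's waveform on every electrode where its vector
norm is below `a` × that electrode's noise scale (default `a = 1`,
configurable; the noise scale is the MAD/0.6745 of the residual, or 1
in whitened space). Pruning is idempotent and only applied in the
first round.

Derivative tensors for the variability correction are computed
numerically from a cubic-spline interpolation of each template:
`d_amp` is the template itself, `d_time` the central difference under a
±0.1-bin time shift, and `d_width` the central difference under time
dilation about the alignment peak (the trough tap on the largest-norm
electrode), so that widening does not move the peak.

## Noise model and whitening

The full spatiotemporal covariance is too large to estimate, so it is
factored: (1) a per-electrode Toeplitz temporal covariance over a
16-bin (0.8 ms) window, estimated from the banded autocovariance of the
residual, symmetrized, and shrunk toward its diagonal if not positive
definite; each electrode is then FIR-filtered with the central column
of the inverse matrix square root (edge samples see a truncated
filter); (2) the instantaneous cross-electrode covariance of the
temporally whitened residual, estimated on every 16th time bin to
reduce serial dependence, whose inverse square root multiplies each
time-bin vector. Matrix inverse square roots use a symmetric
eigendecomposition with eigenvalues floored at 1e-8 × the largest.
Templates are re-estimated (and pruned) on the whitened data rather
than filtered directly, which keeps the template/derivative algebra
exact in the whitened space. After whitening, the likelihood is an
unweighted sum of squares with unit noise variance; the test suite
verifies residual auto- and cross-correlations below 0.05 and agreement
of the separable whitening with a dense-covariance oracle on small
instances.

## Binary pursuit

The solver maintains the correlation surface `C_j(i) = w̄_j · r[i:i+N_w]`
for the current residual `r`. The gain for flipping bin `(j, i)` is
`C − ½‖w̄‖² − θ_j` for an insertion and its negation for a deletion.
The globally best flip is applied, the residual updated over the
template footprint, and `C` updated only on the `2N_w − 1` overlapping
positions using precomputed pairwise template-overlap kernels; a
per-neuron running maximum of the gain surface makes the argmax
incremental as well, so the cost per flip is `O(J · N_w)`.
Ties are broken toward the lowest neuron id, then the lowest bin.
Termination requires every gain ≤ 1e-9 × ‖w̄_j‖²; since each accepted
flip strictly decreases a bounded objective over finitely many states,
termination is guaranteed and the result is a local optimum under
single insertions/deletions (verified exhaustively in tests). A flip
cap (default 2× the number of positions) guards pathological inputs
with a warning.

Long recordings are processed in 1 s blocks. Each block is solved on a
slice padded by one template length on both sides, but only events
whose start bin lies in the block's core region are emitted; every bin
is owned by exactly one block, so boundary spikes are found exactly
once and no cross-block deduplication is needed.

### Sub-lattice variability correction

Immediately after an insertion, the leftover footprint residual is
regressed onto the enabled derivative columns
`D = [−d_time, d_amp, d_width]` (default: time only, the component that
dominates performance) with ridge penalty
`γ = 0.1 × trace(DᵀD)/n_components`; the projection `(DᵀD + γI)⁻¹Dᵀ` is
precomputed per neuron. Coefficients are clamped to ±0.5, and if the
clamped step would not improve the fit (clamping is a box projection,
not a line search) it is discarded. The time coefficient is the spike's
sub-bin offset: event time in seconds is `(bin + offset)/f_s`. A
deletion restores exactly what was subtracted (canonical template plus
correction); its exact gain is evaluated at acceptance time and
non-improving deletions are frozen until a nearby flip changes their
neighborhood, preserving monotone descent.

### Rounds

The default is a single round of coordinate ascent, which already
attains the accuracy reported by the tests. With `rounds > 1` the noise
model and priors stay fixed (re-estimating θ would change the objective
itself and void the descent guarantee); templates are re-fit on the
frozen support and a new pursuit proposal is accepted only if it does
not increase the objective — greedy pursuit restarts from an empty
train, so its local optimum is not automatically better than the
incumbent.

## Clustering initializer

Detection finds local minima deeper than 4 × the per-electrode
MAD/0.6745 noise scale (the threshold statistic is an engineering
choice), deduplicated across electrodes within one window, keeping the
largest. Snippets of 1.5 ms around each peak from the center electrode
and its 6 nearest neighbors are laid out at their absolute electrode
slots (zeros elsewhere) so events detected on different electrodes share
one feature space; at the few-hundred-electrode scale this zero-padded
layout would be replaced by per-neighborhood clustering. PCA to 5
components is followed by seeded k-means, with k user-supplied or
chosen by silhouette score over a range. Points beyond the 0.9999
chi-square Mahalanobis radius of every cluster — using robust (minimum
covariance determinant) location and scatter so contaminants cannot
widen their own gate — are left unassigned. This reproduces, by
design, the canonical failure of clustering sorters: superposition
events land far from every cluster and are dropped, which is exactly
the bias binary pursuit corrects and the CCF diagnostics measure.

## Simulator

The simulator draws from exactly the generative model above, so ground
truth is available for every quantity the sorter estimates. Where the
underlying physiology does not prescribe a forward model, the choices
are explicit stand-ins:

- **Templates**: biphasic gamma-difference shapes, a sharp ≈0.2 ms
  depolarization trough followed by a slower repolarization bump
  (height 0.45–0.75 of the trough, duration scale 0.85–1.2, varied
  deterministically per neuron so no two templates are collinear),
  normalized so the trough equals −1. Amplitude decays as
  `exp(−distance/λ)` with λ = 1.6 grid units, placing each neuron's
  waveform on several electrodes. Neurons sit on electrodes in strided
  order (stride coprime to the electrode count), so consecutive neurons
  are spatially separated and homes are distinct while neurons fit on
  the array.
- **SNR** is defined as trough amplitude on the home electrode divided
  by the noise standard deviation; default 8.
- **Spike trains**: per-bin Bernoulli draws at `rate/f_s`, refractory
  enforcement by deleting the later spike (default 1.5 ms), then
  synchrony injection: each master spike is copied into the partner
  train with the configured probability and uniform jitter (default
  scenarios use ±5 ms, so the coincident core overlaps within a
  waveform while the flanks stay elevated). Partner spikes falling in
  an injected spike's refractory window are dropped in favor of the
  injected spike, keeping the refractory invariant while guaranteeing
  the coincidence.
- **Noise**: AR(1) in time per electrode (φ = 0.4, unit marginal
  variance), mixed across electrodes by the symmetric square root of an
  exponential correlation matrix (length 0.7 grid units), scaled to the
  requested variance — exactly the separable structure the whitener
  assumes.
- **Sub-bin variability mode**: ground-truth offsets uniform in
  (−0.5, 0.5) bins (optionally amplitude/width coefficients), rendered
  through the same first-order Taylor expansion the solver uses.

Passing tests on these simulations therefore demonstrate correctness
of the estimation machinery under the model's own assumptions; they do
not establish robustness to what real recordings add — electrode
drift, non-Gaussian spike-hash noise, bursting amplitude decrement
beyond the linear term, or template non-stationarity — all of which are
out of scope.

## Measurement conventions in the validation suite

- Spike matching is one-to-one within ±0.5 ms by greedy two-pointer
  matching (maximum matching for interval adjacency; checked against a
  Hungarian oracle). Population identity is resolved by the assignment
  maximizing total matched spikes. The error rate is
  (misses + false positives)/true spikes.
- Timing RMSE subtracts each neuron's median time difference before
  pooling: an estimated template is registered to the sample lattice
  only up to a constant, often fractional, offset that carries no
  timing information. The quantization floor for uniform sub-bin
  offsets without correction is `1/sqrt(12) ≈ 0.289` bins.
- The CCF artifact index is (mean rate at 1–5 ms lags − mean rate at
  ≤1 ms lags)/baseline; in the synchrony scenario it is averaged over
  the three injected pairs because a single pair's index has
  Monte-Carlo scatter of ≈0.5 at 600 reference spikes.
- The contamination statistic divides the spike rate inside
  refractory windows by the rate outside, with both rates normalized by
  the time each regime occupies, so the 50% worked example is exact by
  construction and a Poisson train reads ≈100%.
- Prior sensitivity is |d log(count)/d log(multiplier)| at the fitted
  penalty, by central difference at ×2 and ×½, re-running binary
  pursuit with only the probed neuron's penalty scaled. Probe counts
  of zero are floored at one half (continuity correction); a zero count
  at the default leaves the sensitivity undefined. In the power-law
  calibration (24 neurons with distinct home electrodes spanning SNR
  5.5–10 over 30 s, templates seeded from ground truth as in a
  known-waveform simulation), per-neuron error rates are floored at
  half a spike over the true count before the log-log regression.

## Problem sizes

The validation suite runs at desk scale: 8–24 electrodes, 2–24
neurons, 4–60 s at 20 kHz. These sizes were chosen so that every
statistic asserted (rates, correlations, artifact indices, regression
r²) has Monte-Carlo error comfortably below its acceptance margin; the
algorithms themselves are written for the regime where blocks, not
recordings, bound memory, and the 1 s block of a 512-electrode array
(10,240,000 samples) is handled by the same code path.

## Known limitations

- The greedy solver reaches local, not global, optima; characteristic
  failures place a wrong spike combination on dense superpositions.
- The initializer's cluster-count heuristic (silhouette) can over-split
  when spurious threshold crossings form their own cluster; supplying k
  mirrors the manual oversight that is standard practice.
- The separable noise model is an approximation; strongly
  non-separable or non-stationary noise violates it.
- Refractoriness is measured (contamination) but deliberately not
  enforced by the solver, faithful to the independent-Bernoulli prior.
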