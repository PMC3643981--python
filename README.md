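# binpursuit

Model-based spike sorting for multi-electrode extracellular recordings
by greedy **binary pursuit**, with a ground-truth simulator and a
diagnostics suite for assessing sorting quality without ground truth.

## The problem

Clustering-based spike sorters assign each detected voltage event to one
neuron. When two nearby neurons fire within a millisecond of each other
their waveforms superimpose linearly, the composite waveform matches no
cluster, and the event is discarded as an outlier. The resulting misses
are systematic: they carve a spurious notch at zero lag into the
cross-correlogram (CCF) between neighboring neurons, corrupting every
downstream analysis of synchrony.

## The model

The recorded voltage is modelled as a sparse linear superposition of
per-neuron spatiotemporal waveforms in correlated Gaussian noise:

    V(t) = sum_j sum_tau W_j(tau) X_j(t - tau) + eps(t),   eps ~ N(0, C_noise)

where `X_j(t) ∈ {0, 1}` indicates a spike of neuron *j* in sample bin
*t*, `W_j` is its electrodes × taps template, and `C_noise` has
separable space–time structure. With an independent Bernoulli prior
`p_j` per bin, the negative log-posterior after whitening is

    L(X) = 1/2 || V̄ - W̄ * X ||²  +  sum_j θ_j sum_t X_j(t),
    θ_j = log((1 - p_j) / p_j),

a quadratic objective on a binary lattice. **Binary pursuit** maximizes
it greedily: starting from an empty spike train, repeatedly flip the
(neuron, bin) with the largest gain

    ΔL_j(i) = w̄_j · r[i : i + N_w] - 1/2 ||w̄_j||² - θ_j,

updating the residual and gain surface only where template footprints
overlap, until no single insertion or deletion improves the posterior.
Superimposed spikes are resolved naturally, because the residual after
subtracting one spike still contains the other. After each insertion a
ridge-regularized Taylor correction regresses the leftover residual onto
the waveform's time/amplitude/width derivatives, resolving spike times
below the 0.05 ms sample lattice.

The full fit (`SpikeSortingModel.fit`) is one round of coordinate
ascent: least-squares template estimation from an initial (clustering)
spike estimate → subset-selection pruning → noise-covariance estimation
and two-stage (temporal, then spatial) whitening → plug-in Bernoulli
priors scaled by a penalty multiplier (default 6) → blockwise binary
pursuit.

## Worked example

```python
from binpursuit import SimulationConfig, SpikeSortingModel, simulate
from binpursuit.clustering import cluster_initialize
from binpursuit.simulate import SyncPair

cfg = SimulationConfig(n_neurons=4, duration_s=20.0, snr=9.0, rate_hz=10.0,
                       sync_spec=(SyncPair(0, 1, 0.2, 100),))
rec, truth = simulate(cfg, seed=42)

init = cluster_initialize(rec, k=4, seed=0)
res = SpikeSortingModel(rec, init.events).fit()
print(res.summary().round(3))
print(f"error rate vs ground truth: {100 * res.error_vs_truth(truth.spikes)['error_rate']:.2f}%")
```

prints

```
        n_spikes  rate_hz  p_init   theta  template_norm  contamination_pct
neuron
0            211    10.55   0.000  45.724         17.832                0.0
1            206    10.30   0.000  45.602         13.542                0.0
2            239    11.95   0.001  44.895         15.052                0.0
3            199     9.95   0.000  46.006         18.969                0.0
error rate vs ground truth: 0.00%
```

Each row is one recovered neuron: its spike count and rate over the
20 s recording, the plug-in prior probability of a spike per bin and the
per-spike penalty θ derived from it, the whitened template norm (an
isolation measure), and the refractory contamination rate in percent (a
false-positive proxy; 0 means no refractory violations). The clustering
initializer alone missed the injected near-synchronous spikes; binary
pursuit recovered them, bringing the error rate against the simulated
ground truth to zero.

The same pipeline is available from the shell:

```
binpursuit simulate --config cfg.yaml --seed 1 --out sim/
binpursuit init     --recording sim/recording.f32 --seed 0 --out init/
binpursuit sort     --recording sim/recording.f32 --init init/init_spikes.tsv --out sorted/
binpursuit diagnose --spikes sorted/spikes.tsv --truth sim/true_spikes.tsv --out report.json
binpursuit run      --config cfg.yaml --seed 1 --out run/     # all of the above
```

## Diagnostics without ground truth

- `cross_correlogram` / `ccf_artifact_index` — depth of the zero-lag
  CCF notch between neighboring neurons, a measurable proxy for missed
  near-synchronous spikes.
- `contamination_rate` — occupancy-corrected ratio of the spike rate
  inside the refractory window to the rate outside it, in percent; a
  proxy for false positives (100% ≙ no refractory structure).
- `SpikeSortingResults.sensitivity` — how strongly a neuron's spike
  count depends on its Bernoulli prior penalty; well-isolated units are
  insensitive, and across a simulated population the sensitivity
  predicts the true error rate via a power law (`fit_powerlaw`),
  allowing error rates of real recordings to be estimated from their
  measured sensitivities.

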