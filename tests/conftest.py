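import numpy as np
import pytest

from binpursuit.simulate import (NoiseSpec, SimulationConfig, simulate,
                                 true_waveform_set)


@pytest.fixture(scope="session")
def small_sim():
    """5 s, 6 neurons, 8 electrodes, SNR 8 -- shared across unit tests."""
    cfg = SimulationConfig(duration_s=5.0, n_neurons=6, snr=8.0, rate_hz=10.0)
    rec, truth = simulate(cfg, seed=123)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def tiny_templates():
    """Deterministic 2-neuron template set on a 2x4 grid."""
    cfg = SimulationConfig(n_neurons=2)
    ws, geom = true_waveform_set(cfg)
    return ws, geom
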