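"""Validated run configuration (YAML/JSON) for the command-line pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .pursuit import PursuitConfig
from .model import FitConfig
from .simulate import NoiseSpec, SimulationConfig, SyncPair


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseSection(_Strict):
    ar_coeff: float = Field(0.4, gt=-1, lt=1)
    spatial_scale: float | None = Field(1.5, ge=0)
    variance: float = Field(1.0, ge=0)


class SyncSection(_Strict):
    master: int = Field(ge=0)
    partner: int = Field(ge=0)
    prob: float = Field(ge=0, le=1)
    jitter_bins: int = Field(0, ge=0)


class SimulateSection(_Strict):
    n_rows: int = Field(2, ge=1)
    n_cols: int = Field(4, ge=1)
    grid_kind: str = "square"
    spacing: float = Field(1.0, gt=0)
    n_neurons: int = Field(6, ge=1)
    duration_s: float = Field(30.0, gt=0)
    sampling_rate_hz: float = Field(20_000.0, gt=0)
    rate_hz: float | list[float] = 10.0
    snr: float | list[float] = 8.0
    taps: int = Field(30, ge=4)
    decay_lambda: float = Field(1.2, gt=0)
    refractory_ms: float = Field(1.5, ge=0)
    noise: NoiseSection = NoiseSection()
    sync: list[SyncSection] = []
    subbin_variability: bool = False
    amp_sd: float = Field(0.0, ge=0)
    width_sd: float = Field(0.0, ge=0)

    def to_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_rows=self.n_rows, n_cols=self.n_cols, grid_kind=self.grid_kind,
            spacing=self.spacing, n_neurons=self.n_neurons,
            duration_s=self.duration_s, sampling_rate_hz=self.sampling_rate_hz,
            rate_hz=self.rate_hz, snr=self.snr, taps=self.taps,
            decay_lambda=self.decay_lambda, refractory_ms=self.refractory_ms,
            noise=NoiseSpec(self.noise.ar_coeff, self.noise.spatial_scale,
                            self.noise.variance),
            sync_spec=tuple(SyncPair(s.master, s.partner, s.prob, s.jitter_bins)
                            for s in self.sync),
            subbin_variability=self.subbin_variability,
            amp_sd=self.amp_sd, width_sd=self.width_sd,
        )


class InitSection(_Strict):
    enabled: bool = True
    threshold_multiplier: float = Field(4.0, gt=0)
    window_ms: float = Field(1.5, gt=0)
    n_neighbors: int = Field(6, ge=0)
    n_dims: int = Field(5, ge=1)
    k: int | None = None
    k_min: int = Field(2, ge=1)
    k_max: int = Field(10, ge=1)
    outlier_quantile: float = Field(0.9999, gt=0, lt=1)


class SortSection(_Strict):
    taps: int = Field(30, ge=4)
    prune_a: float = Field(1.0, ge=0)
    window_bins: int = Field(16, ge=2)
    prior_multiplier: float = Field(6.0, gt=0)
    rounds: int = Field(1, ge=1)
    block_s: float = Field(1.0, gt=0)
    gain_tol_factor: float = Field(1e-9, ge=0)
    correction: list[str] = ["time"]
    gamma_factor: float = Field(0.1, ge=0)
    coef_clamp: float = Field(0.5, gt=0)
    refractory_ms: float = Field(1.5, gt=0)

    def to_fit_config(self) -> FitConfig:
        return FitConfig(
            taps=self.taps, prune_a=self.prune_a, window_bins=self.window_bins,
            prior_multiplier=self.prior_multiplier, rounds=self.rounds,
            refractory_ms=self.refractory_ms,
            pursuit=PursuitConfig(
                block_s=self.block_s, gain_tol_factor=self.gain_tol_factor,
                correction=tuple(self.correction),
                gamma_factor=self.gamma_factor, coef_clamp=self.coef_clamp),
        )


class DiagnoseSection(_Strict):
    ccf_window_ms: float = Field(10.0, gt=0)
    ccf_bin_ms: float = Field(0.5, gt=0)
    notch_ms: float = Field(1.0, gt=0)
    flank_ms: float = Field(5.0, gt=0)
    refractory_ms: float = Field(1.5, gt=0)
    match_tol_ms: float = Field(0.5, ge=0)


class RunConfig(_Strict):
    """Top-level configuration for a reproducible pipeline run."""

    seed: int = 0
    simulate: SimulateSection | None = None
    init: InitSection = InitSection()
    sort: SortSection = SortSection()
    diagnose: DiagnoseSection = DiagnoseSection()


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML (or JSON) run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
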