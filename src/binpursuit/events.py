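"""Spike event containers and their TSV serialization.

A spike train for a population of neurons is stored as a flat event table
rather than a dense binary lattice: each event carries the neuron id, the
0-based sample bin at which the waveform's first tap is placed, and three
small Taylor coefficients describing per-event deviations from the neuron's
canonical template (sub-bin timing offset, amplitude scaling, width
dilation).  Times in seconds are ``(bin + subbin_offset) / sampling_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPIKE_COLUMNS = ["neuron_id", "bin", "subbin_offset", "amp_coef", "width_coef"]


@dataclass
class SpikeEventSet:
    """Event table for a population of neurons on a common sample clock.

    Parameters
    ----------
    neuron_id, bin : int arrays
        One entry per event.  ``bin`` is the 0-based sample index at which
        waveform tap 0 is placed.
    subbin_offset, amp_coef, width_coef : float arrays
        Per-event Taylor coefficients (all zero when no sub-bin information
        is available).
    n_neurons, n_bins : int
        Extent of the lattice the events live on.
    """

    neuron_id: np.ndarray
    bin: np.ndarray
    subbin_offset: np.ndarray = None
    amp_coef: np.ndarray = None
    width_coef: np.ndarray = None
    n_neurons: int = 0
    n_bins: int = 0

    def __post_init__(self):
        self.neuron_id = np.asarray(self.neuron_id, dtype=np.int64)
        self.bin = np.asarray(self.bin, dtype=np.int64)
        n = self.neuron_id.size
        for name in ("subbin_offset", "amp_coef", "width_coef"):
            v = getattr(self, name)
            v = np.zeros(n) if v is None else np.asarray(v, dtype=float)
            setattr(self, name, v)
            if v.size != n:
                raise ValueError(f"{name} has {v.size} entries, expected {n}")
        if n:
            if self.n_neurons <= self.neuron_id.max():
                self.n_neurons = int(self.neuron_id.max()) + 1
            if self.n_bins <= self.bin.max():
                raise ValueError(
                    f"event bin {self.bin.max()} outside lattice of {self.n_bins} bins"
                )
            key = self.neuron_id * self.n_bins + self.bin
            if np.unique(key).size != n:
                raise ValueError("duplicate (neuron, bin) event")
            if not (np.isfinite(self.subbin_offset).all()
                    and np.isfinite(self.amp_coef).all()
                    and np.isfinite(self.width_coef).all()):
                raise ValueError("non-finite event coefficients")

    # -- basic views -----------------------------------------------------
    def __len__(self):
        return self.neuron_id.size

    def train(self, j: int) -> np.ndarray:
        """Sorted spike bins of neuron ``j``."""
        return np.sort(self.bin[self.neuron_id == j])

    def counts(self) -> np.ndarray:
        """Spike count per neuron (length ``n_neurons``)."""
        return np.bincount(self.neuron_id, minlength=self.n_neurons)

    def rates(self) -> np.ndarray:
        """Plug-in Bernoulli probability per bin, ``p_j = n_j / n_bins``."""
        return self.counts() / float(self.n_bins)

    def times_s(self, sampling_rate_hz: float, neuron: int | None = None) -> np.ndarray:
        """Spike times in seconds, ``(bin + subbin_offset)/rate``, sorted."""
        sel = slice(None) if neuron is None else self.neuron_id == neuron
        t = (self.bin[sel] + self.subbin_offset[sel]) / sampling_rate_hz
        return np.sort(t)

    def select(self, mask) -> "SpikeEventSet":
        return SpikeEventSet(
            self.neuron_id[mask], self.bin[mask], self.subbin_offset[mask],
            self.amp_coef[mask], self.width_coef[mask],
            n_neurons=self.n_neurons, n_bins=self.n_bins,
        )

    def sorted(self) -> "SpikeEventSet":
        order = np.lexsort((self.bin, self.neuron_id))
        return self.select(order)

    # -- pandas / TSV ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": self.neuron_id,
            "bin": self.bin,
            "subbin_offset": self.subbin_offset,
            "amp_coef": self.amp_coef,
            "width_coef": self.width_coef,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_neurons=0, n_bins=0) -> "SpikeEventSet":
        missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"spike table missing columns {missing}")
        return cls(
            df["neuron_id"].to_numpy(), df["bin"].to_numpy(),
            df["subbin_offset"].to_numpy(), df["amp_coef"].to_numpy(),
            df["width_coef"].to_numpy(), n_neurons=n_neurons, n_bins=n_bins,
        )

    @classmethod
    def empty(cls, n_neurons: int, n_bins: int) -> "SpikeEventSet":
        z = np.zeros(0)
        return cls(z, z, z, z, z, n_neurons=n_neurons, n_bins=n_bins)


def write_spikes(events: SpikeEventSet, path) -> None:
    """Write an event set as a TSV table (header row always present)."""
    events.to_dataframe().to_csv(path, sep="\t", index=False)


def read_spikes(path, n_neurons: int = 0, n_bins: int = 0) -> SpikeEventSet:
    """Read a TSV event table written by :func:`write_spikes` (lossless:
    shortest-repr floats re-parsed with the round-trip parser)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if n_bins == 0 and len(df):
        n_bins = int(df["bin"].max()) + 1
    return SpikeEventSet.from_dataframe(df, n_neurons=n_neurons, n_bins=n_bins)
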