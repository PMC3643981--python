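"""Recording container and flat-binary + JSON-sidecar file format.

A recording is an electrodes x samples voltage matrix with sampling
metadata and electrode geometry.  On disk it is a raw little-endian
float32 stream in electrode-major order next to a JSON header describing
shape, sampling rate, dtype and geometry, so that any tool can inspect or
memory-map it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_DTYPES = {"float32": "<f4", "float64": "<f8"}


@dataclass
class Recording:
    """Multi-electrode voltage recording.

    ``data`` has shape (n_electrodes, n_samples); ``geometry`` holds one
    (x, y) coordinate per electrode in grid units.
    """

    data: np.ndarray
    sampling_rate_hz: float
    geometry: np.ndarray = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.geometry is None:
            self.geometry = np.column_stack(
                [np.arange(self.data.shape[0]), np.zeros(self.data.shape[0])]
            ).astype(float)
        self.geometry = np.asarray(self.geometry, dtype=float)
        if self.geometry.shape[0] != self.data.shape[0]:
            raise ValueError("geometry rows must match electrode count")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def window_bins(window_ms: float, sampling_rate_hz: float) -> int:
    """Number of sample bins spanned by a window in milliseconds.

    A 0.8 ms window at 20 kHz is 16 bins; a 1.5 ms spike waveform spans
    30 samples.
    """
    return int(round(window_ms * 1e-3 * sampling_rate_hz))


def lattice_spacing_ms(sampling_rate_hz: float) -> float:
    """Spacing of the discrete spike-time lattice in ms (0.05 at 20 kHz)."""
    return 1e3 / sampling_rate_hz


def write_recording(rec: Recording, data_path, header_path=None) -> None:
    """Write raw little-endian float32 (electrode-major) + JSON sidecar."""
    data_path = Path(data_path)
    header_path = Path(header_path) if header_path else data_path.with_suffix(".json")
    rec.data.astype("<f4").tofile(data_path)
    header = {
        "n_electrodes": rec.n_electrodes,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "layout": "electrode-major",
        "geometry": rec.geometry.tolist(),
    }
    header_path.write_text(json.dumps(header, indent=1))


def read_recording(data_path, header_path=None, mmap: bool = False) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises ``ValueError`` on header/file-size mismatch or unknown dtype.
    """
    data_path = Path(data_path)
    header_path = Path(header_path) if header_path else data_path.with_suffix(".json")
    header = json.loads(header_path.read_text())
    for key in ("n_electrodes", "sampling_rate_hz", "n_samples", "dtype"):
        if key not in header:
            raise ValueError(f"corrupt header: missing field {key!r}")
    if header.get("layout", "electrode-major") != "electrode-major":
        raise ValueError(f"unknown layout {header['layout']!r}")
    dt = _DTYPES.get(header["dtype"])
    if dt is None:
        raise ValueError(f"unknown dtype {header['dtype']!r}")
    n_e, n_s = int(header["n_electrodes"]), int(header["n_samples"])
    expected = n_e * n_s * np.dtype(dt).itemsize
    actual = data_path.stat().st_size
    if expected != actual:
        raise ValueError(
            f"recording size mismatch: header implies {expected} bytes, file has {actual}"
        )
    if mmap:
        data = np.memmap(data_path, dtype=dt, mode="r", shape=(n_e, n_s))
    else:
        data = np.fromfile(data_path, dtype=dt).reshape(n_e, n_s)
    geometry = np.asarray(header["geometry"], float) if "geometry" in header else None
    return Recording(data, float(header["sampling_rate_hz"]), geometry)
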