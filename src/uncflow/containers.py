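"""Core array containers shared across the pipeline.

``EpochArray`` holds trial-segmented multichannel signals; ``TFPower`` holds
time-frequency power. Both persist as a raw binary buffer (little-endian
float64, C order) next to a JSON sidecar describing shape, dtype, sampling
rate and axes, so no binary metadata format is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochArray", "TFPower", "Leadfield"]

_DTYPE = "<f8"


@dataclass
class EpochArray:
    """Trials x channels x samples array with an event-relative time axis.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    sfreq : float
        Sampling rate in Hz.
    tmin : float
        Time of the first sample relative to the event, in seconds.
    ch_names : list of str, optional
    ch_coords : ndarray, shape (n_channels, 3), optional
    """

    data: np.ndarray
    sfreq: float
    tmin: float = -2.0
    ch_names: list[str] = field(default_factory=list)
    ch_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"EpochArray data must be 3-D (trials, channels, samples), got {self.data.shape}"
            )
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def time_mask(self, tstart: float, tstop: float) -> np.ndarray:
        """Boolean mask over samples for the closed window [tstart, tstop]."""
        t = self.times
        return (t >= tstart - 1e-12) & (t <= tstop + 1e-12)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.data.astype(_DTYPE).tofile(path.with_suffix(".bin"))
        sidecar = {
            "format": "uncflow-array-v1",
            "dtype": _DTYPE,
            "order": "C",
            "shape": list(self.data.shape),
            "axes": ["trial", "channel", "time"],
            "sfreq": self.sfreq,
            "tmin": self.tmin,
            "ch_names": self.ch_names,
            "ch_coords": None if self.ch_coords is None else np.asarray(self.ch_coords).tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochArray":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".bin"), dtype=meta["dtype"]).reshape(meta["shape"])
        coords = meta.get("ch_coords")
        return cls(
            data=data,
            sfreq=meta["sfreq"],
            tmin=meta["tmin"],
            ch_names=list(meta["ch_names"]),
            ch_coords=None if coords is None else np.asarray(coords, dtype=float),
        )


@dataclass
class TFPower:
    """Time-frequency power: trials (or 1 for an average) x channels x freqs x times.

    ``invalid`` flags (freq, time) cells contaminated by convolution edge
    effects; consumers must not average over flagged cells.
    """

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list[str] = field(default_factory=list)
    invalid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("TFPower data must be 4-D (trials, channels, freqs, times)")
        if self.invalid is None:
            self.invalid = np.zeros((self.freqs.size, self.times.size), dtype=bool)
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.data.astype(_DTYPE).tofile(path.with_suffix(".bin"))
        sidecar = {
            "format": "uncflow-tfpower-v1",
            "dtype": _DTYPE,
            "order": "C",
            "shape": list(self.data.shape),
            "axes": ["trial", "channel", "freq", "time"],
            "sfreq": self.sfreq,
            "freqs": self.freqs.tolist(),
            "times": self.times.tolist(),
            "ch_names": self.ch_names,
            "invalid": self.invalid.astype(int).tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "TFPower":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".bin"), dtype=meta["dtype"]).reshape(meta["shape"])
        return cls(
            data=data,
            freqs=np.asarray(meta["freqs"]),
            times=np.asarray(meta["times"]),
            sfreq=meta["sfreq"],
            ch_names=list(meta["ch_names"]),
            invalid=np.asarray(meta["invalid"], dtype=bool),
        )


@dataclass
class Leadfield:
    """Sources x channels gain matrix plus the source grid coordinates."""

    gain: np.ndarray  # (n_sources, n_channels)
    source_coords: np.ndarray  # (n_sources, 3)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_coords = np.asarray(self.source_coords, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("leadfield gain must be 2-D (sources, channels)")
        if self.source_coords.shape[0] != self.gain.shape[0]:
            raise ValueError("source_coords rows must match leadfield rows")

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as CSV (one row per source: x,y,z,g_ch0,...)."""
        path = Path(path)
        header = "x,y,z," + ",".join(f"g{i}" for i in range(self.n_channels))
        body = np.hstack([self.source_coords, self.gain])
        np.savetxt(path, body, delimiter=",", header=header, comments="")

    @classmethod
    def load(cls, path: str | Path) -> "Leadfield":
        body = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(gain=body[:, 3:], source_coords=body[:, :3])
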