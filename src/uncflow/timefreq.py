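"""Epoching and Morlet wavelet time-frequency decomposition."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .containers import EpochArray, TFPower

__all__ = [
    "MorletSpec",
    "BaselineSpec",
    "epoch",
    "morlet_kernel",
    "morlet_sigma_t",
    "morlet_power",
    "baseline_correct",
    "band_window_average",
    "THETA_BAND",
    "ALPHA_BAND",
]

logger = logging.getLogger(__name__)

THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 12.0)
DEFAULT_FREQS = np.arange(4.0, 13.0)  # 1 Hz steps, 4-12 Hz

# kernel truncation and edge-invalidation radius, in units of sigma_t
_KERNEL_HALF_WIDTH_SD = 5.0
_EDGE_INVALID_SD = 3.0


@dataclass
class MorletSpec:
    """Complex Morlet analysis parameters.

    The Gaussian envelope has sigma_t = n_cycles / (2*pi*f) and a matching
    spectral width sigma_f = f / n_cycles.
    """

    sfreq: float
    frequencies: np.ndarray = field(default_factory=lambda: DEFAULT_FREQS.copy())
    n_cycles: float = 5.0

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if np.any(self.frequencies <= 0) or np.any(self.frequencies >= self.sfreq / 2):
            raise ValueError("frequencies must lie in (0, sfreq/2)")


@dataclass
class BaselineSpec:
    window: tuple[float, float] = (-0.2, 0.0)
    mode: str = "absolute_subtract"

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1] or self.window[1] > 0.0 + 1e-12:
            raise ValueError("baseline window must precede time 0")
        if self.mode != "absolute_subtract":
            raise ValueError(f"unsupported baseline mode {self.mode!r}")


def epoch(
    signal: np.ndarray,
    events: Sequence[int],
    sfreq: float,
    window: tuple[float, float] = (-2.0, 2.0),
    ch_names: Sequence[str] | None = None,
) -> tuple[EpochArray, list[int]]:
    """Cut a continuous (channels, samples) recording into event epochs.

    Events too close to a recording edge for the full window are dropped and
    reported in the returned list of dropped event indices.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_total = signal.shape[1]
    lo, hi = window
    n_pre = int(round(-lo * sfreq))
    n_post = int(round(hi * sfreq))
    n_samp = n_pre + n_post
    epochs = []
    dropped: list[int] = []
    for idx, ev in enumerate(events):
        start = ev - n_pre
        stop = ev + n_post
        if start < 0 or stop > n_total:
            dropped.append(idx)
            logger.info("dropping event %d at sample %d: window out of bounds", idx, ev)
            continue
        epochs.append(signal[:, start:stop])
    if not epochs:
        raise ValueError("no event leaves a complete epoch inside the recording")
    arr = EpochArray(
        data=np.stack(epochs),
        sfreq=sfreq,
        tmin=-n_pre / sfreq,
        ch_names=list(ch_names) if ch_names else [],
    )
    assert arr.n_samples == n_samp
    return arr, dropped


def morlet_sigma_t(freq: float, n_cycles: float = 5.0) -> float:
    """Temporal standard deviation of the Morlet envelope, in seconds."""
    return n_cycles / (2.0 * np.pi * freq)


def morlet_kernel(freq: float, sfreq: float, n_cycles: float = 5.0) -> np.ndarray:
    """Unit-energy complex Morlet kernel, truncated at +-5 sigma_t."""
    sigma_t = morlet_sigma_t(freq, n_cycles)
    half = int(np.ceil(_KERNEL_HALF_WIDTH_SD * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))


def morlet_power(epochs: EpochArray, spec: MorletSpec) -> TFPower:
    """Squared magnitude of the complex Morlet transform per frequency.

    Samples within 3 sigma_t of either epoch edge are flagged invalid for
    each frequency; power there is still computed but must not be consumed.
    """
    n_trials, n_ch, n_samp = epochs.data.shape
    freqs = spec.frequencies
    power = np.empty((n_trials, n_ch, freqs.size, n_samp))
    invalid = np.zeros((freqs.size, n_samp), dtype=bool)
    flat = epochs.data.reshape(n_trials * n_ch, n_samp)
    for fi, f in enumerate(freqs):
        kernel = morlet_kernel(f, spec.sfreq, spec.n_cycles)
        if kernel.size > n_samp:
            raise ValueError(
                f"frequency {f} Hz too low: kernel ({kernel.size} samples) exceeds epoch length"
            )
        conv = fftconvolve(flat, kernel[None, :], mode="same", axes=1)
        power[:, :, fi, :] = (np.abs(conv) ** 2).reshape(n_trials, n_ch, n_samp)
        n_edge = int(np.ceil(_EDGE_INVALID_SD * morlet_sigma_t(f, spec.n_cycles) * spec.sfreq))
        invalid[fi, :n_edge] = True
        if n_edge > 0:
            invalid[fi, -n_edge:] = True
    return TFPower(
        data=power,
        freqs=freqs,
        times=epochs.times,
        sfreq=epochs.sfreq,
        ch_names=list(epochs.ch_names),
        invalid=invalid,
    )


def baseline_correct(tf: TFPower, spec: BaselineSpec | None = None) -> TFPower:
    """Subtract the per-trial, per-channel, per-frequency mean baseline power."""
    if spec is None:
        spec = BaselineSpec()
    lo, hi = spec.window
    # half-open [lo, hi): the event sample itself never enters the baseline
    win = (tf.times >= lo - 1e-12) & (tf.times < hi - 1e-12)
    if not win.any():
        raise ValueError("baseline window contains no samples")
    data = tf.data.copy()
    for fi in range(tf.freqs.size):
        valid = win & ~tf.invalid[fi]
        if not valid.any():
            raise ValueError(
                f"baseline window lies entirely in the invalid edge region at "
                f"{tf.freqs[fi]} Hz"
            )
        base = data[:, :, fi, valid].mean(axis=-1, keepdims=True)
        data[:, :, fi, :] -= base
    return TFPower(
        data=data,
        freqs=tf.freqs,
        times=tf.times,
        sfreq=tf.sfreq,
        ch_names=list(tf.ch_names),
        invalid=tf.invalid.copy(),
    )


def band_window_average(
    tf: TFPower,
    band: tuple[float, float],
    window: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Mean power over a frequency band and time window: (trials, channels).

    Raises if the selection is empty or touches convolution-invalid cells.
    """
    fsel = (tf.freqs >= band[0] - 1e-12) & (tf.freqs <= band[1] + 1e-12)
    tsel = (tf.times >= window[0] - 1e-12) & (tf.times <= window[1] + 1e-12)
    if not fsel.any():
        raise ValueError(f"no frequencies inside band {band}")
    if not tsel.any():
        raise ValueError(f"no samples inside window {window}")
    if tf.invalid[np.ix_(fsel, tsel)].any():
        raise ValueError("requested window overlaps the invalid edge region")
    return tf.data[:, :, fsel][:, :, :, tsel].mean(axis=(2, 3))
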