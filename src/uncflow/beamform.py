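"""LCMV / DICS beamforming on synthetic leadfields.

Both beamformers share the unit-gain constrained minimum-variance solution
w = C^-1 l / (l^H C^-1 l); DICS applies it to a band-limited cross-spectral
density, LCMV to the broadband time-domain covariance. Filters can be built
once from condition-concatenated data and reused per condition ("common
filters").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import EpochArray, Leadfield

__all__ = [
    "CSDMatrix",
    "SpatialFilter",
    "estimate_csd",
    "dics_source_power",
    "lcmv_filters",
    "top_percent_mask",
    "extract_roi_timecourses",
]

DEFAULT_LAMBDA = 0.05  # fraction of mean sensor power


@dataclass
class CSDMatrix:
    """Trial-averaged cross-spectral density at a target band."""

    matrix: np.ndarray  # (n_channels, n_channels) complex, Hermitian
    band: tuple[float, float]
    freqs: np.ndarray
    n_trials: int
    regularization: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=1e-10):
            raise ValueError("CSD must be Hermitian")


@dataclass
class SpatialFilter:
    """Per-source unit-gain weight vectors over channels."""

    weights: np.ndarray  # (n_sources, n_channels)
    constraint: str = "unit-gain"
    regularization: float = DEFAULT_LAMBDA

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]


def estimate_csd(
    epochs: EpochArray,
    band: tuple[float, float],
    window: tuple[float, float] = (0.0, 0.6),
    taper: str = "hann",
    regularization: float = DEFAULT_LAMBDA,
) -> CSDMatrix:
    """Trial-averaged CSD from windowed-FFT cross products at band frequencies."""
    mask = epochs.time_mask(*window)
    if not mask.any():
        raise ValueError(f"window {window} lies outside the epochs")
    seg = epochs.data[:, :, mask]
    n_samp = seg.shape[2]
    if taper == "hann":
        win = np.hanning(n_samp)
    elif taper in (None, "boxcar"):
        win = np.ones(n_samp)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(seg * win, axis=2)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / epochs.sfreq)
    fsel = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not fsel.any():
        raise ValueError(f"no FFT bins inside band {band} for a {n_samp}-sample window")
    x = spec[:, :, fsel]  # (trials, channels, bins)
    csd = np.einsum("tcb,tdb->cd", x, x.conj()) / (x.shape[0] * fsel.sum())
    csd = 0.5 * (csd + csd.conj().T)
    if epochs.n_trials < epochs.n_channels:
        warnings.warn(
            f"fewer trials ({epochs.n_trials}) than channels ({epochs.n_channels}); "
            "the CSD is rank deficient and regularization is required",
            stacklevel=2,
        )
    return CSDMatrix(
        matrix=csd,
        band=band,
        freqs=freqs[fsel],
        n_trials=epochs.n_trials,
        regularization=regularization,
    )


def _unit_gain_weights(C: np.ndarray, gain: np.ndarray, lam: float) -> np.ndarray:
    """w_s = C_reg^-1 l_s / (l_s^H C_reg^-1 l_s) for every leadfield row."""
    n_ch = C.shape[0]
    diag_mean = float(np.real(np.trace(C))) / n_ch
    if diag_mean == 0.0:
        return np.zeros((gain.shape[0], n_ch), dtype=C.dtype)
    Creg = C + lam * diag_mean * np.eye(n_ch)
    try:
        Cinv_l = np.linalg.solve(Creg, gain.T.astype(Creg.dtype))  # (n_ch, n_src)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "sensor matrix is singular; increase the regularization parameter"
        ) from err
    denom = np.einsum("cs,cs->s", gain.T.conj(), Cinv_l)
    return (Cinv_l / denom).T


def dics_source_power(
    csd: CSDMatrix,
    leadfield: Leadfield,
    regularization: float | None = None,
) -> np.ndarray:
    """Beamformed source power Re(w^H C w) per grid point.

    A filter set built from one CSD (e.g. conditions concatenated) can be
    applied to per-condition CSDs via :func:`apply_filters_to_csd`.
    """
    lam = csd.regularization if regularization is None else regularization
    W = _unit_gain_weights(csd.matrix, leadfield.gain, lam)
    power = np.real(np.einsum("sc,cd,sd->s", W.conj(), csd.matrix, W))
    return np.maximum(power, 0.0)


def apply_filters_to_csd(filters: SpatialFilter, csd: CSDMatrix) -> np.ndarray:
    """Project a (per-condition) CSD through precomputed common filters."""
    W = filters.weights
    return np.maximum(np.real(np.einsum("sc,cd,sd->s", W.conj(), csd.matrix, W)), 0.0)


def dics_filters(
    csd: CSDMatrix, leadfield: Leadfield, regularization: float | None = None
) -> SpatialFilter:
    lam = csd.regularization if regularization is None else regularization
    return SpatialFilter(
        weights=_unit_gain_weights(csd.matrix, leadfield.gain, lam), regularization=lam
    )


def lcmv_filters(
    covariance: np.ndarray,
    leadfield: Leadfield,
    regularization: float = DEFAULT_LAMBDA,
) -> SpatialFilter:
    """Unit-gain minimum-variance filters from a time-domain covariance."""
    C = np.asarray(covariance, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be square symmetric")
    if C.shape[0] != leadfield.n_channels:
        raise ValueError("covariance size does not match leadfield channels")
    W = _unit_gain_weights(C.astype(complex), leadfield.gain, regularization)
    return SpatialFilter(weights=np.real(W), regularization=regularization)


def sensor_covariance(epochs: EpochArray, window: tuple[float, float] | None = None) -> np.ndarray:
    """Trial-pooled channel covariance (mean removed per trial/channel)."""
    data = epochs.data
    if window is not None:
        data = data[:, :, epochs.time_mask(*window)]
    centered = data - data.mean(axis=2, keepdims=True)
    flat = centered.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    return flat @ flat.T / flat.shape[1]


def top_percent_mask(source_power: np.ndarray, percent: float = 5.0) -> np.ndarray:
    """Boolean mask of the top-``percent`` sources by power.

    The selection count is ceil(percent/100 * N); values tied with the cutoff
    are all included, so the mask can exceed the nominal count under ties.
    """
    power = np.asarray(source_power, dtype=float)
    if power.size == 0:
        raise ValueError("empty power map")
    if not 0.0 < percent <= 100.0:
        raise ValueError("percent must be in (0, 100]")
    count = int(np.ceil(percent / 100.0 * power.size))
    cutoff = np.sort(power)[::-1][count - 1]
    return power >= cutoff


def extract_roi_timecourses(
    epochs: EpochArray,
    filters: SpatialFilter,
    rois: Mapping[str, Sequence[int]],
    method: str = "peak",
) -> dict[str, np.ndarray]:
    """Per-trial ROI source signals: (n_trials, n_samples) per ROI.

    ``method='peak'`` returns the filter output of the ROI's highest-variance
    source; ``method='pca'`` returns the first principal component of the
    ROI's source outputs (sign-aligned to the peak source).
    """
    if filters.weights.shape[1] != epochs.n_channels:
        raise ValueError("filters and epochs disagree on channel count")
    out: dict[str, np.ndarray] = {}
    y = np.einsum("sc,tcn->tsn", filters.weights, epochs.data)  # trials x sources x time
    for name, sources in rois.items():
        idx = np.asarray(list(sources), dtype=int)
        if idx.size == 0:
            raise ValueError(f"ROI {name!r} is empty")
        roi_y = y[:, idx, :]
        variances = roi_y.var(axis=(0, 2))
        peak = int(np.argmax(variances))
        if method == "peak":
            out[name] = roi_y[:, peak, :]
        elif method == "pca":
            flat = roi_y.transpose(1, 0, 2).reshape(idx.size, -1)
            flat = flat - flat.mean(axis=1, keepdims=True)
            _, _, vt = np.linalg.svd(flat, full_matrices=False)
            pc = vt[0].reshape(epochs.n_trials, epochs.n_samples)
            if np.corrcoef(pc.ravel(), roi_y[:, peak, :].ravel())[0, 1] < 0:
                pc = -pc
            out[name] = pc * np.linalg.norm(flat) / np.sqrt(flat.shape[1])
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
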