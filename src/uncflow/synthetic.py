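"""Synthetic ground-truth generators.

Everything downstream (behavioural stats, time-frequency, cluster tests,
beamforming, connectivity) is exercised on data produced here, so each
generator exposes its ground truth: trial tables carry the generating rates,
coupled sources carry the coefficient matrices, and sensor projections carry
the exact leadfield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EpochArray, Leadfield

__all__ = [
    "DesignSpec",
    "CellParams",
    "BehaviorParams",
    "NonlinearTerm",
    "CouplingSpec",
    "SensorModel",
    "StationarityError",
    "generate_trial_table",
    "simulate_sources",
    "project_to_sensors",
    "generate_band_power_epochs",
    "make_sensor_model",
    "default_behavior_params",
    "TRIAL_TABLE_COLUMNS",
]

DEFAULT_CONDITIONS = ("high_uc", "low_uc", "low_uc_difficult")
TRIAL_TABLE_COLUMNS = [
    "block",
    "condition",
    "validity",
    "cue_loc",
    "target_loc",
    "target",
    "response",
    "correct",
    "rt_ms",
]

SIGNAL_LETTER = "E"  # counted as signal for d-prime; assignment is arbitrary
NOISE_LETTER = "H"


class StationarityError(ValueError):
    """Raised when the linear part of a coupling spec is not stationary."""


@dataclass
class DesignSpec:
    """Session design: one block per condition, fixed valid-trial proportion."""

    conditions: Sequence[str] = DEFAULT_CONDITIONS
    trials_per_block: int = 256
    p_valid: float = 0.25
    n_locations: int = 4
    sfreq: float = 256.0
    epoch_window: tuple[float, float] = (-2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        # 1.0 admitted as the degenerate all-valid limit used in tests
        if not 0.0 < self.p_valid <= 1.0:
            raise ValueError(f"p_valid must be in (0, 1], got {self.p_valid}")
        if self.trials_per_block < 1 or self.n_locations < 2:
            raise ValueError("need trials_per_block >= 1 and n_locations >= 2")
        lo, hi = self.epoch_window
        if not (lo <= -0.2 and hi >= 1.0):
            raise ValueError("epoch window must contain [-0.2, 1.0] s")

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * len(self.conditions)

    @property
    def n_valid_per_block(self) -> int:
        return int(round(self.trials_per_block * self.p_valid))


@dataclass
class CellParams:
    """Generating parameters for one condition x validity cell."""

    hit_rate: float
    fa_rate: float
    rt_median_ms: float
    rt_sigma: float = 0.35  # lognormal shape

    def __post_init__(self) -> None:
        for name in ("hit_rate", "fa_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 100.0 <= self.rt_median_ms <= 2000.0:
            raise ValueError("rt_median_ms must fall in [100, 2000] ms at defaults")


BehaviorParams = Mapping[tuple[str, str], CellParams]


def default_behavior_params(conditions: Sequence[str] = DEFAULT_CONDITIONS) -> dict:
    """Cell parameters whose accuracies and RT medians sit near typical
    spatial-cueing magnitudes (valid faster/more accurate than invalid)."""
    acc = {
        ("high_uc", "valid"): 0.90,
        ("high_uc", "invalid"): 0.83,
        ("low_uc", "valid"): 0.84,
        ("low_uc", "invalid"): 0.79,
        ("low_uc_difficult", "valid"): 0.77,
        ("low_uc_difficult", "invalid"): 0.69,
    }
    rt = {
        ("high_uc", "valid"): 376.0,
        ("high_uc", "invalid"): 414.0,
        ("low_uc", "valid"): 393.0,
        ("low_uc", "invalid"): 434.0,
        ("low_uc_difficult", "valid"): 429.0,
        ("low_uc_difficult", "invalid"): 489.0,
    }
    out: dict[tuple[str, str], CellParams] = {}
    for i, cond in enumerate(conditions):
        ref = DEFAULT_CONDITIONS[min(i, 2)]
        for validity in ("valid", "invalid"):
            a = acc[(ref, validity)]
            # zero-bias convention: hit rate = accuracy, false alarms = 1 - accuracy
            out[(cond, validity)] = CellParams(
                hit_rate=a, fa_rate=1.0 - a, rt_median_ms=rt[(ref, validity)]
            )
    return out


def generate_trial_table(
    design: DesignSpec,
    behavior: BehaviorParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one session's trial table.

    One block per condition; within each block exactly
    ``round(trials_per_block * p_valid)`` trials are valid (cue location ==
    target location). The target letter is drawn uniformly from {E, H};
    responses are Bernoulli draws using the cell's hit rate when the target
    is the signal letter and the false-alarm rate otherwise, so the table's
    empirical d-prime converges to the configured rates. RTs are lognormal.
    """
    if behavior is None:
        behavior = default_behavior_params(design.conditions)
    for cond in design.conditions:
        for validity in ("valid", "invalid"):
            if (cond, validity) not in behavior:
                raise KeyError(
                    f"behavior parameters missing for cell ({cond!r}, {validity!r})"
                )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows: list[dict] = []
    for block, cond in enumerate(design.conditions):
        n = design.trials_per_block
        n_valid = design.n_valid_per_block
        valid_flags = np.zeros(n, dtype=bool)
        valid_flags[:n_valid] = True
        rng.shuffle(valid_flags)
        cue_locs = rng.integers(0, design.n_locations, size=n)
        # invalid targets drawn uniformly from the non-cued locations
        offsets = rng.integers(1, design.n_locations, size=n)
        target_locs = np.where(valid_flags, cue_locs, (cue_locs + offsets) % design.n_locations)
        targets = rng.choice([SIGNAL_LETTER, NOISE_LETTER], size=n)
        u = rng.random(n)
        rts_by_cell = {}
        for validity in ("valid", "invalid"):
            cell = behavior[(cond, validity)]
            rts_by_cell[validity] = rng.lognormal(
                mean=np.log(cell.rt_median_ms), sigma=cell.rt_sigma, size=n
            )
        for i in range(n):
            validity = "valid" if valid_flags[i] else "invalid"
            cell = behavior[(cond, validity)]
            if targets[i] == SIGNAL_LETTER:
                # hit = correct response to the signal letter
                said_signal = u[i] < cell.hit_rate
            else:
                # false alarm = responding 'signal' to the noise letter
                said_signal = u[i] < cell.fa_rate
            response = SIGNAL_LETTER if said_signal else NOISE_LETTER
            rows.append(
                {
                    "block": block,
                    "condition": cond,
                    "validity": validity,
                    "cue_loc": int(cue_locs[i]),
                    "target_loc": int(target_locs[i]),
                    "target": targets[i],
                    "response": response,
                    "correct": int(response == targets[i]),
                    "rt_ms": float(rts_by_cell[validity][i]),
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Coupled source simulation
# ---------------------------------------------------------------------------

_NONLINEAR_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "square": lambda x: x**2,
    "tanh_product": lambda x: x * np.tanh(x),
}


@dataclass
class NonlinearTerm:
    """One additive nonlinear coupling term g * func(x_source[n - lag])."""

    target: int
    source: int
    lag: int
    gain: float
    func: str = "square"

    def __post_init__(self) -> None:
        if self.func not in _NONLINEAR_FUNCS:
            raise ValueError(f"unknown nonlinear function {self.func!r}; "
                             f"choose from {sorted(_NONLINEAR_FUNCS)}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


@dataclass
class CouplingSpec:
    """Order-p (non)linear MVAR ground truth for M coupled sources."""

    M: int
    p: int
    A: np.ndarray  # (p, M, M): A[k] multiplies x[n - (k+1)]
    nonlinear_terms: Sequence[NonlinearTerm] = field(default_factory=tuple)
    noise_sd: float | np.ndarray = 1.0
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.p, self.M, self.M):
            raise ValueError(f"A must have shape (p, M, M) = {(self.p, self.M, self.M)}, "
                             f"got {self.A.shape}")
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (self.M,)).copy()
        for t in self.nonlinear_terms:
            if not (0 <= t.target < self.M and 0 <= t.source < self.M and 1 <= t.lag <= self.p):
                raise ValueError(f"nonlinear term out of range: {t}")

    def companion_matrix(self) -> np.ndarray:
        Mp = self.M * self.p
        C = np.zeros((Mp, Mp))
        C[: self.M, :] = np.concatenate(list(self.A), axis=1)
        if self.p > 1:
            C[self.M:, : Mp - self.M] = np.eye(Mp - self.M)
        return C

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion_matrix()))))


def simulate_sources(
    spec: CouplingSpec,
    n_trials: int,
    n_samples: int,
    seed: int | None = None,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate independent trials of the coupled system.

    Returns an array of shape (n_trials, M, n_samples). The linear part must
    be stationary (companion-matrix spectral radius < 1); each trial runs
    ``burn_in`` extra samples that are discarded.
    """
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise StationarityError(
            f"linear part is not stationary: companion spectral radius {rho:.4f} >= 1"
        )
    if n_samples <= 10 * spec.p:
        raise ValueError(f"n_samples must exceed 10*p = {10 * spec.p}")
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    out = np.empty((n_trials, spec.M, n_samples))
    for trial in range(n_trials):
        x = np.zeros((total + spec.p, spec.M))
        eps = rng.standard_normal((total, spec.M)) * spec.noise_sd
        for n in range(spec.p, total + spec.p):
            acc = eps[n - spec.p]
            for k in range(spec.p):
                acc = acc + spec.A[k] @ x[n - k - 1]
            for t in spec.nonlinear_terms:
                acc = acc.copy()
                acc[t.target] += t.gain * _NONLINEAR_FUNCS[t.func](x[n - t.lag, t.source])
            x[n] = acc
        out[trial] = x[spec.p + burn_in:].T
    return out


@dataclass
class SensorModel:
    """Forward model: leadfield gains, channel positions, sensor noise level."""

    leadfield: Leadfield
    channel_coords: np.ndarray
    sensor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.channel_coords = np.asarray(self.channel_coords, dtype=float)
        g = self.leadfield.gain
        if self.channel_coords.shape != (g.shape[1], 3):
            raise ValueError("channel_coords must be (n_channels, 3)")
        # full row rank when sources <= channels; maximal rank otherwise
        if np.linalg.matrix_rank(g) < min(g.shape):
            raise ValueError("leadfield must have full row rank")
        if np.any(np.all(g == 0.0, axis=0)):
            raise ValueError("leadfield has an all-zero channel column")


def make_sensor_model(
    n_channels: int = 60,
    n_sources: int = 50,
    sensor_noise_sd: float = 0.0,
    source_radius: float = 0.6,
    seed: int = 0,
) -> SensorModel:
    """Build a spherical-geometry sensor model with distance-falloff gains.

    Channels sit on a unit sphere (Fibonacci lattice); sources occupy a jittered
    grid inside radius ``source_radius``; gain decays as 1 / (d^2 + 0.25).
    """
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - 2 * (i + 0.5) / n_channels
    r = np.sqrt(1 - z**2)
    ch = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    src = rng.standard_normal((n_sources, 3))
    src *= (source_radius * rng.random(n_sources) ** (1 / 3) / np.linalg.norm(src, axis=1))[:, None]
    d = np.linalg.norm(src[:, None, :] - ch[None, :, :], axis=2)
    gain = 1.0 / (d**2 + 0.25)
    lf = Leadfield(gain=gain, source_coords=src)
    return SensorModel(leadfield=lf, channel_coords=ch, sensor_noise_sd=sensor_noise_sd)


def project_to_sensors(
    sources: np.ndarray,
    model: SensorModel,
    seed: int | None = None,
    sfreq: float = 256.0,
    tmin: float = 0.0,
) -> EpochArray:
    """Project (trials, M, time) source signals through the leadfield.

    Channel data = gain^T @ sources + Gaussian sensor noise.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim == 2:
        sources = sources[None]
    g = model.leadfield.gain
    if sources.shape[1] != g.shape[0]:
        raise ValueError(
            f"source count {sources.shape[1]} does not match leadfield rows {g.shape[0]}"
        )
    data = np.einsum("mc,tms->tcs", g, sources)
    if model.sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.standard_normal(data.shape) * model.sensor_noise_sd
    return EpochArray(data=data, sfreq=sfreq, tmin=tmin, ch_coords=model.channel_coords)


# ---------------------------------------------------------------------------
# Band-limited burst epochs for power-contrast testing
# ---------------------------------------------------------------------------

THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 12.0)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sfreq: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    return out / max(out.std(), 1e-12)


def generate_band_power_epochs(
    design: DesignSpec,
    effects: Mapping[tuple[str, str], Mapping[str, float]],
    model: SensorModel,
    n_trials: int = 30,
    effect_channels: Sequence[int] | None = None,
    burst_freqs: Mapping[str, float] | None = None,
    noise_amp: float = 1.0,
    seed: int | None = None,
) -> dict[tuple[str, str], EpochArray]:
    """Epochs with condition-dependent theta/alpha bursts on a 1/f floor.

    ``effects`` maps (condition, validity) cells to band amplitudes, e.g.
    ``{("high_uc", "valid"): {"theta": 2.0, "alpha": 1.0}, ...}``. Bursts are
    Hann-windowed sinusoids confined to 0-1000 ms post-cue with random phase
    per trial, applied only on ``effect_channels`` (all channels by default).
    """
    if burst_freqs is None:
        burst_freqs = {"theta": 5.5, "alpha": 10.0}
    for band_name, f in burst_freqs.items():
        lo, hi = THETA_BAND if band_name == "theta" else ALPHA_BAND
        if not lo <= f <= hi:
            raise ValueError(f"{band_name} burst frequency {f} Hz outside [{lo}, {hi}]")
    n_ch = model.leadfield.n_channels
    if effect_channels is None:
        effect_channels = np.arange(n_ch)
    effect_channels = np.asarray(effect_channels, dtype=int)
    rng = np.random.default_rng(design.seed if seed is None else seed)

    lo, hi = design.epoch_window
    n_samp = int(round((hi - lo) * design.sfreq))
    t = lo + np.arange(n_samp) / design.sfreq
    burst_mask = (t >= 0.0) & (t <= 1.0)
    envelope = np.zeros(n_samp)
    envelope[burst_mask] = np.hanning(burst_mask.sum())

    out: dict[tuple[str, str], EpochArray] = {}
    for cell, amps in effects.items():
        data = noise_amp * _pink_noise(rng, (n_trials, n_ch, n_samp), design.sfreq)
        for band_name, amp in amps.items():
            if amp == 0.0:
                continue
            f = burst_freqs[band_name]
            phase = rng.uniform(0, 2 * np.pi, size=n_trials)
            burst = envelope * np.sin(2 * np.pi * f * t[None, :] + phase[:, None])
            data[:, effect_channels, :] += amp * burst[:, None, :]
        out[cell] = EpochArray(
            data=data, sfreq=design.sfreq, tmin=lo, ch_coords=model.channel_coords
        )
    return out
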