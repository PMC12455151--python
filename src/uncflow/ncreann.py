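"""Neural-network estimation of (non)linear multivariate autoregressive
effective connectivity.

The current sample of each of M region signals is modelled as a function of
the p past samples of every region, f: R^{M p} -> R^M, fitted by a
one-hidden-layer perceptron trained with incremental error back-propagation
(momentum + adaptive learning rate, early stopping, permuted k-fold
cross-validation). The fitted f is split into a linear part (its first-order
Taylor term at the origin) and the nonlinear remainder; directed linear
connectivity is the lag-averaged magnitude of the linear Jacobian, and
nonlinear connectivity is the data-averaged magnitude of the remainder's
sensitivity. Significance uses time-shifted circular surrogates re-estimated
with identical hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as sps
from scipy import stats

__all__ = [
    "NMVARSpec",
    "TrainedNet",
    "ConnectivityResult",
    "SurrogateResult",
    "OrderSelection",
    "bandpass_fir",
    "select_model_order",
    "standardize",
    "design_matrices",
    "train_nmvar_net",
    "decompose_connectivity",
    "surrogate_null",
    "group_compare",
]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass_fir(
    signals: np.ndarray,
    sfreq: float,
    band: tuple[float, float] = (4.0, 7.0),
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase Hamming-windowed-sinc FIR bandpass along the last axis.

    Forward-backward filtering preserves length and cancels phase delay.
    """
    lo, hi = band
    if not 0.0 < lo < hi < sfreq / 2.0:
        raise ValueError(f"band {band} invalid for sfreq {sfreq}")
    if numtaps is None:
        # ~3 cycles of the low edge, forced odd
        numtaps = int(3 * sfreq / lo) | 1
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=sfreq)
    x = np.asarray(signals, dtype=float)
    padlen = min(3 * numtaps, x.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def standardize(signals: np.ndarray) -> np.ndarray:
    """Zero mean, unit variance per region (axis -2 of (..., M, L))."""
    x = np.asarray(signals, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd


# ---------------------------------------------------------------------------
# Linear VAR order selection
# ---------------------------------------------------------------------------

@dataclass
class OrderSelection:
    p_aic: int
    p_sbc: int
    table: np.ndarray  # (p_max, 3): order, AIC, SBC


def _var_ols(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares VAR(p) fit on (M, L) data: coefficients (p, M, M), residual cov."""
    M, L = x.shape
    N = L - p
    X = np.empty((N, M * p))
    for k in range(p):
        X[:, k * M:(k + 1) * M] = x[:, p - 1 - k:L - 1 - k].T
    Y = x[:, p:].T
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ B
    sigma = resid.T @ resid / N
    A = B.T.reshape(M, p, M).transpose(1, 0, 2)
    return A, sigma


def select_model_order(signals: np.ndarray, p_max: int = 10) -> OrderSelection:
    """Fit VAR(p) for p = 1..p_max by OLS; pick the AIC minimiser (SBC reported).

    AIC = ln|Sigma| + 2 p M^2 / N,  SBC = ln|Sigma| + ln(N) p M^2 / N.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim == 3:  # trials: concatenate for the order scan
        x = np.concatenate(list(x), axis=1)
    M, L = x.shape
    if L <= 10 * p_max * M:
        raise ValueError(f"need more than {10 * p_max * M} samples for p_max={p_max}")
    rows = []
    for p in range(1, p_max + 1):
        _, sigma = _var_ols(x, p)
        N = L - p
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf
        k = p * M * M
        rows.append((p, logdet + 2.0 * k / N, logdet + np.log(N) * k / N))
    table = np.array(rows)
    return OrderSelection(
        p_aic=int(table[np.argmin(table[:, 1]), 0]),
        p_sbc=int(table[np.argmin(table[:, 2]), 0]),
        table=table,
    )


# ---------------------------------------------------------------------------
# Network specification and training
# ---------------------------------------------------------------------------

@dataclass
class NMVARSpec:
    """Hyperparameters of the autoregressive network."""

    order: int = 10
    hidden_units: int = 10
    momentum: float = 0.9
    learning_rate: float = 0.005
    init_range: tuple[float, float] = (-0.5, 0.5)
    cv_folds: int = 10
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    patience: int = 10
    max_epochs: int = 100
    lr_up: float = 1.05
    lr_down: float = 0.7

    def __post_init__(self) -> None:
        if self.order < 1 or self.hidden_units < 1:
            raise ValueError("order and hidden_units must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainedNet:
    W_in: np.ndarray   # (H, M*p), lag-major input ordering
    b_in: np.ndarray   # (H,)
    W_out: np.ndarray  # (M, H)
    b_out: np.ndarray  # (M,)
    spec: NMVARSpec
    n_regions: int
    history: list[float] = field(default_factory=list)
    fold_metrics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = np.tanh(X @ self.W_in.T + self.b_in)
        return h @ self.W_out.T + self.b_out

    @property
    def train_r2(self) -> float:
        return float(np.mean(self.fold_metrics["train_r2"]))

    @property
    def test_r2(self) -> float:
        return float(np.mean(self.fold_metrics["test_r2"]))


def design_matrices(signals: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged input/target pairs, never straddling trial boundaries.

    ``signals`` is (M, L) or (n_trials, M, L). The input vector is lag-major:
    [x_1[n-1], ..., x_M[n-1], x_1[n-2], ..., x_M[n-p]].
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim == 2:
        x = x[None]
    Xs, Ys = [], []
    for trial in x:
        M, L = trial.shape
        if L <= p:
            raise ValueError(f"trial length {L} must exceed order {p}")
        N = L - p
        X = np.empty((N, M * p))
        for k in range(p):
            X[:, k * M:(k + 1) * M] = trial[:, p - 1 - k:L - 1 - k].T
        Xs.append(X)
        Ys.append(trial[:, p:].T)
    return np.vstack(Xs), np.vstack(Ys)


@njit(cache=False)
def _epoch_pass(W_in, b_in, W_out, b_out, vW_in, vb_in, vW_out, vb_out,
                X, Y, order, lr, momentum):  # pragma: no cover - jit
    """One incremental (per-sample) EBP pass; mutates weights in place."""
    H, D = W_in.shape
    M = W_out.shape[0]
    sse = 0.0
    for oi in range(order.shape[0]):
        n = order[oi]
        u = X[n]
        y = Y[n]
        h = np.empty(H)
        for j in range(H):
            z = b_in[j]
            for d in range(D):
                z += W_in[j, d] * u[d]
            h[j] = np.tanh(z)
        e = np.empty(M)
        for m in range(M):
            o = b_out[m]
            for j in range(H):
                o += W_out[m, j] * h[j]
            e[m] = o - y[m]
            sse += e[m] * e[m]
        # hidden deltas
        dz = np.empty(H)
        for j in range(H):
            s = 0.0
            for m in range(M):
                s += W_out[m, j] * e[m]
            dz[j] = s * (1.0 - h[j] * h[j])
        # momentum updates
        for m in range(M):
            for j in range(H):
                vW_out[m, j] = momentum * vW_out[m, j] - lr * e[m] * h[j]
                W_out[m, j] += vW_out[m, j]
            vb_out[m] = momentum * vb_out[m] - lr * e[m]
            b_out[m] += vb_out[m]
        for j in range(H):
            for d in range(D):
                vW_in[j, d] = momentum * vW_in[j, d] - lr * dz[j] * u[d]
                W_in[j, d] += vW_in[j, d]
            vb_in[j] = momentum * vb_in[j] - lr * dz[j]
            b_in[j] += vb_in[j]
    return sse / (order.shape[0] * M)


def _mse(net_pred: np.ndarray, Y: np.ndarray) -> float:
    return float(np.mean((net_pred - Y) ** 2))


def _r2(pred: np.ndarray, Y: np.ndarray) -> float:
    sse = np.sum((pred - Y) ** 2)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2)
    return float(1.0 - sse / sst) if sst > 0 else 0.0


def _fit_once(
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    spec: NMVARSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    D = X.shape[1]
    M = Y.shape[1]
    H = spec.hidden_units
    lo, hi = spec.init_range
    W_in = rng.uniform(lo, hi, size=(H, D))
    b_in = rng.uniform(lo, hi, size=H)
    W_out = rng.uniform(lo, hi, size=(M, H))
    b_out = rng.uniform(lo, hi, size=M)
    vW_in = np.zeros_like(W_in)
    vb_in = np.zeros_like(b_in)
    vW_out = np.zeros_like(W_out)
    vb_out = np.zeros_like(b_out)

    lr = spec.learning_rate
    prev_mse = np.inf
    best_val = np.inf
    best = None
    since_best = 0
    history: list[float] = []
    Xv, Yv = X[val_idx], Y[val_idx]
    for _ in range(spec.max_epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        train_mse = _epoch_pass(
            W_in, b_in, W_out, b_out, vW_in, vb_in, vW_out, vb_out,
            X, Y, order, lr, spec.momentum,
        )
        if not np.isfinite(train_mse):
            raise FloatingPointError(
                f"training diverged (non-finite loss); history: {history}"
            )
        history.append(train_mse)
        lr = lr * spec.lr_up if train_mse < prev_mse else lr * spec.lr_down
        lr = float(np.clip(lr, 1e-7, 1.0))
        prev_mse = train_mse
        pred_v = np.tanh(Xv @ W_in.T + b_in) @ W_out.T + b_out
        val_mse = _mse(pred_v, Yv)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best = (W_in.copy(), b_in.copy(), W_out.copy(), b_out.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    assert best is not None
    return (*best, history)


def train_nmvar_net(
    signals: np.ndarray,
    spec: NMVARSpec | None = None,
    seed: int | None = None,
) -> TrainedNet:
    """Fit the autoregressive network on (pre-standardized) region signals.

    ``signals`` is (M, L) concatenated data or (n_trials, M, L); lagged pairs
    never cross trial boundaries. Inputs are standardized per region. The
    permuted ``cv_folds``-fold protocol shuffles the sample pairs once, holds
    out one block for testing and the next for early-stopping validation in
    each fold, and reports per-fold train/test R^2 and MSE. The returned
    weights come from the first fold's network.
    """
    if spec is None:
        spec = NMVARSpec()
    x = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signals contain non-finite values")
    x = standardize(x)
    X, Y = design_matrices(x, spec.order)
    N = X.shape[0]
    if N <= 10 * X.shape[1]:
        raise ValueError(f"need more than {10 * X.shape[1]} usable samples, got {N}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    folds = max(1, spec.cv_folds)
    blocks = np.array_split(perm, max(folds, int(round(1 / spec.split[1]))))
    n_blocks = len(blocks)

    metrics = {k: [] for k in ("train_r2", "test_r2", "train_mse", "test_mse")}
    kept: TrainedNet | None = None
    for f in range(folds):
        test_idx = blocks[f % n_blocks]
        val_idx = blocks[(f + 1) % n_blocks]
        train_idx = np.concatenate(
            [blocks[b] for b in range(n_blocks) if b not in (f % n_blocks, (f + 1) % n_blocks)]
        )
        W_in, b_in, W_out, b_out, history = _fit_once(X, Y, train_idx, val_idx, spec, rng)
        net = TrainedNet(
            W_in=W_in, b_in=b_in, W_out=W_out, b_out=b_out,
            spec=spec, n_regions=Y.shape[1], history=history,
        )
        pred_tr = net.predict(X[train_idx])
        pred_te = net.predict(X[test_idx])
        metrics["train_r2"].append(_r2(pred_tr, Y[train_idx]))
        metrics["test_r2"].append(_r2(pred_te, Y[test_idx]))
        metrics["train_mse"].append(_mse(pred_tr, Y[train_idx]))
        metrics["test_mse"].append(_mse(pred_te, Y[test_idx]))
        if kept is None:
            kept = net
    assert kept is not None
    kept.fold_metrics = {k: np.asarray(v) for k, v in metrics.items()}
    return kept


# ---------------------------------------------------------------------------
# Connectivity decomposition
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityResult:
    """Directed coupling magnitudes: entry [i, j] is the i -> j influence."""

    lc: np.ndarray  # (M, M) linear
    nc: np.ndarray  # (M, M) nonlinear


def decompose_connectivity(
    net: TrainedNet,
    inputs: np.ndarray,
    method: str = "data_mean",
    max_samples: int = 20_000,
    seed: int | None = None,
) -> ConnectivityResult:
    """Split the fitted map into linear and nonlinear directed connectivity.

    ``method='data_mean'`` (default) takes the linear part as the
    data-averaged input Jacobian of f: lC[i, j] averages |mean_n J_n| over
    the p lags of region i as seen by output j, and the nonlinear part as
    the mean magnitude of the per-sample Jacobian's deviation from that
    average. A genuinely linear fitted map has a constant Jacobian, so its
    NC vanishes regardless of where the tanh units operate.

    ``method='origin'`` instead linearises f at the origin
    (J0 = W_out diag(g'(b_in)) W_in) and takes f - f(0) - f_Lin as the
    nonlinear remainder; this variant attributes any curvature the network
    uses to represent strong couplings to NC, so linear edges can leak into
    the nonlinear matrix.
    """
    if method not in ("data_mean", "origin"):
        raise ValueError("method must be 'data_mean' or 'origin'")
    M = net.n_regions
    p = net.spec.order
    X = np.asarray(inputs, dtype=float)
    if X.shape[0] > max_samples:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_samples, replace=False)]

    h = np.tanh(X @ net.W_in.T + net.b_in)  # (N, H)
    gp = 1.0 - h**2
    Jn = np.einsum("mh,nh,hd->nmd", net.W_out, gp, net.W_in)  # per-sample Jacobian
    if method == "origin":
        g0 = 1.0 - np.tanh(net.b_in) ** 2
        J_lin = net.W_out @ (g0[:, None] * net.W_in)  # (M, D)
    else:
        J_lin = Jn.mean(axis=0)
    nonlin_sens = np.abs(Jn - J_lin[None]).mean(axis=0)  # (M, D)

    # lag-major input layout: column (k*M + i) is region i at lag k+1
    lc = np.abs(J_lin).reshape(M, p, M).mean(axis=1).T
    nc = nonlin_sens.reshape(M, p, M).mean(axis=1).T
    return ConnectivityResult(lc=lc, nc=nc)


def estimate_connectivity(
    signals: np.ndarray,
    spec: NMVARSpec | None = None,
    seed: int | None = None,
) -> tuple[ConnectivityResult, TrainedNet]:
    """Train the network and decompose it in one call."""
    if spec is None:
        spec = NMVARSpec()
    net = train_nmvar_net(signals, spec, seed=seed)
    X, _ = design_matrices(standardize(np.asarray(signals, dtype=float)), spec.order)
    return decompose_connectivity(net, X, seed=seed), net


# ---------------------------------------------------------------------------
# Time-shifted surrogates
# ---------------------------------------------------------------------------

@dataclass
class SurrogateResult:
    null_lc: np.ndarray  # (n_surrogates, M, M)
    null_nc: np.ndarray
    lc_threshold: np.ndarray  # (M, M) 90th percentile of the null
    nc_threshold: np.ndarray
    lc_mask: np.ndarray  # observed > threshold
    nc_mask: np.ndarray


def time_shift_surrogate(
    signals: np.ndarray, rng: np.random.Generator, min_shift_frac: float = 0.1
) -> np.ndarray:
    """Independent circular shift per region; marginal dynamics preserved."""
    x = np.asarray(signals, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    out = np.empty_like(x)
    L_total = x.shape[0] * x.shape[2]
    min_shift = max(1, int(min_shift_frac * L_total))
    for i in range(x.shape[1]):
        shift = int(rng.integers(min_shift, L_total - min_shift + 1))
        flat = x[:, i, :].reshape(-1)
        out[:, i, :] = np.roll(flat, shift).reshape(x.shape[0], x.shape[2])
    return out[0] if squeeze else out


def surrogate_null(
    signals: np.ndarray,
    observed: ConnectivityResult,
    spec: NMVARSpec | None = None,
    n_surrogates: int = 100,
    threshold_quantile: float = 0.90,
    seed: int | None = None,
) -> SurrogateResult:
    """Re-estimate connectivity on time-shifted surrogates (identical
    hyperparameters) and threshold observed values at the null's 90th
    percentile per connection."""
    if spec is None:
        spec = NMVARSpec()
    if n_surrogates < 20:
        warnings.warn(
            f"n_surrogates={n_surrogates} gives an unstable percentile threshold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    M = observed.lc.shape[0]
    null_lc = np.empty((n_surrogates, M, M))
    null_nc = np.empty((n_surrogates, M, M))
    for s in range(n_surrogates):
        surr = time_shift_surrogate(signals, rng)
        res, _ = estimate_connectivity(surr, spec, seed=int(rng.integers(2**31)))
        null_lc[s] = res.lc
        null_nc[s] = res.nc
    # 'higher' interpolation: the smallest null value covering >= 90% of draws
    # (slightly conservative for small surrogate counts)
    lc_thr = np.quantile(null_lc, threshold_quantile, axis=0, method="higher")
    nc_thr = np.quantile(null_nc, threshold_quantile, axis=0, method="higher")
    return SurrogateResult(
        null_lc=null_lc,
        null_nc=null_nc,
        lc_threshold=lc_thr,
        nc_threshold=nc_thr,
        lc_mask=observed.lc > lc_thr,
        nc_mask=observed.nc > nc_thr,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    kind: str,
    masks_a: np.ndarray | None = None,
    masks_b: np.ndarray | None = None,
) -> list[dict]:
    """Per-connection group comparison between conditions A and B.

    ``values_*`` are (n_subjects, M, M) connectivity stacks. ``kind='linear'``
    runs a two-sided paired t test; ``kind='nonlinear'`` a Wilcoxon
    signed-rank test (exact for n <= 25, normal approximation with continuity
    correction above). Subjects whose connection failed the surrogate mask in
    either condition are dropped for that connection; the diagonal is skipped.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("value stacks must be (n_subjects, M, M) and matched")
    if kind not in ("linear", "nonlinear"):
        raise ValueError("kind must be 'linear' or 'nonlinear'")
    M = a.shape[1]
    include = np.ones(a.shape, dtype=bool)
    if masks_a is not None:
        include &= np.asarray(masks_a, dtype=bool)
    if masks_b is not None:
        include &= np.asarray(masks_b, dtype=bool)
    out = []
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            sel = include[:, i, j]
            da, db = a[sel, i, j], b[sel, i, j]
            n = int(sel.sum())
            row = {"source": i, "target": j, "n": n, "kind": kind}
            if n < 2:
                row.update({"stat": np.nan, "p": np.nan, "note": "fewer than 2 subjects"})
                out.append(row)
                continue
            diff = da - db
            if kind == "linear":
                res = stats.ttest_rel(da, db)
                row.update(
                    {"stat": float(res.statistic) if np.isfinite(res.statistic) else 0.0,
                     "p": float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
                     "df": n - 1, "mean_diff": float(diff.mean())}
                )
            else:
                if np.all(diff == 0):
                    row.update({"stat": 0.0, "p": 1.0, "note": "all differences zero"})
                else:
                    mode = "exact" if n <= 25 else "approx"
                    res = stats.wilcoxon(da, db, zero_method="wilcox",
                                         correction=(mode == "approx"), mode=mode)
                    row.update({"stat": float(res.statistic), "p": float(res.pvalue),
                                "median_diff": float(np.median(diff))})
            out.append(row)
    return out
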