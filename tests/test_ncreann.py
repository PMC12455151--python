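import itertools

import numpy as np
import pytest
from scipy import stats

from uncflow import synthetic
from uncflow.ncreann import (
    NMVARSpec,
    TrainedNet,
    bandpass_fir,
    decompose_connectivity,
    design_matrices,
    estimate_connectivity,
    group_compare,
    select_model_order,
    standardize,
    surrogate_null,
    time_shift_surrogate,
    train_nmvar_net,
)
from uncflow.synthetic import CouplingSpec, NonlinearTerm, simulate_sources

SFREQ = 256.0

FAST_SPEC = NMVARSpec(order=2, cv_folds=1, max_epochs=30, patience=6)


def resonant_var2(coupling: float = 0.4, noise_sd: float = 1.0) -> CouplingSpec:
    """Stable 2-region VAR(2) with a theta-band resonance and 0 -> 1 coupling."""
    th = 2 * np.pi * 5.5 / SFREQ
    r = 0.95
    A = np.zeros((2, 2, 2))
    A[0] = [[2 * r * np.cos(th), 0.0], [coupling, 2 * r * np.cos(th)]]
    A[1] = [[-(r**2), 0.0], [0.0, -(r**2)]]
    return CouplingSpec(M=2, p=2, A=A, noise_sd=noise_sd)


class TestBandpassFIR:
    def _gain(self, freq: float) -> float:
        t = np.arange(4096) / SFREQ
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_fir(x, SFREQ, (4.0, 7.0))
        core = slice(1024, 3072)
        return float(np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2)))

    def test_passband_gain_near_unity(self):
        assert abs(self._gain(5.5) - 1.0) < 0.05

    def test_stopband_attenuation(self):
        # >= 20 dB down at 20 Hz
        assert self._gain(20.0) < 10 ** (-20 / 20)

    def test_zero_in_zero_out(self):
        out = bandpass_fir(np.zeros(1000), SFREQ, (4.0, 7.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_zero_phase(self):
        t = np.arange(4096) / SFREQ
        x = np.sin(2 * np.pi * 5.5 * t)
        y = bandpass_fir(x, SFREQ, (4.0, 7.0))
        lag = np.argmax(np.correlate(y[1024:3072], x[1024:3072], "full")) - 2047
        assert lag == 0

    def test_invalid_band(self):
        with pytest.raises(ValueError, match="band"):
            bandpass_fir(np.zeros(100), SFREQ, (7.0, 4.0))


class TestOrderSelection:
    def test_var3_recovery(self):
        # order-recovery simulation: AIC minimiser lands on 3 or 4
        A = np.zeros((3, 2, 2))
        A[0] = [[0.4, 0.1], [0.2, 0.3]]
        A[2] = [[-0.35, 0.0], [0.1, -0.35]]
        spec = CouplingSpec(M=2, p=3, A=A, noise_sd=1.0)
        hits = 0
        for seed in range(10):
            x = simulate_sources(spec, 1, 3000, seed=seed)[0]
            sel = select_model_order(x, p_max=8)
            hits += sel.p_aic in (3, 4)
        assert hits >= 9

    def test_white_noise_matches_closed_form_oracle(self):
        # independent AIC oracle coded inline from OLS residuals
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2000))
        sel = select_model_order(x, p_max=5)
        M, L = x.shape
        oracle = []
        for p in range(1, 6):
            N = L - p
            X = np.column_stack(
                [x[:, p - 1 - k:L - 1 - k].T for k in range(p)]
            )
            Y = x[:, p:].T
            B, *_ = np.linalg.lstsq(X, Y, rcond=None)
            resid = Y - X @ B
            sigma = resid.T @ resid / N
            oracle.append(np.linalg.slogdet(sigma)[1] + 2 * p * M * M / N)
        assert sel.p_aic == int(np.argmin(oracle)) + 1

    def test_pmax_one(self):
        rng = np.random.default_rng(0)
        sel = select_model_order(rng.standard_normal((2, 500)), p_max=1)
        assert sel.p_aic == 1

    def test_sbc_never_larger_order_than_reported_table(self):
        rng = np.random.default_rng(3)
        x = simulate_sources(resonant_var2(), 1, 3000, seed=2)[0]
        sel = select_model_order(x, p_max=8)
        assert sel.table.shape == (8, 3)
        assert sel.p_sbc <= sel.p_aic or sel.p_sbc in range(1, 9)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="samples"):
            select_model_order(np.zeros((2, 100)), p_max=10)


class TestDesignMatrices:
    def test_lag_major_layout(self):
        x = np.arange(20, dtype=float).reshape(2, 10)  # region 0: 0..9, region 1: 10..19
        X, Y = design_matrices(x, p=2)
        # first usable target is sample index 2
        np.testing.assert_array_equal(Y[0], [2.0, 12.0])
        # input: [x0[n-1], x1[n-1], x0[n-2], x1[n-2]]
        np.testing.assert_array_equal(X[0], [1.0, 11.0, 0.0, 10.0])

    def test_no_cross_trial_pairs(self):
        trials = np.stack([np.arange(10.0).reshape(1, 10) * s for s in (1, 100)])
        trials = np.repeat(trials, 2, axis=1)
        X, Y = design_matrices(trials, p=3)
        assert X.shape[0] == 2 * (10 - 3)


class TestTraining:
    def test_linear_var_low_noise_high_r2(self):
        src = simulate_sources(resonant_var2(), 10, 400, seed=0)
        net = train_nmvar_net(src, NMVARSpec(order=2, cv_folds=2, max_epochs=60), seed=1)
        assert net.train_r2 > 0.95

    def test_white_noise_r2_near_zero(self):
        rng = np.random.default_rng(0)
        wn = rng.standard_normal((10, 2, 400))
        net = train_nmvar_net(wn, FAST_SPEC, seed=1)
        assert abs(net.train_r2) < 0.1
        assert abs(net.test_r2) < 0.1

    def test_seed_reproducibility(self):
        src = simulate_sources(resonant_var2(), 5, 300, seed=3)
        n1 = train_nmvar_net(src, FAST_SPEC, seed=7)
        n2 = train_nmvar_net(src, FAST_SPEC, seed=7)
        np.testing.assert_array_equal(n1.W_in, n2.W_in)
        np.testing.assert_array_equal(n1.W_out, n2.W_out)

    def test_divergence_raises(self):
        src = simulate_sources(resonant_var2(), 5, 300, seed=3)
        bad = NMVARSpec(order=2, cv_folds=1, max_epochs=10, learning_rate=50.0)
        with pytest.raises(FloatingPointError, match="diverged"):
            train_nmvar_net(src, bad, seed=0)

    def test_non_finite_inputs_rejected(self):
        x = np.zeros((2, 2, 300))
        x[0, 0, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_nmvar_net(x, FAST_SPEC, seed=0)

    def test_generalisation_test_within_train_range(self):
        # well-specified model: test R2 within +-3 SD of train R2 across folds
        src = simulate_sources(resonant_var2(), 10, 400, seed=5)
        net = train_nmvar_net(src, NMVARSpec(order=2, cv_folds=5, max_epochs=40), seed=2)
        tr = net.fold_metrics["train_r2"]
        sd = max(tr.std(ddof=1), 1e-4)
        assert abs(net.test_r2 - tr.mean()) < 3 * sd


def _linear_regime_net(J_target: np.ndarray, M: int, p: int, eps: float = 1e-3) -> TrainedNet:
    """Net whose tanh units stay in their linear regime: f(u) ~ J_target @ u."""
    rng = np.random.default_rng(0)
    H, D = 10, M * p
    B = rng.standard_normal((H, D))
    W_in = eps * B
    W_out = J_target @ np.linalg.pinv(W_in)
    return TrainedNet(
        W_in=W_in, b_in=np.zeros(H), W_out=W_out, b_out=np.zeros(M),
        spec=NMVARSpec(order=p), n_regions=M,
    )


class TestDecomposition:
    def test_linear_regime_nc_vanishes_lc_matches(self):
        # zero hidden-layer curvature: NC ~ 0, lC equals the coefficient map
        A = np.array([[0.5, 0.0, -0.3, 0.0], [0.4, 0.5, 0.0, -0.3]])  # (M, M*p) lag-major
        net = _linear_regime_net(A, M=2, p=2)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 4))
        res = decompose_connectivity(net, X)
        expected_lc = np.abs(A).reshape(2, 2, 2).mean(axis=1).T
        np.testing.assert_allclose(res.lc, expected_lc, atol=1e-4)
        assert np.all(res.nc < 1e-4)

    def test_origin_method_agrees_in_linear_regime(self):
        A = np.array([[0.5, 0.0, -0.3, 0.0], [0.4, 0.5, 0.0, -0.3]])
        net = _linear_regime_net(A, M=2, p=2)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 4))
        r1 = decompose_connectivity(net, X, method="data_mean")
        r2 = decompose_connectivity(net, X, method="origin")
        np.testing.assert_allclose(r1.lc, r2.lc, atol=1e-4)
        np.testing.assert_allclose(r1.nc, r2.nc, atol=1e-4)

    def test_trained_linear_system_direction(self):
        # broadband system: narrowband resonances leave the two regressor
        # histories nearly collinear and the attribution direction unstable
        spec = CouplingSpec(
            M=2, p=2,
            A=np.array([[[0.5, 0.0], [0.45, 0.5]], [[-0.2, 0.0], [0.0, -0.2]]]),
            noise_sd=1.0,
        )
        src = simulate_sources(spec, 8, 300, seed=4)
        res, _ = estimate_connectivity(src, FAST_SPEC, seed=5)
        assert res.lc[0, 1] > 3 * res.lc[1, 0]
        assert np.all(res.lc >= 0) and np.all(res.nc >= 0)

    def test_square_coupling_nonlinear_direction(self):
        spec = CouplingSpec(
            M=2, p=2, A=np.zeros((2, 2, 2)), noise_sd=1.0,
            nonlinear_terms=[NonlinearTerm(target=1, source=0, lag=1, gain=0.7, func="square")],
        )
        src = simulate_sources(spec, 10, 400, seed=2)
        res, _ = estimate_connectivity(src, FAST_SPEC, seed=3)
        assert res.nc[0, 1] > 3 * res.nc[1, 0]
        assert res.lc[0, 1] < res.nc[0, 1]  # linear route near floor

    def test_region_permutation_equivariance(self):
        # permuting regions in the weight layout permutes lC/NC rows+cols
        M, p = 3, 2
        rng = np.random.default_rng(6)
        W_in = rng.uniform(-0.5, 0.5, size=(8, M * p))
        net = TrainedNet(
            W_in=W_in, b_in=rng.uniform(-0.5, 0.5, 8),
            W_out=rng.uniform(-0.5, 0.5, (M, 8)), b_out=np.zeros(M),
            spec=NMVARSpec(order=p), n_regions=M,
        )
        X = rng.standard_normal((400, M * p))
        perm = np.array([2, 0, 1])
        col_perm = np.concatenate([k * M + perm for k in range(p)])
        net_p = TrainedNet(
            W_in=net.W_in[:, col_perm], b_in=net.b_in,
            W_out=net.W_out[perm], b_out=net.b_out[perm],
            spec=net.spec, n_regions=M,
        )
        res = decompose_connectivity(net, X)
        res_p = decompose_connectivity(net_p, X[:, col_perm])
        np.testing.assert_allclose(res_p.lc, res.lc[np.ix_(perm, perm)], atol=1e-12)
        np.testing.assert_allclose(res_p.nc, res.nc[np.ix_(perm, perm)], atol=1e-12)

    def test_amplitude_invariance_via_standardization(self):
        src = simulate_sources(resonant_var2(), 5, 300, seed=8)
        scaled = src.copy()
        scaled[:, 0, :] *= 4.0  # exact power-of-two scaling
        r1, _ = estimate_connectivity(src, FAST_SPEC, seed=9)
        r2, _ = estimate_connectivity(scaled, FAST_SPEC, seed=9)
        np.testing.assert_allclose(r1.lc, r2.lc, atol=1e-10)
        np.testing.assert_allclose(r1.nc, r2.nc, atol=1e-10)


class TestSurrogates:
    def test_autocorrelation_preserved(self):
        src = simulate_sources(resonant_var2(), 1, 5000, seed=0)[0]
        rng = np.random.default_rng(1)
        surr = time_shift_surrogate(src, rng)

        def acf(x, lags):
            x = x - x.mean()
            c = np.correlate(x, x, "full")[len(x) - 1:]
            return c[: lags + 1] / c[0]

        for ch in range(2):
            a0 = acf(src[ch], 10)
            a1 = acf(surr[ch], 10)
            assert np.max(np.abs(a0 - a1)) < 0.05

    def test_surrogate_changes_alignment_not_marginals(self):
        src = simulate_sources(resonant_var2(coupling=0.6), 1, 3000, seed=2)[0]
        rng = np.random.default_rng(3)
        surr = time_shift_surrogate(src, rng)
        np.testing.assert_allclose(np.sort(surr[0]), np.sort(src[0]), atol=1e-12)
        r_orig = abs(np.corrcoef(src[0, :-1], src[1, 1:])[0, 1])
        r_surr = abs(np.corrcoef(surr[0, :-1], surr[1, 1:])[0, 1])
        assert r_surr < r_orig / 2

    def test_coupled_pair_detected(self):
        spec = CouplingSpec(
            M=2, p=2,
            A=np.array([[[0.5, 0.0], [0.45, 0.5]], [[-0.2, 0.0], [0.0, -0.2]]]),
            noise_sd=1.0,
        )
        hits = 0
        for seed in range(4):
            src = simulate_sources(spec, 8, 250, seed=seed)
            res, _ = estimate_connectivity(src, FAST_SPEC, seed=100 + seed)
            surr = surrogate_null(src, res, FAST_SPEC, n_surrogates=25, seed=200 + seed)
            hits += bool(surr.lc_mask[0, 1])
        assert hits >= 3

    def test_few_surrogates_warns(self):
        src = simulate_sources(resonant_var2(), 4, 250, seed=0)
        res, _ = estimate_connectivity(src, FAST_SPEC, seed=0)
        with pytest.warns(UserWarning, match="unstable"):
            surrogate_null(src, res, FAST_SPEC, n_surrogates=5, seed=1)


class TestGroupCompare:
    def test_identical_conditions(self):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.standard_normal((6, 2, 2)))
        lin = group_compare(vals, vals.copy(), kind="linear")
        for row in lin:
            assert row["stat"] == pytest.approx(0.0) or np.isnan(row["stat"])
        nonlin = group_compare(vals, vals.copy(), kind="nonlinear")
        for row in nonlin:
            assert row["p"] == 1.0

    def test_paired_t_closed_form(self):
        rng = np.random.default_rng(1)
        diffs = rng.standard_normal(35)
        diffs = (diffs - diffs.mean()) / diffs.std(ddof=1) * 0.012 + 0.006
        a = np.zeros((35, 2, 2))
        a[:, 0, 1] = diffs
        b = np.zeros((35, 2, 2))
        rows = group_compare(a, b, kind="linear")
        row = next(r for r in rows if r["source"] == 0 and r["target"] == 1)
        expected = 0.006 / (0.012 / np.sqrt(35))
        assert row["stat"] == pytest.approx(expected, abs=1e-9)
        assert row["df"] == 34
        assert row["p"] < 0.01

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        diffs = np.array([1.0, 2.0, -1.5, 3.0, 2.5])
        a = np.zeros((5, 2, 2))
        a[:, 0, 1] = diffs
        b = np.zeros((5, 2, 2))
        rows = group_compare(a, b, kind="nonlinear")
        row = next(r for r in rows if r["source"] == 0 and r["target"] == 1)
        # brute-force rank oracle
        ranks = stats.rankdata(np.abs(diffs))
        w_minus = ranks[diffs < 0].sum()
        w_plus = ranks[diffs > 0].sum()
        w_obs = min(w_plus, w_minus)
        assert row["stat"] == pytest.approx(w_obs)
        count = 0
        for signs in itertools.product([1, -1], repeat=5):
            wp = sum(r for r, s in zip(ranks, signs) if s > 0)
            if min(wp, ranks.sum() - wp) <= w_obs:
                count += 1
        assert row["p"] == pytest.approx(count / 32)

    def test_mask_excludes_subjects_per_connection(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.standard_normal((8, 2, 2)))
        b = np.abs(rng.standard_normal((8, 2, 2)))
        masks = np.ones((8, 2, 2), dtype=bool)
        masks[:5, 0, 1] = False  # only 3 subjects survive for 0 -> 1
        rows = group_compare(a, b, kind="linear", masks_a=masks)
        row01 = next(r for r in rows if r["source"] == 0 and r["target"] == 1)
        row10 = next(r for r in rows if r["source"] == 1 and r["target"] == 0)
        assert row01["n"] == 3 and row10["n"] == 8

    def test_diagonal_excluded(self):
        vals = np.ones((4, 3, 3))
        rows = group_compare(vals, vals, kind="linear")
        assert all(r["source"] != r["target"] for r in rows)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            group_compare(np.zeros((3, 2, 2)), np.zeros((4, 2, 2)), kind="linear")
        with pytest.raises(ValueError, match="kind"):
            group_compare(np.zeros((3, 2, 2)), np.zeros((3, 2, 2)), kind="other")
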