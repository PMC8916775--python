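"""VAR fitting, Geweke spectra against an independent oracle, net GC, RGT."""

import warnings

import numpy as np
import pytest

from lamflow.gc import (
    VARModel,
    band_net_gc,
    build_gc_graph,
    default_freq_grid,
    fit_var_pair,
    geweke_spectral_gc,
    reverse_granger_test,
    simulate_var,
)
from lamflow.containers import EpochedSignal

from _oracles import geweke_gc_oracle

warnings.filterwarnings("ignore", category=UserWarning)


def resonant_var(f_drive=40.0, coupling=0.4, lag=1, r_x=0.9, r_y=0.85, fs=1000.0):
    """x is a resonant AR(2); y has its own AR(2) plus lagged drive from x."""
    p = max(2, lag)
    A = np.zeros((p, 2, 2))
    th = 2 * np.pi * f_drive / fs
    A[0, 0, 0], A[1, 0, 0] = 2 * r_x * np.cos(th), -(r_x**2)
    A[0, 1, 1], A[1, 1, 1] = 2 * r_y * np.cos(th), -(r_y**2)
    A[lag - 1, 1, 0] = coupling
    return A


class TestFitVarPair:
    def test_known_var2_coefficient_recovery(self, rng):
        A = resonant_var()
        z = simulate_var(A, np.eye(2), 200, 256, rng)
        model = fit_var_pair(z[:, 0], z[:, 1], order=2)
        rmse = np.sqrt(np.mean((model.coef - A) ** 2))
        assert rmse < 0.05
        assert model.companion_spectral_radius() < 1.0

    def test_independent_noise_cross_coefficients_null(self, rng):
        n_trials, n = 100, 256
        x = rng.standard_normal((n_trials, n))
        y = rng.standard_normal((n_trials, n))
        model = fit_var_pair(x, y, order=10)
        # standard error of an OLS coefficient on unit-variance white noise
        se = 1.0 / np.sqrt(model.n_obs_effective)
        cross = np.concatenate([model.coef[:, 0, 1], model.coef[:, 1, 0]])
        assert np.mean(np.abs(cross) <= 3 * se) >= 0.95

    def test_constant_input_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_var_pair(np.ones((10, 256)), np.zeros((10, 256)), order=5)

    def test_thin_sample_warns(self, rng):
        with pytest.warns(UserWarning, match="parameter"):
            fit_var_pair(rng.standard_normal((2, 256)),
                         rng.standard_normal((2, 256)), order=50)


class TestGewekeSpectrum:
    def test_decoupled_var_gives_zero_gc(self):
        A = resonant_var(coupling=0.0)
        model = VARModel(order=2, coef=A, noise_cov=np.diag([1.0, 1.3]),
                         fs_hz=1000.0, n_obs_effective=0)
        spec = geweke_spectral_gc(model)
        assert np.allclose(spec.gci_xy, 0.0, atol=1e-12)
        assert np.allclose(spec.gci_yx, 0.0, atol=1e-12)

    def test_unidirectional_matches_independent_oracle(self):
        A = resonant_var(coupling=0.4)
        cov = np.array([[1.0, 0.2], [0.2, 1.2]])
        freqs = default_freq_grid()
        model = VARModel(order=2, coef=A, noise_cov=cov, fs_hz=1000.0,
                         n_obs_effective=0)
        spec = geweke_spectral_gc(model, freqs)
        oracle_xy, oracle_yx = geweke_gc_oracle(A, cov, freqs, 1000.0)
        assert np.max(np.abs(spec.gci_xy - oracle_xy)) < 1e-10
        assert np.max(np.abs(spec.gci_yx - np.clip(oracle_yx, 0, None))) < 1e-10
        assert np.all(spec.gci_xy >= 0)
        assert spec.gci_xy.min() > 0  # x drives y at every frequency

    def test_estimated_spectrum_converges_to_oracle(self, rng):
        A = resonant_var(coupling=0.4)
        cov = np.array([[1.0, 0.2], [0.2, 1.2]])
        z = simulate_var(A, cov, 400, 256, rng)
        model = fit_var_pair(z[:, 0], z[:, 1], order=50)
        freqs = default_freq_grid()
        spec = geweke_spectral_gc(model, freqs)
        oracle_xy, _ = geweke_gc_oracle(A, cov, freqs, 1000.0)
        band = (freqs >= 4) & (freqs <= 55)
        mad = np.mean(np.abs(spec.gci_xy[band] - oracle_xy[band]))
        assert mad < 0.10 * oracle_xy[band].mean()

    def test_stronger_drive_raises_gc_everywhere(self):
        freqs = default_freq_grid()
        specs = []
        for c in (0.2, 0.4):
            model = VARModel(order=2, coef=resonant_var(coupling=c),
                             noise_cov=np.eye(2), fs_hz=1000.0, n_obs_effective=0)
            specs.append(geweke_spectral_gc(model, freqs))
        assert np.all(specs[1].gci_xy > specs[0].gci_xy)

    def test_model_order_robustness(self, rng):
        # VAR(2) truth: band GC at fitted order 50 within 15 % of order 2
        A = resonant_var(coupling=0.4)
        z = simulate_var(A, np.eye(2), 400, 256, rng)
        nets = {}
        for order in (2, 50):
            model = fit_var_pair(z[:, 0], z[:, 1], order=order)
            nets[order] = band_net_gc(geweke_spectral_gc(model), "gamma")[0]
        assert nets[50] == pytest.approx(nets[2], rel=0.15)


class TestBandNet:
    def test_symmetric_coupling_cancels(self, rng):
        # Two independent resonant latents cross-coupled with equal lagged
        # gain in both directions (feedforward construction, so stable).
        ar = resonant_var(coupling=0.0)
        a = simulate_var(ar[:, :1, :1], np.eye(1), 200, 260, rng)[:, 0]
        b = simulate_var(ar[:, :1, :1], np.eye(1), 200, 260, rng)[:, 0]
        lag = 4
        x = a[:, lag:] + 0.5 * b[:, :-lag]
        y = b[:, lag:] + 0.5 * a[:, :-lag]
        model = fit_var_pair(x, y, order=20)
        fwd, bwd, net = band_net_gc(geweke_spectral_gc(model), "gamma")
        assert fwd > 0.01 and bwd > 0.01  # both directions genuinely coupled
        assert abs(net) < 0.2 * (fwd + bwd)

    def test_unidirectional_band_specific(self, rng):
        # Narrowband lagged coupling (as the generator plants it): a gamma
        # oscillator's delayed copy drives the target, so the predictable
        # component — and hence the GC — concentrates in the gamma band.
        import scipy.signal

        sos = scipy.signal.butter(3, (35, 55), btype="bandpass", fs=1000.0,
                                  output="sos")
        src = scipy.signal.sosfilt(sos, rng.standard_normal((200, 260)), axis=-1)
        own = rng.standard_normal((200, 260))
        lag = 4
        x = src[:, lag:]
        y = own[:, lag:] + 0.6 * src[:, :-lag] / src.std()
        model = fit_var_pair(x, y, order=30)
        spec = geweke_spectral_gc(model)
        _, _, net_gamma = band_net_gc(spec, "gamma")
        _, _, net_theta = band_net_gc(spec, "theta")
        assert net_gamma > 0
        assert net_gamma > 5 * abs(net_theta)

    def test_pair_swap_antisymmetry_exact(self, rng):
        z = simulate_var(resonant_var(), np.eye(2), 50, 256, rng)
        m_xy = fit_var_pair(z[:, 0], z[:, 1], order=10)
        m_yx = fit_var_pair(z[:, 1], z[:, 0], order=10)
        net_xy = band_net_gc(geweke_spectral_gc(m_xy), "gamma")[2]
        net_yx = band_net_gc(geweke_spectral_gc(m_yx), "gamma")[2]
        assert net_xy == pytest.approx(-net_yx, abs=1e-10)

    def test_empty_band_rejected(self):
        model = VARModel(order=2, coef=resonant_var(), noise_cov=np.eye(2),
                         fs_hz=1000.0, n_obs_effective=0)
        spec = geweke_spectral_gc(model)
        with pytest.raises(ValueError, match="band"):
            band_net_gc(spec, (200.0, 300.0))

    def test_time_reversal_preserves_instantaneous_covariance(self, rng):
        z = simulate_var(resonant_var(), np.eye(2), 20, 256, rng)
        cov_fwd = np.cov(z[:, 0].ravel(), z[:, 1].ravel())
        cov_rev = np.cov(z[:, 0, ::-1].ravel(), z[:, 1, ::-1].ravel())
        assert np.allclose(cov_fwd, cov_rev)


class TestReverseGranger:
    def test_genuine_coupling_passes(self):
        passes = 0
        for i in range(10):
            z = simulate_var(resonant_var(coupling=0.4, lag=3), np.eye(2), 120, 256,
                             np.random.default_rng(100 + i))
            ok, _ = reverse_granger_test(z[:, 0], z[:, 1], "gamma", seed=i)
            passes += ok
        assert passes >= 9

    def test_common_noise_fails(self):
        fails = 0
        for i in range(10):
            rg = np.random.default_rng(200 + i)
            lat = simulate_var(resonant_var()[:, :1, :1], np.eye(1), 120, 256, rg)[:, 0]
            x = lat + 0.7 * rg.standard_normal(lat.shape)
            y = 0.8 * lat + 0.7 * rg.standard_normal(lat.shape)
            ok, _ = reverse_granger_test(x, y, "gamma", seed=i)
            fails += not ok
        assert fails >= 9

    def test_independent_channels_fail_floor(self, rng):
        x = rng.standard_normal((120, 256))
        y = rng.standard_normal((120, 256))
        ok, details = reverse_granger_test(x, y, "gamma", seed=0)
        assert not ok


class TestGraph:
    def _epoched(self, data):
        n_trials, n_ch, n_t = data.shape
        return EpochedSignal(
            data=data, time_ms=np.arange(n_t) + 200.0, fs_hz=1000.0, kind="LFPbp",
            condition=np.ones(n_trials), channel_ids=np.arange(1, n_ch + 1),
        )

    def test_four_channels_give_twelve_ordered_pairs(self, rng):
        data = rng.standard_normal((30, 4, 300))
        graph = build_gc_graph(self._epoched(data), order=5, with_rgt=False)
        per_band = graph[graph.band == "gamma"]
        assert len(per_band) == 12
        # net antisymmetry within the table
        for _, row in per_band.iterrows():
            mirror = per_band[(per_band.source == row.target)
                              & (per_band.target == row.source)].iloc[0]
            assert row.net == pytest.approx(-mirror.net, abs=1e-12)

    def test_planted_session_adjacency_recovered(self, preprocessed, default_session):
        _, _, gt = default_session
        bp = preprocessed["lfp_bp"]
        pairs = [(s, t) for (s, t) in gt.coupling_adjacency]
        graph = build_gc_graph(bp, with_rgt=True, pairs=pairs, seed=0)
        for (s, t), (band, strength, lag) in gt.coupling_adjacency.items():
            row = graph[(graph.source == s) & (graph.target == t)
                        & (graph.band == band)].iloc[0]
            assert row.net > 0
            assert row.rgt_pass

    def test_no_coupling_yields_no_rgt_edges(self, rng):
        data = rng.standard_normal((60, 3, 300))
        graph = build_gc_graph(self._epoched(data), order=20, with_rgt=True, seed=1)
        gamma = graph[graph.band == "gamma"]
        assert gamma.rgt_pass.sum() == 0

    def test_bad_channel_recorded_not_fatal(self, rng):
        data = rng.standard_normal((30, 3, 300))
        data[:, 2, :] = 1.0  # constant channel
        graph = build_gc_graph(self._epoched(data), order=5, with_rgt=False)
        ok = graph[(graph.source == 1) & (graph.target == 2)]
        bad = graph[(graph.source == 3)]
        assert np.isfinite(ok.net).all()
        assert np.isnan(bad.net).all()
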