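"""Generator tests: forward model, oscillator network, carrier, sessions."""

import numpy as np
import pytest
import scipy.signal

from lamflow.csd import compute_icsd, qc_session, csd_from_epoched
from lamflow import preprocess
from lamflow.synth import (
    SynthConfig,
    CouplingEdge,
    balanced_sink_profile,
    forward_potentials_from_csd,
    generate_session,
    simulate_coupled_oscillations,
    simulate_mua_carrier,
    make_events,
)

from _oracles import brute_force_crossing


class TestForwardModel:
    def test_zero_csd_gives_zero_potentials(self):
        phi = forward_potentials_from_csd(np.zeros((16, 10)), 150.0)
        assert np.allclose(phi, 0.0)

    def test_balanced_impulse_round_trip(self):
        # A unit sink at contact 8 with its return current spread uniformly:
        # the round trip through the CSD stage must be exact.
        csd_map = np.zeros((16, 1))
        csd_map[7, 0] = 1.0
        csd_map -= csd_map.mean(axis=0)
        phi = forward_potentials_from_csd(csd_map, 150.0, 0.3)
        back = compute_icsd(phi * 1e6, [45.0], 150.0, 0.3).values
        assert np.max(np.abs(back - csd_map)) < 1e-9 * np.abs(csd_map).max()

    def test_gaussian_profile_round_trip_correlation(self):
        prof = balanced_sink_profile(16, 8)
        t = np.linspace(0, 100, 80)
        csd_map = 2.5e4 * np.outer(prof, np.exp(-0.5 * ((t - 45) / 8) ** 2))
        phi = forward_potentials_from_csd(csd_map, 150.0, 0.3)
        back = compute_icsd(phi * 1e6, t, 150.0, 0.3).values
        rel = np.max(np.abs(back - csd_map)) / np.abs(csd_map).max()
        assert rel < 1e-9
        r = np.corrcoef(back.ravel(), csd_map.ravel())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_unbalanced_input_rejected_unless_projected(self):
        impulse = np.zeros((16, 1))
        impulse[7, 0] = 1.0
        with pytest.raises(ValueError, match="charge-balanced"):
            forward_potentials_from_csd(impulse, 150.0)
        phi = forward_potentials_from_csd(impulse, 150.0, balance=True)
        assert np.all(np.isfinite(phi))

    def test_degenerate_geometry_fails(self):
        with pytest.raises(ValueError, match="spacing"):
            forward_potentials_from_csd(np.zeros((16, 2)), 0.0)
        with pytest.raises(ValueError):
            forward_potentials_from_csd(np.zeros((2, 2)), 150.0)


class TestCoupledOscillations:
    def test_empty_coupling_gives_no_latents_and_low_coherence(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, coupling_spec=(), common_noise_gain=0.0,
            evoked_csd_peak=0.0,  # stimulus-locked dipole is shared by design
            n_trials_per_condition=10,  # enough data to bound estimator bias
        )
        latents, chans, mixing = simulate_coupled_oscillations(
            cfg, 500, np.random.default_rng(0)
        )
        assert latents.shape[0] == 0 and chans == []
        # Whole-session check: channels are independent noise.
        rec, _ = generate_session(cfg)
        lfp, fs = preprocess.extract_lfp(rec, fs_target_hz=1000.0)
        f, coh = scipy.signal.coherence(lfp[3], lfp[10], fs=fs, nperseg=1024)
        band = (f >= 4) & (f <= 55)
        assert coh[band].max() < 0.1

    def test_single_edge_cross_correlation_peaks_at_lag(self):
        cfg = SynthConfig(
            seed=3,
            coupling_spec=(CouplingEdge(11, 5, "gamma", 0.9, 5.0),),
        )
        latents, chans, _ = simulate_coupled_oscillations(
            cfg, 20000, np.random.default_rng(5), diameter=15.0
        )
        src, tgt = latents[chans.index(11)], latents[chans.index(5)]
        lags = scipy.signal.correlation_lags(len(tgt), len(src))
        xc = scipy.signal.correlate(tgt, src)
        keep = np.abs(lags) <= 50
        peak_lag = lags[keep][np.argmax(xc[keep])]
        assert abs(peak_lag - 5) <= 1  # samples at 1 kHz = ms

    def test_common_noise_correlation_without_lag_asymmetry(self):
        rng = np.random.default_rng(2)
        n = 40000
        common = rng.standard_normal(n)
        x = common + 0.5 * rng.standard_normal(n)
        y = 0.9 * common + 0.5 * rng.standard_normal(n)
        # Instantaneous mixture: strong zero-lag correlation...
        r0 = np.corrcoef(x, y)[0, 1]
        assert r0 > 0.5
        # ... and a symmetric cross-correlation (no lead/lag structure).
        lags = scipy.signal.correlation_lags(n, n)
        xc = scipy.signal.correlate(y - y.mean(), x - x.mean()) / n
        pos = xc[(np.abs(lags) <= 20) & (lags > 0)]
        neg = xc[(np.abs(lags) <= 20) & (lags < 0)][::-1]
        assert np.max(np.abs(pos - neg)) < 0.2 * r0

    def test_unstable_network_raises(self):
        cfg = SynthConfig(seed=0)
        cfg.osc_pole_radius = 1.01
        with pytest.raises(ValueError, match="unstable"):
            simulate_coupled_oscillations(cfg, 100, np.random.default_rng(0))


class TestMuaCarrier:
    def test_zero_amplitude_profile_is_stationary(self, small_config):
        import dataclasses

        flat = {
            layer: dict(p, peak1=0.0, peak2=0.0, plateau=0.0)
            for layer, p in small_config.latency_params_by_layer.items()
        }
        cfg = dataclasses.replace(small_config, latency_params_by_layer=flat)
        events = make_events(cfg, np.random.default_rng(0))
        n = int(cfg.duration_s * cfg.fs_raw_hz)
        carrier = simulate_mua_carrier(cfg, events, n, np.random.default_rng(1))
        # Envelope never modulates: RMS in stimulus vs blank periods matches.
        fs = cfg.fs_raw_hz
        on = int(events.iloc[0]["onset_s"] * fs)
        stim_rms = carrier[:, on : on + int(0.5 * fs)].std()
        blank_rms = carrier[:, on - int(0.5 * fs) : on].std()
        assert stim_rms == pytest.approx(blank_rms, rel=0.05)

    def test_ground_truth_latency_is_dense_grid_crossing(self, default_session):
        cfg, _, gt = default_session
        for (ch, d) in [(8, 0.5), (5, 15.0), (11, 3.0)]:
            p = cfg.latency_params_by_layer[cfg.layer_of(ch)]
            frac = cfg.size_fraction(d)
            amp = 1.0 - p["amp_suppression"] * frac
            shift = p["mu_shift_ms"] * frac
            params = dict(
                G1=p["peak1"] * amp * np.sqrt(2 * np.pi) * p["sigma1"],
                mu1=p["mu1"] + shift, sigma1=p["sigma1"],
                G2=p["peak2"] * amp * np.sqrt(2 * np.pi) * p["sigma2"],
                mu2=p["mu2"] + shift, sigma2=p["sigma2"],
                G3=p["plateau"] * amp, mu3=p["mu3"] + shift, sigma3=p["sigma3"],
            )
            expected = brute_force_crossing(params, threshold=3.0)
            assert gt.true_latency_ms[(ch, d)] == pytest.approx(expected, abs=1e-9)

    def test_latency_order_preserved_between_offset_channels(self):
        # Two compartments with a 7 ms planted latency offset: the measured
        # MUAe onset order must be preserved across seeds.
        base = dict(
            peak1=8.0, mu1=55.0, sigma1=8.0, peak2=0.0, mu2=95.0, sigma2=18.0,
            plateau=3.5, mu3=60.0, sigma3=15.0, mu_shift_ms=0.0, amp_suppression=0.0,
        )
        late = dict(base, mu1=62.0, mu3=67.0)
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SynthConfig(
                seed=seed, fs_raw_hz=4000.0, mua_band_hz=(600.0, 1800.0),
                n_trials_per_condition=10, diameters_deg=(3.0,),
                coupling_spec=(), common_noise_gain=0.0,
                latency_params_by_layer=dict(
                    granular=base, infragranular=late, supragranular=base
                ),
            )
            rec, gt = generate_session(cfg)
            muae, fs = preprocess.extract_muae(
                rec, fs_target_hz=1000.0, band_hz=cfg.mua_band_hz
            )
            ep = preprocess.epoch_trials(muae, fs, rec.events, "MUAe")
            z = preprocess.zscore_to_baseline(ep)
            avg = z.data.mean(axis=0)
            t = z.time_ms
            # first threshold crossing of the trial-averaged z trace
            def onset(tr):
                hits = np.where((t >= 0) & (tr > 3.0))[0]
                return t[hits[0]] if hits.size else np.inf
            early = onset(avg[7])  # granular contact 8
            late_on = onset(avg[10])  # infragranular contact 11
            ok += early < late_on
        assert ok >= 0.95 * n_seeds


class TestGenerateSession:
    def test_same_seed_bit_identical(self, small_config):
        rec1, _ = generate_session(small_config)
        rec2, _ = generate_session(small_config)
        assert np.array_equal(rec1.samples, rec2.samples)
        assert rec1.events.equals(rec2.events)

    def test_event_count_and_structure(self, default_session):
        _, rec, _ = default_session
        assert len(rec.events) == 120
        onsets = rec.events["onset_s"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert np.allclose(np.diff(onsets), 1.0)  # 500 ms blank + 500 ms stimulus

    def test_default_session_passes_qc(self, preprocessed, default_session):
        _, _, gt = default_session
        profile = csd_from_epoched(preprocessed["lfp"], 150.0)
        report = qc_session(profile)
        assert report.passed
        assert report.alignment_channel == gt.sink_channel
        assert 7 <= report.alignment_channel <= 12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sink_channel"):
            SynthConfig(sink_channel=20)
        with pytest.raises(ValueError, match="MUA band"):
            SynthConfig(fs_raw_hz=4000.0)  # default MUA band up to 3.6 kHz
        with pytest.raises(ValueError, match="lags"):
            SynthConfig(coupling_spec=(CouplingEdge(1, 2, "gamma", 0.5, 0.0),))
        with pytest.raises(ValueError, match="divide"):
            SynthConfig(fs_raw_hz=8000.0, fs_target_hz=1017.0)
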