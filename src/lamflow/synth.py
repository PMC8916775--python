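"""Synthetic laminar V1 sessions with full ground truth.

The generator emulates a 16-contact laminar probe recording during a
passive-fixation grating protocol: each trial is 500 ms blank followed by
500 ms stimulus, with six grating diameters interleaved.  Four signal
families are composed into the raw broadband trace:

1. An evoked current dipole — a charge-balanced current sink centered on a
   configurable granular contact, peaking 35–55 ms after onset, projected
   to potentials through the exact inverse of the discrete CSD operator so
   the CSD stage has a bit-exact oracle.
2. Band-limited oscillatory latents with directed cross-channel coupling
   (lagged-oscillator network) mixed into the potentials with a dipolar
   footprint, giving ground truth for phase-triggered averaging and
   Granger causality.
3. A multi-unit carrier — band-limited noise whose amplitude follows a
   per-channel, per-size transient rate profile, calibrated so the MUAe
   z-score tracks the planted profile; the noiseless profile's dense-grid
   threshold crossing is the latency ground truth.
4. Background 1/f-ish noise, sensor noise, and a shared common-noise
   component with depth-varying gain for reversal-test scenarios.

Everything is deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .containers import GroundTruth, SessionRecording
from .latency import transient_response

__all__ = [
    "BANDS",
    "CouplingEdge",
    "SynthConfig",
    "forward_potentials_from_csd",
    "simulate_coupled_oscillations",
    "simulate_mua_carrier",
    "generate_session",
]

#: Analysis frequency bands (Hz).  The gamma band used for band power is
#: 35-55 Hz; the phase-triggered-averaging module uses its own 30-55 Hz
#: definition.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 25.0),
    "gamma": (35.0, 55.0),
}


@dataclass(frozen=True)
class CouplingEdge:
    """Directed lagged coupling between two contacts in one band."""

    source: int  # 1-based channel from the top
    target: int
    band: str
    strength: float
    lag_ms: float


def _default_coupling() -> tuple[CouplingEdge, ...]:
    # Deep-to-superficial gamma routing: layer 5 -> layer 6 -> supragranular,
    # plus a granular -> supragranular edge.
    return (
        CouplingEdge(source=11, target=14, band="gamma", strength=0.8, lag_ms=4.0),
        CouplingEdge(source=14, target=5, band="gamma", strength=0.7, lag_ms=5.0),
        CouplingEdge(source=8, target=5, band="gamma", strength=0.6, lag_ms=3.0),
    )


def default_latency_params() -> dict[str, dict[str, float]]:
    """Per-compartment transient-response parameters.

    Amplitudes are peak z-scores (converted internally to the normalized-
    Gaussian amplitudes of the response model).  ``mu_shift_ms`` is the
    shift of the transient center from the smallest to the largest
    stimulus; ``amp_suppression`` the fractional amplitude loss at the
    largest size (surround suppression).
    """
    return {
        "granular": dict(
            peak1=8.0, mu1=55.0, sigma1=8.0,
            peak2=1.5, mu2=95.0, sigma2=18.0,
            plateau=3.5, mu3=60.0, sigma3=15.0,
            mu_shift_ms=3.0, amp_suppression=0.35,
        ),
        "infragranular": dict(
            peak1=7.0, mu1=62.0, sigma1=8.0,
            peak2=1.2, mu2=100.0, sigma2=18.0,
            plateau=3.0, mu3=67.0, sigma3=15.0,
            mu_shift_ms=-6.0, amp_suppression=0.20,
        ),
        "supragranular": dict(
            peak1=6.5, mu1=70.0, sigma1=9.0,
            peak2=1.0, mu2=110.0, sigma2=20.0,
            plateau=3.2, mu3=75.0, sigma3=16.0,
            mu_shift_ms=0.0, amp_suppression=0.45,
        ),
    }


@dataclass
class SynthConfig:
    """Study-condition constants and generator knobs.

    Defaults follow the recording protocol being emulated: 16 contacts at
    150 µm, six grating diameters, 500 ms blank + 500 ms stimulus per
    trial, granular sink peaking 45 ms after onset.  The raw rate defaults
    to 8 kHz (the same filter chains apply at 32 kHz, configurable) with
    the multi-unit band scaled to fit below Nyquist.
    """

    n_channels: int = 16
    spacing_um: float = 150.0
    fs_raw_hz: float = 8000.0
    fs_target_hz: float = 1000.0
    n_trials_per_condition: int = 20
    diameters_deg: tuple[float, ...] = (0.5, 0.75, 1.5, 3.0, 7.0, 15.0)
    sink_channel: int = 8  # 1-based from the top
    sink_peak_ms: float = 45.0
    coupling_spec: tuple[CouplingEdge, ...] = field(default_factory=_default_coupling)
    common_noise_gain: float = 0.5
    mua_band_hz: tuple[float, float] = (600.0, 3600.0)
    latency_params_by_layer: dict[str, dict[str, float]] | None = None
    seed: int = 0
    # Amplitudes (µV except the CSD peak).
    evoked_csd_peak: float = 1500.0  # A/m^3 at the smallest stimulus
    osc_amp_uv: float = 35.0
    background_noise_uv: float = 30.0
    sensor_noise_uv: float = 8.0
    mua_baseline_uv: float = 15.0
    # Gamma peak frequency range across sizes (smallest -> largest).
    gamma_freq_range_hz: tuple[float, float] = (45.0, 38.0)
    osc_pole_radius: float = 0.93
    sigma_s_per_m: float = 0.3

    def __post_init__(self) -> None:
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if not 1 <= self.sink_channel <= self.n_channels:
            raise ValueError("sink_channel outside probe")
        if self.fs_raw_hz < 2.0 * self.mua_band_hz[1]:
            raise ValueError("fs_raw_hz must be at least twice the MUA band upper edge")
        if self.fs_raw_hz % self.fs_target_hz:
            raise ValueError("fs_target_hz must divide fs_raw_hz")
        if not 35.0 <= self.sink_peak_ms <= 55.0:
            raise ValueError("sink_peak_ms must lie in [35, 55] ms")
        for e in self.coupling_spec:
            if e.lag_ms <= 0:
                raise ValueError("coupling lags must be positive")
            lo, hi = BANDS[e.band]
            if not 0 < lo < hi < self.fs_target_hz / 2:
                raise ValueError(f"band {e.band} outside (0, Nyquist)")
            for ch in (e.source, e.target):
                if not 1 <= ch <= self.n_channels:
                    raise ValueError("coupling channel outside probe")
        if self.latency_params_by_layer is None:
            self.latency_params_by_layer = default_latency_params()

    # -- derived protocol layout ------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(self.diameters_deg)

    @property
    def trial_s(self) -> float:
        return 1.0  # 500 ms blank + 500 ms stimulus

    @property
    def lead_s(self) -> float:
        return 1.0

    @property
    def duration_s(self) -> float:
        return 2 * self.lead_s + self.n_trials * self.trial_s

    def layer_of(self, channel: int) -> str:
        depth = (self.sink_channel - channel) * self.spacing_um
        if depth > 0:
            return "supragranular"
        if depth == 0:
            return "granular"
        return "infragranular"

    def size_fraction(self, diameter: float) -> float:
        order = sorted(self.diameters_deg)
        i = order.index(diameter)
        return i / max(len(order) - 1, 1)

    def gamma_freq(self, diameter: float) -> float:
        f0, f1 = self.gamma_freq_range_hz
        return f0 + (f1 - f0) * self.size_fraction(diameter)


# ---------------------------------------------------------------------------
# Forward volume-conduction model (exact inverse of the discrete CSD operator)
# ---------------------------------------------------------------------------


def csd_operator(n_channels: int, spacing_um: float, sigma_s_per_m: float) -> np.ndarray:
    """The discrete CSD matrix with duplicated-endpoint (Vaknin) handling.

    Maps potentials (V) to CSD (A/m^3): ``-sigma * D2 / h^2`` where ``D2``
    is the second spatial difference with the boundary potentials
    duplicated, so the output keeps all ``n_channels`` rows.
    """
    if n_channels < 3:
        raise ValueError("CSD operator needs at least 3 channels")
    if spacing_um <= 0:
        raise ValueError("degenerate geometry: spacing must be positive")
    h_m = spacing_um * 1e-6
    t = np.zeros((n_channels, n_channels))
    for i in range(n_channels):
        lo, hi = max(i - 1, 0), min(i + 1, n_channels - 1)
        t[i, lo] += 1.0
        t[i, i] += -2.0
        t[i, hi] += 1.0
    return -(sigma_s_per_m / h_m**2) * t


def forward_potentials_from_csd(
    csd_map: np.ndarray,
    spacing_um: float,
    sigma_s_per_m: float = 0.3,
    balance: bool = False,
) -> np.ndarray:
    """Potentials (V) whose discrete CSD equals ``csd_map`` exactly.

    The CSD operator annihilates depth-constant potentials, so its range is
    the charge-balanced subspace (columns of CSD summing to zero over
    depth).  Input maps must be balanced; pass ``balance=True`` to project
    an unbalanced map by removing its depth mean.  The returned potentials
    use the zero-depth-mean gauge.

    Parameters
    ----------
    csd_map : ndarray, (channels, time) or (channels,)
        Planted CSD in A/m^3, sink-positive.
    """
    x = np.atleast_2d(np.asarray(csd_map, dtype=float).T).T
    if not np.all(np.isfinite(x)):
        raise ValueError("CSD map must be finite")
    n = x.shape[0]
    m = csd_operator(n, spacing_um, sigma_s_per_m)
    col_mean = x.mean(axis=0)
    if balance:
        x = x - col_mean
    elif np.any(np.abs(col_mean) > 1e-9 * (np.abs(x).max() + 1e-300)):
        raise ValueError(
            "CSD map is not charge-balanced (columns must sum to zero over "
            "depth); pass balance=True to project"
        )
    phi = np.linalg.pinv(m, rcond=1e-12) @ x
    phi -= phi.mean(axis=0)  # zero-mean gauge
    return phi.reshape(np.shape(csd_map))


def balanced_sink_profile(
    n_channels: int, sink_channel: int, width_channels: float = 0.9
) -> np.ndarray:
    """Charge-balanced depth profile with a Gaussian sink of unit peak.

    The compensating (source) current is spread uniformly over depth, so
    the profile sums to zero and lies in the CSD operator's range.
    """
    ch = np.arange(1, n_channels + 1)
    g = np.exp(-0.5 * ((ch - sink_channel) / width_channels) ** 2)
    g -= g.mean()
    return g / g.max()


# ---------------------------------------------------------------------------
# Coupled band-limited oscillations
# ---------------------------------------------------------------------------


def _ar2_coeffs(freq_hz: float, fs_hz: float, r: float) -> tuple[float, float]:
    a1 = 2.0 * r * np.cos(2.0 * np.pi * freq_hz / fs_hz)
    a2 = -(r**2)
    return a1, a2


def _stability_radius(a1: float, a2: float) -> float:
    roots = np.roots([1.0, -a1, -a2])
    return float(np.max(np.abs(roots)))


def simulate_coupled_oscillations(
    config: SynthConfig,
    n_samples: int,
    rng: np.random.Generator,
    diameter: float | None = None,
) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Simulate the latent oscillator network for one trial.

    Each channel named in ``coupling_spec`` gets a latent: a stable
    resonant AR(2) process (pole radius ``osc_pole_radius`` at the band
    center, or at the size-dependent gamma frequency for gamma-band
    latents) plus, for coupling targets, lagged copies of their source
    latents (lagged-oscillator coupling, so the planted lag is exactly the
    peak of the latent cross-correlation).  Latents are normalized to unit
    variance.

    Returns
    -------
    latents : ndarray (n_latents, n_samples)
    latent_channels : list of 1-based channel ids, one per latent
    mixing : ndarray (n_latents, n_channels)
        Dipolar potential footprint of each latent (unit bipolar gain at
        its home contact).
    """
    channels: list[int] = []
    for e in config.coupling_spec:
        for ch in (e.source, e.target):
            if ch not in channels:
                channels.append(ch)
    n_lat = len(channels)
    if n_lat == 0:
        return np.zeros((0, n_samples)), [], np.zeros((0, config.n_channels))

    fs = config.fs_target_hz
    band_of: dict[int, str] = {}
    for e in config.coupling_spec:
        band_of.setdefault(e.source, e.band)
        band_of.setdefault(e.target, e.band)

    max_lag = max(int(round(e.lag_ms * fs / 1000.0)) for e in config.coupling_spec)
    burn = 300 + 3 * max_lag
    total = n_samples + burn

    own = np.empty((n_lat, total))
    for i, ch in enumerate(channels):
        band = band_of[ch]
        lo, hi = BANDS[band]
        if band == "gamma" and diameter is not None:
            f = config.gamma_freq(diameter)
        else:
            f = 0.5 * (lo + hi)
        a1, a2 = _ar2_coeffs(f, fs, config.osc_pole_radius)
        if _stability_radius(a1, a2) >= 1.0:
            raise ValueError(f"unstable oscillator for band {band}")
        # Band-shaped innovations: a gentle (1st-order, widened) band-pass
        # on the drive suppresses the low-frequency shoulder a resonant
        # AR(2) would otherwise carry while leaving enough innovation
        # bandwidth for the directed coupling to stay Granger-detectable.
        sos = scipy.signal.butter(
            1, (0.7 * lo, min(1.3 * hi, 0.45 * fs)), btype="bandpass",
            fs=fs, output="sos",
        )
        e = scipy.signal.sosfilt(sos, rng.standard_normal(total))
        x = np.empty(total)
        x[0] = e[0]
        x[1] = a1 * x[0] + e[1]
        for t in range(2, total):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
        own[i] = x / x.std()

    latents = own.copy()
    # Topological accumulation: apply edges repeatedly so chains propagate.
    idx = {ch: i for i, ch in enumerate(channels)}
    for _ in range(n_lat):
        updated = own.copy()
        for e in config.coupling_spec:
            lag = int(round(e.lag_ms * fs / 1000.0))
            src = latents[idx[e.source]]
            shifted = np.concatenate([np.zeros(lag), src[:-lag]]) if lag else src
            updated[idx[e.target]] = updated[idx[e.target]] + e.strength * shifted
        latents = updated
    latents = latents[:, burn:]
    latents /= latents.std(axis=1, keepdims=True)

    mixing = np.zeros((n_lat, config.n_channels))
    for i, ch in enumerate(channels):
        # +/- 0.5 on the flanking contacts: the centered-difference bipolar
        # signal at the home contact recovers the latent with unit gain.
        if ch - 2 >= 0:
            mixing[i, ch - 2] = 0.5
        if ch <= config.n_channels - 1:
            mixing[i, ch] = -0.5
    return latents, channels, mixing


# ---------------------------------------------------------------------------
# Multi-unit carrier
# ---------------------------------------------------------------------------


def rate_profile(config: SynthConfig, channel: int, diameter: float, t_ms: np.ndarray) -> np.ndarray:
    """Noiseless MUAe rate profile (z-units) for one contact and size.

    Zero before stimulus onset (t < 0); the transient-response model with
    size-dependent amplitude scaling and transient-center shift afterwards.
    """
    p = config.latency_params_by_layer[config.layer_of(channel)]
    frac = config.size_fraction(diameter)
    amp = 1.0 - p["amp_suppression"] * frac
    shift = p["mu_shift_ms"] * frac
    params = dict(
        G1=p["peak1"] * amp * np.sqrt(2 * np.pi) * p["sigma1"],
        mu1=p["mu1"] + shift, sigma1=p["sigma1"],
        G2=p["peak2"] * amp * np.sqrt(2 * np.pi) * p["sigma2"],
        mu2=p["mu2"] + shift, sigma2=p["sigma2"],
        G3=p["plateau"] * amp, mu3=p["mu3"] + shift, sigma3=p["sigma3"],
    )
    out = transient_response(np.asarray(t_ms, dtype=float), **params)
    return np.where(np.asarray(t_ms) < 0, 0.0, out)


def true_threshold_latency(
    config: SynthConfig, channel: int, diameter: float, threshold: float = 3.0,
    window_ms: tuple[float, float] = (0.0, 200.0), grid_ms: float = 0.1,
) -> float:
    """Dense-grid threshold crossing of the noiseless rate profile (NaN if none)."""
    t = np.arange(window_ms[0], window_ms[1] + grid_ms / 2, grid_ms)
    r = rate_profile(config, channel, diameter, t)
    above = np.nonzero(r > threshold)[0]
    return float(t[above[0]]) if above.size else float("nan")


def _muae_chain_stats(config: SynthConfig) -> tuple[float, float]:
    """Mean and SD of the MUAe of a unit-RMS carrier, for envelope scaling.

    Runs the rectify -> 200 Hz low-pass -> decimate chain on a fixed
    2-second unit carrier; deterministic for a given configuration.
    """
    rng = np.random.default_rng(987654321)
    n = int(2.0 * config.fs_raw_hz)
    sos = scipy.signal.butter(
        3, config.mua_band_hz, btype="bandpass", fs=config.fs_raw_hz, output="sos"
    )
    carrier = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    carrier /= carrier.std()
    sos_lp = scipy.signal.butter(3, 200.0, btype="lowpass", fs=config.fs_raw_hz, output="sos")
    env = scipy.signal.sosfiltfilt(sos_lp, np.abs(carrier))
    dec = env[:: int(config.fs_raw_hz // config.fs_target_hz)]
    dec = dec[50:-50]  # drop filter edges
    return float(dec.mean()), float(dec.std())


def simulate_mua_carrier(
    config: SynthConfig,
    events: pd.DataFrame,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated band-limited carrier for the whole session (µV).

    The envelope is ``A0 * (1 + R(t) * sd/mean)`` where R is the planted
    z-profile and (mean, sd) are the MUAe statistics of a unit carrier, so
    the baseline-z-scored MUAe tracks R(t) in expectation.
    """
    fs = config.fs_raw_hz
    sos = scipy.signal.butter(3, config.mua_band_hz, btype="bandpass", fs=fs, output="sos")
    carrier = scipy.signal.sosfilt(sos, rng.standard_normal((config.n_channels, n_samples)), axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)

    kappa, sd1 = _muae_chain_stats(config)
    gain = sd1 / kappa

    stim_len = int(round(0.5 * fs))
    t_stim_ms = np.arange(stim_len) / fs * 1000.0
    env = np.ones((config.n_channels, n_samples))
    profiles: dict[float, np.ndarray] = {}
    for d in config.diameters_deg:
        prof = np.stack(
            [rate_profile(config, ch, d, t_stim_ms) for ch in range(1, config.n_channels + 1)]
        )
        profiles[d] = np.maximum(1.0 + gain * prof, 0.05)
    for _, ev in events.iterrows():
        i0 = int(round(ev["onset_s"] * fs))
        env[:, i0 : i0 + stim_len] = profiles[float(ev["diameter_deg"])]
    return config.mua_baseline_uv * env * carrier


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], pole: float) -> np.ndarray:
    w = rng.standard_normal(shape)
    x = scipy.signal.lfilter([1.0], [1.0, -pole], w, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def make_events(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    diameters = np.repeat(config.diameters_deg, config.n_trials_per_condition)
    diameters = rng.permutation(diameters)
    onsets = config.lead_s + np.arange(config.n_trials) * config.trial_s + 0.5
    return pd.DataFrame(
        {"onset_s": onsets, "diameter_deg": diameters, "trial_id": np.arange(config.n_trials)}
    )


def generate_session(config: SynthConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate one full synthetic session with ground truth.

    Deterministic for a fixed ``config.seed``: the master seed spawns one
    named stream per signal family.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(6)
    rng_events, rng_bg, rng_common, rng_osc, rng_mua, rng_sensor = (
        np.random.default_rng(s) for s in streams
    )

    fs = config.fs_raw_hz
    n_samples = int(round(config.duration_s * fs))
    events = make_events(config, rng_events)

    samples = config.background_noise_uv * _ar1_noise(
        rng_bg, (config.n_channels, n_samples), pole=0.995
    )
    samples += config.sensor_noise_uv * rng_sensor.standard_normal(
        (config.n_channels, n_samples)
    )

    if config.common_noise_gain > 0:
        common = _ar1_noise(rng_common, (n_samples,), pole=0.995)
        gains = config.common_noise_gain * (
            1.0 + 0.3 * rng_common.standard_normal(config.n_channels)
        )
        samples += 20.0 * gains[:, None] * common[None, :]

    # --- evoked current dipole -------------------------------------------
    spatial = config.evoked_csd_peak * balanced_sink_profile(
        config.n_channels, config.sink_channel
    )
    phi_spatial_uv = (
        forward_potentials_from_csd(spatial, config.spacing_um, config.sigma_s_per_m) * 1e6
    )
    t_trial_ms = np.arange(int(round(0.5 * fs))) / fs * 1000.0
    temporal = np.exp(-0.5 * ((t_trial_ms - config.sink_peak_ms) / 8.0) ** 2)
    evoked_amp = {
        d: 1.0 - 0.3 * config.size_fraction(d) for d in config.diameters_deg
    }
    for _, ev in events.iterrows():
        i0 = int(round(ev["onset_s"] * fs))
        a = evoked_amp[float(ev["diameter_deg"])]
        samples[:, i0 : i0 + temporal.size] += a * np.outer(phi_spatial_uv, temporal)

    # --- coupled oscillations --------------------------------------------
    factor = int(fs // config.fs_target_hz)
    stim_len_t = int(round(0.5 * config.fs_target_hz))
    ramp = np.clip((np.arange(stim_len_t) / config.fs_target_hz * 1000.0 - 100.0) / 80.0, 0.0, 1.0)
    mixing = np.zeros((0, config.n_channels))
    for _, ev in events.iterrows():
        d = float(ev["diameter_deg"])
        latents, latent_channels, mixing = simulate_coupled_oscillations(
            config, stim_len_t, rng_osc, diameter=d
        )
        if latents.shape[0] == 0:
            break
        amp = config.osc_amp_uv * (0.35 + 0.65 * config.size_fraction(d))
        contrib_t = (amp * (latents * ramp)).T @ mixing  # (time, channels)
        contrib_raw = scipy.signal.resample_poly(contrib_t, factor, 1, axis=0)
        i0 = int(round(ev["onset_s"] * fs))
        samples[:, i0 : i0 + contrib_raw.shape[0]] += contrib_raw.T

    # --- multi-unit carrier ----------------------------------------------
    samples += simulate_mua_carrier(config, events, n_samples, rng_mua)

    # --- ground truth -----------------------------------------------------
    t_csd_ms = np.arange(0.0, 200.0, 1000.0 / config.fs_target_hz)
    temporal_t = np.exp(-0.5 * ((t_csd_ms - config.sink_peak_ms) / 8.0) ** 2)
    mean_amp = float(np.mean(list(evoked_amp.values())))
    true_csd = mean_amp * np.outer(spatial, temporal_t)

    latency = {
        (ch, float(d)): true_threshold_latency(config, ch, d)
        for ch in range(1, config.n_channels + 1)
        for d in config.diameters_deg
    }
    adjacency = {
        (e.source, e.target): (e.band, e.strength, e.lag_ms) for e in config.coupling_spec
    }
    phase_lag = {(e.source, e.target): (e.band, e.lag_ms) for e in config.coupling_spec}

    gt = GroundTruth(
        true_csd=true_csd,
        true_csd_time_ms=t_csd_ms,
        sink_channel=config.sink_channel,
        sink_peak_ms=config.sink_peak_ms,
        true_latency_ms=latency,
        coupling_adjacency=adjacency,
        true_phase_lag_ms=phase_lag,
        mixing_matrix=mixing,
        seed=config.seed,
    )
    rec = SessionRecording(
        samples=samples, fs_hz=fs, events=events, spacing_um=config.spacing_um,
        ground_truth=gt,
    )
    return rec, gt
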