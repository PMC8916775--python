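"""Moving-window spectral analysis and induced power of the bipolar LFP.

The spectrogram uses 100 ms Hann-tapered windows stepped by 10 ms with a
zero-padded 1024-point FFT, so the frequency grid is fs/1024.  Induced
spectral power (iSP) expresses the stimulus-period power as a z-score
against the 300 ms pre-stimulus baseline: per trial, the power in each
stimulus window is compared with that trial's mean baseline-window power,
and the across-trial mean difference is divided by its standard error.
Under a stimulus identical to baseline this statistic is null-distributed
close to N(0, 1) per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .containers import DepthMap, EpochedSignal

__all__ = [
    "Spectrogram",
    "ISPResult",
    "spectrogram",
    "induced_power_z",
    "band_power_profile",
    "gamma_peak_frequency",
]

#: Band edges (Hz) used for band-integrated power.
POWER_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 25.0),
    "gamma": (35.0, 55.0),
}


@dataclass
class Spectrogram:
    """Moving-window power, shape (..., n_freq, n_windows)."""

    power: np.ndarray
    freq_hz: np.ndarray
    time_ms: np.ndarray  # window centers
    window_ms: float
    step_ms: float
    fs_hz: float
    n_fft: int


def spectrogram(
    data: np.ndarray,
    fs_hz: float,
    start_ms: float = 0.0,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
    n_fft: int = 1024,
    max_freq_hz: float | None = 120.0,
) -> Spectrogram:
    """Hann-tapered moving-window power spectrogram.

    Each window is demeaned, Hann-tapered, zero-padded to ``n_fft`` and
    squared in magnitude.  ``start_ms`` is the time of the first sample of
    ``data`` (e.g. −500 for an epoch starting 500 ms before onset); window
    timestamps are window centers.

    Parameters
    ----------
    data : ndarray (..., n_time)
    max_freq_hz : keep only bins up to this frequency (None for all).
    """
    data = np.asarray(data, dtype=float)
    n_time = data.shape[-1]
    n_win = int(round(window_ms * fs_hz / 1000.0))
    step = int(round(step_ms * fs_hz / 1000.0))
    if n_time < n_win:
        raise ValueError(f"trace of {n_time} samples shorter than one {n_win}-sample window")
    starts = np.arange(0, n_time - n_win + 1, step)
    taper = scipy.signal.windows.hann(n_win, sym=True)

    segs = np.stack([data[..., s : s + n_win] for s in starts], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    spec = scipy.fft.rfft(segs * taper, n=n_fft, axis=-1)
    power = np.abs(spec) ** 2
    freq = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    if max_freq_hz is not None:
        keep = freq <= max_freq_hz
        freq, power = freq[keep], power[..., keep]
    power = np.moveaxis(power, -2, -1)  # (..., n_freq, n_windows)
    centers_ms = start_ms + (starts + n_win / 2.0) * 1000.0 / fs_hz
    return Spectrogram(
        power=power, freq_hz=freq, time_ms=centers_ms,
        window_ms=window_ms, step_ms=step_ms, fs_hz=fs_hz, n_fft=n_fft,
    )


@dataclass
class ISPResult:
    """Induced spectral power as z-scores, shape (channels, n_freq, n_windows).

    ``flagged`` marks bins with zero baseline variability (excluded from
    summaries).
    """

    z: np.ndarray
    freq_hz: np.ndarray
    time_ms: np.ndarray
    flagged: np.ndarray
    n_trials: int
    method: str


def induced_power_z(
    spec: Spectrogram,
    baseline_ms: tuple[float, float] = (-300.0, 0.0),
    method: str = "trial-mean",
) -> ISPResult:
    """Z-score a (trials, channels, freq, windows) spectrogram to baseline.

    ``trial-mean`` (default): per trial and bin, subtract that trial's mean
    baseline-window power; z = across-trial mean difference / its s.e.m.
    ``single-trial``: z-score each trial's power against the across-trial
    distribution of baseline power (mean over baseline windows), then
    average z over trials.
    """
    if spec.power.ndim != 4:
        raise ValueError("expected (trials, channels, freq, windows) power")
    base_mask = (spec.time_ms >= baseline_ms[0]) & (spec.time_ms < baseline_ms[1])
    if not base_mask.any():
        raise ValueError("no spectrogram windows inside the baseline")
    n_trials = spec.power.shape[0]
    base = spec.power[:, :, :, base_mask].mean(axis=3)  # (trials, ch, freq)

    if method == "trial-mean":
        diff = spec.power - base[:, :, :, None]
        sd = diff.std(axis=0, ddof=1)
        flagged = sd == 0
        sem = np.where(flagged, np.nan, sd) / np.sqrt(n_trials)
        z = diff.mean(axis=0) / sem
    elif method == "single-trial":
        mu = base.mean(axis=0)
        sd = base.std(axis=0, ddof=1)
        flagged = sd == 0
        sd = np.where(flagged, np.nan, sd)
        z = ((spec.power - mu[None, :, :, None]) / sd[None, :, :, None]).mean(axis=0)
        flagged = flagged[:, :, None]
    else:
        raise ValueError(f"unknown method {method!r}")
    return ISPResult(
        z=z, freq_hz=spec.freq_hz, time_ms=spec.time_ms,
        flagged=np.broadcast_to(flagged, z.shape).copy() if flagged.shape != z.shape else flagged,
        n_trials=n_trials, method=method,
    )


def band_power_profile(
    isp: ISPResult,
    bands: dict[str, tuple[float, float]] = POWER_BANDS,
    window_ms: tuple[float, float] = (200.0, 500.0),
    channel_ids: np.ndarray | None = None,
    depths: DepthMap | None = None,
) -> pd.DataFrame:
    """Mean iSP z per band and channel over the sustained window.

    Returns a tidy table ``band, channel, depth_um, z, n_bins``.  Flagged
    bins are excluded; a band with no frequency bins in range raises.
    """
    t_mask = (isp.time_ms >= window_ms[0]) & (isp.time_ms < window_ms[1])
    if not t_mask.any():
        raise ValueError("sustained window contains no spectrogram timestamps")
    n_ch = isp.z.shape[0]
    if channel_ids is None:
        channel_ids = np.arange(1, n_ch + 1)
    rows = []
    for band, (lo, hi) in bands.items():
        f_mask = (isp.freq_hz >= lo) & (isp.freq_hz <= hi)
        if not f_mask.any():
            raise ValueError(f"band {band} [{lo}, {hi}] Hz has no frequency bins")
        for ci in range(n_ch):
            vals = isp.z[ci][np.ix_(f_mask, t_mask)]
            ok = ~isp.flagged[ci][np.ix_(f_mask, t_mask)]
            rows.append(
                dict(
                    band=band,
                    channel=int(channel_ids[ci]),
                    depth_um=(
                        depths.depth_of(int(channel_ids[ci])) if depths else np.nan
                    ),
                    z=float(vals[ok].mean()) if ok.any() else np.nan,
                    n_bins=int(ok.sum()),
                )
            )
    return pd.DataFrame(rows)


def gamma_peak_frequency(
    isp: ISPResult,
    search_hz: tuple[float, float] = (25.0, 65.0),
    window_ms: tuple[float, float] = (200.0, 500.0),
    channels: np.ndarray | None = None,
) -> float:
    """Frequency of maximal sustained iSP in the gamma search range.

    Averages z over the sustained window (and over ``channels`` if given,
    else all) and returns the frequency bin of the maximum.  NaN when no
    bin in the range has positive z.
    """
    t_mask = (isp.time_ms >= window_ms[0]) & (isp.time_ms < window_ms[1])
    f_mask = (isp.freq_hz >= search_hz[0]) & (isp.freq_hz <= search_hz[1])
    z = isp.z if channels is None else isp.z[np.asarray(channels)]
    with np.errstate(invalid="ignore"):
        mean_z = np.nanmean(z[:, :, t_mask], axis=(0, 2))
    band = mean_z[f_mask]
    if not np.any(band > 0):
        return float("nan")
    return float(isp.freq_hz[f_mask][np.nanargmax(band)])
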