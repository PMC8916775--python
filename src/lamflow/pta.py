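"""Phase-triggered averaging of the broadband bipolar LFP.

A reference contact's bipolar LFP is band-pass filtered (zero-phase
3rd-order Butterworth) to give the phase-providing signal; its troughs
inside the sustained window act as alignment points.  The *broadband*
(unfiltered) bipolar LFP of every contact — the amplitude-providing
signal — is then averaged in a band-specific window around each trough
(±120, 80, 80, 25 ms for θ, α, β, γ).  Temporal structure in the average
reveals oscillations phase-coupled to the reference, and the displacement
of the extremum nearest lag 0 measures the phase lag.

The γ band here is 30–55 Hz (the phase-extraction definition), intentionally
different from the 35–55 Hz band used for band-integrated power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .containers import EpochedSignal

__all__ = [
    "PTA_BANDS",
    "PTA_HALF_WIDTH_MS",
    "PTAProfile",
    "detect_phase_triggers",
    "phase_triggered_average",
    "pta_lag",
]

logger = logging.getLogger(__name__)

#: Band edges (Hz) for phase extraction.
PTA_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 25.0),
    "gamma": (30.0, 55.0),
}

#: Averaging half-width (ms) per band.
PTA_HALF_WIDTH_MS: dict[str, float] = {
    "theta": 120.0,
    "alpha": 80.0,
    "beta": 80.0,
    "gamma": 25.0,
}


@dataclass
class PTAProfile:
    """Channel x lag phase-triggered averages (µV) around reference troughs."""

    averages: np.ndarray  # (channels, lags)
    lag_ms: np.ndarray  # symmetric about 0
    channel_ids: np.ndarray
    reference_channel: int
    band: str
    n_triggers: int
    triggers_per_trial: np.ndarray


def bandpass_phase_signal(
    data: np.ndarray, fs_hz: float, band: str | tuple[float, float]
) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass along the last axis."""
    corners = PTA_BANDS[band] if isinstance(band, str) else band
    if not 0 < corners[0] < corners[1] < fs_hz / 2:
        raise ValueError(f"band corners {corners} outside (0, Nyquist)")
    sos = scipy.signal.butter(3, corners, btype="bandpass", fs=fs_hz, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def detect_phase_triggers(
    reference: np.ndarray,
    time_ms: np.ndarray,
    fs_hz: float,
    band: str,
    window_ms: tuple[float, float] = (200.0, 500.0),
    half_width_ms: float | None = None,
) -> list[np.ndarray]:
    """Trough times of the band-passed reference, one array per trial.

    Troughs are strict local minima (no amplitude threshold — spurious
    noise triggers average out).  Triggers whose averaging window would
    leave the epoch are discarded.

    Parameters
    ----------
    reference : ndarray (n_trials, n_time)
        Broadband bipolar LFP of the reference contact.

    Returns
    -------
    list of ndarray — trigger sample indices (into the epoch) per trial.
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    phase_sig = bandpass_phase_signal(reference, fs_hz, band)
    if half_width_ms is None:
        half_width_ms = PTA_HALF_WIDTH_MS[band]
    half = int(round(half_width_ms * fs_hz / 1000.0))
    n_time = reference.shape[1]
    triggers: list[np.ndarray] = []
    for raw, trial in zip(reference, phase_sig):
        # Guard against numerically-zero filtered traces (e.g. a constant
        # input), whose round-off ripple would otherwise yield spurious
        # minima; real troughs of a zero-mean band-passed signal are negative.
        eps = 1e-9 * max(float(np.abs(raw).max()), 1e-300)
        minima = scipy.signal.argrelextrema(trial, np.less, order=1)[0]
        minima = minima[trial[minima] < -eps]
        in_window = minima[
            (time_ms[minima] >= window_ms[0]) & (time_ms[minima] < window_ms[1])
        ]
        valid = in_window[(in_window - half >= 0) & (in_window + half < n_time)]
        triggers.append(valid)
    total = sum(len(t) for t in triggers)
    if total == 0:
        logger.warning("no phase triggers detected in %s band", band)
    return triggers


def phase_triggered_average(
    targets: EpochedSignal,
    triggers: list[np.ndarray],
    band: str,
    reference_channel: int,
    half_width_ms: float | None = None,
) -> PTAProfile:
    """Average broadband target segments centered on each trigger.

    ``triggers`` must have one entry per trial of ``targets``; segments of
    ±half-width around every trigger are pooled across trials.
    """
    if len(triggers) != targets.n_trials:
        raise ValueError("need one trigger array per trial")
    if half_width_ms is None:
        half_width_ms = PTA_HALF_WIDTH_MS[band]
    half = int(round(half_width_ms * targets.fs_hz / 1000.0))
    lag_ms = np.arange(-half, half + 1) * 1000.0 / targets.fs_hz

    acc = np.zeros((targets.n_channels, 2 * half + 1))
    count = 0
    per_trial = np.zeros(targets.n_trials, dtype=int)
    for ti, trig in enumerate(triggers):
        for s in trig:
            acc += targets.data[ti, :, s - half : s + half + 1]
        count += len(trig)
        per_trial[ti] = len(trig)
    averages = acc / count if count else np.full_like(acc, np.nan)
    return PTAProfile(
        averages=averages, lag_ms=lag_ms, channel_ids=targets.channel_ids,
        reference_channel=reference_channel, band=band,
        n_triggers=count, triggers_per_trial=per_trial,
    )


def pta_lag(profile: PTAProfile) -> np.ndarray:
    """Per-channel phase lag: time of the trough nearest lag 0.

    Triggers are troughs of the reference, so a phase-coupled target shows
    a trough displaced by its lag; negative lag means the target leads the
    reference.  Channels whose average has no interior local minimum get
    NaN.
    """
    lags = np.full(profile.averages.shape[0], np.nan)
    for ci, avg in enumerate(profile.averages):
        if not np.all(np.isfinite(avg)) or np.ptp(avg) == 0:
            continue
        minima = scipy.signal.argrelextrema(avg, np.less, order=1)[0]
        if minima.size == 0:
            continue
        t_min = profile.lag_ms[minima]
        lags[ci] = t_min[np.argmin(np.abs(t_min))]
    return lags
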