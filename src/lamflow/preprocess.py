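"""Raw samples → LFP, MUAe, epoched trials, bipolar LFP, baseline z-scores.

Filter chains follow the standard laminar-probe conditioning: the LFP is
the raw signal band-passed 0.75–300 Hz (3rd-order Butterworth) and
decimated to ~1 kHz; the MUAe is the raw signal band-passed in the
multi-unit range, full-wave rectified, low-passed at 200 Hz and decimated.
All filtering is zero-phase (forward–backward), so group delay cannot bias
latency estimates; decimation is by an integer factor only.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.signal

from .containers import EpochedSignal, SessionRecording

__all__ = [
    "extract_lfp",
    "extract_muae",
    "epoch_trials",
    "bipolar_reference",
    "zscore_to_baseline",
]

logger = logging.getLogger(__name__)


def _decimation_factor(fs_raw: float, fs_target: float) -> int:
    factor = fs_raw / fs_target
    if abs(factor - round(factor)) > 1e-9:
        divisors = [fs_raw / k for k in range(1, 65) if (fs_raw / k) == int(fs_raw / k)]
        raise ValueError(
            f"fs_target {fs_target} Hz does not divide fs_raw {fs_raw} Hz; "
            f"nearest valid targets: {sorted(divisors, reverse=True)[:6]}"
        )
    return int(round(factor))


def extract_lfp(
    raw: SessionRecording,
    fs_target_hz: float = 1000.0,
    band_hz: tuple[float, float] = (0.75, 300.0),
) -> tuple[np.ndarray, float]:
    """Continuous LFP: zero-phase 3rd-order Butterworth band-pass, decimate.

    Returns ``(lfp, fs)`` with ``lfp`` of shape (channels, time) in µV.
    """
    if raw.fs_hz < 2 * band_hz[1]:
        raise ValueError("raw sampling rate below twice the LFP upper corner")
    factor = _decimation_factor(raw.fs_hz, fs_target_hz)
    sos = scipy.signal.butter(3, band_hz, btype="bandpass", fs=raw.fs_hz, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, raw.samples, axis=-1)
    return filtered[:, ::factor], fs_target_hz


def extract_muae(
    raw: SessionRecording,
    fs_target_hz: float = 1000.0,
    band_hz: tuple[float, float] = (600.0, 3600.0),
    lowpass_hz: float = 200.0,
) -> tuple[np.ndarray, float]:
    """Continuous MUAe: band-pass, full-wave rectify, 200 Hz low-pass, decimate.

    The multi-unit band defaults to 600–3600 Hz (the 0.6–9 kHz chain scaled
    to an 8 kHz raw rate; pass the wider band when the raw rate allows it).
    Output is non-negative apart from low-pass filter ringing.
    """
    if raw.fs_hz < 2 * band_hz[1]:
        raise ValueError("raw sampling rate below twice the MUA band upper edge")
    factor = _decimation_factor(raw.fs_hz, fs_target_hz)
    sos_bp = scipy.signal.butter(3, band_hz, btype="bandpass", fs=raw.fs_hz, output="sos")
    sos_lp = scipy.signal.butter(3, lowpass_hz, btype="lowpass", fs=raw.fs_hz, output="sos")
    rectified = np.abs(scipy.signal.sosfiltfilt(sos_bp, raw.samples, axis=-1))
    envelope = scipy.signal.sosfiltfilt(sos_lp, rectified, axis=-1)
    return envelope[:, ::factor], fs_target_hz


def epoch_trials(
    continuous: np.ndarray,
    fs_hz: float,
    events,
    kind: str,
    window_ms: tuple[float, float] = (-500.0, 500.0),
) -> EpochedSignal:
    """Cut one trial per event around stimulus onset.

    The window is half-open [start, stop) in ms with 0-based sample
    indexing, so a [-500, 500) window at 1 kHz yields exactly 1000 samples.
    Events whose window falls outside the recording are dropped with a
    logged warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_ch, n_samp = continuous.shape
    i_start = int(np.round(window_ms[0] * fs_hz / 1000.0))
    i_stop = int(np.round(window_ms[1] * fs_hz / 1000.0))
    n_t = i_stop - i_start
    time_ms = (np.arange(i_start, i_stop)) * 1000.0 / fs_hz

    data, cond = [], []
    n_dropped = 0
    for _, ev in events.iterrows():
        i_onset = int(np.round(ev["onset_s"] * fs_hz))
        lo, hi = i_onset + i_start, i_onset + i_stop
        if lo < 0 or hi > n_samp:
            n_dropped += 1
            logger.warning(
                "dropping trial %s: window [%d, %d) outside recording",
                ev.get("trial_id", "?"), lo, hi,
            )
            continue
        data.append(continuous[:, lo:hi])
        cond.append(float(ev["diameter_deg"]))
    if n_dropped:
        logger.warning("dropped %d/%d trials at recording edges", n_dropped, len(events))
    if not data:
        raise ValueError("no trials survive epoching")
    return EpochedSignal(
        data=np.stack(data),
        time_ms=time_ms,
        fs_hz=fs_hz,
        kind=kind,
        condition=np.asarray(cond),
        channel_ids=np.arange(1, n_ch + 1),
    )


def bipolar_reference(lfp: EpochedSignal) -> EpochedSignal:
    """Bipolar LFP: centered difference Φ(i−1) − Φ(i+1) at each interior contact.

    Subtracting the potentials at the two flanking contacts removes
    volume-conducted common signals; the end contacts have no flanking
    pair and are dropped, so the output has two fewer channels.
    """
    if lfp.kind != "LFP":
        raise ValueError(f"bipolar referencing expects kind LFP, got {lfp.kind}")
    if lfp.n_channels < 3:
        raise ValueError("bipolar referencing needs at least 3 channels")
    bp = lfp.data[:, :-2, :] - lfp.data[:, 2:, :]
    return dataclasses.replace(
        lfp, data=bp, kind="LFPbp", channel_ids=lfp.channel_ids[1:-1], zscored=False
    )


def zscore_to_baseline(
    epoched: EpochedSignal, baseline_ms: tuple[float, float] = (-300.0, 0.0)
) -> EpochedSignal:
    """Z-score each channel against its pre-stimulus baseline.

    The baseline mean and standard deviation are pooled over all baseline
    samples of all trials, per channel; every sample is then transformed as
    (x − mean)/SD.
    """
    mask = epoched.time_mask(*baseline_ms)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = epoched.data[:, :, mask]  # (trials, channels, t_base)
    mu = base.mean(axis=(0, 2))
    sd = base.std(axis=(0, 2))
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero baseline variance on channel(s) {epoched.channel_ids[bad].tolist()}"
        )
    z = (epoched.data - mu[None, :, None]) / sd[None, :, None]
    return dataclasses.replace(epoched, data=z, zscored=True)
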