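"""Standard inverse-CSD, granular-sink alignment, depth maps, and session QC.

The current source density is the discrete second spatial derivative of
the trial-averaged laminar potential profile,

    CSD(z) = −σ · (Φ(z+h) − 2Φ(z) + Φ(z−h)) / h²,

with extracellular conductivity σ = 0.3 S/m and the top/bottom contacts
regained by duplicating the boundary potentials (Vaknin).  Under this
minus-sign convention current *sinks* are positive — the opposite of a
common alternative convention, so exported values state it explicitly.

Sessions are aligned across recordings at the early granular sink: the
contact whose positive CSD peak in the 35–55 ms window is largest defines
depth 0 µm (putative layer 4c), with contacts above it at positive depths.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .containers import CSDProfile, DepthMap, EpochedSignal
from .synth import csd_operator

__all__ = [
    "compute_icsd",
    "find_alignment_channel",
    "assign_depths",
    "qc_session",
    "QCReport",
    "normalize_to_sink",
]

logger = logging.getLogger(__name__)


class NoSinkError(RuntimeError):
    """Raised when no positive CSD deflection exists in the search window."""


def compute_icsd(
    vep_uv: np.ndarray,
    time_ms: np.ndarray,
    spacing_um: float,
    sigma_s_per_m: float = 0.3,
    channel_ids: np.ndarray | None = None,
) -> CSDProfile:
    """Inverse CSD of a trial-averaged potential profile.

    Parameters
    ----------
    vep_uv : ndarray (channels, time)
        Trial-averaged potentials in µV, channels ordered top-to-bottom at
        uniform spacing.  Converted to volts internally so the output is in
        SI units (A/m³).
    """
    vep_uv = np.asarray(vep_uv, dtype=float)
    if vep_uv.ndim != 2:
        raise ValueError("vep must be (channels, time)")
    n = vep_uv.shape[0]
    m = csd_operator(n, spacing_um, sigma_s_per_m)
    values = m @ (vep_uv * 1e-6)
    if channel_ids is None:
        channel_ids = np.arange(1, n + 1)
    # Depths relative to the top contact until an alignment is chosen.
    depth = -(np.asarray(channel_ids) - 1) * spacing_um
    return CSDProfile(
        values=values,
        depth_um=depth,
        time_ms=np.asarray(time_ms, dtype=float),
        sigma_s_per_m=sigma_s_per_m,
        spacing_um=spacing_um,
        channel_ids=np.asarray(channel_ids),
    )


def find_alignment_channel(
    csd: CSDProfile, window_ms: tuple[float, float] = (35.0, 55.0)
) -> tuple[int, float]:
    """Locate the early granular current sink.

    Returns the 1-based channel whose maximum positive CSD inside the
    search window is largest, and the time of that peak.  Ties break toward
    the more superficial contact with a warning.
    """
    if csd.time_ms.min() > 0 or csd.time_ms.max() < 60.0:
        raise ValueError("CSD time axis must cover at least [0, 60] ms")
    mask = (csd.time_ms >= window_ms[0]) & (csd.time_ms <= window_ms[1])
    window = csd.values[:, mask]
    peaks = window.max(axis=1)
    if peaks.max() <= 0:
        raise NoSinkError(
            f"no identifiable sink: no positive CSD in {window_ms} ms window"
        )
    best = int(np.argmax(peaks))
    ties = np.nonzero(peaks == peaks[best])[0]
    if ties.size > 1:
        logger.warning(
            "alignment tie between channels %s; choosing the most superficial",
            (ties + 1).tolist(),
        )
        best = int(ties.min())
    t_peak = float(csd.time_ms[mask][np.argmax(window[best])])
    return int(csd.channel_ids[best]), t_peak


def assign_depths(alignment_channel: int, n_channels: int, spacing_um: float) -> DepthMap:
    """Depth per contact: (alignment − channel) × spacing, alignment at 0 µm.

    Channels are 1-based top-to-bottom, so contacts above the alignment get
    positive depths (+450 µm = three contacts above).
    """
    if not 1 <= alignment_channel <= n_channels:
        raise ValueError("alignment channel outside probe")
    channels = np.arange(1, n_channels + 1)
    depth = (alignment_channel - channels) * spacing_um
    return DepthMap(
        depth_um=depth.astype(float),
        alignment_channel=alignment_channel,
        spacing_um=spacing_um,
    )


@dataclasses.dataclass
class QCReport:
    """Session quality-control outcome.

    ``criterion_results`` holds one entry per criterion: 'pass', 'fail' or
    'manual'.  A session passes when every automatable criterion passes and
    no manual flag is set to fail.
    """

    criterion_results: dict[str, str]
    notes: dict[str, str]
    alignment_channel: int | None
    sink_peak_ms: float | None

    @property
    def passed(self) -> bool:
        return all(v in ("pass", "manual") for v in self.criterion_results.values())


def qc_session(
    csd: CSDProfile,
    contact_range: tuple[int, int] = (7, 12),
    latest_peak_ms: float = 50.0,
    manual_pattern_ok: bool | None = None,
) -> QCReport:
    """Apply the session rejection criteria to a CSD profile.

    1. An identifiable early sink with peak no later than ``latest_peak_ms``.
    2. The sink contact lies between the 7th and 12th contact from the top
       (guaranteeing coverage of layers 2–6).
    3. CSD pattern consistent with the majority of sessions — a manual
       judgement, recorded but not auto-decided.
    """
    results: dict[str, str] = {}
    notes: dict[str, str] = {}
    align, t_peak = None, None
    try:
        align, t_peak = find_alignment_channel(csd)
        if t_peak <= latest_peak_ms:
            results["early_sink"] = "pass"
        else:
            results["early_sink"] = "fail"
            notes["early_sink"] = f"sink peak at {t_peak:.1f} ms > {latest_peak_ms} ms"
    except NoSinkError as exc:
        results["early_sink"] = "fail"
        notes["early_sink"] = str(exc)

    if align is None:
        results["sink_contact_range"] = "fail"
        notes["sink_contact_range"] = "no sink found"
    elif contact_range[0] <= align <= contact_range[1]:
        results["sink_contact_range"] = "pass"
    else:
        results["sink_contact_range"] = "fail"
        notes["sink_contact_range"] = (
            f"sink on contact {align}, outside [{contact_range[0]}, {contact_range[1]}]"
        )

    if manual_pattern_ok is None:
        results["pattern_consistency"] = "manual"
        notes["pattern_consistency"] = "not auto-decided; flag via manual_pattern_ok"
    else:
        results["pattern_consistency"] = "pass" if manual_pattern_ok else "fail"

    return QCReport(
        criterion_results=results, notes=notes, alignment_channel=align,
        sink_peak_ms=t_peak,
    )


def normalize_to_sink(
    csd: CSDProfile,
    alignment_channel: int,
    window_ms: tuple[float, float] = (40.0, 70.0),
) -> CSDProfile:
    """Normalize a CSD profile to its early granular sink amplitude.

    Divides by the positive peak at the alignment contact inside
    ``window_ms`` so profiles are comparable across sessions.
    """
    row = np.nonzero(csd.channel_ids == alignment_channel)[0]
    if row.size != 1:
        raise ValueError("alignment channel not in profile")
    mask = (csd.time_ms >= window_ms[0]) & (csd.time_ms <= window_ms[1])
    peak = csd.values[row[0], mask].max()
    if peak <= 0:
        raise NoSinkError("no positive peak at the alignment contact to normalize by")
    return dataclasses.replace(
        csd, values=csd.values / peak, normalization="sink-peak-normalized"
    )


def csd_from_epoched(
    lfp: EpochedSignal, spacing_um: float, sigma_s_per_m: float = 0.3
) -> CSDProfile:
    """Convenience: trial-average an epoched LFP and compute its CSD."""
    if lfp.kind != "LFP":
        raise ValueError("CSD is computed from the (unipolar) LFP")
    vep = lfp.data.mean(axis=0)
    return compute_icsd(
        vep, lfp.time_ms, spacing_um, sigma_s_per_m, channel_ids=lfp.channel_ids
    )
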