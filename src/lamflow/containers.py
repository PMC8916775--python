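"""In-memory containers and the session file format.

The central containers mirror the stages of a laminar-probe analysis:

* :class:`SessionRecording` — continuous multichannel samples plus stimulus
  events, as they come off a 16-contact probe.
* :class:`EpochedSignal` — trials x channels x time, cut around stimulus
  onset, with a ``kind`` tag tracking what the signal is (LFP, MUAe,
  bipolar LFP, CSD).
* :class:`CSDProfile` — depth x time current source density map,
  sink-positive.
* :class:`GroundTruth` — what a synthetic session actually contains
  (latencies, sink, coupling graph, mixing), so estimators can be scored.

Sessions round-trip through a small versioned HDF5 layout
(``/samples``, ``/events``, ``/geometry``, ``/ground_truth``) with a CSV
events sidecar for quick inspection.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

CONTAINER_SCHEMA_VERSION = "1.0"

#: Signal kinds an EpochedSignal may carry.
SIGNAL_KINDS = ("LFP", "MUAe", "LFPbp", "CSD")


@dataclass
class EpochedSignal:
    """Trials x channels x time array with a uniform time axis.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Signal in µV, or z-units after baseline z-scoring.
    time_ms : ndarray, shape (n_times,)
        Uniform time axis in ms relative to stimulus onset.
    fs_hz : float
        Sampling rate of the time axis.
    kind : str
        One of ``LFP``, ``MUAe``, ``LFPbp``, ``CSD``.
    condition : ndarray, shape (n_trials,)
        Stimulus diameter (deg) per trial.
    channel_ids : ndarray, shape (n_channels,)
        1-based contact numbers, counted from the top of the probe. Bipolar
        referencing drops the end contacts, so ids need not start at 1.
    zscored : bool
        True once the signal has been z-scored to its baseline.
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs_hz: float
    kind: str
    condition: np.ndarray
    channel_ids: np.ndarray
    zscored: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition = np.asarray(self.condition, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length mismatch")
        if self.data.shape[0] != self.condition.size:
            raise ValueError("condition labels must match trial count")
        if self.data.shape[1] != self.channel_ids.size:
            raise ValueError("channel_ids must match channel count")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and (dt.min() <= 0 or np.ptp(dt) > 1e-6 * dt.mean()):
            raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask for the half-open window [start_ms, stop_ms)."""
        return (self.time_ms >= start_ms) & (self.time_ms < stop_ms)

    def condition_average(self) -> tuple[np.ndarray, np.ndarray]:
        """Trial-average per condition.

        Returns
        -------
        diameters : ndarray, sorted unique condition labels
        averages : ndarray, shape (n_conditions, n_channels, n_times)
        """
        diameters = np.unique(self.condition)
        out = np.empty((diameters.size, self.n_channels, self.time_ms.size))
        for i, d in enumerate(diameters):
            out[i] = self.data[self.condition == d].mean(axis=0)
        return diameters, out

    def select_condition(self, diameter: float) -> "EpochedSignal":
        mask = self.condition == diameter
        if not mask.any():
            raise ValueError(f"no trials with diameter {diameter}")
        return dataclasses.replace(
            self, data=self.data[mask], condition=self.condition[mask]
        )


@dataclass
class CSDProfile:
    """Depth x time current source density, sink-positive.

    ``values`` are in A/m³ (SI) when computed from potentials in volts and
    spacing in meters.  Rows are ordered superficial → deep.
    """

    values: np.ndarray
    depth_um: np.ndarray
    time_ms: np.ndarray
    sigma_s_per_m: float
    spacing_um: float
    channel_ids: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.values.shape != (self.depth_um.size, self.time_ms.size):
            raise ValueError("values must be (depth, time)")
        if self.normalization not in ("raw", "sink-peak-normalized"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (depth_um, time_ms, value) table."""
        d, t = np.meshgrid(self.depth_um, self.time_ms, indexing="ij")
        return pd.DataFrame(
            {"depth_um": d.ravel(), "time_ms": t.ravel(), "value": self.values.ravel()}
        )


@dataclass
class DepthMap:
    """Per-contact cortical depth, aligned to the early granular sink at 0 µm.

    Contacts above the alignment channel get positive depths.
    """

    depth_um: np.ndarray
    alignment_channel: int  # 1-based from the top
    spacing_um: float

    def depth_of(self, channel_id: int) -> float:
        return float((self.alignment_channel - channel_id) * self.spacing_um)


@dataclass
class GroundTruth:
    """Everything a synthetic session knows about itself.

    ``coupling_adjacency`` maps ordered channel pairs (1-based source,
    target) to (band name, strength, lag ms).  ``true_latency_ms`` maps
    (channel, diameter) to the dense-grid threshold crossing of the
    noiseless rate profile (NaN where the profile never crosses).
    """

    true_csd: np.ndarray  # (channels, time) planted evoked CSD, A/m^3
    true_csd_time_ms: np.ndarray
    sink_channel: int  # 1-based from the top
    sink_peak_ms: float
    true_latency_ms: dict[tuple[int, float], float]
    coupling_adjacency: dict[tuple[int, int], tuple[str, float, float]]
    true_phase_lag_ms: dict[tuple[int, int], tuple[str, float]]
    mixing_matrix: np.ndarray  # (n_latents, n_channels)
    seed: int


@dataclass
class SessionRecording:
    """Continuous probe recording plus stimulus events.

    ``samples`` are channels x time in µV at ``fs_hz``; channels ordered
    top-to-bottom.  ``events`` is a DataFrame with columns ``onset_s``,
    ``diameter_deg``, ``trial_id`` (onsets strictly increasing).
    """

    samples: np.ndarray
    fs_hz: float
    events: pd.DataFrame
    spacing_um: float
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, time)")
        onsets = np.asarray(self.events["onset_s"], dtype=float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_hz


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------


def _gt_to_group(gt: GroundTruth, grp: h5py.Group) -> None:
    grp.create_dataset("true_csd", data=gt.true_csd)
    grp.create_dataset("true_csd_time_ms", data=gt.true_csd_time_ms)
    grp.attrs["sink_channel"] = gt.sink_channel
    grp.attrs["sink_peak_ms"] = gt.sink_peak_ms
    grp.attrs["seed"] = gt.seed
    grp.create_dataset("mixing_matrix", data=gt.mixing_matrix)
    lat = np.array(
        [(ch, d, v) for (ch, d), v in sorted(gt.true_latency_ms.items())], dtype=float
    ).reshape(-1, 3)
    grp.create_dataset("true_latency_ms", data=lat)
    adj = json.dumps(
        [[s, t, band, float(w), float(lag)]
         for (s, t), (band, w, lag) in sorted(gt.coupling_adjacency.items())]
    )
    grp.attrs["coupling_adjacency_json"] = adj
    grp.attrs["true_phase_lag_json"] = json.dumps(
        [[s, t, band, float(lag)]
         for (s, t), (band, lag) in sorted(gt.true_phase_lag_ms.items())]
    )


def _gt_from_group(grp: h5py.Group) -> GroundTruth:
    lat_rows = np.asarray(grp["true_latency_ms"])
    latency = {(int(r[0]), float(r[1])): float(r[2]) for r in lat_rows}
    adj = {
        (int(s), int(t)): (band, float(w), float(lag))
        for s, t, band, w, lag in json.loads(grp.attrs["coupling_adjacency_json"])
    }
    phase = {
        (int(s), int(t)): (band, float(lag))
        for s, t, band, lag in json.loads(grp.attrs["true_phase_lag_json"])
    }
    return GroundTruth(
        true_csd=np.asarray(grp["true_csd"]),
        true_csd_time_ms=np.asarray(grp["true_csd_time_ms"]),
        sink_channel=int(grp.attrs["sink_channel"]),
        sink_peak_ms=float(grp.attrs["sink_peak_ms"]),
        true_latency_ms=latency,
        coupling_adjacency=adj,
        true_phase_lag_ms=phase,
        mixing_matrix=np.asarray(grp["mixing_matrix"]),
        seed=int(grp.attrs["seed"]),
    )


def write_session(path: str | Path, rec: SessionRecording) -> None:
    """Write a session to the versioned HDF5 container plus a CSV sidecar."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = CONTAINER_SCHEMA_VERSION
            f.create_dataset("samples", data=rec.samples.astype(np.float32))
            f["samples"].attrs["fs_hz"] = rec.fs_hz
            f["samples"].attrs["units"] = "uV"
            ev = f.create_group("events")
            ev.create_dataset("onset_s", data=np.asarray(rec.events["onset_s"], float))
            ev.create_dataset(
                "diameter_deg", data=np.asarray(rec.events["diameter_deg"], float)
            )
            ev.create_dataset("trial_id", data=np.asarray(rec.events["trial_id"], int))
            geo = f.create_group("geometry")
            geo.attrs["spacing_um"] = rec.spacing_um
            geo.attrs["n_channels"] = rec.n_channels
            geo.attrs["channel_order"] = "top-to-bottom"
            if rec.ground_truth is not None:
                _gt_to_group(rec.ground_truth, f.create_group("ground_truth"))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"could not write session container to {path}: {exc}") from exc
    rec.events.to_csv(path.with_suffix(path.suffix + ".events.csv"), index=False)


def read_session(path: str | Path) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != CONTAINER_SCHEMA_VERSION:
            raise ValueError(f"unsupported container schema {version!r}")
        samples = np.asarray(f["samples"], dtype=float)
        fs = float(f["samples"].attrs["fs_hz"])
        events = pd.DataFrame(
            {
                "onset_s": np.asarray(f["events/onset_s"]),
                "diameter_deg": np.asarray(f["events/diameter_deg"]),
                "trial_id": np.asarray(f["events/trial_id"]),
            }
        )
        spacing = float(f["geometry"].attrs["spacing_um"])
        gt = _gt_from_group(f["ground_truth"]) if "ground_truth" in f else None
    return SessionRecording(
        samples=samples, fs_hz=fs, events=events, spacing_um=spacing, ground_truth=gt
    )
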