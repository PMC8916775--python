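"""End-to-end orchestration of the laminar analysis.

``run_pipeline`` takes a session (in-memory or from the HDF5 container)
through the full chain — LFP/MUAe conditioning, CSD + QC + depth
alignment, transient latencies, induced band power, phase-triggered
averaging, and the Granger-causality graph — and collects every product in
an :class:`AnalysisBundle` that serializes to plain CSV/JSON.  A failed
quality control stops after the CSD stage unless ``force`` is set.  All
randomness flows from one seed through named per-stage streams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd as csd_mod
from . import gc as gc_mod
from . import latency as latency_mod
from . import preprocess, pta, spectral
from .containers import CSDProfile, DepthMap, EpochedSignal, SessionRecording, read_session
from .synth import BANDS

__all__ = ["AnalysisConfig", "AnalysisBundle", "run_pipeline", "summarize_size_tuning"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every numeric constant used by any stage, in one validated place."""

    fs_target_hz: float = 1000.0
    lfp_band_hz: tuple[float, float] = (0.75, 300.0)
    mua_band_hz: tuple[float, float] = (600.0, 3600.0)
    mua_lowpass_hz: float = 200.0
    epoch_ms: tuple[float, float] = (-500.0, 500.0)
    baseline_ms: tuple[float, float] = (-300.0, 0.0)
    sustained_ms: tuple[float, float] = (200.0, 500.0)
    latency_window_ms: tuple[float, float] = (0.0, 200.0)
    latency_threshold_z: float = 3.0
    power_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(spectral.POWER_BANDS)
    )
    pta_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(pta.PTA_BANDS)
    )
    pta_half_width_ms: dict[str, float] = field(
        default_factory=lambda: dict(pta.PTA_HALF_WIDTH_MS)
    )
    pta_reference_depth_um: float = -150.0
    gc_order: int = 50
    gc_start_ms: float = 200.0
    gc_n_bins: int = 256
    gc_rgt_shuffles: int = 19
    gc_conditions: tuple[float, ...] | None = None  # None: smallest + largest
    pta_conditions: tuple[float, ...] | None = None
    enforce_qc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("baseline", self.baseline_ms),
            ("sustained", self.sustained_ms),
            ("latency", self.latency_window_ms),
        ):
            if not (self.epoch_ms[0] <= a < b <= self.epoch_ms[1]):
                raise ValueError(f"{name} window {a, b} outside epoch {self.epoch_ms}")
        for bands in (self.power_bands, self.pta_bands):
            if not bands:
                raise ValueError("band definitions must be non-empty")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class AnalysisBundle:
    """Everything one session's analysis produced."""

    config: AnalysisConfig
    qc: csd_mod.QCReport
    csd: CSDProfile
    depths: DepthMap | None = None
    latency_table: pd.DataFrame | None = None
    latency_compartments: pd.DataFrame | None = None
    muae_sustained: pd.DataFrame | None = None
    band_power: pd.DataFrame | None = None
    gamma_peak: pd.DataFrame | None = None
    pta_profiles: dict[tuple[str, float], pta.PTAProfile] = field(default_factory=dict)
    gc_graph: pd.DataFrame | None = None
    complete: bool = False

    def write(self, outdir: str | Path) -> None:
        """Serialize all tables (CSV/TSV) plus the config echo and QC (JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(self.config.to_json())
        qc_payload = dict(
            passed=self.qc.passed,
            criterion_results=self.qc.criterion_results,
            notes=self.qc.notes,
            alignment_channel=self.qc.alignment_channel,
            sink_peak_ms=self.qc.sink_peak_ms,
            complete=self.complete,
        )
        (out / "qc.json").write_text(json.dumps(qc_payload, indent=2))
        self.csd.to_frame().to_csv(out / "csd_profile.tsv", sep="\t", index=False)
        tables = {
            "latency.csv": self.latency_table,
            "latency_compartments.csv": self.latency_compartments,
            "muae_sustained.csv": self.muae_sustained,
            "band_power.csv": self.band_power,
            "gamma_peak.csv": self.gamma_peak,
            "gc_graph.csv": self.gc_graph,
        }
        for name, tab in tables.items():
            if tab is not None:
                tab.to_csv(out / name, index=False)
        for (band, diam), profile in self.pta_profiles.items():
            df = pd.DataFrame(profile.averages.T, columns=[
                f"ch{c}" for c in profile.channel_ids
            ])
            df.insert(0, "lag_ms", profile.lag_ms)
            df["n_triggers"] = profile.n_triggers
            df.to_csv(out / f"pta_{band}_{diam:g}deg.tsv", sep="\t", index=False)


def _stage_seed(base: int, name: str) -> int:
    # Named per-stage streams derived from one master seed (stable hash).
    import zlib

    return int(
        np.random.SeedSequence([base, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(
    session: SessionRecording | str | Path,
    config: AnalysisConfig | None = None,
    force: bool = False,
) -> AnalysisBundle:
    """Run the complete analysis of one session.

    QC criteria 1–2 are enforced automatically (criterion 3 is a manual
    flag); a failing session yields a bundle with only QC and CSD unless
    ``force`` is given.  Deterministic given (session, config).
    """
    if not isinstance(session, SessionRecording):
        session = read_session(session)
    cfg = config or AnalysisConfig()

    # --- conditioning -----------------------------------------------------
    lfp_cont, fs = preprocess.extract_lfp(session, cfg.fs_target_hz, cfg.lfp_band_hz)
    muae_cont, _ = preprocess.extract_muae(
        session, cfg.fs_target_hz, cfg.mua_band_hz, cfg.mua_lowpass_hz
    )
    lfp = preprocess.epoch_trials(lfp_cont, fs, session.events, "LFP", cfg.epoch_ms)
    muae = preprocess.epoch_trials(muae_cont, fs, session.events, "MUAe", cfg.epoch_ms)
    muae_z = preprocess.zscore_to_baseline(muae, cfg.baseline_ms)

    # --- CSD, QC, alignment ----------------------------------------------
    profile = csd_mod.csd_from_epoched(lfp, session.spacing_um)
    qc = csd_mod.qc_session(profile)
    bundle = AnalysisBundle(config=cfg, qc=qc, csd=profile)
    if not qc.passed and cfg.enforce_qc and not force:
        logger.warning("session failed QC (%s); downstream stages skipped",
                       {k: v for k, v in qc.criterion_results.items() if v == "fail"})
        return bundle
    align = qc.alignment_channel
    if align is None:
        if not force:
            return bundle
        align = session.n_channels // 2
    depths = csd_mod.assign_depths(align, session.n_channels, session.spacing_um)
    bundle.depths = depths

    # --- latency ----------------------------------------------------------
    lat = latency_mod.latency_profile(
        muae_z, depths, threshold=cfg.latency_threshold_z,
        window_ms=cfg.latency_window_ms, seed=_stage_seed(cfg.seed, "latency"),
    )
    bundle.latency_table = lat
    bundle.latency_compartments = latency_mod.compartment_latency(lat)

    # --- sustained MUAe -----------------------------------------------------
    sus_mask = muae_z.time_mask(*cfg.sustained_ms)
    diameters, averages = muae_z.condition_average()
    rows = []
    for di, d in enumerate(diameters):
        for ci, ch in enumerate(muae_z.channel_ids):
            rows.append(dict(
                channel=int(ch), depth_um=depths.depth_of(int(ch)),
                diameter_deg=float(d),
                z=float(averages[di, ci, sus_mask].mean()),
            ))
    bundle.muae_sustained = pd.DataFrame(rows)

    # --- induced spectral power ------------------------------------------
    lfp_bp = preprocess.bipolar_reference(lfp)
    bp_rows, peak_rows = [], []
    for d in diameters:
        sub = lfp_bp.select_condition(float(d))
        spec = spectral.spectrogram(sub.data, fs, start_ms=sub.time_ms[0])
        isp = spectral.induced_power_z(spec, cfg.baseline_ms)
        tab = spectral.band_power_profile(
            isp, cfg.power_bands, cfg.sustained_ms,
            channel_ids=lfp_bp.channel_ids, depths=depths,
        )
        tab.insert(0, "diameter_deg", float(d))
        bp_rows.append(tab)
        peak_rows.append(dict(
            diameter_deg=float(d),
            gamma_peak_hz=spectral.gamma_peak_frequency(isp, window_ms=cfg.sustained_ms),
        ))
    bundle.band_power = pd.concat(bp_rows, ignore_index=True)
    bundle.gamma_peak = pd.DataFrame(peak_rows)

    # --- phase-triggered averaging ---------------------------------------
    pta_conditions = cfg.pta_conditions or (float(diameters.min()), float(diameters.max()))
    ref_channel = int(round(align - cfg.pta_reference_depth_um / session.spacing_um))
    ref_idx = np.nonzero(lfp_bp.channel_ids == ref_channel)[0]
    if ref_idx.size:
        for d in pta_conditions:
            sub = lfp_bp.select_condition(d)
            for band in cfg.pta_bands:
                trig = pta.detect_phase_triggers(
                    sub.data[:, ref_idx[0], :], sub.time_ms, fs, band,
                    window_ms=cfg.sustained_ms,
                    half_width_ms=cfg.pta_half_width_ms[band],
                )
                bundle.pta_profiles[(band, d)] = pta.phase_triggered_average(
                    sub, trig, band, ref_channel,
                    half_width_ms=cfg.pta_half_width_ms[band],
                )
    else:
        logger.warning("PTA reference contact %d not available in bipolar montage",
                       ref_channel)

    # --- Granger causality graph -----------------------------------------
    gc_conditions = cfg.gc_conditions or (float(diameters.min()), float(diameters.max()))
    gc_tables = []
    for d in gc_conditions:
        sub = lfp_bp.select_condition(d)
        graph = gc_mod.build_gc_graph(
            sub, depths, bands=BANDS, order=cfg.gc_order,
            start_ms=cfg.gc_start_ms, n_bins=cfg.gc_n_bins,
            n_shuffles=cfg.gc_rgt_shuffles, seed=_stage_seed(cfg.seed, "gc"),
        )
        graph.insert(0, "diameter_deg", d)
        gc_tables.append(graph)
    bundle.gc_graph = pd.concat(gc_tables, ignore_index=True)
    bundle.complete = True
    return bundle


def summarize_size_tuning(bundles: list[AnalysisBundle]) -> pd.DataFrame:
    """Across-session size tuning per laminar compartment.

    For each compartment (supragranular +450/+600 µm, granular 0,
    infragranular −450/−600 µm) and diameter: mean ± s.e.m. across
    sessions of sustained MUAe z, each band's power z, and latency.
    Sessions missing a compartment are excluded with a count; with a
    single session the s.e.m. is NaN and flagged.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    rows = []
    comp_depths = latency_mod.COMPARTMENT_DEPTHS_UM

    def collect(measure: str, table_name: str, value_col: str, extra_filter=None):
        for comp, dlist in comp_depths.items():
            per_diam: dict[float, list[float]] = {}
            for b in bundles:
                tab = getattr(b, table_name)
                if tab is None:
                    continue
                sub = tab[tab["depth_um"].isin(dlist)]
                if extra_filter is not None:
                    sub = extra_filter(sub)
                for d, grp in sub.groupby("diameter_deg"):
                    vals = grp[value_col].dropna()
                    if len(vals):
                        per_diam.setdefault(float(d), []).append(float(vals.mean()))
            for d, vals in sorted(per_diam.items()):
                arr = np.asarray(vals)
                rows.append(dict(
                    measure=measure, compartment=comp, diameter_deg=d,
                    mean=float(arr.mean()),
                    sem=float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan"),
                    n_sessions=int(arr.size),
                    single_session=arr.size == 1,
                ))

    collect("muae_z", "muae_sustained", "z")
    collect("latency_ms", "latency_table", "latency_ms")
    for band in ("theta", "alpha", "beta", "gamma"):
        collect(
            f"power_{band}", "band_power", "z",
            extra_filter=lambda s, band=band: s[s["band"] == band],
        )
    return pd.DataFrame(rows)
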