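"""Shared fixtures: one default synthetic session, preprocessed once."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from lamflow import preprocess
from lamflow.synth import SynthConfig, generate_session

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_session():
    """Default 6-diameter x 20-trial session with ground truth (seed 1)."""
    cfg = SynthConfig(seed=1)
    rec, gt = generate_session(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def preprocessed(default_session):
    """LFP/MUAe epochs, z-scored MUAe, and bipolar LFP of the default session."""
    cfg, rec, gt = default_session
    lfp_cont, fs = preprocess.extract_lfp(rec)
    muae_cont, _ = preprocess.extract_muae(rec)
    lfp = preprocess.epoch_trials(lfp_cont, fs, rec.events, "LFP")
    muae = preprocess.epoch_trials(muae_cont, fs, rec.events, "MUAe")
    muae_z = preprocess.zscore_to_baseline(muae)
    lfp_bp = preprocess.bipolar_reference(lfp)
    return dict(lfp=lfp, muae_z=muae_z, lfp_bp=lfp_bp, fs=fs)


@pytest.fixture(scope="session")
def small_config():
    """Fast, reduced-size generator configuration for structural tests."""
    return SynthConfig(
        seed=7,
        fs_raw_hz=4000.0,
        mua_band_hz=(600.0, 1800.0),
        n_trials_per_condition=3,
        diameters_deg=(0.5, 15.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
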