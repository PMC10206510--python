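"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from endotrait.cohort import (NightRecording, TraitConfig, TraitMoments,
                              _sample_subject, simulate_night)
from endotrait.scoring import SleepSummary


def fixed_trait_config(**overrides) -> TraitConfig:
    """A degenerate-variance config whose every night realises the same traits."""
    values = dict(lg1=0.55, tau_s=20.0, delay_s=16.0, arth=112.0, vra=20.0,
                  vpassive=60.0, vcomp=10.0, vmin_floor=20.0)
    values.update(overrides.pop("trait_values", {}))
    traits = {k: TraitMoments(v, 0.0, 0.0) for k, v in values.items()}
    defaults = dict(traits=traits, n_subjects=1, n_nights=1, tst_mean_min=200.0,
                    tst_sd_min=0.0, min_ahi=None, rng_seed=0)
    defaults.update(overrides)
    return TraitConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> TraitConfig:
    return TraitConfig(n_subjects=4, n_nights=2, tst_mean_min=240.0, rng_seed=42)


@pytest.fixture(scope="session")
def one_night(small_cfg):
    """One noisy simulated night from the default-style cohort."""
    truth = _sample_subject(small_cfg, 0)
    return truth, simulate_night(truth, 0, small_cfg)


@pytest.fixture(scope="session")
def clean_night():
    """A measurement-noise-free night with fixed moderate-severity traits."""
    cfg = fixed_trait_config(noise_sd=0.0, tst_mean_min=390.0, rng_seed=7)
    truth = _sample_subject(cfg, 0)
    return cfg, truth, simulate_night(truth, 0, cfg)


def make_night(vent, breath_s=4.0, stages=None, arousals=None, positions=None):
    """Construct a NightRecording from a bare ventilation vector."""
    vent = np.asarray(vent, float)
    n = vent.size
    onset = np.arange(n) * breath_s
    span = n * breath_s
    n_epochs = int(np.ceil(span / 30.0))
    if stages is None:
        stages = ["N2"] * n_epochs
    if positions is None:
        positions = ["supine"] * n_epochs
    arousals = arousals or []
    return NightRecording(
        subject_id="T001", night_index=0,
        breaths=pd.DataFrame({
            "onset_s": onset, "duration_s": np.full(n, breath_s),
            "ventilation": vent, "drive": np.full(n, np.nan),
            "obstructed": vent < 90.0,
        }),
        epochs=pd.DataFrame({
            "start_s": np.arange(n_epochs) * 30.0,
            "stage": stages[:n_epochs],
            "position": positions[:n_epochs],
        }),
        events=pd.DataFrame(columns=["type", "start_s", "end_s", "desat_pct", "arousal_linked"]),
        arousals=pd.DataFrame(arousals, columns=["start_s", "end_s"]),
        summary=SleepSummary.invalid(),
    )
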