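"""Synthetic cohort generator: sampling moments, determinism, loop behaviour."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from endotrait.cohort import (TRAIT_NAMES, TraitConfig, TraitMoments,
                              _sample_subject, sample_cohort_truth,
                              simulate_cohort, simulate_night)

from conftest import fixed_trait_config


class TestSampling:
    def test_zero_variance_collapses_to_population_means(self):
        cfg = fixed_trait_config(n_subjects=3, n_nights=2)
        for tr in sample_cohort_truth(cfg):
            assert np.allclose(tr.lg1, 0.55)
            assert np.allclose(tr.arth, 112.0)
            assert np.allclose(tr.vpassive, 60.0)
            # delay is implemented on the breath clock
            assert np.allclose(tr.delay_s, round(16.0 / 4.0) * 4.0)

    def test_determinism(self):
        cfg = TraitConfig(n_subjects=5, n_nights=2, rng_seed=3)
        a = sample_cohort_truth(cfg)
        b = sample_cohort_truth(TraitConfig(n_subjects=5, n_nights=2, rng_seed=3))
        for x, y in zip(a, b):
            for name in TRAIT_NAMES:
                assert np.array_equal(getattr(x, name), getattr(y, name))

    def test_moment_matching_oracle(self):
        """Sample moments of 1000 subjects match the configured moments.

        SDs are kept small relative to the distance to the truncation
        bounds so the draws are effectively untruncated normals.
        """
        traits = {
            "lg1": TraitMoments(0.55, 0.08, 0.03),
            "tau_s": TraitMoments(20.0, 2.0, 1.0),
            "delay_s": TraitMoments(14.0, 1.5, 0.0),
            "arth": TraitMoments(115.0, 3.0, 2.0),
            "vra": TraitMoments(20.0, 3.0, 2.0),
            "vpassive": TraitMoments(60.0, 4.0, 2.0),
            "vcomp": TraitMoments(10.0, 2.0, 1.0),
            "vmin_floor": TraitMoments(30.0, 3.0, 2.0),
        }
        cfg = TraitConfig(traits=traits, n_subjects=1000, n_nights=2, rng_seed=17)
        cohort = sample_cohort_truth(cfg)
        for name in TRAIT_NAMES:
            if name == "delay_s":
                continue  # snapped to the breath clock
            tm = traits[name]
            night_vals = np.concatenate([getattr(t, name) for t in cohort])
            subj_means = np.array([getattr(t, name).mean() for t in cohort])
            total_sd = math.hypot(tm.between_subject_sd, tm.between_night_sd)
            se_mean = total_sd / math.sqrt(len(cohort))
            assert abs(night_vals.mean() - tm.mean) < 3 * se_mean, name
            # between-subject spread: SD of subject means ~ sqrt(bs^2 + bn^2/k)
            expect_sd = math.sqrt(tm.between_subject_sd ** 2
                                  + tm.between_night_sd ** 2 / 2)
            se_sd = expect_sd / math.sqrt(2 * (len(cohort) - 1))
            assert abs(subj_means.std(ddof=1) - expect_sd) < 3 * se_sd, name

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="arth"):
            fixed_trait_config(trait_values={"arth": 95.0})
        with pytest.raises(ValueError, match="n_subjects"):
            TraitConfig(n_subjects=0)
        with pytest.raises(ValueError, match="SDs"):
            TraitConfig(traits={**TraitConfig().traits,
                                "lg1": TraitMoments(0.5, -1.0, 0.1)})

    def test_night_invariants_hold(self):
        cfg = TraitConfig(n_subjects=30, n_nights=2, rng_seed=9)
        for tr in sample_cohort_truth(cfg):
            assert np.all(tr.arth > 100)
            assert np.all(tr.vpassive <= 100)
            assert np.all(tr.vmin_floor <= tr.vpassive)
            assert np.all(tr.tau_s > 0)
            assert np.all(tr.delay_s >= 0)


class TestSimulateNight:
    def test_stable_loop_is_event_free(self):
        cfg = fixed_trait_config(
            trait_values={"lg1": 0.06, "vpassive": 100.0, "vmin_floor": 50.0},
            noise_sd=0.0, rng_seed=1)
        tr = _sample_subject(cfg, 0)
        night = simulate_night(tr, 0, cfg)
        assert len(night.arousals) == 0
        assert len(night.events) == 0
        assert night.summary.ahi == 0.0

    def test_arth_at_or_below_eupnea_rejected(self):
        cfg = fixed_trait_config()
        tr = _sample_subject(cfg, 0)
        tr.arth[0] = 100.0
        with pytest.raises(ValueError, match="ArTh"):
            simulate_night(tr, 0, cfg)

    def test_bit_identical_rerun(self):
        cfg = TraitConfig(n_subjects=2, n_nights=1, tst_mean_min=120.0, rng_seed=21)
        t1, r1 = simulate_cohort(cfg)
        t2, r2 = simulate_cohort(TraitConfig(n_subjects=2, n_nights=1,
                                             tst_mean_min=120.0, rng_seed=21))
        for a, b in zip(r1, r2):
            pd.testing.assert_frame_equal(a.breaths, b.breaths)
            pd.testing.assert_frame_equal(a.epochs, b.epochs)
            pd.testing.assert_frame_equal(a.events, b.events)

    def test_epochs_are_contiguous_thirty_seconds(self, one_night):
        _, night = one_night
        starts = night.epochs["start_s"].to_numpy()
        assert np.allclose(np.diff(starts), 30.0)
        assert set(night.epochs["stage"]) <= {"W", "N1", "N2", "N3", "REM"}
        assert set(night.epochs["position"]) <= {"supine", "nonsupine"}

    def test_breaths_ordered_and_nonnegative(self, one_night):
        _, night = one_night
        b = night.breaths
        assert np.all(np.diff(b["onset_s"]) > 0)
        assert np.all(b["duration_s"] > 0)
        assert np.all(b["ventilation"] >= 0)

    def test_events_and_arousals_inside_recording(self, one_night):
        _, night = one_night
        span = night.span_s
        for df, lo, hi in [(night.events, "start_s", "end_s"),
                           (night.arousals, "start_s", "end_s")]:
            if len(df):
                assert df[lo].min() >= 0
                assert df[hi].max() <= span + 1e-9
        if len(night.events):
            assert np.all(night.events["end_s"] - night.events["start_s"] >= 10.0 - 1e-9)

    def test_every_event_maps_to_a_ventilation_deficit(self, clean_night):
        _, _, night = clean_night
        b = night.breaths
        assert len(night.events) > 0
        for _, ev in night.events.iterrows():
            m = (b["onset_s"] >= ev.start_s - 2.0) & (b["onset_s"] < ev.end_s + 2.0)
            assert b.loc[m, "ventilation"].min() <= 70.0

    def test_dose_response_of_collapsibility(self):
        """Raising Vpassive toward eupnea monotonically lowers median AHI."""
        medians = []
        for vp in (45.0, 65.0, 85.0):
            ahis = []
            for seed in range(20):
                cfg = fixed_trait_config(trait_values={"vpassive": vp},
                                         tst_mean_min=150.0, rng_seed=seed)
                tr = _sample_subject(cfg, 0)
                ahis.append(simulate_night(tr, 0, cfg).summary.ahi)
            medians.append(float(np.median(ahis)))
        assert medians[0] >= medians[1] >= medians[2]
        assert medians[0] > medians[2]

    def test_unstable_loop_oscillates_at_the_natural_period(self):
        """Periodic-breathing period matches the 180-degree phase condition.

        Oracle: bisection on 2 pi f delta + arctan(2 pi f tau) = pi,
        compared against the periodogram peak of simulated ventilation.
        """
        cfg = fixed_trait_config(
            trait_values={"lg1": 0.9, "arth": 150.0, "vpassive": 60.0,
                          "vra": 10.0, "vmin_floor": 10.0},
            tst_mean_min=390.0, efficiency_mean=0.97, efficiency_sd=0.0,
            rng_seed=3)
        tr = _sample_subject(cfg, 0)
        night = simulate_night(tr, 0, cfg)

        tau, delay = tr.tau_s[0], tr.delay_s[0]

        def phase(f):
            w = 2 * math.pi * f
            return w * delay + math.atan(w * tau) - math.pi

        lo, hi = 1e-5, 0.5 / delay
        for _ in range(200):  # plain bisection oracle
            mid = 0.5 * (lo + hi)
            if phase(mid) > 0:
                hi = mid
            else:
                lo = mid
        f_nat = 0.5 * (lo + hi)

        v = night.breaths["ventilation"].to_numpy()
        stages = night.epochs["stage"].to_numpy()
        eidx = np.minimum((night.breaths["onset_s"].to_numpy() / 30).astype(int),
                          len(stages) - 1)
        asleep = stages[eidx] != "W"
        d = np.diff(np.concatenate([[0], asleep.astype(int), [0]]))
        runs = list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))
        s, e = max(runs, key=lambda r: r[1] - r[0])
        seg = v[s:e] - v[s:e].mean()
        freqs, power = periodogram(seg, fs=1.0 / 4.0)
        f_peak = freqs[1:][np.argmax(power[1:])]
        assert abs(f_peak - f_nat) / f_nat < 0.2

    def test_inclusion_screen_enforces_minimum_severity(self):
        cfg = TraitConfig(n_subjects=8, n_nights=1, tst_mean_min=240.0,
                          min_ahi=15.0, rng_seed=13)
        _, recs = simulate_cohort(cfg)
        first_nights = [r for r in recs if r.night_index == 0]
        assert sum(r.summary.ahi >= 15.0 for r in first_nights) >= 7
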