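"""Agreement statistics: paired tests, ANOVA decomposition, ICC, SEM/MDD."""

import math

import numpy as np
import pytest

from endotrait.reliability import (MeasurementMatrix, anova_mean_squares,
                                   bland_altman, bootstrap_two_night_sem,
                                   delta_correlation, icc_absolute_agreement,
                                   interpret_icc, mdd_from_sem,
                                   paired_comparison, reliability_summary,
                                   sem_agreement, sem_from_difference_summary,
                                   shapiro_normality)


def mm(values):
    return MeasurementMatrix(np.asarray(values, float))


class TestPairedComparison:
    def test_identical_columns_degenerate(self):
        m = mm([[1, 1], [2, 2], [3, 3]])
        mean_diff, sd_diff, t, p, sig, degenerate = paired_comparison(m)
        assert mean_diff == 0.0 and degenerate and not sig

    def test_toy_diffs_match_hand_computation(self):
        # diffs {1,2,3}: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        m = mm([[0, 1], [0, 2], [0, 3]])
        mean_diff, sd_diff, t, p, sig, _ = paired_comparison(m)
        assert mean_diff == pytest.approx(2.0)
        assert sd_diff == pytest.approx(1.0)
        assert t == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-12)

    def test_bonferroni_threshold_is_strict(self):
        # a p-value like 0.046 (nominally significant) is not significant
        # at the multiplicity-adjusted alpha of 0.003
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=(20, 2))
            _, _, _, p, sig, _ = paired_comparison(MeasurementMatrix(x), alpha=0.003)
            assert sig == (p < 0.003)


class TestShapiro:
    def test_calibration_under_normality(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(size=67)
            _, p = shapiro_normality(d)
            hits += p > 0.05
        assert hits >= 90

    def test_power_against_exponential(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).exponential(size=67)
            _, p = shapiro_normality(d)
            hits += p < 0.05
        assert hits >= 90

    def test_symmetric_toy_passes_and_constant_rejected(self):
        _, p = shapiro_normality([-1.0, 0.0, 1.0])
        assert p > 0.05
        with pytest.raises(ValueError):
            shapiro_normality([2.0, 2.0, 2.0])


class TestAnova:
    def test_identical_columns_kill_occasion_and_error_terms(self):
        ms = anova_mean_squares(mm([[1, 1], [2, 2], [3, 3]]))
        assert ms.ms_rows == pytest.approx(2.0)
        assert ms.ms_cols == pytest.approx(0.0)
        assert ms.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) * 10
            ms = anova_mean_squares(MeasurementMatrix(x))
            # brute force by explicit loops
            grand = x.mean()
            ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
            ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
            ss_err = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                         for i in range(n) for j in range(k))
            assert ms.ms_rows == pytest.approx(ss_rows / (n - 1), abs=1e-10)
            assert ms.ms_cols == pytest.approx(ss_cols / (k - 1), abs=1e-10)
            assert ms.ms_error == pytest.approx(ss_err / ((n - 1) * (k - 1)), abs=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            mm([[1, 2], [3, 4]])


class TestICC:
    def test_identical_columns_give_unity(self):
        icc, _ = icc_absolute_agreement(anova_mean_squares(mm([[1, 1], [2, 2], [3, 3]])))
        assert icc == pytest.approx(1.0)

    def test_systematic_offset_is_penalised(self):
        x = np.array([[0.0, 5.0], [10.0, 15.0], [20.0, 25.0]])
        ms = anova_mean_squares(MeasurementMatrix(x))
        icc, _ = icc_absolute_agreement(ms)
        expected = (ms.ms_rows - ms.ms_error) / (
            ms.ms_rows + ms.ms_error + (2 / 3) * (ms.ms_cols - ms.ms_error))
        assert icc == pytest.approx(expected, rel=1e-12)
        assert icc < 1.0

    def test_variance_component_recovery(self):
        # sigma2_subject = 9, sigma2_err = 1 -> ICC = 0.9
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 3, size=(10000, 1))
        x = subj + rng.normal(0, 1, size=(10000, 2))
        icc, _ = icc_absolute_agreement(anova_mean_squares(MeasurementMatrix(x)))
        assert icc == pytest.approx(0.9, abs=0.01)

    def test_matches_pingouin_two_way_absolute_single(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(8)
        for _ in range(5):
            n, k = 20, 3
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": x.ravel(),
            })
            ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                           ratings="score")
            ref2 = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
            icc, (lo, hi) = icc_absolute_agreement(anova_mean_squares(MeasurementMatrix(x)))
            assert icc == pytest.approx(ref2["ICC"], abs=1e-6)
            # pingouin prints its CI rounded to 2 decimals
            assert lo == pytest.approx(ref2["CI95"][0], abs=0.0055)
            assert hi == pytest.approx(ref2["CI95"][1], abs=0.0055)

    def test_interpretation_cutoffs_are_strict(self):
        assert interpret_icc(0.82) == "good"
        assert interpret_icc(0.59) == "moderate"
        assert interpret_icc(0.5) == "poor"
        assert interpret_icc(0.75) == "moderate"
        assert interpret_icc(-0.2) == "poor"


class TestSemMdd:
    def test_zero_differences_give_zero_sem(self):
        assert sem_agreement(anova_mean_squares(mm([[1, 1], [2, 2], [3, 3]]))) \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n, mean_diff, sd_diff, expected", [
        (67, -3.4, 13.8, 10.0),   # AHI row
        (67, 2.7, 10.6, 7.7),     # VRA row
        (67, 0.11, 2.16, 1.5),    # delay row
    ])
    def test_published_difference_rows_reconstruct_sem(self, n, mean_diff, sd_diff, expected):
        assert sem_from_difference_summary(n, mean_diff, sd_diff) \
            == pytest.approx(expected, abs=0.05)

    def test_sem_from_summary_equals_sem_from_matrix(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 2)) * 7 + 50
        d = x[:, 1] - x[:, 0]
        direct = sem_agreement(anova_mean_squares(MeasurementMatrix(x)))
        summary = sem_from_difference_summary(40, float(d.mean()), float(d.std(ddof=1)))
        assert direct == pytest.approx(summary, rel=1e-12)

    def test_mdd_identity(self):
        assert mdd_from_sem(10.0) == pytest.approx(1.96 * math.sqrt(2) * 10.0)
        assert mdd_from_sem(0.0) == 0.0
        with pytest.raises(ValueError):
            mdd_from_sem(-1.0)


class TestBootstrapTwoNight:
    def test_identical_nights_give_zero(self):
        x = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        sem, (lo, hi), mdd = bootstrap_two_night_sem(MeasurementMatrix(x), iters=50, seed=0)
        assert sem == pytest.approx(0.0, abs=1e-12)
        assert mdd == pytest.approx(0.0, abs=1e-12)

    def test_pure_noise_halves_variance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(300, 4)) + rng.normal(0, 3, size=(300, 1))
        m = MeasurementMatrix(x)
        sem_single = sem_agreement(anova_mean_squares(m))
        sem2, _, _ = bootstrap_two_night_sem(m, iters=300, seed=1)
        assert sem2 == pytest.approx(sem_single / math.sqrt(2), rel=0.03)

    def test_requires_four_occasions(self):
        with pytest.raises(ValueError):
            bootstrap_two_night_sem(mm([[1, 2], [3, 4], [5, 6]]))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 4))
        a = bootstrap_two_night_sem(MeasurementMatrix(x), iters=100, seed=3)
        b = bootstrap_two_night_sem(MeasurementMatrix(x), iters=100, seed=3)
        assert a == b


class TestBlandAltmanAndDeltas:
    def test_identical_columns(self):
        bias, loa, pairs = bland_altman(mm([[1, 1], [2, 2], [3, 3]]))
        assert bias == 0.0 and loa == (0.0, 0.0)

    def test_constant_shift(self):
        bias, loa, _ = bland_altman(mm([[0, 4], [10, 14], [20, 24]]))
        assert bias == pytest.approx(4.0)
        assert loa[1] - loa[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_pair_fixture_matches_hand_computation(self):
        x = np.array([[10.0, 12.0], [20.0, 19.0], [30.0, 33.0],
                      [40.0, 38.0], [50.0, 55.0]])
        d = x[:, 1] - x[:, 0]
        bias, loa, pairs = bland_altman(MeasurementMatrix(x))
        assert bias == pytest.approx(d.mean())
        sd = d.std(ddof=1)
        assert loa == (pytest.approx(d.mean() - 1.96 * sd),
                       pytest.approx(d.mean() + 1.96 * sd))
        assert np.allclose(pairs[:, 0], x.mean(axis=1))

    def test_delta_correlation_flags(self):
        d = np.array([1.0, -2.0, 3.0, 0.5])
        r, f = delta_correlation(d, d)
        assert r == pytest.approx(1.0) and f
        r, f = delta_correlation(d, -d)
        assert r == pytest.approx(-1.0) and f
        r, f = delta_correlation(d, np.zeros(4))
        assert math.isnan(r) and not f

    def test_delta_correlation_matches_covariance_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        y = np.array([3.0, 1.0, 5.0, 9.0])
        r, _ = delta_correlation(x, y)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(expected, rel=1e-12)


def test_reliability_summary_degenerate_cascade():
    m = mm([[5, 5], [7, 7], [9, 9]])
    res = reliability_summary(m)
    assert res.degenerate
    assert res.sem == pytest.approx(0.0, abs=1e-12)
    assert res.mdd == pytest.approx(0.0, abs=1e-12)
    assert res.icc == pytest.approx(1.0)


def test_simulation_recovers_configured_reliability():
    """n=67 x 2 with variance ratio 0.8 -> mean estimated ICC near 0.8."""
    iccs = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        subj = rng.normal(0, math.sqrt(0.8), size=(67, 1))
        x = subj + rng.normal(0, math.sqrt(0.2), size=(67, 2))
        icc, _ = icc_absolute_agreement(anova_mean_squares(MeasurementMatrix(x)))
        iccs.append(icc)
    assert np.mean(iccs) == pytest.approx(0.8, abs=0.03)
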