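"""Test-retest agreement statistics for repeated sleep-study measurements.

Implements the battery used to quantify night-to-night variability of a
trait measured on n subjects over k occasions (nights):

* paired t comparison of two occasions with a Bonferroni-adjusted alpha,
* Shapiro-Wilk normality check on the paired differences,
* two-way (subject x occasion) ANOVA mean squares without replication,
* single-measure intraclass correlation under absolute agreement,
  ICC(A,1), with its F-distribution confidence interval,
* agreement standard error of measurement (SEM) with a subject-level
  bootstrap CI,
* minimal detectable difference MDD = 1.96 * sqrt(2) * SEM,
* bootstrap SEM of two-night averages from four repeated nights,
* Bland-Altman bias and limits of agreement,
* Pearson correlation screen between night-to-night deltas.

The ICC form used throughout is the single-rater absolute-agreement
coefficient; it is computed identically under two-way random- and
mixed-effects models, so the distinction does not affect any number
reported here.

All functions operate on a complete n x k matrix (subjects with a
missing night are dropped row-wise upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MeasurementMatrix",
    "AnovaMS",
    "ReliabilityResult",
    "paired_comparison",
    "shapiro_normality",
    "anova_mean_squares",
    "icc_absolute_agreement",
    "sem_agreement",
    "mdd_from_sem",
    "sem_from_difference_summary",
    "bootstrap_two_night_sem",
    "bland_altman",
    "delta_correlation",
    "interpret_icc",
    "reliability_summary",
]

MDD_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass
class MeasurementMatrix:
    """n subjects x k occasions of one trait, complete rows only."""

    values: np.ndarray
    trait: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x occasions) array")
        n, k = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if k < 2:
            raise ValueError(f"need at least 2 occasions, got {k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values; drop incomplete rows first")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaMS:
    """Mean squares of the two-way subject x occasion decomposition."""

    ms_rows: float      # between subjects
    ms_cols: float      # between occasions
    ms_error: float     # residual
    n: int
    k: int


@dataclass
class ReliabilityResult:
    """Per-trait agreement summary for one pair of occasions."""

    trait: str
    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float
    p_value: float
    significant: bool
    degenerate: bool
    icc: float
    icc_ci: tuple[float, float]
    sem: float
    sem_ci: tuple[float, float]
    mdd: float
    interpretation: str
    shapiro_p: float = float("nan")
    extras: dict = field(default_factory=dict)


def paired_comparison(m: MeasurementMatrix, alpha: float = 0.003):
    """Paired t test on occasion 2 minus occasion 1.

    Returns (mean_diff, sd_diff, t, p, significant, degenerate).  With a
    Bonferroni-adjusted alpha (default 0.003) the flag marks differences
    unlikely to be multiple-testing artifacts.  A zero-variance
    difference vector leaves t undefined (NaN) and the flag False.
    """
    if m.k < 2:
        raise ValueError("paired comparison needs at least two occasions")
    d = m.values[:, 1] - m.values[:, 0]
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff == 0.0:
        return mean_diff, 0.0, float("nan"), float("nan"), False, True
    t, p = stats.ttest_rel(m.values[:, 1], m.values[:, 0])
    return mean_diff, sd_diff, float(t), float(p), bool(p < alpha), False


def shapiro_normality(diffs) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a vector of paired differences."""
    d = np.asarray(diffs, dtype=float)
    if not 3 <= d.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(d) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(d)
    return float(w), float(p)


def anova_mean_squares(m: MeasurementMatrix) -> AnovaMS:
    """Two-way subject x occasion mean squares without replication."""
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    return AnovaMS(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=max(0.0, ss_err) / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_absolute_agreement(ms: AnovaMS, ci_level: float = 0.95):
    """Single-measure absolute-agreement ICC(A,1) with its 95% CI.

    Point estimate
        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    penalises both random error and systematic occasion offsets.  The CI
    follows the F-distribution construction of McGraw & Wong for this
    form (Satterthwaite degrees of freedom for the lower-tail F).
    Returns (icc, (lo, hi)); a matrix with zero total variance yields
    NaN throughout.
    """
    n, k = ms.n, ms.k
    msr, msc, mse = ms.ms_rows, ms.ms_cols, ms.ms_error
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0.0:
        return float("nan"), (float("nan"), float("nan"))
    icc = (msr - mse) / denom

    alpha = 1.0 - ci_level
    if mse <= 0.0:
        # degenerate: perfect within-subject agreement
        return float(icc), (float(icc), float(icc))
    fj = msc / mse
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else float("inf")
    if not math.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v_num = (a * fj + b) ** 2
    v_den = (a ** 2 * fj ** 2) / (k - 1.0) + b ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den
    f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return float(icc), (float(lower), float(upper))


def sem_agreement(ms: AnovaMS) -> float:
    """Agreement standard error of measurement.

    sqrt(MSE + max(0, (MSC - MSE)/n)): the absolute-agreement form,
    which charges systematic occasion shifts to measurement error.  A
    negative occasion-variance estimate is truncated at zero.
    """
    return math.sqrt(ms.ms_error + max(0.0, (ms.ms_cols - ms.ms_error) / ms.n))


def sem_agreement_ci(
    m: MeasurementMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the agreement SEM, resampling subjects."""
    rng = np.random.default_rng(seed)
    n = m.n
    sems = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sems[i] = sem_agreement(anova_mean_squares(MeasurementMatrix(m.values[idx])))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(sems, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def mdd_from_sem(sem: float) -> float:
    """Minimal detectable difference: 1.96 * sqrt(2) * SEM.

    The smallest change between two measurements exceeding 95% of
    test-retest noise.
    """
    if sem < 0:
        raise ValueError("SEM must be non-negative")
    return MDD_FACTOR * sem


def sem_from_difference_summary(n: int, mean_diff: float, sd_diff: float) -> float:
    """Agreement SEM reconstructed from a printed n, mean +/- SD of paired differences.

    For k = 2 occasions the two-way mean squares depend on the
    differences only: MSE = sd_diff^2 / 2 and MSC = n * mean_diff^2 / 2,
    so a published difference row determines the agreement SEM exactly.
    """
    mse = sd_diff ** 2 / 2.0
    msc = n * mean_diff ** 2 / 2.0
    return math.sqrt(mse + max(0.0, (msc - mse) / n))


def bootstrap_two_night_sem(
    m: MeasurementMatrix,
    iters: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
):
    """SEM of two-night averages from k = 4 repeated nights.

    Each iteration partitions, per subject, the four nights at random
    into two disjoint pairs, averages each pair, and computes the
    agreement SEM of the resulting n x 2 matrix.  Returns
    (mean SEM, (lo, hi) percentile CI across iterations, MDD of the
    mean SEM).  Deterministic given the seed.
    """
    if m.k != 4:
        raise ValueError(f"two-night averaging requires exactly 4 occasions, got {m.k}")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    # the 3 distinct partitions of {0,1,2,3} into two unordered pairs
    partitions = np.array(
        [[0, 1, 2, 3], [0, 2, 1, 3], [0, 3, 1, 2]], dtype=int
    )
    n = m.n
    sems = np.empty(iters)
    for i in range(iters):
        choice = rng.integers(0, 3, size=n)
        pairs = partitions[choice]  # (n, 4)
        rows = np.arange(n)[:, None]
        a = m.values[rows, pairs[:, :2]].mean(axis=1)
        b = m.values[rows, pairs[:, 2:]].mean(axis=1)
        sems[i] = sem_agreement(anova_mean_squares(MeasurementMatrix(np.column_stack([a, b]))))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(sems, [alpha / 2.0, 1.0 - alpha / 2.0])
    mean_sem = float(np.mean(sems))
    return mean_sem, (float(lo), float(hi)), mdd_from_sem(mean_sem)


def bland_altman(m: MeasurementMatrix):
    """Bland-Altman bias, limits of agreement and per-subject (mean, diff) pairs.

    Returns (bias, (loa_lo, loa_hi), pairs) where pairs is an (n, 2)
    array of subject means and differences for plotting.
    """
    if m.k != 2:
        raise ValueError("Bland-Altman needs exactly 2 occasions")
    d = m.values[:, 1] - m.values[:, 0]
    avg = m.values.mean(axis=1)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    return bias, loa, np.column_stack([avg, d])


def delta_correlation(delta_trait, delta_psg, threshold: float = 0.4):
    """Pearson r between night-to-night changes; flags |r| > threshold.

    A flagged correlation marks endotype fluctuations that track ordinary
    polysomnographic fluctuations (e.g. AHI) rather than being
    independent night-to-night noise.  Zero-variance input yields
    (nan, False).
    """
    x = np.asarray(delta_trait, dtype=float)
    y = np.asarray(delta_psg, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("delta vectors must have equal length >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), False
    r = float(np.corrcoef(x, y)[0, 1])
    return r, bool(abs(r) > threshold)


def interpret_icc(icc: float) -> str:
    """Qualitative reliability label: good > 0.75, moderate > 0.5, else poor."""
    if not math.isfinite(icc):
        return "undefined"
    if icc > 0.75:
        return "good"
    if icc > 0.5:
        return "moderate"
    return "poor"


def reliability_summary(
    m: MeasurementMatrix,
    alpha: float = 0.003,
    n_boot: int = 1000,
    seed: int = 0,
) -> ReliabilityResult:
    """Full agreement battery for one trait on two occasions."""
    if m.k != 2:
        raise ValueError("reliability_summary compares exactly 2 occasions")
    mean_diff, sd_diff, t, p, sig, degenerate = paired_comparison(m, alpha=alpha)
    ms = anova_mean_squares(m)
    icc, icc_ci = icc_absolute_agreement(ms)
    sem = sem_agreement(ms)
    if degenerate:
        sem_ci = (sem, sem)
        shapiro_p = float("nan")
    else:
        sem_ci = sem_agreement_ci(m, n_boot=n_boot, seed=seed)
        d = m.values[:, 1] - m.values[:, 0]
        shapiro_p = shapiro_normality(d)[1] if np.ptp(d) > 0 else float("nan")
    return ReliabilityResult(
        trait=m.trait,
        n=m.n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        t_stat=t,
        p_value=p,
        significant=sig,
        degenerate=degenerate,
        icc=icc,
        icc_ci=icc_ci,
        sem=sem,
        sem_ci=sem_ci,
        mdd=mdd_from_sem(sem),
        interpretation=interpret_icc(icc),
        shapiro_p=shapiro_p,
    )
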