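"""Synthetic multi-night cohort generator.

Generates breath-level polysomnography-like recordings from a closed-loop
ventilatory-control + upper-airway model with known ground-truth traits
and an explicit two-level variance structure: each subject draws a trait
mean from the population (between-subject SD) and each night adds an
independent deviation (between-night SD).  Those variance components are
what the downstream reliability analysis (ICC, SEM, MDD) is meant to
recover, so they are first-class configuration, not incidental noise.

Mechanism of one night, on a fixed breath clock:

* chemical drive D follows the first-order delayed chemoreflex of
  :mod:`endotrait.model` with per-night gain G, time constant tau and
  circulatory delay delta (delta rounded to whole breaths);
* the upper airway converts drive to achieved ventilation through the
  "endogram" line  V = min(D, Vpassive + s * (D - 100)),
  s = Vcomp / (ArTh - 100), floored at Vmin_floor and 0 — an airway
  that delivers Vpassive at eupneic drive and Vpassive + Vcomp at the
  arousal threshold, collapsing below drive whenever the line binds
  (the breath is then flagged obstructed);
* when D crosses ArTh an arousal is emitted (2-breath scored interval,
  2-breath refractory after the run) and for a 3-breath post-arousal
  run the airway opens with an excess ventilatory response: V = D + VRA;
  drive then relaxes through the loop's own negative feedback;
* wake epochs hold ventilation and drive at eupnea;
* recorded ventilation adds Gaussian measurement noise to the achieved
  (latent) ventilation.

Sleep architecture (total sleep time, REM fraction, supine fraction,
wake placement) is generated as 30-s epoch labels from per-night draws
of the configured architecture parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EUPNEA, g_from_lg1, lg_magnitude, natural_frequency
from .scoring import SleepSummary, score_events

__all__ = [
    "TraitMoments",
    "TraitConfig",
    "SubjectTruth",
    "NightRecording",
    "sample_cohort_truth",
    "simulate_night",
    "simulate_cohort",
]

TRAIT_NAMES = ("lg1", "tau_s", "delay_s", "arth", "vra", "vpassive", "vcomp", "vmin_floor")

# truncation bounds enforced on sampled subject means and night values
TRAIT_BOUNDS = {
    "lg1": (0.05, 3.0),
    "tau_s": (6.0, 60.0),
    "delay_s": (6.0, 28.0),
    "arth": (101.0, 180.0),
    "vra": (2.0, 60.0),
    "vpassive": (5.0, 100.0),
    "vcomp": (0.0, 60.0),
    "vmin_floor": (0.0, 100.0),
}

POST_AROUSAL_BREATHS = 3     # ventilation follows drive + VRA for this run
AROUSAL_SCORED_BREATHS = 2   # length of the scored arousal interval
AROUSAL_REFRACTORY = 2       # breaths after the run before the next arousal
EPOCH_S = 30.0


@dataclass(frozen=True)
class TraitMoments:
    """Population mean and the two variance components of one trait."""

    mean: float
    between_subject_sd: float
    between_night_sd: float


@dataclass
class TraitConfig:
    """Cohort-level configuration of the synthetic study.

    Trait means/SDs are in trait units (loop gain dimensionless, delays
    and time constants in seconds, everything else in % eupnea).  The
    defaults sketch a moderate-to-severe OSA trial cohort: a collapsible
    airway (Vpassive well below eupnea), modest muscle compensation,
    sub-critical loop gain with a ~45-60 s natural period, and
    between-night SDs a factor ~2 below the between-subject SDs so that
    single-night reliability lands in the moderate-to-good ICC range.
    """

    traits: dict[str, TraitMoments] = field(default_factory=lambda: {
        "lg1": TraitMoments(0.55, 0.12, 0.05),
        "tau_s": TraitMoments(20.0, 3.0, 1.0),
        "delay_s": TraitMoments(14.0, 2.2, 1.2),
        "arth": TraitMoments(112.0, 10.0, 5.0),
        "vra": TraitMoments(20.0, 9.0, 5.0),
        "vpassive": TraitMoments(65.0, 12.0, 5.0),
        "vcomp": TraitMoments(10.0, 5.0, 3.0),
        "vmin_floor": TraitMoments(35.0, 10.0, 5.0),
    })
    n_subjects: int = 67
    n_nights: int = 2
    # sleep architecture
    tst_mean_min: float = 390.0
    tst_sd_min: float = 45.0
    rem_frac_mean: float = 0.15
    rem_frac_sd: float = 0.05
    supine_frac_mean: float = 0.45
    supine_frac_sd: float = 0.22
    efficiency_mean: float = 0.81
    efficiency_sd: float = 0.06
    # breath clock and observation model
    breath_s: float = 4.0
    process_noise_sd: float = 4.0   # breath-to-breath variability of achieved ventilation
    noise_sd: float = 1.5           # measurement noise on recorded ventilation
    desat_coef: float = 0.005   # % SpO2 dip per (% eupnea x s) of integrated deficit
    # trial-style inclusion screen applied by simulate_cohort: subjects whose
    # screening night scores below this AHI are redrawn (None disables)
    min_ahi: float | None = 15.0
    max_screen_tries: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in TRAIT_NAMES:
            if name not in self.traits:
                raise ValueError(f"traits missing entry '{name}'")
            tm = self.traits[name]
            if tm.between_subject_sd < 0 or tm.between_night_sd < 0:
                raise ValueError(f"trait '{name}': SDs must be >= 0")
        for name in ("vpassive", "vcomp", "vmin_floor"):
            if not 0.0 <= self.traits[name].mean <= 150.0:
                raise ValueError(f"trait '{name}': mean must lie in [0, 150]")
        if self.traits["arth"].mean <= 100.0:
            raise ValueError("trait 'arth': mean must exceed 100 (% eupnea)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        for fld in ("tst_sd_min", "rem_frac_sd", "supine_frac_sd", "efficiency_sd",
                    "noise_sd", "process_noise_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be >= 0")
        if self.breath_s <= 0:
            raise ValueError("breath_s must be positive")


@dataclass
class SubjectTruth:
    """Ground-truth per-night trait values for one subject.

    Each per-night array has length n_nights.  `g` is the steady-state
    chemoreflex gain implied by lg1 and tau; `delay_s` is stored as
    implemented, i.e. rounded to whole breaths.  lgn/natural frequency
    follow from (g, tau, delay).
    """

    subject_id: str
    index: int
    lg1: np.ndarray
    tau_s: np.ndarray
    delay_s: np.ndarray
    arth: np.ndarray
    vra: np.ndarray
    vpassive: np.ndarray
    vcomp: np.ndarray
    vmin_floor: np.ndarray
    g: np.ndarray
    lgn: np.ndarray
    natural_freq: np.ndarray

    def night(self, j: int) -> dict[str, float]:
        return {k: float(getattr(self, k)[j]) for k in
                ("lg1", "tau_s", "delay_s", "arth", "vra", "vpassive",
                 "vcomp", "vmin_floor", "g", "lgn", "natural_freq")}


@dataclass
class NightRecording:
    """One subject-night bundle of breath, epoch, event and arousal tables.

    breaths:  onset_s, duration_s, ventilation (% eupnea, noisy),
              drive (% eupnea, latent — simulator only), obstructed
    epochs:   start_s, stage in {W,N1,N2,N3,REM}, position in
              {supine, nonsupine} (contiguous 30-s epochs)
    events:   type, start_s, end_s, desat_pct, arousal_linked
    arousals: start_s, end_s
    """

    subject_id: str
    night_index: int
    breaths: pd.DataFrame
    epochs: pd.DataFrame
    events: pd.DataFrame
    arousals: pd.DataFrame
    summary: SleepSummary
    vmin_realized: float = float("nan")

    @property
    def span_s(self) -> float:
        if len(self.breaths) == 0:
            return 0.0
        last = self.breaths.iloc[-1]
        return float(last.onset_s + last.duration_s)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 100) -> float:
    """Draw N(mean, sd) truncated to [lo, hi] by resampling, then clipping."""
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _sample_subject(config: TraitConfig, index: int, attempt: int = 0) -> SubjectTruth:
    rng = np.random.default_rng([config.rng_seed, 101, index, attempt])
    vals: dict[str, np.ndarray] = {}
    for name in TRAIT_NAMES:
        tm = config.traits[name]
        lo, hi = TRAIT_BOUNDS[name]
        smean = _truncated_normal(rng, tm.mean, tm.between_subject_sd, lo, hi)
        vals[name] = np.array([
            _truncated_normal(rng, smean, tm.between_night_sd, lo, hi)
            for _ in range(config.n_nights)
        ])
    vals["vmin_floor"] = np.minimum(vals["vmin_floor"], vals["vpassive"])
    # snap delay to the breath clock: that is what the night implements
    vals["delay_s"] = np.maximum(
        config.breath_s,
        np.round(vals["delay_s"] / config.breath_s) * config.breath_s,
    )
    g = np.array([g_from_lg1(l, t) for l, t in zip(vals["lg1"], vals["tau_s"])])
    fn = np.array([natural_frequency(t, d) for t, d in zip(vals["tau_s"], vals["delay_s"])])
    lgn = np.array([lg_magnitude(gg, t, f) for gg, t, f in zip(g, vals["tau_s"], fn)])
    return SubjectTruth(subject_id=f"S{index + 1:03d}", index=index,
                        g=g, lgn=lgn, natural_freq=fn, **vals)


def sample_cohort_truth(config: TraitConfig) -> list[SubjectTruth]:
    """Draw per-subject, per-night ground-truth traits.

    Per-night value = subject mean (population mean + between-subject
    deviation) + between-night deviation, truncated to the trait bounds;
    Vmin_floor is additionally capped at the night's Vpassive.  No
    inclusion screening is applied here (see :func:`simulate_cohort`).
    Deterministic given config.rng_seed.
    """
    config.validate()
    return [_sample_subject(config, i) for i in range(config.n_subjects)]


def _build_hypnogram(rng: np.random.Generator, config: TraitConfig):
    """Epoch-level stage and position labels for one night.

    Wake is placed as an initial sleep latency, two or three mid-night
    awakenings and a final awakening; sleep alternates ~90-min NREM/REM
    cycles with the night's REM fraction at each cycle's end; position
    is a single contiguous supine block covering the night's supine
    fraction.  Only the stage/position proportions matter downstream.
    """
    tst_min = max(60.0, rng.normal(config.tst_mean_min, config.tst_sd_min))
    eff = float(np.clip(rng.normal(config.efficiency_mean, config.efficiency_sd), 0.5, 0.98))
    rem_frac = float(np.clip(rng.normal(config.rem_frac_mean, config.rem_frac_sd), 0.0, 0.45))
    sup_frac = float(np.clip(rng.normal(config.supine_frac_mean, config.supine_frac_sd), 0.0, 1.0))

    n_sleep = int(round(tst_min * 60.0 / EPOCH_S))
    n_total = int(round(n_sleep / eff))
    n_wake = n_total - n_sleep

    # distribute wake: 40% latency, 3 mid-night blocks, 10% final
    latency = int(round(0.4 * n_wake))
    final = int(round(0.1 * n_wake))
    mid = n_wake - latency - final
    mid_blocks = [mid // 3, mid // 3, mid - 2 * (mid // 3)]

    # sleep stages in cycles
    cycle_epochs = int(90 * 60 / EPOCH_S)
    stages: list[str] = []
    while len(stages) < n_sleep:
        n_cyc = min(cycle_epochs, n_sleep - len(stages))
        n_rem = int(round(rem_frac * n_cyc))
        n_nrem = n_cyc - n_rem
        block = ["N1"] + ["N3"] * max(0, min(n_nrem - 1, int(0.2 * n_nrem))) \
            + ["N2"] * max(0, n_nrem - 1 - min(n_nrem - 1, int(0.2 * n_nrem)))
        stages.extend(block[:n_nrem])
        stages.extend(["REM"] * n_rem)
    stages = stages[:n_sleep]

    # interleave wake blocks
    seq: list[str] = ["W"] * latency
    thirds = np.array_split(np.asarray(stages, dtype=object), 3)
    for part, wblock in zip(thirds, mid_blocks):
        seq.extend(part.tolist())
        seq.extend(["W"] * wblock)
    seq.extend(["W"] * final)
    n_total = len(seq)

    # single supine block at a random offset
    n_sup = int(round(sup_frac * n_total))
    start = int(rng.integers(0, max(1, n_total - n_sup + 1)))
    position = np.array(["nonsupine"] * n_total, dtype=object)
    position[start:start + n_sup] = "supine"

    epochs = pd.DataFrame({
        "start_s": np.arange(n_total) * EPOCH_S,
        "stage": seq,
        "position": position,
    })
    return epochs


def simulate_night(
    truth: SubjectTruth,
    night_index: int,
    config: TraitConfig,
    score: bool = True,
) -> NightRecording:
    """Simulate one subject-night on the breath clock.

    Raises
    ------
    ValueError
        If the night's arousal threshold is <= 100 %eupnea (the
        compensation slope Vcomp / (ArTh - 100) is then undefined).
    """
    t = truth.night(night_index)
    if t["arth"] <= 100.0:
        raise ValueError("ArTh must exceed 100 %eupnea: compensation slope undefined")

    rng = np.random.default_rng([config.rng_seed, 202, truth.index, night_index])
    epochs = _build_hypnogram(rng, config)
    tb = config.breath_s
    span_s = float(len(epochs)) * EPOCH_S
    n_breaths = int(span_s // tb)

    stage_of_breath = np.asarray(epochs["stage"])[
        np.minimum((np.arange(n_breaths) * tb / EPOCH_S).astype(int), len(epochs) - 1)
    ]
    asleep = stage_of_breath != "W"

    g, tau, delay = t["g"], t["tau_s"], t["delay_s"]
    arth, vra = t["arth"], t["vra"]
    vpassive, vcomp, vmin_floor = t["vpassive"], t["vcomp"], t["vmin_floor"]
    slope = vcomp / (arth - 100.0)
    alpha = math.exp(-tb / tau)
    d_breaths = max(1, int(round(delay / tb)))

    v_true = np.empty(n_breaths)
    drive = np.empty(n_breaths)
    obstructed = np.zeros(n_breaths, dtype=bool)
    arousal_onsets: list[int] = []

    # breath-to-breath variability of achieved ventilation (sighs, tidal
    # volume fluctuation); feeds back through the loop, unlike the
    # measurement noise added to the recorded signal below
    eps = rng.normal(0.0, config.process_noise_sd, n_breaths)
    d_state = EUPNEA
    run_left = 0
    refractory = 0
    armed = True   # re-arms only after drive falls below ArTh (hysteresis)
    for i in range(n_breaths):
        v_del = v_true[i - d_breaths] if i >= d_breaths else EUPNEA
        if not asleep[i]:
            d_state = EUPNEA
            drive[i] = d_state
            v_true[i] = max(0.0, EUPNEA + eps[i])
            run_left = 0
            refractory = 0
            armed = True
            continue
        d_state = alpha * d_state + (1.0 - alpha) * (EUPNEA + g * (EUPNEA - v_del))
        drive[i] = d_state
        if d_state < arth:
            armed = True
        if run_left > 0:
            v_true[i] = max(0.0, d_state + vra + eps[i])
            run_left -= 1
            if run_left == 0:
                refractory = AROUSAL_REFRACTORY
        elif refractory == 0 and armed and d_state >= arth:
            arousal_onsets.append(i)
            armed = False
            v_true[i] = max(0.0, d_state + vra + eps[i])
            run_left = POST_AROUSAL_BREATHS - 1
        else:
            if refractory > 0:
                refractory -= 1
            v_line = vpassive + slope * (d_state - EUPNEA)
            v = min(d_state, v_line)
            v_true[i] = max(v + eps[i], vmin_floor, 0.0)
            obstructed[i] = v_true[i] < d_state - 1e-9

    ventilation = np.maximum(0.0, v_true + rng.normal(0.0, config.noise_sd, n_breaths))

    breaths = pd.DataFrame({
        "onset_s": np.arange(n_breaths) * tb,
        "duration_s": np.full(n_breaths, tb),
        "ventilation": ventilation,
        "drive": drive,
        "obstructed": obstructed,
    })
    arousals = pd.DataFrame({
        "start_s": [i * tb for i in arousal_onsets],
        "end_s": [(i + AROUSAL_SCORED_BREATHS) * tb for i in arousal_onsets],
    })

    # realized "ventilation at minimal drive": lowest-decile median of the
    # latent trace on obstructed-phase sleep breaths (the quantity the
    # endogram estimator reads off)
    run_mask = np.zeros(n_breaths, dtype=bool)
    for i in arousal_onsets:
        run_mask[i:i + POST_AROUSAL_BREATHS] = True
    sel = asleep & ~run_mask
    if sel.sum() >= 50:
        dr, vv = drive[sel], v_true[sel]
        lo_edge = np.quantile(dr, 0.1)
        vmin_real = float(np.median(vv[dr <= lo_edge]))
    else:
        vmin_real = float("nan")

    night = NightRecording(
        subject_id=truth.subject_id,
        night_index=night_index,
        breaths=breaths,
        epochs=epochs,
        events=pd.DataFrame(columns=["type", "start_s", "end_s", "desat_pct", "arousal_linked"]),
        arousals=arousals,
        summary=SleepSummary.invalid(),
        vmin_realized=vmin_real,
    )
    if score:
        night.summary, night.events = score_events(night, desat_coef=config.desat_coef,
                                                   return_events=True)
    return night


def simulate_cohort(config: TraitConfig):
    """Sample truths and simulate every subject-night.

    Applies the trial-style inclusion screen: a subject whose first
    (screening) night scores AHI below config.min_ahi is redrawn, up to
    config.max_screen_tries attempts, emulating an enrolment criterion
    of moderate-to-severe OSA.  Returns (truths, recordings) with
    recordings a flat list ordered by subject then night.  Bit-identical
    for identical (config, seed).
    """
    config.validate()
    truths: list[SubjectTruth] = []
    recordings: list[NightRecording] = []
    for i in range(config.n_subjects):
        for attempt in range(max(1, config.max_screen_tries)):
            tr = _sample_subject(config, i, attempt)
            nights = [simulate_night(tr, j, config) for j in range(config.n_nights)]
            if config.min_ahi is None or nights[0].summary.ahi >= config.min_ahi:
                break
        truths.append(tr)
        recordings.extend(nights)
    return truths, recordings
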