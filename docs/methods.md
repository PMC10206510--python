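# Methods

## Scope and design

The package answers a methodological question: given the way OSA
endotypic traits are estimated from routine polysomnography — a
chemoreflex model fitted to breath-by-breath ventilation in 7-minute
windows — how reliable is a single-night assessment, and how much does
averaging two nights help?  Real patient recordings from the motivating
setting are not public, so the package pairs the estimation and
statistics stages with a generative model whose ground truth and
variance components are known.  Everything downstream of the generator
(windowing, drive fits, endogram, ICC/SEM/MDD) is written exactly as it
would be for real breath tables and consumes only the observable
columns.

## Ventilatory-control model

Chemical drive D and ventilation V are in % of eupneic ventilation
(eupnea = 100).  Drive follows a first-order delayed chemoreflex,

    tau dD/dt = -D + 100 + G (100 - V(t - delta)),

discretised exactly on a fixed breath clock (default 4 s; the analysis
concerns ventilation, not respiratory timing, and a fixed clock makes
the circulatory delay an integer shift).  The loop-gain magnitude is
LG(f) = G / sqrt(1 + (2 pi f tau)^2); LG1 is its value at 1 cycle/min
and LGn its value at the natural frequency, the unique root of
2 pi f delta + arctan(2 pi f tau) = pi (solved by bracketed bisection,
xtol 1e-12).

The upper airway maps drive to achieved ventilation along the endogram
line V = min(D, Vpassive + s (D - 100)) with s = Vcomp / (ArTh - 100),
floored at Vmin_floor and 0; a breath is "obstructed" when the line
binds.  When drive crosses ArTh a cortical arousal fires: the scored
arousal interval spans 2 breaths, ventilation follows drive plus the
overshoot VRA for a 3-breath run, a 2-breath refractory follows, and the
trigger re-arms only once drive falls back below ArTh (hysteresis, so
every scored arousal is a genuine upward crossing).  Drive then relaxes
through the loop's own negative feedback — the overshoot suppresses
drive after one circulatory delay.  Wake epochs pin ventilation and
drive at eupnea.

Two noise sources are distinct on purpose.  *Process* variability
(default SD 4 %eupnea) perturbs achieved ventilation and feeds back
through the loop: it represents genuine breath-to-breath physiologic
variation (sighs, tidal-volume fluctuation) and is what makes the
window fits identifiable — a noiseless simulated night settles into an
exactly periodic cycle in which every arousal run is identical and
(G, tau, delta) are underdetermined.  *Measurement* noise (default SD
1.5 %eupnea) is added only to the recorded signal.  The asymmetry of
the defaults reflects that ventilation derived from calibrated airflow
has small instrument error relative to physiologic variation; see
Limitations for why this matters to the estimator.

## Cohort generation

Each of the eight generator traits (LG1, tau, delta, ArTh, VRA,
Vpassive, Vcomp, Vmin_floor) has a population mean, a between-subject
SD and a between-night SD; a subject draws a mean, each night adds an
independent deviation, and draws are truncated to physiologic bounds by
resampling (up to 100 tries) then clipping.  G is derived from the
sampled LG1 and tau; delta is snapped to the breath clock and the
snapped value is recorded as truth.  Defaults (raw scale: Vpassive 65,
Vcomp 10, ArTh 112, VRA 20, LG1 0.55, tau 20 s, delta 14 s; night SDs
roughly half the subject SDs) sketch a moderate-to-severe OSA trial
cohort and are illustrative: published trait medians on the transformed
reporting scale cannot be inverted to raw values because the exact
transform dialect used in that reporting is not fully specified.
`simulate_cohort` additionally applies a trial-style inclusion screen —
subjects whose first (screening) night scores AHI < 15 events/h are
redrawn — mirroring enrolment into a moderate-to-severe cohort;
`sample_cohort_truth` itself is a pure variance-component generator.

Sleep architecture is generated as 30-s epochs: total sleep time
N(390, 45) min, efficiency N(0.81, 0.06), wake placed as sleep latency
plus mid-night awakenings, ~90-min NREM/REM cycles with the night's REM
fraction N(0.15, 0.05) at each cycle's end, and one contiguous supine
block covering the night's supine fraction N(0.45, 0.22) — only the
stage/position proportions matter downstream, and the wide supine SD
deliberately produces recordings failing the ≤ 2 h supine-sleep rule so
the strictest stratum shows realistic attrition.

Event scoring uses clinical thresholds on the recorded trace (3-breath
median filter so single-breath noise neither splits nor fabricates
events): apnea = ventilation < 10% for ≥ 10 s; hypopnea = reduction
≥ 30% for ≥ 10 s validated by a ≥ 3% desaturation and/or an arousal
starting within 5 s of the event; desaturation depth is modelled as
desat_coef (default 0.005 %SpO2 per %eupnea·s) times the event's
integrated ventilation deficit — a threshold-faithful stand-in, not
oximetry physiology.  ODI counts ≥ 4% desaturations per hour of sleep.

## Trait estimation

Recordings are segmented into 420-s windows at a 210-s step (50%
overlap; published per-night window counts imply overlap but not the
exact step).  A window is eligible if it overlaps ≥ 1 scored event and
≤ 30 s of wake.  Each eligible window is fitted by bounded least
squares (G ∈ (0, 10], tau ∈ [5, 120] s, delta ∈ [5, 30] s; three fixed
starts; fractional delays interpolate between integer shifts so the
objective is continuous).  The fit residual compares model drive —
the chemoreflex recursion run over observed ventilation, with a 30-breath
burn-in so the filter state and delay line are data-determined — to
observed ventilation on *drive-revealing breaths*: breaths inside scored
arousal intervals plus one following breath, where the airway is open.
On those breaths ventilation exceeds drive by the arousal overshoot, so
a per-window intercept gamma ≥ 0 is profiled out in closed form; gamma
is itself the window's VRA estimate.

Aggregation to one recording/stratum: per-window LG1/LGn/delay medians
initialise a single night-level (G, tau, delta, gamma) refit pooling
all arousal breaths of the selected windows, and the reported
LG1/LGn/delay, the VRA (= pooled gamma) and the consensus drive trace
come from that refit.  The pooled refit exists because a single 7-min
window holds only a handful of arousal runs: LG1 is well identified but
(G, tau) individually sit on a flat ridge, and drive traces predicted
from per-window parameters scattered enough to corrupt the endogram
(+3–6 %eupnea drive bias in testing).  ArTh is the median, over arousal
onsets in the selected windows, of the midpoint of the pre-onset and
onset breath drives — the threshold is crossed between those two
breaths, and the midpoint halves the breath-clock discretisation bias.
With zero arousals ArTh/VRA are reported absent (NaN), never zero.

Upper-airway traits come from the pooled endogram: (consensus drive,
observed ventilation) pairs on non-arousal sleep breaths of the
selected windows, drive binned into deciles, decile medians
interpolated at drive = 100 (Vpassive) and at drive = ArTh (Vactive;
flagged if ArTh lies outside the observed drive range); Vmin is the
lowest-decile median; fewer than 50 pairs yields absent traits.
Vactive and Vpassive are then passed through the clamped-logit
floor/ceiling correction (x = clamp(V/100, eps, 1−eps), y = logit(x),
affinely rescaled to (0, 100) with fixpoint 50; eps default 0.005,
configurable to emulate other dialects of the correction), and
Vcomp = Vactive_t − Vpassive_t on that scale (may be negative).

Ventilation is assumed calibrated so that 100 = eupnea, as the
simulator guarantees and as upstream flow calibration provides for real
data.  Anchoring eupnea to the window-mean ventilation instead was
rejected: in severe OSA the within-window mean sits near 75% of eupnea,
which would inflate ArTh and deflate Vpassive by ~25 %eupnea.

Ground truth for Vmin is recorded as the lowest-decile median of the
latent noiseless trace (`vmin_realized`), because that is the quantity
the endogram definition names; the generator's floor parameter rarely
binds at realised drive minima and is not the estimand.

## Agreement statistics

For a complete n × k matrix of one trait (subjects with a missing
occasion dropped row-wise): two-way subject × occasion mean squares
without replication; single-measure absolute-agreement ICC

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with the McGraw–Wong F-distribution CI (Satterthwaite df); the
single-rater absolute-agreement coefficient is identical under two-way
random- and mixed-effects models, so no separate branch exists.  The
agreement SEM is sqrt(MSE + max(0, (MSC - MSE)/n)) — it charges
systematic occasion shifts to measurement error, and for k = 2 it is an
exact function of the paired-difference summary (MSE = sd²/2,
MSC = n·mean²/2), which is what lets published difference rows
reconstruct published SEMs; negative occasion-variance estimates are
truncated at zero.  SEM CIs use a subject-level percentile bootstrap
(1,000 resamples, seeded) since no closed form is standard for the
absolute-agreement SEM.  MDD = 1.96·√2·SEM exactly.  Paired t tests use
α = 0.003 by default (Bonferroni for ~15 simultaneous comparisons; the
family size behind that adjustment is conventional, so α is
configurable).  ICC labels: good > 0.75, moderate > 0.5, else poor,
strict inequalities.  Bland-Altman: bias ± 1.96·SD of differences, with
per-subject (mean, diff) pairs emitted for plotting.  The delta screen
flags Pearson |r| > 0.4 between night-to-night changes.

Two-night averaging: each of 500 seeded iterations partitions every
subject's four nights at random into two disjoint pairs (three possible
partitions), averages each pair, and computes the agreement SEM of the
resulting n × 2 matrix; the reported SEM is the mean across iterations
with a 2.5/97.5 percentile spread, and its MDD uses the same identity.
Under pure i.i.d. noise this converges to the single-night SEM/√2 (an
MDD reduction of 29.3%); structured night-to-night physiology keeps
real traits below that bound.

## Numerical choices and degenerate inputs

Zero-variance difference vectors mark the paired test degenerate (t
undefined, not significant) and give SEM = MDD = 0 and ICC = 1 where
rows differ; a matrix with zero total variance yields NaN ICC, flagged
undefined.  Shapiro-Wilk refuses constant vectors and n outside
[3, 5000].  Optimiser non-convergence or < 3 drive-revealing breaths
drops a window with a counted reason.  A recording shorter than 420 s
yields zero windows, not an error; zero sleep yields an invalid summary
rather than division by zero.  TSV output uses 6 significant digits,
which also makes rerun outputs byte-identical.

## Problem sizes

The default study conditions are 67 subjects × 2 nights (main cohort)
and 22 × 4 (averaging subgroup), with ~390 min recordings at 4-s
breaths (~80–110 fitted windows per night).  Tests that only need the
mechanics run on 3–10-subject cohorts with 2–4-h nights; recovery and
acceptance checks run at the full 67 × 2.

## What the generator does and does not emulate

It reproduces the structure the analysis assumes: latent drive dynamics
with known loop parameters, an endogram-shaped airway, arousal-
terminated events with scored AHI/ODI, stage/position labels, and
explicit between-subject/between-night variance components.  It does
not emulate REM-specific physiology (stage labels exist, trait dynamics
do not differ by stage — so stratified results here measure data
attrition, not stage physiology), position-dependent collapsibility,
signal artefacts, scorer disagreement, drifting calibration, variable
respiratory timing, or realistic oximetry.  Passing tests therefore
demonstrate that the estimation and statistics stages are correct and
self-consistent under the model's assumptions, not that the specific
ICC/SEM values generalise to patients.

## Limitations

* The chemoreflex fit treats observed ventilation as the true loop
  input; when measurement noise rivals process variability this causes
  classical errors-in-variables attenuation (G biased low by ~30% at
  measurement SD 4 %eupnea in testing).  The default noise split keeps
  this small, but applying the estimator to noisy uncalibrated signals
  would need an errors-in-variables treatment.
* Per-window (G, tau) is weakly identified by design of the data — only
  arousal breaths reveal drive; the night-level pooled refit is the
  remedy and per-window values should not be interpreted individually.
* ArTh estimates carry a positive bias bounded by half the drive
  increment per breath at threshold crossing (~1–3 %eupnea at the
  defaults).
* The trial-style AHI ≥ 15 screen conditions the realised trait
  distribution (e.g. slightly lower Vpassive than the unconditioned
  population), as a real enrolment criterion would.
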