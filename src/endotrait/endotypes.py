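"""Per-recording endotypic trait estimation.

Combines the 7-min windowing, the chemoreflex window fits and the
endogram construction into the nine traits reported for one recording
(optionally per stage/position stratum):

* a night-level consensus fit: the per-window medians of (G, tau,
  delta) seed a single pooled refit over all arousal breaths of the
  selected windows.  Single windows hold too few arousal runs to pin
  (G, tau) individually, so the pooled fit supplies the reported LG1,
  LGn, circulatory delay, the VRA (the pooled arousal overshoot of
  ventilation above drive) and one consistent drive trace;
* arousal threshold (ArTh): median consensus drive at the threshold
  crossing (midpoint of the pre-onset and onset breaths) over arousals
  inside the selected windows;
* upper-airway traits: (consensus drive, observed ventilation) pairs
  from non-arousal sleep breaths of the selected windows are pooled,
  drive is binned into deciles, and the decile-median endogram is read
  off at eupneic drive (Vpassive), at the arousal threshold (Vactive),
  and in the lowest decile (Vmin); raw Vcomp = Vactive - Vpassive, with
  the floor/ceiling-corrected version derived from transformed Vactive
  and Vpassive.

Windows are fitted once; stratified trait sets re-aggregate the same
fits, so stratification never refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drivefit import (BURNIN_BREATHS, DriveFitError, WindowFit, fit_drive_model,
                       refine_drive_fit)
from .model import F_ONE_PER_MIN, lg_magnitude, natural_frequency, predict_drive
from .transforms import TransformSpec, logit_squash, vcomp_transformed
from .windows import Window, segment_windows, stratify

__all__ = ["EndotypeSet", "FittedNight", "fit_night", "estimate_recording",
           "estimate_ventilatory_traits", "estimate_ua_traits", "STRATA"]

MIN_UA_PAIRS = 50


@dataclass
class EndotypeSet:
    """The nine endotypic traits for one recording/stratum.

    vpassive/vactive/vcomp are raw %-eupnea values; the _t fields carry
    the floor/ceiling-corrected scale the reliability analysis uses.
    Traits that cannot be estimated (no arousals, too few endogram
    pairs) are NaN, never zero.
    """

    stratum: str
    n_windows: int
    lg1: float = float("nan")
    lgn: float = float("nan")
    delay_s: float = float("nan")
    arth: float = float("nan")
    vra: float = float("nan")
    vpassive: float = float("nan")
    vactive: float = float("nan")
    vcomp: float = float("nan")
    vmin: float = float("nan")
    vpassive_t: float = float("nan")
    vactive_t: float = float("nan")
    vcomp_t: float = float("nan")
    vactive_extrapolated: bool = False


@dataclass
class FittedNight:
    """All retained window fits for one recording, plus shared context."""

    windows: list[Window]
    fits: dict[int, WindowFit]          # window index -> fit
    arousal_onset_idx: np.ndarray       # breath index of each arousal onset
    unobstructed: np.ndarray            # bool mask over breaths (arousal runs)
    asleep: np.ndarray                  # bool mask over breaths
    vent: np.ndarray
    breath_s: float
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)


def _arousal_masks(night):
    """Drive-revealing breath mask and arousal onset indices.

    Drive-revealing breaths are those within a scored arousal interval
    plus one following breath — there the airway is open and ventilation
    tracks drive (plus the arousal overshoot).
    """
    onset = np.asarray(night.breaths["onset_s"], float)
    n = onset.size
    mask = np.zeros(n, dtype=bool)
    onsets = []
    for a0, a1 in zip(np.asarray(night.arousals["start_s"], float),
                      np.asarray(night.arousals["end_s"], float)):
        i0 = int(np.searchsorted(onset, a0 - 1e-9))
        i1 = int(np.searchsorted(onset, a1 - 1e-9)) + 1  # plus one following breath
        if i0 >= n:
            continue
        mask[i0:min(i1, n)] = True
        onsets.append(i0)
    return mask, np.asarray(onsets, dtype=int)


def _asleep_mask(night) -> np.ndarray:
    epochs = night.epochs
    epoch_len = float(epochs["start_s"].iloc[1] - epochs["start_s"].iloc[0]) \
        if len(epochs) > 1 else 30.0
    stages = np.asarray(epochs["stage"])
    onset = np.asarray(night.breaths["onset_s"], float)
    eidx = np.minimum((onset / epoch_len).astype(int), len(epochs) - 1)
    return stages[eidx] != "W"


def fit_night(night, step_s: float = 210.0) -> FittedNight:
    """Segment a recording into windows and fit every eligible one."""
    windows = segment_windows(night, step_s=step_s)
    vent = np.asarray(night.breaths["ventilation"], float)
    breath_s = float(np.median(np.asarray(night.breaths["duration_s"], float))) \
        if len(night.breaths) else 4.0
    unobstructed, onsets = _arousal_masks(night)

    fits: dict[int, WindowFit] = {}
    reasons: dict[str, int] = {}
    for wi, w in enumerate(windows):
        if not w.eligible:
            continue
        i0, i1 = w.breath_slice.start, w.breath_slice.stop
        b0 = max(0, i0 - BURNIN_BREATHS)
        local_fit = np.flatnonzero(unobstructed[i0:i1]) + (i0 - b0)
        try:
            fits[wi] = fit_drive_model(vent[b0:i1], local_fit, breath_s, n_burnin=i0 - b0)
        except DriveFitError as exc:
            reasons[str(exc)] = reasons.get(str(exc), 0) + 1
    return FittedNight(
        windows=windows,
        fits=fits,
        arousal_onset_idx=onsets,
        unobstructed=unobstructed,
        asleep=_asleep_mask(night),
        vent=vent,
        breath_s=breath_s,
        n_dropped=sum(reasons.values()),
        drop_reasons=reasons,
    )


def estimate_ventilatory_traits(fitted: FittedNight, window_indices) -> dict:
    """Control-system traits aggregated over the selected windows.

    Returns the trait medians plus the consensus drive trace re-inferred
    from the median (G, tau, delta).  With zero arousals inside the
    selection ArTh/VRA are NaN (absent, not zero).
    """
    nan = float("nan")
    sel = [i for i in window_indices if i in fitted.fits]
    if not sel:
        return {"lg1": nan, "lgn": nan, "delay_s": nan, "arth": nan, "vra": nan,
                "drive": None}
    fits = [fitted.fits[i] for i in sel]
    med = {k: float(np.median([getattr(f, k) for f in fits]))
           for k in ("g", "tau_s", "delay_s", "lg1", "lgn", "vra")}

    # consensus drive: one (G, tau, delta, gamma) refit over all arousal
    # breaths of the selected windows, started from the window medians
    in_win = np.zeros(fitted.vent.size, dtype=bool)
    onset_set: set[int] = set()
    for i in sel:
        w = fitted.windows[i]
        in_win[w.breath_slice] = True
        for j in fitted.arousal_onset_idx:
            if w.breath_slice.start <= j < w.breath_slice.stop:
                onset_set.add(int(j))
    fit_idx = np.flatnonzero(in_win & fitted.unobstructed)
    g_c, tau_c, delay_c, gamma_c = refine_drive_fit(
        fitted.vent, fit_idx, fitted.breath_s,
        (med["g"], med["tau_s"], med["delay_s"]))
    drive = predict_drive(fitted.vent, g_c, tau_c, delay_c, fitted.breath_s)
    fn_c = natural_frequency(tau_c, delay_c)
    lg1_c = lg_magnitude(g_c, tau_c, F_ONE_PER_MIN)
    lgn_c = lg_magnitude(g_c, tau_c, fn_c)
    # the threshold is crossed between the pre-onset and onset breaths;
    # the midpoint halves the discretisation bias of reading drive on
    # the onset breath alone
    arth_samples = [0.5 * (drive[j - 1] + drive[j]) if j > 0 else drive[j]
                    for j in sorted(onset_set)]
    arth = float(np.median(arth_samples)) if arth_samples else nan
    vra = gamma_c if arth_samples else nan
    return {"lg1": lg1_c, "lgn": lgn_c, "delay_s": delay_c,
            "arth": arth, "vra": vra, "drive": drive}


def estimate_ua_traits(fitted: FittedNight, window_indices, drive: np.ndarray,
                       arth: float, spec: TransformSpec | None = None) -> dict:
    """Upper-airway traits from the pooled decile-median endogram.

    Pools (consensus drive, observed ventilation) pairs from non-arousal
    sleep breaths of the selected windows, bins drive into deciles, and
    interpolates the decile-median curve at drive = 100 (Vpassive) and
    at drive = ArTh (Vactive); Vmin is the lowest-decile median.  Fewer
    than 50 pooled pairs yields NaN traits; an ArTh outside the observed
    drive range flags Vactive as extrapolated.
    """
    nan = float("nan")
    out = {"vpassive": nan, "vactive": nan, "vcomp": nan, "vmin": nan,
           "vpassive_t": nan, "vactive_t": nan, "vcomp_t": nan,
           "vactive_extrapolated": False}
    if drive is None:
        return out
    n = fitted.vent.size
    in_win = np.zeros(n, dtype=bool)
    for i in window_indices:
        if i in fitted.fits:
            w = fitted.windows[i]
            in_win[w.breath_slice] = True
    sel = in_win & fitted.asleep & ~fitted.unobstructed
    if sel.sum() < MIN_UA_PAIRS:
        return out
    drv = drive[sel]
    v = fitted.vent[sel]

    edges = np.quantile(drv, np.linspace(0.0, 1.0, 11))
    bin_drv, bin_v = [], []
    for b in range(10):
        m = (drv >= edges[b]) & ((drv < edges[b + 1]) if b < 9 else (drv <= edges[b + 1]))
        if m.sum() > 0:
            bin_drv.append(float(np.median(drv[m])))
            bin_v.append(float(np.median(v[m])))
    bin_drv = np.asarray(bin_drv)
    bin_v = np.asarray(bin_v)
    order = np.argsort(bin_drv)
    bin_drv, bin_v = bin_drv[order], bin_v[order]

    vpassive = float(np.interp(100.0, bin_drv, bin_v))
    vmin = float(bin_v[0])
    out.update(vpassive=vpassive, vmin=vmin)
    spec = spec or TransformSpec()
    out["vpassive_t"] = logit_squash(max(0.0, vpassive), spec)
    if np.isfinite(arth):
        vactive = float(np.interp(arth, bin_drv, bin_v))
        out["vactive"] = vactive
        out["vcomp"] = vactive - vpassive
        out["vactive_extrapolated"] = bool(arth < bin_drv[0] or arth > bin_drv[-1])
        out["vactive_t"] = logit_squash(max(0.0, vactive), spec)
        out["vcomp_t"] = vcomp_transformed(out["vactive_t"], out["vpassive_t"])
    return out


STRATA = {
    "all-all": ("all", "all", None),
    "nrem-all": ("NREM", "all", None),
    "nrem-supine": ("NREM", "supine", None),
    "nrem-supine-120": ("NREM", "supine", 120.0),
}


def estimate_recording(
    night,
    strata: dict[str, tuple] | None = None,
    step_s: float = 210.0,
    fitted: FittedNight | None = None,
    spec: TransformSpec | None = None,
) -> dict[str, EndotypeSet]:
    """Estimate the nine traits for one recording under each stratum.

    strata maps label -> (stage_filter, position_filter,
    min_supine_min); defaults to the four standard analysis strata.
    Returns one EndotypeSet per stratum (possibly with n_windows = 0
    and all-NaN traits when the stratum is empty or the recording is
    excluded by the supine-time rule).
    """
    strata = strata if strata is not None else STRATA
    fitted = fitted or fit_night(night, step_s=step_s)
    supine_min = None
    if night.summary.valid:
        supine_min = night.summary.supine_pct / 100.0 * night.summary.tst_min
    by_id = {id(w): i for i, w in enumerate(fitted.windows)}

    out: dict[str, EndotypeSet] = {}
    for label, (stage_f, pos_f, min_sup) in strata.items():
        sel_windows = stratify(fitted.windows, stage_f, pos_f,
                               min_supine_min=min_sup, supine_sleep_min=supine_min)
        indices = [by_id[id(w)] for w in sel_windows]
        fit_indices = [i for i in indices if i in fitted.fits]
        es = EndotypeSet(stratum=label, n_windows=len(fit_indices))
        if fit_indices:
            vt = estimate_ventilatory_traits(fitted, fit_indices)
            ua = estimate_ua_traits(fitted, fit_indices, vt["drive"], vt["arth"], spec=spec)
            es.lg1, es.lgn, es.delay_s = vt["lg1"], vt["lgn"], vt["delay_s"]
            es.arth, es.vra = vt["arth"], vt["vra"]
            es.vpassive, es.vactive, es.vcomp, es.vmin = (
                ua["vpassive"], ua["vactive"], ua["vcomp"], ua["vmin"])
            es.vpassive_t, es.vactive_t, es.vcomp_t = (
                ua["vpassive_t"], ua["vactive_t"], ua["vcomp_t"])
            es.vactive_extrapolated = ua["vactive_extrapolated"]
        out[label] = es
    return out
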