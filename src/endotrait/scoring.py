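"""Respiratory event scoring and sleep summary metrics.

Scores a breath-level recording into apneas/hypopneas with clinical-style
rules: an apnea is ventilation below 10% of eupnea sustained >= 10 s; a
hypopnea is a ventilation reduction >= 30% (i.e. ventilation <= 70%)
sustained >= 10 s and accompanied by a >= 3% desaturation, an arousal,
or both.  Desaturations >= 4% feed the oxygen desaturation index (ODI).

No SpO2 waveform is simulated: each candidate event's desaturation depth
is modelled as proportional to its integrated ventilation deficit
(desat_coef, % SpO2 per %eupnea-second), which reproduces the threshold
rules the indices depend on without any oximetry physiology.

Event detection runs on a 3-breath median filter of recorded ventilation
so that single-breath measurement noise neither splits nor fabricates
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = ["SleepSummary", "score_events"]

APNEA_THRESHOLD = 10.0      # % eupnea
HYPOPNEA_THRESHOLD = 70.0   # % eupnea (>= 30% reduction)
MIN_EVENT_S = 10.0
HYPOPNEA_DESAT = 3.0        # % required to validate a hypopnea
ODI_DESAT = 4.0             # % required to count toward ODI
AROUSAL_LINK_S = 5.0        # arousal starting within this lag terminates the event


@dataclass
class SleepSummary:
    """Scored per-night summary metrics."""

    ahi: float
    odi: float
    tst_min: float
    sleep_efficiency: float
    rem_pct: float
    supine_pct: float
    valid: bool = True

    @classmethod
    def invalid(cls) -> "SleepSummary":
        nan = float("nan")
        return cls(nan, nan, 0.0, nan, nan, nan, valid=False)


def _runs(mask: np.ndarray):
    """Start/end indices (half-open) of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends))


def score_events(night, desat_coef: float = 0.005, return_events: bool = False):
    """Score a night's breath trace into events and summary metrics.

    Parameters
    ----------
    night
        A recording with `breaths`, `epochs` and `arousals` tables.
    desat_coef
        % SpO2 dip per %eupnea-second of integrated ventilation deficit.
    return_events
        Also return the scored event table.

    A night with zero sleep yields an invalid summary rather than a
    division by zero.
    """
    breaths = night.breaths
    epochs = night.epochs
    if len(breaths) == 0 or len(epochs) == 0:
        raise ValueError("scoring requires breath and epoch tables")

    epoch_len = float(epochs["start_s"].iloc[1] - epochs["start_s"].iloc[0]) if len(epochs) > 1 else 30.0
    stages = np.asarray(epochs["stage"])
    positions = np.asarray(epochs["position"])
    sleep_epochs = stages != "W"
    tst_min = sleep_epochs.sum() * epoch_len / 60.0
    tib_min = len(epochs) * epoch_len / 60.0

    onset = np.asarray(breaths["onset_s"], float)
    dur = np.asarray(breaths["duration_s"], float)
    vent = np.asarray(breaths["ventilation"], float)
    epoch_idx = np.minimum((onset / epoch_len).astype(int), len(epochs) - 1)
    asleep = sleep_epochs[epoch_idx]

    events = []
    if tst_min > 0:
        v_f = medfilt(vent, kernel_size=3) if len(vent) >= 3 else vent
        arousal_starts = np.asarray(night.arousals["start_s"], float) if len(night.arousals) else np.empty(0)
        for s, e in _runs((v_f <= HYPOPNEA_THRESHOLD) & asleep):
            t0, t1 = onset[s], onset[e - 1] + dur[e - 1]
            if t1 - t0 < MIN_EVENT_S:
                continue
            deficit = float(np.sum((100.0 - np.minimum(vent[s:e], 100.0)) * dur[s:e]))
            desat = max(0.0, desat_coef * deficit)
            linked = bool(np.any((arousal_starts >= t0) & (arousal_starts <= t1 + AROUSAL_LINK_S)))
            # apnea if a >= 10 s stretch below the apnea threshold exists inside
            is_apnea = False
            apnea_kind = "obstructive_apnea"
            for s2, e2 in _runs(v_f[s:e] < APNEA_THRESHOLD):
                d2 = onset[s + e2 - 1] + dur[s + e2 - 1] - onset[s + s2]
                if d2 >= MIN_EVENT_S:
                    is_apnea = True
                    obs_frac = float(np.mean(np.asarray(breaths["obstructed"])[s + s2:s + e2])) \
                        if "obstructed" in breaths else 1.0
                    apnea_kind = ("obstructive_apnea" if obs_frac >= 2 / 3
                                  else "central_apnea" if obs_frac <= 1 / 3 else "mixed_apnea")
                    break
            if is_apnea:
                events.append((apnea_kind, t0, t1, desat, linked))
            elif desat >= HYPOPNEA_DESAT or linked:
                events.append(("hypopnea", t0, t1, desat, linked))

    events_df = pd.DataFrame(events, columns=["type", "start_s", "end_s", "desat_pct", "arousal_linked"])

    if tst_min <= 0:
        summary = SleepSummary.invalid()
    else:
        tst_h = tst_min / 60.0
        n_desat = int((events_df["desat_pct"] >= ODI_DESAT).sum()) if len(events_df) else 0
        summary = SleepSummary(
            ahi=len(events_df) / tst_h,
            odi=n_desat / tst_h,
            tst_min=tst_min,
            sleep_efficiency=100.0 * tst_min / tib_min,
            rem_pct=100.0 * (stages == "REM").sum() / sleep_epochs.sum(),
            supine_pct=100.0 * ((positions == "supine") & sleep_epochs).sum() / sleep_epochs.sum(),
        )
    if return_events:
        return summary, events_df
    return summary
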