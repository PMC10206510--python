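"""7-minute analysis windows and stage/position stratification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Window", "segment_windows", "stratify"]

WINDOW_S = 420.0
DEFAULT_STEP_S = 210.0
MAX_WAKE_S = 30.0


@dataclass
class Window:
    """One 420-s analysis window over a breath sequence.

    breath_slice indexes the night's breath table; eligibility requires
    at least one scored respiratory event and at most 30 s of wake
    (drive inference needs disturbed breathing, and wake breaks the
    closed-loop model).  Stage/position labels are the overlap-weighted
    majority over the window's epochs.
    """

    start_s: float
    end_s: float
    breath_slice: slice
    majority_stage: str
    majority_position: str
    n_events: int
    wake_s: float
    eligible: bool


def _overlap_weights(epochs: pd.DataFrame, start: float, end: float, epoch_len: float):
    e_start = np.asarray(epochs["start_s"], float)
    e_end = e_start + epoch_len
    ov = np.minimum(e_end, end) - np.maximum(e_start, start)
    return np.maximum(ov, 0.0)


def segment_windows(
    night,
    step_s: float = DEFAULT_STEP_S,
    window_s: float = WINDOW_S,
) -> list[Window]:
    """Sliding 7-min windows over a recording at the configured step.

    A recording shorter than one window yields an empty list (not an
    error).  Majority stage is taken over the window's epoch overlap;
    wake seconds and event count determine eligibility.
    """
    breaths = night.breaths
    if len(breaths) == 0:
        return []
    onset = np.asarray(breaths["onset_s"], float)
    dur = np.asarray(breaths["duration_s"], float)
    span_end = float(onset[-1] + dur[-1])
    t0 = float(onset[0])
    epochs = night.epochs
    epoch_len = float(epochs["start_s"].iloc[1] - epochs["start_s"].iloc[0]) if len(epochs) > 1 else 30.0
    ev_start = np.asarray(night.events["start_s"], float) if len(night.events) else np.empty(0)
    ev_end = np.asarray(night.events["end_s"], float) if len(night.events) else np.empty(0)
    stages = np.asarray(epochs["stage"])
    positions = np.asarray(epochs["position"])

    out: list[Window] = []
    start = t0
    while start + window_s <= span_end + 1e-9:
        end = start + window_s
        i0 = int(np.searchsorted(onset, start - 1e-9))
        i1 = int(np.searchsorted(onset, end - 1e-9))
        w = _overlap_weights(epochs, start, end, epoch_len)
        wake_s = float(w[stages == "W"].sum())
        sleep_w = w.copy()
        sleep_w[stages == "W"] = 0.0
        if sleep_w.sum() > 0:
            nrem = sleep_w[np.isin(stages, ("N1", "N2", "N3"))].sum()
            rem = sleep_w[stages == "REM"].sum()
            stage = "NREM" if nrem >= rem else "REM"
            sup = sleep_w[positions == "supine"].sum()
            pos = "supine" if sup >= sleep_w.sum() / 2 else "nonsupine"
        else:
            stage, pos = "W", "nonsupine"
        n_events = int(np.sum((ev_start < end) & (ev_end > start))) if ev_start.size else 0
        eligible = (stage != "W") and (n_events >= 1) and (wake_s <= MAX_WAKE_S) and (i1 - i0 >= 3)
        out.append(Window(start, end, slice(i0, i1), stage, pos, n_events, wake_s, eligible))
        start += step_s
    return out


def stratify(
    windows: list[Window],
    stage_filter: str = "all",
    position_filter: str = "all",
    min_supine_min: float | None = None,
    supine_sleep_min: float | None = None,
) -> list[Window]:
    """Filter labelled windows by stage and position.

    stage_filter in {"all", "NREM"}; position_filter in {"all",
    "supine"}.  If min_supine_min is given together with the
    recording's supine sleep minutes, a recording with supine sleep
    <= min_supine_min is excluded wholesale (empty result).
    """
    if stage_filter not in ("all", "NREM"):
        raise ValueError(f"unknown stage_filter {stage_filter!r}")
    if position_filter not in ("all", "supine"):
        raise ValueError(f"unknown position_filter {position_filter!r}")
    if min_supine_min is not None and supine_sleep_min is not None \
            and supine_sleep_min <= min_supine_min:
        return []
    out = windows
    if stage_filter == "NREM":
        out = [w for w in out if w.majority_stage == "NREM"]
    if position_filter == "supine":
        out = [w for w in out if w.majority_position == "supine"]
    return out
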