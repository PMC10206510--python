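"""Chemoreflex loop math shared by the simulator and the estimator.

The ventilatory control loop is modelled as a first-order chemoreflex
with steady-state gain G, time constant tau and a pure circulatory delay
delta.  Chemical drive D (in % of eupneic ventilation) responds to past
ventilation V through

    tau * dD/dt = -D + E + G * (E - V(t - delta)),    E = 100 (eupnea)

so that holding V at eupnea settles D at eupnea, and a sustained
ventilation deficit raises drive in proportion to G.  On a fixed breath
clock of length Tb the dynamics discretise exactly to

    D_t = a * D_{t-1} + (1 - a) * (E + G * (E - V_{t-d})),
    a = exp(-Tb / tau),  d = delta / Tb breaths.

The loop's frequency response has magnitude

    LG(f) = G / sqrt(1 + (2 pi f tau)^2)

and total phase lag 2 pi f delta + arctan(2 pi f tau); the natural
frequency is where that lag reaches pi (180 degrees), the frequency at
which a disturbance can self-sustain.  LG1 is the gain at 1 cycle/min,
LGn the gain at the natural frequency.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

EUPNEA = 100.0
F_ONE_PER_MIN = 1.0 / 60.0


def lg_magnitude(g: float, tau_s: float, f: float) -> float:
    """Loop-gain magnitude G / sqrt(1 + (2 pi f tau)^2) at frequency f (Hz)."""
    return g / math.sqrt(1.0 + (2.0 * math.pi * f * tau_s) ** 2)


def g_from_lg1(lg1: float, tau_s: float) -> float:
    """Steady-state gain implied by a loop gain at 1 cycle/min."""
    return lg1 * math.sqrt(1.0 + (2.0 * math.pi * F_ONE_PER_MIN * tau_s) ** 2)


def natural_frequency(tau_s: float, delay_s: float) -> float:
    """Frequency (Hz) at which the loop phase lag reaches 180 degrees.

    Solves 2 pi f delta + arctan(2 pi f tau) = pi by bisection.  With a
    positive delay the equation always has a unique root below
    1/(2 delta).
    """
    if delay_s <= 0:
        raise ValueError("natural frequency undefined without a positive delay")

    def phase(f: float) -> float:
        w = 2.0 * math.pi * f
        return w * delay_s + math.atan(w * tau_s) - math.pi

    hi = 0.5 / delay_s
    return float(brentq(phase, 1e-6, hi, xtol=1e-12))


def delayed_series(v: np.ndarray, delay_s: float, breath_s: float, pad: float = EUPNEA) -> np.ndarray:
    """Ventilation shifted by a (possibly fractional) delay in breath units.

    Fractional delays interpolate linearly between the two neighbouring
    integer shifts, so the map is continuous in delay_s (needed by the
    least-squares fit); an integer number of breaths reproduces a pure
    shift exactly.  The head of the series is padded with `pad`.
    """
    db = delay_s / breath_s
    d0 = int(math.floor(db))
    w = db - d0

    def shift(arr: np.ndarray, d: int) -> np.ndarray:
        if d <= 0:
            return arr.copy()
        out = np.empty_like(arr)
        out[:d] = pad
        out[d:] = arr[:-d]
        return out

    if w == 0.0:
        return shift(v, d0)
    return (1.0 - w) * shift(v, d0) + w * shift(v, d0 + 1)


def predict_drive(
    v: np.ndarray,
    g: float,
    tau_s: float,
    delay_s: float,
    breath_s: float,
    d0: float = EUPNEA,
    pad: float = EUPNEA,
) -> np.ndarray:
    """Chemical drive trace implied by a ventilation series.

    Runs the exact first-order discretisation on the breath clock with
    initial state d0 and delay padding `pad`.  Vectorised with an IIR
    filter; identical to the per-breath recursion.
    """
    a = math.exp(-breath_s / tau_s)
    u = EUPNEA + g * (EUPNEA - delayed_series(np.asarray(v, float), delay_s, breath_s, pad=pad))
    out, _ = lfilter([1.0 - a], [1.0, -a], u, zi=[a * d0])
    return out
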