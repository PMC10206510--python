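"""Floor/ceiling correction for upper-airway traits.

Ventilation at eupneic drive (Vpassive) and at the arousal threshold
(Vactive) are bounded percentages: values pile up near 0 (complete
collapse) and 100 (fully patent airway), which distorts difference-based
agreement statistics.  The correction maps the 0-100 scale through a
clamped logit and linearly rescales the result back onto (0, 100), so
that the transformed trait is unbounded-behaved in the interior while
remaining reportable on the familiar %-eupnea-like scale.  Muscle
compensation (Vcomp) is then defined as the difference of the two
transformed traits and may be negative.

Only Vactive and Vpassive are transformed; loop gains, arousal
threshold, VRA and Vmin are reported untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransformSpec", "logit_squash", "vcomp_transformed"]


@dataclass(frozen=True)
class TransformSpec:
    """Parameters of the bounded-logit correction.

    eps is the clamp applied to the fractional value x = V/100 before the
    logit; it bounds the transform and sets the slope of the linear
    back-map.  Alternative dialects of the correction (different clamps,
    steeper sigmoids) are obtained by changing eps.
    """

    eps: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.eps < 0.5:
            raise ValueError(f"eps must lie in (0, 0.5), got {self.eps}")


def logit_squash(v, spec: TransformSpec | None = None):
    """Apply the clamped-logit floor/ceiling correction to a %-eupnea value.

    x = clamp(v/100, eps, 1-eps); y = ln(x/(1-x)); the logit is then
    mapped affinely so that the output spans (0, 100) with fixpoint 50.
    Strictly increasing on [0, 100]; accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any input value is negative.
    """
    spec = spec or TransformSpec()
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ventilation must be non-negative")
    x = np.clip(arr / 100.0, spec.eps, 1.0 - spec.eps)
    y = np.log(x / (1.0 - x))
    lo = np.log(spec.eps / (1.0 - spec.eps))
    out = 100.0 * (y - lo) / (-2.0 * lo)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def inverse_logit_squash(t, spec: TransformSpec | None = None):
    """Invert :func:`logit_squash` back to the clamped %-eupnea value."""
    spec = spec or TransformSpec()
    arr = np.asarray(t, dtype=float)
    lo = np.log(spec.eps / (1.0 - spec.eps))
    y = arr / 100.0 * (-2.0 * lo) + lo
    x = 1.0 / (1.0 + np.exp(-y))
    out = 100.0 * x
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def vcomp_transformed(vactive_t: float, vpassive_t: float) -> float:
    """Muscle compensation on the transformed scale: Vactive_t - Vpassive_t.

    May be negative (upper-airway muscles can worsen ventilation as drive
    rises in some patients).
    """
    return vactive_t - vpassive_t
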