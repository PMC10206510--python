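"""Chemoreflex-model fit of one analysis window.

The latent ventilatory drive is inferred by running the first-order
delayed chemoreflex (see :mod:`endotrait.model`) over the observed
ventilation series and choosing the parameters (G, tau, delta) that make
the predicted drive agree with observed ventilation on the
drive-revealing breaths — breaths inside scored arousals plus one
following breath, where the airway is open and ventilation tracks drive
up to the ventilatory response to arousal.  That arousal overshoot is a
nuisance level on exactly those breaths, so it is profiled out in closed
form at each parameter evaluation; its fitted value is itself the
window's VRA estimate.

Each window is fitted by bounded least squares from three fixed starting
points (the problem is not convex; a deterministic multistart keeps runs
reproducible).  A burn-in stretch of preceding breaths initialises the
filter state and the delay line so the inferred drive does not depend on
an arbitrary initial condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import F_ONE_PER_MIN, lg_magnitude, natural_frequency, predict_drive

__all__ = ["WindowFit", "fit_drive_model", "DriveFitError"]

BOUNDS_LO = (1e-3, 5.0, 5.0)     # G, tau (s), delta (s)
BOUNDS_HI = (10.0, 120.0, 30.0)
MULTISTARTS = ((0.6, 15.0, 10.0), (1.5, 25.0, 15.0), (4.0, 45.0, 20.0))
MIN_FIT_BREATHS = 3
BURNIN_BREATHS = 30


class DriveFitError(RuntimeError):
    """Raised when a window cannot be fitted (too few breaths, no convergence)."""


@dataclass
class WindowFit:
    """Fitted chemoreflex parameters and inferred drive for one window."""

    g: float
    tau_s: float
    delay_s: float
    vra: float                  # profiled arousal overshoot (% eupnea)
    lg1: float
    lgn: float
    natural_frequency: float
    fit_rmse: float
    n_fit_breaths: int
    drive: np.ndarray           # % eupnea, aligned to the window's breaths


def refine_drive_fit(
    vent: np.ndarray,
    fit_idx: np.ndarray,
    breath_s: float,
    x0: tuple[float, float, float],
):
    """Single (G, tau, delta) fit over many drive-revealing breaths.

    Used to pool all arousal breaths of a recording (or stratum) into
    one well-conditioned problem: individual 7-min windows carry only a
    handful of arousal runs, which leaves the (G, tau) pair on a flat
    ridge of near-equivalent solutions; hundreds of breaths across
    heterogeneous cycles pin it down.  The arousal overshoot gamma is
    profiled out as in the window fit.  Returns (g, tau, delta, gamma).
    """
    vent = np.asarray(vent, float)
    fit_idx = np.asarray(fit_idx, int)
    v_fit = vent[fit_idx]

    def residuals(theta):
        g, tau, delta = theta
        d = predict_drive(vent, g, tau, delta, breath_s)
        resid = v_fit - d[fit_idx]
        return resid - max(0.0, float(np.mean(resid)))

    x0 = np.clip(x0, BOUNDS_LO, BOUNDS_HI)
    sol = least_squares(residuals, x0, bounds=(BOUNDS_LO, BOUNDS_HI),
                        x_scale=(1.0, 10.0, 5.0), method="trf")
    g, tau, delta = (float(x) for x in sol.x)
    d = predict_drive(vent, g, tau, delta, breath_s)
    gamma = max(0.0, float(np.mean(v_fit - d[fit_idx])))
    return g, tau, delta, gamma


def fit_drive_model(
    vent: np.ndarray,
    fit_idx: np.ndarray,
    breath_s: float,
    n_burnin: int = 0,
) -> WindowFit:
    """Fit (G, tau, delta) to one window's ventilation series.

    Parameters
    ----------
    vent
        Ventilation in % eupnea, burn-in breaths first, then the window.
    fit_idx
        Indices into `vent` of the drive-revealing (arousal) breaths;
        all must lie at or beyond n_burnin.
    breath_s
        Breath duration (s).
    n_burnin
        Leading breaths used only to settle the filter and delay line.

    Raises
    ------
    DriveFitError
        If fewer than 3 fit breaths are available or no start converges.
    """
    vent = np.asarray(vent, float)
    fit_idx = np.asarray(fit_idx, int)
    if fit_idx.size < MIN_FIT_BREATHS:
        raise DriveFitError(f"only {fit_idx.size} drive-revealing breaths (need >= {MIN_FIT_BREATHS})")
    v_fit = vent[fit_idx]

    def residuals(theta):
        g, tau, delta = theta
        d = predict_drive(vent, g, tau, delta, breath_s)
        resid = v_fit - d[fit_idx]
        gamma = max(0.0, float(np.mean(resid)))
        return resid - gamma

    best = None
    for x0 in MULTISTARTS:
        try:
            sol = least_squares(
                residuals, x0, bounds=(BOUNDS_LO, BOUNDS_HI),
                x_scale=(1.0, 10.0, 5.0), method="trf",
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise DriveFitError("optimizer failed to converge from all starts")

    g, tau, delta = (float(x) for x in best.x)
    drive_full = predict_drive(vent, g, tau, delta, breath_s)
    gamma = max(0.0, float(np.mean(v_fit - drive_full[fit_idx])))
    fn = natural_frequency(tau, delta)
    return WindowFit(
        g=g,
        tau_s=tau,
        delay_s=delta,
        vra=gamma,
        lg1=lg_magnitude(g, tau, F_ONE_PER_MIN),
        lgn=lg_magnitude(g, tau, fn),
        natural_frequency=fn,
        fit_rmse=math.sqrt(2.0 * best.cost / fit_idx.size),
        n_fit_breaths=int(fit_idx.size),
        drive=drive_full[n_burnin:],
    )
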