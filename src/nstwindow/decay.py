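"""First-order dissipation kinetics for tissue residue series.

The model is C(t) = C0 * exp(-k t), fit by Levenberg-Marquardt nonlinear
least squares on the raw (untransformed, background-unsubtracted)
concentrations.  Deterministic initialization: C0 starts at the maximum
observed concentration and k at the negated slope of a log-linear regression
on the positive concentrations, so the same data always give the same fit.

Derived quantities:

* half-life DT50 = ln 2 / k;
* the "flattening day" t* = -ln(f)/k — the day the instantaneous decay rate
  |dC/dt| = k C0 e^(-kt) has fallen to a fraction f of its initial value,
  an algorithmic stand-in for judging by eye where a decay curve levels off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayFit",
    "DecayFitError",
    "fit_first_order_decay",
    "r_squared",
    "flattening_day",
    "half_life",
    "predict",
]


class DecayFitError(ValueError):
    """Insufficient or degenerate data for a dissipation fit."""


@dataclass(frozen=True)
class DecayFit:
    """Fitted dissipation curve for one treatment x region x year series."""

    c0: float
    k: float
    r2: float
    n_points: int
    series: tuple = ()

    @property
    def half_life(self) -> float:
        return half_life(self.k)


def _model(t, c0, k):
    return c0 * np.exp(-k * t)


def predict(fit: DecayFit, dpp) -> np.ndarray:
    return _model(np.asarray(dpp, dtype=float), fit.c0, fit.k)


def _initial_guess(dpp: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    c0_init = float(conc.max())
    pos = conc > 0
    if pos.sum() >= 2 and np.unique(dpp[pos]).size >= 2:
        slope = np.polyfit(dpp[pos], np.log(conc[pos]), 1)[0]
        k_init = max(-slope, 1e-6)
    else:
        k_init = 1e-6
    return c0_init, k_init


def fit_first_order_decay(points, series: tuple = ()) -> DecayFit:
    """Fit C(t) = C0 e^(-kt) to (dpp, conc) pairs by nonlinear least squares.

    Parameters
    ----------
    points : iterable of (dpp, conc) pairs, or (n, 2) array-like
        Requires >= 3 points with >= 2 distinct dpp values and conc >= 0.
    series : tuple, optional
        Identifier (year, treatment, region) carried into the result and any
        error message.

    Returns
    -------
    DecayFit
        With r2 about the series mean.  An exactly-constant series yields
        k = 0, c0 = the constant, and r2 = 0.0 by convention (there is no
        variance to explain).
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DecayFitError(f"series {series}: expected (dpp, conc) pairs")
    dpp, conc = arr[:, 0], arr[:, 1]
    label = f"series {series}" if series else "series"
    if len(arr) < 3:
        raise DecayFitError(f"{label}: need >= 3 points, got {len(arr)}")
    if np.unique(dpp).size < 2:
        raise DecayFitError(f"{label}: need >= 2 distinct dpp values")
    if (conc < 0).any():
        raise DecayFitError(f"{label}: negative concentrations")

    if np.ptp(conc) == 0.0:
        # Constant series: exact fit at k=0; nothing for the model to explain.
        return DecayFit(c0=float(conc[0]), k=0.0, r2=0.0,
                        n_points=len(arr), series=tuple(series))

    p0 = _initial_guess(dpp, conc)
    try:
        popt, _ = curve_fit(_model, dpp, conc, p0=p0, method="lm", maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - LM rarely fails here
        raise DecayFitError(f"{label}: fit did not converge ({exc})") from exc
    c0_hat, k_hat = float(popt[0]), float(popt[1])
    fit = DecayFit(c0=c0_hat, k=k_hat, r2=math.nan,
                   n_points=len(arr), series=tuple(series))
    r2 = r_squared(arr, fit)
    return DecayFit(c0=c0_hat, k=k_hat, r2=r2,
                    n_points=len(arr), series=tuple(series))


def r_squared(points, fit: DecayFit) -> float:
    """Coefficient of determination 1 - SSres/SStot about the mean.

    May be negative when the decay curve fits worse than the series mean
    (typical for untreated plots, where only background is present).
    Raises on a zero-variance series, where R2 is undefined.
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if len(arr) < 2:
        raise DecayFitError("r_squared: need >= 2 points")
    y = arr[:, 1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DecayFitError("r_squared: zero total variance, R2 undefined")
    resid = y - _model(arr[:, 0], fit.c0, fit.k)
    return 1.0 - float(np.sum(resid ** 2)) / ss_tot


def flattening_day(fit: DecayFit | float, f: float) -> float:
    """Day the decay rate falls to fraction ``f`` of its initial value.

    |dC/dt| = k C0 e^(-kt), so the rate reaches f of its t=0 value at
    t* = -ln(f)/k.  Returns ``math.inf`` ("never flattens") when k <= 0.
    """
    k = fit.k if isinstance(fit, DecayFit) else float(fit)
    if not 0.0 < f < 1.0:
        raise ValueError("flattening fraction f must be in (0, 1)")
    if k <= 0.0:
        return math.inf
    return -math.log(f) / k


def half_life(k: float) -> float:
    """DT50 = ln 2 / k, in days."""
    if k <= 0.0:
        raise ValueError("half_life requires k > 0")
    return math.log(2.0) / k
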