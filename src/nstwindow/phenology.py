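"""Degree-day phenology, pest activity windows, and protection overlap.

Early-season maize pests are active in windows of days post planting (DPP):
the western corn rootworm's damaging larval stage starts when overwintered
eggs hatch (~27 DPP in the field observations these defaults encode), white
grub and wireworm attack is taken to end at 41 and 56 DPP respectively, and
seedcorn maggot egg hatch / larval development is driven by a degree-day
model from adult emergence (default May 1).

Degree-days are computed from daily min/max temperatures by either the
simple-average method or single-sine interpolation (Baskerville-Emin) with an
optional horizontal upper cutoff.  The overlap of a protection window
[0, end] with a pest activity window [start, end] gives the days of expected
benefit and the unprotected remainder of the pest's season.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .windows import ProtectionWindow

__all__ = [
    "PestActivity",
    "DegreeDayModel",
    "daily_degree_days",
    "accumulate_to_event",
    "overlap_days",
    "PEST_PRESETS",
]


@dataclass(frozen=True)
class PestActivity:
    """Activity window of one pest on the DPP axis."""

    pest: str
    start_dpp: float
    end_dpp: float
    source: str = "configured"  # observed | degree_day_model | configured

    def __post_init__(self):
        if self.start_dpp > self.end_dpp:
            raise ValueError("start_dpp must be <= end_dpp")

    @property
    def length(self) -> float:
        return self.end_dpp - self.start_dpp


#: Named activity presets (DPP axis, planting = 0).  WCR onset from direct
#: field scouting of neonate larvae; white grub / wireworm end dates from
#: regional extension calendars (June 15 / June 30 for an early-May planting);
#: WCR end is a nominal late-season bound. Seedcorn maggot is modelled, not
#: preset.
PEST_PRESETS: dict[str, PestActivity] = {
    "western_corn_rootworm": PestActivity("western_corn_rootworm", 27.0, 85.0,
                                          "observed"),
    "white_grub": PestActivity("white_grub", 0.0, 41.0, "configured"),
    "wireworm": PestActivity("wireworm", 0.0, 56.0, "configured"),
}


@dataclass(frozen=True)
class DegreeDayModel:
    """Thermal-accumulation model: base/cutoff temperatures and a threshold
    of degree-days to the event of interest (e.g. egg hatch)."""

    base: float
    threshold: float
    cutoff: float | None = None
    method: str = "simple_average"  # or "single_sine"

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.cutoff is not None and self.cutoff <= self.base:
            raise ValueError("cutoff must exceed base")
        if self.method not in ("simple_average", "single_sine"):
            raise ValueError(f"unknown method {self.method!r}")


def _sine_area_above(tmin: float, tmax: float, threshold: float) -> float:
    """Degree-days above ``threshold`` for a day whose temperature traces one
    sine cycle between tmin and tmax."""
    m = (tmax + tmin) / 2.0
    a = (tmax - tmin) / 2.0
    if threshold >= tmax:
        return 0.0
    if threshold <= tmin:
        return m - threshold
    theta = math.asin((threshold - m) / a)
    return ((m - threshold) * (math.pi / 2.0 - theta)
            + a * math.cos(theta)) / math.pi


def daily_degree_days(tmin: float, tmax: float, model: DegreeDayModel) -> float:
    """Degree-days contributed by one day under the model.

    simple_average: max(0, (tmin+tmax)/2 - base), capped at cutoff - base.
    single_sine: area of the day's sine curve above base, with heat above the
    horizontal cutoff excluded.
    """
    if tmin > tmax:
        raise ValueError("tmin must be <= tmax")
    if model.method == "simple_average":
        dd = max(0.0, (tmin + tmax) / 2.0 - model.base)
        if model.cutoff is not None:
            dd = min(dd, model.cutoff - model.base)
        return dd
    dd = _sine_area_above(tmin, tmax, model.base)
    if model.cutoff is not None:
        dd -= _sine_area_above(tmin, tmax, model.cutoff)
    return dd


def accumulate_to_event(
    weather: pd.DataFrame,
    model: DegreeDayModel,
    start_date: str | date,
    planting_date: str | date | None = None,
):
    """First date cumulative degree-days from ``start_date`` reach the model
    threshold.

    Returns ``(event_date, dpp)``; ``dpp`` is None without a planting date,
    and the whole result is ``(None, None)`` if the horizon ends first.
    The weather series must cover consecutive days from ``start_date``.
    """
    if isinstance(start_date, str):
        start_date = date.fromisoformat(start_date)
    if isinstance(planting_date, str):
        planting_date = date.fromisoformat(planting_date)
    dates = pd.to_datetime(weather["date"]).dt.date.to_numpy()
    keep = dates >= start_date
    dates, sub = dates[keep], weather.loc[keep]
    if len(dates) == 0:
        raise ValueError("weather series does not cover start_date")
    gaps = np.diff([d.toordinal() for d in dates])
    if (gaps != 1).any():
        raise ValueError("weather series has gaps after start_date")
    cum = 0.0
    for d, tmin, tmax in zip(dates, sub["tmin"], sub["tmax"]):
        cum += daily_degree_days(float(tmin), float(tmax), model)
        if cum >= model.threshold:
            dpp = (d - planting_date).days if planting_date else None
            return d, dpp
    return None, None


def overlap_days(
    protection: ProtectionWindow, activity: PestActivity
) -> tuple[float, float]:
    """Days of pest activity covered by protection, and the unprotected tail.

    Protection spans [0, end_dpp] (the seed is protected from sowing).
    Overlap = |[0, protection.end] ∩ [activity.start, activity.end]|;
    remainder = activity days after protection ends.
    """
    p_end = protection.end_dpp
    lo = max(0.0, activity.start_dpp)
    hi = min(p_end, activity.end_dpp)
    overlap = max(0.0, hi - lo)
    remainder = max(0.0, activity.end_dpp - max(p_end, activity.start_dpp))
    return overlap, remainder
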