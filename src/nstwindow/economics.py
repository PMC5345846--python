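"""Economic-injury-level (EIL) and leaching-risk (GUS) calculations.

The EIL is the pest-injury level at which the value of the yield it destroys
equals the cost of controlling it:

    EIL = C / (V * b * K)

with C the management cost ($/ha), V the commodity value ($/100 kg), b the
yield loss per unit injury (100 kg/ha per unit of the 0-3 node-injury scale),
and K the proportionate reduction in injury the control tactic achieves.
Injury here is the node-injury root-damage score, so the EIL is a minimum
root rating at which a seed treatment pays for itself, and its inverse,
``break_even_cost``, is the highest treatment cost justified by an observed
rating.

The yield-loss coefficient b for moderate environmental stress is not carried
around as a magic number: the product V*b is calibrated from a known
(EIL, cost) anchor point via ``calibrate_vb`` (the EIL is linear in C, so one
anchor fixes the whole line) and rescales proportionally with V.

K can be estimated from damage in untreated vs treated plots two ways:
``"ratio"`` (treated/untreated — the arithmetic some published estimates
use) and ``"pedigo"`` (1 - treated/untreated — K's textbook definition as
the proportionate *reduction*).  The two always sum to 1; the mode travels
with the number so the discrepancy stays visible.

The Groundwater Ubiquity Score GUS = log10(DT50) * (4 - log10(Koc)) indexes
leaching potential from soil persistence (DT50, days) and sorption (Koc,
mL/g): > 2.8 high, 1.8-2.8 medium, < 1.8 low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EILInputs",
    "EILResult",
    "GusInputs",
    "compute_eil",
    "calibrate_vb",
    "rescale_vb",
    "break_even_cost",
    "estimate_K",
    "compute_gus",
    "gus_class",
    "eil_scenario_table",
]


@dataclass(frozen=True)
class EILInputs:
    """Inputs of one EIL evaluation; ``vb`` is the product V*b in $/ha per
    unit node-injury."""

    control_cost: float  # C, $/ha
    vb: float            # V*b, $/ha per node-injury unit
    efficacy: float = 1.0  # K in (0, 1]

    def __post_init__(self):
        if self.control_cost < 0:
            raise ValueError("control_cost must be >= 0")
        if self.vb <= 0:
            raise ValueError("vb (V*b) must be > 0")
        if not 0.0 < self.efficacy <= 1.0:
            raise ValueError("efficacy K must be in (0, 1]")


@dataclass(frozen=True)
class EILResult:
    eil: float           # node-injury units
    inputs: EILInputs


@dataclass(frozen=True)
class GusInputs:
    dt50: float  # days
    koc: float   # mL/g

    def __post_init__(self):
        if self.dt50 <= 0:
            raise ValueError("dt50 must be > 0")
        if self.koc <= 0:
            raise ValueError("koc must be > 0")


def compute_eil(inputs: EILInputs) -> EILResult:
    """Minimum node-injury score at which control cost is recovered."""
    return EILResult(
        eil=inputs.control_cost / (inputs.vb * inputs.efficacy), inputs=inputs
    )


def calibrate_vb(anchor_eil: float, anchor_cost: float, efficacy: float = 1.0) -> float:
    """Recover V*b ($/ha per node-injury unit) from one (EIL, cost) anchor.

    Inverts EIL = C/(V*b*K):  V*b = C / (EIL * K).  b alone follows as
    vb / V for a given commodity value.
    """
    if anchor_eil <= 0:
        raise ValueError("anchor_eil must be > 0")
    if anchor_cost <= 0:
        raise ValueError("anchor_cost must be > 0")
    if not 0.0 < efficacy <= 1.0:
        raise ValueError("efficacy K must be in (0, 1]")
    return anchor_cost / (anchor_eil * efficacy)


def rescale_vb(vb: float, v_old: float, v_new: float) -> float:
    """Rescale the V*b product to a different commodity value, b held fixed."""
    if v_old <= 0 or v_new <= 0:
        raise ValueError("commodity values must be > 0")
    return vb * v_new / v_old


def break_even_cost(rating: float, vb: float, efficacy: float = 1.0) -> float:
    """Control cost at which the EIL equals an observed node-injury rating.

    C* = rating * V*b * K — spend more than this and the damage observed
    cannot pay for the treatment.
    """
    if rating < 0:
        raise ValueError("rating must be >= 0")
    if vb <= 0:
        raise ValueError("vb must be > 0")
    if not 0.0 < efficacy <= 1.0:
        raise ValueError("efficacy K must be in (0, 1]")
    return rating * vb * efficacy


def estimate_K(
    untreated_mean_rating: float,
    treated_mean_rating: float,
    mode: str = "ratio",
) -> tuple[float, str]:
    """Efficacy coefficient from untreated vs treated mean injury.

    ``"ratio"``: treated/untreated.  ``"pedigo"``: 1 - treated/untreated
    (proportionate reduction, K's definitional form).  Returns (K, mode) so
    downstream tables record which arithmetic produced the number.
    """
    if untreated_mean_rating <= 0:
        raise ValueError("untreated_mean_rating must be > 0")
    if treated_mean_rating < 0:
        raise ValueError("treated_mean_rating must be >= 0")
    ratio = treated_mean_rating / untreated_mean_rating
    if mode == "ratio":
        return ratio, mode
    if mode == "pedigo":
        return 1.0 - ratio, mode
    raise ValueError(f"unknown mode {mode!r}; use 'ratio' or 'pedigo'")


def compute_gus(inputs: GusInputs) -> tuple[float, str]:
    """Groundwater Ubiquity Score and its leaching class."""
    score = math.log10(inputs.dt50) * (4.0 - math.log10(inputs.koc))
    return score, gus_class(score)


def gus_class(score: float) -> str:
    if score > 2.8:
        return "high"
    if score >= 1.8:
        return "medium"
    return "low"


def eil_scenario_table(
    control_costs,
    vb_by_value: dict[float, float],
    efficacies=(1.0,),
) -> pd.DataFrame:
    """EIL grid over control costs x commodity values x efficacies.

    ``vb_by_value`` maps a commodity value V ($/100 kg) to its V*b product.
    """
    rows = []
    for v, vb in vb_by_value.items():
        for k in efficacies:
            for c in np.atleast_1d(control_costs):
                res = compute_eil(EILInputs(float(c), vb, float(k)))
                rows.append({
                    "control_cost": float(c),
                    "commodity_value": float(v),
                    "vb": vb,
                    "efficacy": float(k),
                    "eil": res.eil,
                })
    return pd.DataFrame(rows)
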