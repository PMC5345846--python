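"""Percent-of-applied-AI accounting per plant region and whole plant.

A treated kernel carries ``dose`` mg of active ingredient.  A region that
measures ``conc`` ug/g across ``region_mass`` g of fresh tissue has recovered
``conc * region_mass`` ug of the ``dose * 1000`` ug applied, i.e.

    pct_of_dose = 100 * conc * region_mass / (dose * 1000).

Subsampled homogenates (only <= 1 g of a large region is extracted) are
handled upstream by carrying the *total* region mass on the record, so the
product scales the concentration back to the whole region.

Completeness gating mirrors field scoring: a region recovered > threshold
(default 80%) of intact is "complete"; a plant whose root and shoot are both
complete is a "total sample", and only total samples contribute whole-plant
percentages (root + shoot; the seed region is the reservoir the AI departs
from, so its remaining fraction is reported separately, never counted as
"translocated").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_translocated",
    "completeness_gate",
    "whole_plant_percent",
    "translocation_summary",
]


def percent_translocated(conc, region_mass, dose_mg: float):
    """Percent of the per-kernel applied AI recovered in one region.

    ``conc`` in ug/g, ``region_mass`` in g, ``dose_mg`` in mg AI/kernel.
    Undefined for untreated seed (dose 0).
    """
    if dose_mg <= 0:
        raise ValueError("percent_translocated undefined for dose <= 0 (untreated)")
    conc = np.asarray(conc, dtype=float)
    mass = np.asarray(region_mass, dtype=float)
    if (conc < 0).any() or (mass < 0).any():
        raise ValueError("conc and region_mass must be >= 0")
    out = 100.0 * conc * mass / (dose_mg * 1000.0)
    return float(out) if out.ndim == 0 else out


def completeness_gate(
    records: pd.DataFrame,
    threshold: float = 0.80,
    doses: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Flag complete regions and total-sample plants; compute pct_of_dose.

    Expects residue-style rows (year, dpp, treatment, block, region, plant,
    conc, region_mass, completeness).  Adds:

    * ``complete`` — completeness strictly greater than ``threshold``
      (exactly 80% recovered counts as incomplete);
    * ``pct_of_dose`` — NaN for zero-dose treatments;
    * ``total_sample`` — root and shoot of the same plant both complete.
    """
    out = records.copy()
    out["complete"] = out["completeness"] > threshold
    if doses is not None:
        dose = out["treatment"].map(doses).astype(float)
    elif "dose" in out.columns:
        dose = out["dose"].astype(float)
    else:
        raise ValueError("need a doses mapping or a dose column")
    treated = dose > 0
    out["pct_of_dose"] = np.nan
    out.loc[treated, "pct_of_dose"] = (
        100.0 * out.loc[treated, "conc"] * out.loc[treated, "region_mass"]
        / (dose[treated] * 1000.0)
    )

    plant_key = ["year", "dpp", "treatment", "block", "plant"]
    rs = out[out["region"].isin(["root", "shoot"])]
    both_complete = (
        rs.groupby(plant_key, observed=True)["complete"]
        .agg(lambda s: bool(s.all()) and len(s) == 2)
        .rename("total_sample")
    )
    out = out.merge(both_complete.reset_index(), on=plant_key, how="left")
    out["total_sample"] = out["total_sample"].fillna(False).astype(bool)
    return out


def whole_plant_percent(gated: pd.DataFrame) -> pd.DataFrame:
    """Per-plant whole-plant percent (root + shoot) for total samples only."""
    rs = gated[
        gated["total_sample"]
        & gated["region"].isin(["root", "shoot"])
        & gated["pct_of_dose"].notna()
    ]
    plant_key = ["year", "dpp", "treatment", "block", "plant"]
    whole = (
        rs.groupby(plant_key, observed=True)["pct_of_dose"]
        .sum()
        .rename("pct_whole_plant")
        .reset_index()
    )
    return whole


def translocation_summary(gated: pd.DataFrame) -> pd.DataFrame:
    """Mean and max percent-of-dose per year x treatment x region (complete
    samples only), plus a ``whole_plant`` row per year x treatment from total
    samples.  Seed rows report the fraction still on/in the seed."""
    treated = gated[gated["pct_of_dose"].notna() & gated["complete"]]
    per_region = (
        treated.groupby(["year", "treatment", "region"], observed=True)["pct_of_dose"]
        .agg(["mean", "max", "count"])
        .reset_index()
        .rename(columns={"mean": "pct_mean", "max": "pct_max", "count": "n"})
    )
    whole = whole_plant_percent(gated)
    if len(whole):
        wp = (
            whole.groupby(["year", "treatment"], observed=True)["pct_whole_plant"]
            .agg(["mean", "max", "count"])
            .reset_index()
            .rename(columns={"mean": "pct_mean", "max": "pct_max", "count": "n"})
        )
        wp["region"] = "whole_plant"
        per_region = pd.concat([per_region, wp], ignore_index=True)
    return per_region.sort_values(["year", "treatment", "region"]).reset_index(
        drop=True
    )
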