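"""End-to-end pipeline: simulate/load -> LOD policy -> decay fits ->
contrasts -> protection windows -> translocation -> phenology -> economics.

:func:`run_pipeline` sequences every analysis stage, writes each stage's
table as CSV under an output directory, and returns the tables plus a
provenance block (config hash, seed, versions) as a :class:`PipelineReport`.
Runs are deterministic for a fixed configuration and seed.  Stages whose
inputs are absent (e.g. phenology without weather) are marked skipped, not
silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, SimConfig
from .decay import DecayFitError, fit_first_order_decay, flattening_day
from .economics import (
    EILInputs,
    break_even_cost,
    calibrate_vb,
    compute_eil,
    compute_gus,
    estimate_K,
    eil_scenario_table,
    rescale_vb,
    GusInputs,
)
from .phenology import PEST_PRESETS, DegreeDayModel, accumulate_to_event, overlap_days
from .simulate import simulate_ratings_stand_yield, simulate_residues, simulate_weather
from .translocation import completeness_gate, translocation_summary
from .trial_io import apply_lod_policy, write_residues
from .windows import (
    ProtectionWindow,
    contrast_table,
    convergence_date,
    ContrastResult,
    rcb_anova,
    reconcile_years,
    tukey_hsd,
)

log = logging.getLogger("nstwindow")

__all__ = ["PipelineReport", "run_pipeline"]

#: Anchor used to calibrate V*b when none is supplied: minimum economically
#: damaging node-injury 0.245 at a control cost of $17.5/ha with K = 1, at a
#: commodity value of $14.96/100 kg.
DEFAULT_ECON_ANCHOR = {"eil": 0.245, "cost": 17.5, "value": 14.96}


@dataclass
class PipelineReport:
    """All stage outputs of one pipeline run."""

    decay_fits: pd.DataFrame
    contrasts: pd.DataFrame
    windows: pd.DataFrame
    trial_summary: pd.DataFrame
    translocation: pd.DataFrame
    phenology: pd.DataFrame | None
    economics: pd.DataFrame
    provenance: dict
    skipped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def section_names(self):
        return ["decay_fits", "contrasts", "windows", "trial_summary",
                "translocation", "phenology", "economics"]


def _config_hash(sim: SimConfig, analysis: AnalysisConfig) -> str:
    payload = json.dumps(
        {"sim": sim.to_dict(), "analysis": analysis.to_dict()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _date_means(residues: pd.DataFrame) -> pd.DataFrame:
    return (
        residues.groupby(["year", "treatment", "region", "dpp"], observed=True)["conc"]
        .mean()
        .reset_index()
    )


def decay_fit_table(
    residues: pd.DataFrame, flatten_frac: float, per_plant: bool = False
) -> pd.DataFrame:
    """Fit the dissipation curve per year x treatment x region.

    Fits use date means across plots by default (one curve per series, the
    replicate-pooled view); ``per_plant=True`` fits the plant-level cloud
    instead.
    """
    data = residues if per_plant else _date_means(residues)
    rows = []
    for (year, treatment, region), sub in data.groupby(
        ["year", "treatment", "region"], observed=True
    ):
        pts = sub[["dpp", "conc"]].to_numpy(dtype=float)
        series = (year, treatment, region)
        try:
            fit = fit_first_order_decay(pts, series=series)
        except DecayFitError as exc:
            log.warning("decay fit skipped: %s", exc)
            continue
        t_flat = flattening_day(fit, flatten_frac) if fit.k > 0 else math.inf
        rows.append({
            "year": year, "treatment": treatment, "region": region,
            "c0": fit.c0, "k": fit.k, "r2": fit.r2, "n_points": fit.n_points,
            "flattening_dpp": t_flat,
            "half_life": math.log(2) / fit.k if fit.k > 0 else math.inf,
        })
    return pd.DataFrame(rows)


def protection_windows(
    decay_fits: pd.DataFrame,
    contrasts: pd.DataFrame,
    alpha: float,
    treated: tuple[str, ...] = ("low", "high"),
) -> pd.DataFrame:
    """Both window estimates per region x treatment, reconciled across years."""
    rows = []
    for treatment in treated:
        for region in sorted(decay_fits["region"].unique()):
            # decay-flattening method
            sub = decay_fits[
                (decay_fits["treatment"] == treatment)
                & (decay_fits["region"] == region)
            ]
            per_year = {
                str(y): float(t) for y, t in zip(sub["year"], sub["flattening_dpp"])
                if np.isfinite(t)
            }
            if per_year:
                rows.append({
                    "region": region, "treatment": treatment,
                    "method": "decay_flattening",
                    "end_dpp": reconcile_years(per_year.values()),
                    "per_year": json.dumps(per_year),
                })
            # contrast-convergence method
            label = f"untreated_vs_{treatment}"
            csub = contrasts[
                (contrasts["contrast"] == label) & (contrasts["region"] == region)
            ]
            per_year_c: dict[str, float] = {}
            for year, ysub in csub.groupby("year", observed=True):
                series = [
                    ContrastResult(int(r.dpp), label, r.estimate, r.F, 1,
                                   int(r.df2), r.p)
                    for r in ysub.itertuples()
                ]
                d = convergence_date(series, alpha=alpha)
                if d is not None:
                    per_year_c[str(year)] = float(d)
            if per_year_c:
                rows.append({
                    "region": region, "treatment": treatment,
                    "method": "contrast_convergence",
                    "end_dpp": reconcile_years(per_year_c.values()),
                    "per_year": json.dumps(per_year_c),
                })
    return pd.DataFrame(rows)


def trial_summary_table(
    ratings: pd.DataFrame, stand: pd.DataFrame, yields: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-year treatment means with SE and Tukey HSD letters for yield,
    stand, and root ratings."""
    tables = {
        "rating": ratings.rename(columns={"rating": "value"}),
        "plants_per_ha": stand.rename(columns={"plants_per_ha": "value"}),
        "yield_kg_ha": yields.rename(columns={"yield_kg_ha": "value"}),
    }
    rows = []
    for varname, df in tables.items():
        for year, sub in df.groupby("year", observed=True):
            res = rcb_anova(sub, value="value")
            means = sub.groupby("treatment", observed=True)["value"].mean()
            ses = sub.groupby("treatment", observed=True)["value"].sem()
            n_b = sub["block"].nunique()
            letters = tukey_hsd(
                means.to_dict(), res.mse, res.df_error, n_b, alpha=alpha
            ).set_index("group")["letters"]
            for trt in means.index:
                rows.append({
                    "year": year, "variable": varname, "treatment": trt,
                    "mean": means[trt], "se": ses[trt], "n": n_b,
                    "letters": letters[trt],
                    "f_treatment": res.f_treatment, "p_treatment": res.p_treatment,
                })
    return pd.DataFrame(rows)


def economics_table(
    ratings: pd.DataFrame,
    anchor: dict = DEFAULT_ECON_ANCHOR,
    values=(14.96, 28.46),
    control_costs=(17.5, 27.0, 32.5, 55.0),
    gus_compounds: dict | None = None,
) -> pd.DataFrame:
    """Scenario table: EIL grid, per-treatment break-even costs from observed
    ratings, K estimates, and GUS scores, in one long table."""
    vb0 = calibrate_vb(anchor["eil"], anchor["cost"], efficacy=1.0)
    vb_by_value = {v: rescale_vb(vb0, anchor["value"], v) for v in values}
    rows = []
    grid = eil_scenario_table(control_costs, vb_by_value)
    for r in grid.itertuples():
        rows.append({
            "kind": "eil", "year": "", "treatment": "",
            "commodity_value": r.commodity_value, "control_cost": r.control_cost,
            "quantity": "eil_node_injury", "value": r.eil,
        })
    # Break-even cost of each treatment's observed mean rating.
    mean_ratings = ratings.groupby(["year", "treatment"], observed=True)["rating"].mean()
    for (year, trt), rating in mean_ratings.items():
        for v, vb in vb_by_value.items():
            rows.append({
                "kind": "break_even", "year": str(year), "treatment": trt,
                "commodity_value": v, "control_cost": np.nan,
                "quantity": "break_even_cost_usd_ha",
                "value": break_even_cost(rating, vb),
            })
    # Efficacy estimates: untreated (naked+fungicide pooled) vs each treated.
    for year, sub in ratings.groupby("year", observed=True):
        m = sub.groupby("treatment", observed=True)["rating"].mean()
        untr = [t for t in ("naked", "fungicide") if t in m.index]
        if not untr:
            continue
        untreated = float(m[untr].mean())
        if untreated <= 0:
            continue
        for trt in ("low", "high"):
            if trt not in m.index:
                continue
            for mode in ("ratio", "pedigo"):
                k, _ = estimate_K(untreated, float(m[trt]), mode=mode)
                rows.append({
                    "kind": "efficacy", "year": str(year), "treatment": trt,
                    "commodity_value": np.nan, "control_cost": np.nan,
                    "quantity": f"K_{mode}", "value": k,
                })
    compounds = gus_compounds or {
        "clothianidin_dt50_277": GusInputs(277.0, 60.0),
        "clothianidin_dt50_1386": GusInputs(1386.0, 60.0),
        "thiamethoxam_dt50_7.1": GusInputs(7.1, 68.4),
        "thiamethoxam_dt50_92.3": GusInputs(92.3, 68.4),
    }
    for name, gi in compounds.items():
        score, klass = compute_gus(gi)
        rows.append({
            "kind": "gus", "year": "", "treatment": name,
            "commodity_value": np.nan, "control_cost": np.nan,
            "quantity": f"gus_{klass}", "value": score,
        })
    return pd.DataFrame(rows)


def phenology_table(
    windows: pd.DataFrame,
    weather: pd.DataFrame | None,
    planting_date: str = "2015-05-05",
    maggot_model: DegreeDayModel | None = None,
    emergence_date: str = "2015-05-01",
) -> pd.DataFrame:
    """Overlap of every protection window with every pest activity window."""
    activities = dict(PEST_PRESETS)
    if weather is not None:
        # Seedcorn maggot: degree-days from adult emergence (May 1) to the end
        # of the damaging larval stage.  Model constants are assumed defaults.
        model = maggot_model or DegreeDayModel(base=3.9, threshold=360.0,
                                               method="simple_average")
        event, dpp = accumulate_to_event(
            weather, model, emergence_date, planting_date
        )
        if event is not None:
            from .phenology import PestActivity

            activities["seedcorn_maggot"] = PestActivity(
                "seedcorn_maggot", 0.0, float(max(dpp, 0)), "degree_day_model"
            )
    rows = []
    for w in windows.itertuples():
        pw = ProtectionWindow(w.region, w.treatment, float(w.end_dpp), w.method)
        for pest, act in activities.items():
            ov, rem = overlap_days(pw, act)
            rows.append({
                "region": w.region, "treatment": w.treatment, "method": w.method,
                "protection_end_dpp": pw.end_dpp, "pest": pest,
                "activity_start": act.start_dpp, "activity_end": act.end_dpp,
                "activity_source": act.source,
                "overlap_days": ov, "unprotected_days": rem,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    sim_config: SimConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
    residues: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    stand: pd.DataFrame | None = None,
    yields: pd.DataFrame | None = None,
    weather: pd.DataFrame | None = None,
) -> PipelineReport:
    """Run the full analysis; simulate any table not supplied.

    ``seed`` overrides ``sim_config.rng_seed``.  When ``outdir`` is given,
    every stage table is written there as CSV alongside a provenance JSON.
    """
    sim = sim_config or SimConfig()
    if seed is not None:
        sim = SimConfig(**{**sim.to_dict(), "rng_seed": int(seed)})
        sim.treatments = tuple((n, d) for n, d in sim.treatments)
    ana = analysis_config or AnalysisConfig()
    skipped: list[str] = []
    warnings: list[str] = []

    if residues is None:
        log.info("simulating residue trial (seed=%s)", sim.rng_seed)
        residues, truth = simulate_residues(sim)
    if ratings is None or stand is None or yields is None:
        r, s, y, _ = simulate_ratings_stand_yield(sim)
        ratings = ratings if ratings is not None else r
        stand = stand if stand is not None else s
        yields = yields if yields is not None else y
    log.info("residue samples: %d rows", len(residues))

    residues_sub = apply_lod_policy(residues, ana)
    log.info("below-LOD records handled (%s): %d flagged",
             ana.lod_policy, int(residues["below_lod"].sum()))

    fits = decay_fit_table(residues_sub, ana.flattening_fraction)
    log.info("decay fits: %d series", len(fits))
    contrasts = contrast_table(residues_sub, alpha=ana.alpha)
    log.info("planned contrasts: %d rows", len(contrasts))
    windows = protection_windows(fits, contrasts, alpha=ana.alpha)
    summary = trial_summary_table(ratings, stand, yields, alpha=ana.alpha)
    gated = completeness_gate(residues_sub, ana.completeness_threshold,
                              doses=dict(ana.doses))
    trans = translocation_summary(gated)

    if weather is None:
        weather = simulate_weather("2015-04-01", 120, rng_seed=sim.rng_seed)
    if weather is not None and len(windows):
        phen = phenology_table(windows, weather)
    else:
        phen = None
        skipped.append("phenology")
        warnings.append("phenology skipped: no weather or no windows")

    econ = economics_table(ratings)

    provenance = {
        "package_version": __version__,
        "seed": sim.rng_seed,
        "config_hash": _config_hash(sim, ana),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    report = PipelineReport(
        decay_fits=fits, contrasts=contrasts, windows=windows,
        trial_summary=summary, translocation=trans, phenology=phen,
        economics=econ, provenance=provenance,
        skipped=skipped, warnings=warnings,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_residues(residues, outdir / "residues.csv")
        for name in report.section_names():
            table = getattr(report, name)
            if table is not None:
                table.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump({**provenance, "skipped": skipped, "warnings": warnings},
                      fh, indent=1)
    return report
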