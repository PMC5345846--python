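"""Synthetic maize seed-treatment field trial with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that parameter-recovery and type-I-error behaviour can be tested
against a known answer:

* tissue residue concentration decays first-order from a dose-proportional
  initial value on top of a nonzero ambient background present in *all* plots
  (untreated plots in real fields are never neonicotinoid-free — lateral
  subsurface movement and carry-over guarantee cross-contamination);
* measurement/plant noise is multiplicative lognormal (concentrations are
  positive and right-skewed, which is also why the analysis log-transforms);
* blocks act as shared multiplicative effects (randomized complete block);
* region fresh mass follows a monotone logistic growth curve, and the seed
  region is only recoverable early in the season;
* 0-3 node-injury root ratings are reduced in insecticide-treated plots by a
  fractional efficacy; stand and yield are Gaussian with block effects.

The weather generator produces a smooth seasonal min/max temperature series
for the degree-day phenology module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "GroundTruth",
    "simulate_residues",
    "simulate_ratings_stand_yield",
    "simulate_weather",
    "logistic_mass",
]

RESIDUE_COLUMNS = [
    "year", "dpp", "treatment", "block", "region", "plant",
    "conc", "region_mass", "completeness", "below_lod",
]


@dataclass
class GroundTruth:
    """True parameters behind a simulated dataset, keyed for recovery tests."""

    #: (year, treatment, region) -> true initial concentration C0 (ug/g),
    #: excluding background.
    c0: dict = field(default_factory=dict)
    #: region -> true decay rate k (day^-1).
    k: dict = field(default_factory=dict)
    #: ambient concentration (ug/g) common to all plots.
    background: float = 0.0
    #: treatment -> true mean node-injury rating.
    mean_rating: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "c0": {"|".join(k): v for k, v in self.c0.items()},
            "k": dict(self.k),
            "background": self.background,
            "mean_rating": dict(self.mean_rating),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            c0={tuple(k.split("|")): v for k, v in d["c0"].items()},
            k=dict(d["k"]),
            background=float(d["background"]),
            mean_rating=dict(d["mean_rating"]),
        )


def logistic_mass(dpp, params) -> np.ndarray:
    """Monotone logistic fresh-mass curve m(t) = max / (1 + exp(-r (t - t0)))."""
    m_max, t0, rate = params
    t = np.asarray(dpp, dtype=float)
    return m_max / (1.0 + np.exp(-rate * (t - t0)))


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with E[X]=1 and the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_residues(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long-format residue table and its ground truth.

    Each sample's expected concentration is ``background + C0 * exp(-k * dpp)``
    with ``C0 = dose * c0_per_dose_unit[region]``.  Noise is mean-one
    multiplicative lognormal at ``noise_cv``; a mean-one lognormal block
    multiplier at ``block_sd`` is shared by every sample in a (year, block).
    The seed region is emitted only for ``dpp <= seed_cutoff_dpp``.  Samples
    whose realized concentration falls below ``config.lod`` are flagged
    ``below_lod`` (concentration retained — substitution is the analysis's
    job, not the field's).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    truth = GroundTruth(
        k=dict(config.k_per_region),
        background=config.background_conc,
    )

    blocks = [f"b{i + 1}" for i in range(config.n_blocks)]
    rows: list[dict] = []
    for year in config.years:
        block_mult = dict(
            zip(blocks, _mean_one_lognormal(rng, config.block_sd, config.n_blocks))
        )
        for treatment, dose in config.treatments:
            for region in config.regions:
                c0 = dose * config.c0_per_dose_unit[region]
                truth.c0[(str(year), treatment, region)] = c0
        for dpp in config.sampling_dpp[year]:
            regions_here = [
                r for r in config.regions
                if r != "seed" or dpp <= config.seed_cutoff_dpp
            ]
            for treatment, dose in config.treatments:
                for block in blocks:
                    n = config.plants_per_plot_per_date
                    for region in regions_here:
                        k = config.k_per_region[region]
                        c0 = dose * config.c0_per_dose_unit[region]
                        expected = config.background_conc + c0 * np.exp(-k * dpp)
                        noise = _mean_one_lognormal(rng, config.noise_cv, n)
                        conc = expected * block_mult[block] * noise
                        mass = float(logistic_mass(dpp, config.mass_growth[region]))
                        if config.incomplete_prob > 0:
                            incomplete = rng.random(n) < config.incomplete_prob
                            completeness = np.where(
                                incomplete, rng.uniform(0.3, 0.8, n), 1.0
                            )
                        else:
                            completeness = np.ones(n)
                        for p in range(n):
                            rows.append({
                                "year": str(year),
                                "dpp": int(dpp),
                                "treatment": treatment,
                                "block": block,
                                "region": region,
                                "plant": p + 1,
                                "conc": float(conc[p]),
                                "region_mass": mass * float(completeness[p]),
                                "completeness": float(completeness[p]),
                                "below_lod": bool(conc[p] < config.lod),
                            })
    df = pd.DataFrame(rows, columns=RESIDUE_COLUMNS)
    return df, truth


def simulate_ratings_stand_yield(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate per-plot root-rating, stand, and yield tables.

    Expected node-injury in a clothianidin-treated plot is
    ``rating_mean_untreated * (1 - rating_efficacy)``; realized plot ratings
    are Gaussian around that and clipped to the 0-3 node-injury scale.
    Yields and stands are Gaussian with shared additive block effects.
    """
    config.validate()
    # Offset stream so ratings do not reuse the residue draws for one seed.
    rng = np.random.default_rng(config.rng_seed + 1)
    truth = GroundTruth(background=config.background_conc)
    blocks = [f"b{i + 1}" for i in range(config.n_blocks)]

    for treatment, dose in config.treatments:
        mean = config.rating_mean_untreated
        if dose > 0:
            mean *= 1.0 - config.rating_efficacy
        truth.mean_rating[treatment] = mean

    ratings, stand, yields = [], [], []
    for year in config.years:
        block_yield = dict(zip(blocks, rng.normal(0.0, config.yield_sd / 2, config.n_blocks)))
        block_stand = dict(zip(blocks, rng.normal(0.0, config.stand_sd / 2, config.n_blocks)))
        for treatment, dose in config.treatments:
            mu = truth.mean_rating[treatment]
            for block in blocks:
                r = float(np.clip(rng.normal(mu, config.rating_sd), 0.0, 3.0))
                ratings.append(
                    {"year": str(year), "treatment": treatment, "block": block,
                     "rating": r}
                )
                stand.append(
                    {"year": str(year), "treatment": treatment, "block": block,
                     "plants_per_ha": float(
                         config.stand_mean + block_stand[block]
                         + rng.normal(0.0, config.stand_sd)
                     )}
                )
                yields.append(
                    {"year": str(year), "treatment": treatment, "block": block,
                     "yield_kg_ha": float(
                         config.yield_mean + block_yield[block]
                         + rng.normal(0.0, config.yield_sd)
                     )}
                )
    return (
        pd.DataFrame(ratings),
        pd.DataFrame(stand),
        pd.DataFrame(yields),
        truth,
    )


def simulate_weather(
    start_date: date | str,
    n_days: int,
    mean_tmin: float = 10.0,
    mean_tmax: float = 22.0,
    amplitude: float = 8.0,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Daily min/max temperature series with a smooth seasonal cycle.

    The seasonal term is a sine peaking in mid-July (day of year ~200); with
    ``amplitude=0`` and ``noise_sd=0`` every day is exactly
    ``(mean_tmin, mean_tmax)``.  ``tmin <= tmax`` holds by construction.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if isinstance(start_date, str):
        start_date = date.fromisoformat(start_date)
    rng = np.random.default_rng(rng_seed)
    dates = [start_date + timedelta(days=i) for i in range(n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = amplitude * np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    tmin = mean_tmin + seasonal + rng.normal(0.0, noise_sd, n_days)
    tmax = mean_tmax + seasonal + rng.normal(0.0, noise_sd, n_days)
    tmin, tmax = np.minimum(tmin, tmax), np.maximum(tmin, tmax)
    return pd.DataFrame(
        {"date": [d.isoformat() for d in dates], "tmin": tmin, "tmax": tmax}
    )
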