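"""Trial and analysis configuration.

Two dataclasses drive everything:

* :class:`SimConfig` — the design of the synthetic two-year maize seed-treatment
  trial (treatments, doses, blocks, sampling schedule, decay kinetics, noise).
  Its defaults encode the field-study conditions the analysis assumes: four
  treatments (untreated "naked" seed, a fungicide-only coating, and clothianidin
  at 0.25 and 1.25 mg AI/kernel) replicated in four blocks of a randomized
  complete block design, sampled from ~5 to 61 days post planting (DPP).
* :class:`AnalysisConfig` — analysis-side knobs: the limit of detection and the
  substitution policy for censored residues, the significance level for planned
  contrasts, the tissue-completeness threshold, and the decay-flattening
  fraction.

Both can be loaded from a declarative YAML mapping via :func:`load_sim_config`
/ :func:`load_analysis_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SimConfig",
    "AnalysisConfig",
    "ConfigError",
    "load_sim_config",
    "load_analysis_config",
    "REGIONS",
    "DEFAULT_TREATMENTS",
]

#: Plant regions a sampled seedling is split into.
REGIONS = ("root", "seed", "shoot")

#: (treatment name, dose in mg AI per kernel).
DEFAULT_TREATMENTS: tuple[tuple[str, float], ...] = (
    ("naked", 0.0),
    ("fungicide", 0.0),
    ("low", 0.25),
    ("high", 1.25),
)


class ConfigError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


def _default_sampling() -> dict[str, list[int]]:
    # Two seasons' residue-sampling schedules in days post planting.
    return {
        "2014": [6, 8, 10, 13, 15, 17, 20, 34],
        "2015": [5, 7, 9, 12, 14, 16, 19, 47, 61],
    }


def _default_k() -> dict[str, float]:
    # First-order dissipation rate per region, day^-1.  Root/shoot rates put
    # the 5%-of-initial-rate flattening day in the mid-teens to mid-20s DPP;
    # the seed surface loses its coating fastest.
    return {"root": 0.16, "seed": 0.30, "shoot": 0.12}


def _default_c0() -> dict[str, float]:
    # Initial tissue concentration (ug/g) contributed per mg AI/kernel of dose.
    return {"root": 65.0, "seed": 120.0, "shoot": 25.0}


def _default_mass_growth() -> dict[str, tuple[float, float, float]]:
    # Logistic region-mass curve (max_g, midpoint_dpp, rate_per_day);
    # root/shoot cross 1 g in the mid-teens DPP, seed mass is ~constant.
    return {
        "root": (5.0, 21.5, 0.25),
        "seed": (0.25, 0.0, 1.0),
        "shoot": (8.0, 23.0, 0.30),
    }


@dataclass
class SimConfig:
    """Design and ground-truth parameters of the synthetic field trial."""

    rng_seed: int = 20170310
    years: Sequence[str] = ("2014", "2015")
    sampling_dpp: Mapping[str, Sequence[int]] = field(default_factory=_default_sampling)
    treatments: Sequence[tuple[str, float]] = DEFAULT_TREATMENTS
    n_blocks: int = 4
    plants_per_plot_per_date: int = 5
    regions: Sequence[str] = REGIONS
    k_per_region: Mapping[str, float] = field(default_factory=_default_k)
    c0_per_dose_unit: Mapping[str, float] = field(default_factory=_default_c0)
    #: Ambient residue (ug/g) present in every plot, treated or not —
    #: cross-contamination / carry-over from prior seasons.
    background_conc: float = 0.01
    #: CV of the multiplicative lognormal measurement/plant noise.
    noise_cv: float = 0.3
    #: Between-block multiplicative SD (shared multiplier within a block-year).
    block_sd: float = 0.1
    mass_growth: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_mass_growth
    )
    #: Seed region is only recoverable up to this DPP.
    seed_cutoff_dpp: int = 20
    #: Mean 0-3 node-injury score in plots without insecticide.
    rating_mean_untreated: float = 0.3245
    #: Fractional reduction of expected node injury in insecticide-treated plots.
    rating_efficacy: float = 0.6055
    rating_sd: float = 0.15
    yield_mean: float = 13400.0
    yield_sd: float = 600.0
    stand_mean: float = 13300.0
    stand_sd: float = 800.0
    #: Limit of detection, ug/g (0.1 ng/g).
    lod: float = 1e-4
    #: Probability a sampled region is recovered <80% intact.
    incomplete_prob: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.plants_per_plot_per_date < 1:
            raise ConfigError("plants_per_plot_per_date must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.block_sd < 0:
            raise ConfigError("block_sd must be >= 0")
        if self.background_conc < 0:
            raise ConfigError("background_conc must be >= 0")
        if not 0.0 <= self.rating_efficacy <= 1.0:
            raise ConfigError("rating_efficacy must be in [0, 1]")
        if self.rating_mean_untreated < 0:
            raise ConfigError("rating_mean_untreated must be >= 0")
        if self.lod <= 0:
            raise ConfigError("lod must be > 0")
        for name, dose in self.treatments:
            if dose < 0:
                raise ConfigError(f"treatments: dose for {name!r} must be >= 0")
        for year in self.years:
            if year not in self.sampling_dpp:
                raise ConfigError(f"sampling_dpp missing year {year!r}")
            dpps = list(self.sampling_dpp[year])
            if any(b <= a for a, b in zip(dpps, dpps[1:])):
                raise ConfigError(f"sampling_dpp[{year!r}] must be strictly increasing")
            if any(d < 0 for d in dpps):
                raise ConfigError(f"sampling_dpp[{year!r}] must be >= 0")
        for region in self.regions:
            if region not in self.k_per_region:
                raise ConfigError(f"k_per_region missing region {region!r}")
            if self.k_per_region[region] < 0:
                raise ConfigError(f"k_per_region[{region!r}] must be >= 0")
            if region not in self.c0_per_dose_unit:
                raise ConfigError(f"c0_per_dose_unit missing region {region!r}")
            if self.c0_per_dose_unit[region] < 0:
                raise ConfigError(f"c0_per_dose_unit[{region!r}] must be >= 0")
            if region not in self.mass_growth:
                raise ConfigError(f"mass_growth missing region {region!r}")

    @property
    def doses(self) -> dict[str, float]:
        """Treatment name -> dose in mg AI/kernel."""
        return dict(self.treatments)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        d["treatments"] = [list(t) for t in self.treatments]
        d["regions"] = list(self.regions)
        d["sampling_dpp"] = {y: list(v) for y, v in self.sampling_dpp.items()}
        d["k_per_region"] = dict(self.k_per_region)
        d["c0_per_dose_unit"] = dict(self.c0_per_dose_unit)
        d["mass_growth"] = {r: list(v) for r, v in self.mass_growth.items()}
        return d


LOD_POLICIES = ("half_lod", "zero", "drop")


@dataclass
class AnalysisConfig:
    """Knobs of the residue analysis itself (not of the trial design)."""

    lod: float = 1e-4  # ug/g == 0.1 ng/g
    lod_policy: str = "half_lod"
    alpha: float = 0.05
    completeness_threshold: float = 0.80
    #: Fraction of the initial decay rate at which the curve is called "flat".
    flattening_fraction: float = 0.05
    doses: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.lod <= 0:
            raise ConfigError("lod must be > 0")
        if self.lod_policy not in LOD_POLICIES:
            raise ConfigError(
                f"lod_policy must be one of {LOD_POLICIES}, got {self.lod_policy!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0.0 < self.flattening_fraction < 1.0:
            raise ConfigError("flattening_fraction must be in (0, 1)")
        if not 0.0 <= self.completeness_threshold <= 1.0:
            raise ConfigError("completeness_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["doses"] = dict(self.doses)
        return d


def _coerce(cls, mapping: Mapping) -> dict:
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return dict(mapping)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML mapping; unknown keys are errors."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = _coerce(SimConfig, raw)
    if "treatments" in kwargs:
        kwargs["treatments"] = tuple((str(n), float(d)) for n, d in kwargs["treatments"])
    if "mass_growth" in kwargs:
        kwargs["mass_growth"] = {
            r: tuple(float(x) for x in v) for r, v in kwargs["mass_growth"].items()
        }
    return SimConfig(**kwargs)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**_coerce(AnalysisConfig, raw))
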