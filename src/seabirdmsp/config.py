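"""Simulation configuration: covariate summaries, species truths, scores.

The synthetic-data generator is parameterized against the covariate
summaries observed in the central-California shelf surveys this package
emulates (per-variable mean, SD and min-max window), a fixed cruise
calendar, vessel-dependent strip widths, and per-species "true"
zero-inflated negative binomial coefficients.  Species defaults were
calibrated once by simulation so that default zero fractions match the
survey's per-species zero/non-zero bin splits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CovariateSpec",
    "SpeciesTruth",
    "SimulationConfig",
    "COVARIATE_STATS",
    "SPECIES",
    "DEFAULT_ACTIVITY_SCORES",
    "VESSEL_STRIP_WIDTH_M",
]

# Vessel -> nominal strip width (m); observers narrow the strip (never
# below 50 m) when visibility is poor.
VESSEL_STRIP_WIDTH_M = {"Martin": 100.0, "Fulmar": 200.0, "McArthur": 300.0}

# Consolidated human activities and their 1-5 impact scores
# (frequency x passive disturbance x endangerment, by expert consensus).
DEFAULT_ACTIVITY_SCORES = {
    "military": 1,
    "wildlife_viewing": 2,
    "benthic_fishing_mobile": 2,
    "benthic_fishing_fixed": 3,
    "industrial_shipping": 4,
    "oil_gas_shipping": 5,
}


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal + spatial structure for one simulated environmental field."""

    name: str
    mean: float
    sd: float
    vmin: float
    vmax: float
    range_m: float = 15_000.0  # spatial autocorrelation length
    transform: str = "normal"  # "normal" | "lognormal"

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"{self.name}: SD must be >= 0")
        if not (self.vmin <= self.mean <= self.vmax):
            raise ValueError(f"{self.name}: mean outside [min, max]")
        if self.range_m <= 0:
            raise ValueError(f"{self.name}: spatial range must be > 0")


# Reference covariate summaries (mean, SD, min, max) at the 3-km bin scale.
COVARIATE_STATS: dict[str, dict] = {
    "sst": dict(mean=12.6, sd=1.62, vmin=8.9, vmax=16.0),
    "sss": dict(mean=33.3, sd=0.48, vmin=29.7, vmax=34.0),
    "ssf": dict(mean=1.08, sd=2.23, vmin=0.0, vmax=14.9),
    "npgo": dict(mean=0.51, sd=0.94, vmin=-1.4, vmax=1.9),
    "pdo": dict(mean=-0.1, sd=1.01, vmin=-1.8, vmax=1.86),
    "soi": dict(mean=0.41, sd=1.76, vmin=-2.7, vmax=4.3),
    "ui": dict(mean=93.0, sd=40.2, vmin=6.4, vmax=171.5),
    "dist_land_m": dict(mean=27016.0, sd=9396.0, vmin=1210.0, vmax=47790.0),
    "dist_200_m": dict(mean=10759.0, sd=9315.0, vmin=23.0, vmax=47260.0),
    "dist_sefi_m": dict(mean=29062.0, sd=17211.0, vmin=1273.0, vmax=65366.0),
    "strip_width_m": dict(mean=167.8, sd=79.2, vmin=50.0, vmax=300.0),
    "sea_state": dict(mean=2.56, sd=1.28, vmin=0.0, vmax=6.0),
    # The reference swell-height SD (5.07) is not attainable on the stated
    # 0-8 m support; the simulator matches the mean and range instead.
    "swell_height_m": dict(mean=1.98, sd=1.6, vmin=0.0, vmax=8.0),
    "visibility": dict(mean=5.51, sd=2.04, vmin=0.0, vmax=9.0),
    "cloud_cover": dict(mean=5.21, sd=3.37, vmin=0.0, vmax=9.0),
    # time of day in decimal hours (survey effort is daylight-only)
    "time_hours": dict(mean=12.3, sd=3.0, vmin=6.13, vmax=20.08),
}


def _cov(name, **over) -> CovariateSpec:
    d = dict(COVARIATE_STATS[name])
    d.update(over)
    return CovariateSpec(name=name, **d)


@dataclass(frozen=True)
class SpeciesTruth:
    """Generating coefficients for one species' ZINB count process.

    ``beta`` maps a covariate name to ``(linear, quadratic)`` coefficients
    on the standardized covariate scale (quadratic ``None`` for purely
    linear effects); ``gamma`` maps detection-bias covariates to their
    coefficients in the logistic zero-inflation part.  ``alpha`` is the
    NB2 dispersion (variance mu + alpha * mu^2).
    """

    code: str
    common_name: str
    intercept: float
    beta: dict[str, tuple[float, float | None]]
    alpha: float
    infl_intercept: float
    gamma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"{self.code}: dispersion alpha must be > 0")


# Five focal colony-breeding species.  Habitat effects follow each
# species' known associations (shelf break, colony distance, surface
# water properties, basin-scale indices); intercepts were calibrated so
# default zero fractions mirror the reference survey (WEGU 0.82,
# COMU 0.50, CAAU 0.77, RHAU 0.85, BRAC 0.92).
SPECIES: dict[str, SpeciesTruth] = {
    "WEGU": SpeciesTruth(
        code="WEGU", common_name="western gull", intercept=0.443,
        beta={"dist_200_m": (-0.3, -0.2), "dist_sefi_m": (-0.6, None), "ui": (-0.3, None)},
        alpha=1.2, infl_intercept=0.405, gamma={"sea_state": 0.4},
    ),
    "COMU": SpeciesTruth(
        code="COMU", common_name="common murre", intercept=0.786,
        beta={"sst": (-0.2, -0.25), "ssf": (0.3, 0.15), "dist_land_m": (-0.3, -0.15),
              "dist_200_m": (0.4, None), "dist_sefi_m": (-0.4, 0.2), "npgo": (0.3, 0.1)},
        alpha=1.5, infl_intercept=-5.0, gamma={},
    ),
    "CAAU": SpeciesTruth(
        code="CAAU", common_name="Cassin's auklet", intercept=0.990,
        beta={"sss": (0.4, None), "ssf": (0.3, 0.15), "dist_200_m": (-0.3, -0.2),
              "dist_sefi_m": (0.3, 0.2), "soi": (0.2, 0.1)},
        alpha=1.6, infl_intercept=0.0, gamma={"cloud_cover": -0.35, "time_hours": 0.3},
    ),
    "RHAU": SpeciesTruth(
        code="RHAU", common_name="rhinoceros auklet", intercept=0.463,
        beta={"sss": (0.35, None), "ssf": (-0.25, None), "dist_200_m": (-0.4, None),
              "dist_sefi_m": (0.4, None), "npgo": (-0.3, None), "soi": (0.25, None)},
        alpha=0.8, infl_intercept=0.405, gamma={"sea_state": 0.35, "cloud_cover": -0.3},
    ),
    "BRAC": SpeciesTruth(
        code="BRAC", common_name="Brandt's cormorant", intercept=-0.040,
        beta={"sst": (-0.2, -0.3), "dist_200_m": (0.35, None), "dist_sefi_m": (-0.5, None)},
        alpha=2.0, infl_intercept=1.1, gamma={"time_hours": -0.3},
    ),
}


@dataclass
class SimulationConfig:
    """Everything the synthetic-data generator needs, under one seed."""

    seed: int = 0
    # survey design -----------------------------------------------------
    n_transects: int = 7
    transect_lengths_km: tuple[float, ...] = (38.0, 40.0, 36.0, 41.0, 37.0, 39.0, 35.0)
    length_jitter_km: float = 1.5  # per-cruise truncation/extension of each line
    vessel_cycle: tuple[str, ...] = ("Martin", "Fulmar", "Martin", "McArthur")
    # environmental fields ---------------------------------------------
    covariates: dict[str, CovariateSpec] = field(default_factory=lambda: {
        "sst": _cov("sst", range_m=15_000),
        "sss": _cov("sss", range_m=20_000),
        "ssf": _cov("ssf", range_m=8_000, transform="lognormal"),
    })
    # climate index series (AR(1) in time, clipped to the stated window)
    index_rho_monthly: float = 0.8
    ui_rho_daily: float = 0.9
    # CTD sampling ------------------------------------------------------
    ctd_stations_min: int = 15
    ctd_stations_max: int = 18
    ctd_noise_sd: float = 0.15
    # fraction of cruises whose vessel lacks a thermosalinograph, so
    # continuous surface fluorescence is missing and must be gap-filled
    ssf_missing_fraction: float = 11.0 / 27.0
    # species truths ----------------------------------------------------
    species: dict[str, SpeciesTruth] = field(default_factory=lambda: dict(SPECIES))
    # sighting clustering: counts in a bin are split into groups whose
    # sizes follow a geometric distribution with this mean (free
    # parameter; the survey design does not pin down a clustering law)
    mean_group_size: float = 3.0
    # rate of non-foraging decoy records (flying / ship-attract) per bin
    decoy_rate: float = 0.6

    def __post_init__(self):
        for name, spec in self.covariates.items():
            if spec.range_m <= 0:
                raise ValueError(f"{name}: invalid spatial range")
        for sp in self.species.values():
            if sp.alpha <= 0:
                raise ValueError(f"{sp.code}: dispersion must be > 0")
        for v in VESSEL_STRIP_WIDTH_M.values():
            if not 50 <= v <= 300:
                raise ValueError("strip widths must lie within [50, 300] m")
        if not 0 <= self.ssf_missing_fraction <= 1:
            raise ValueError("ssf_missing_fraction must be in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named substream."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stream.encode()) % (2**31)])
        return np.random.default_rng(ss)


def standardize(name: str, values):
    """Map a covariate onto the reference z-scale used by species truths."""
    st = COVARIATE_STATS[name]
    return (np.asarray(values, dtype=float) - st["mean"]) / st["sd"]
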