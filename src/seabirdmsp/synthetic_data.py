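"""Synthetic shipboard survey generator.

Emulates the data a multi-year strip-transect seabird monitoring program
produces: smooth per-cruise ocean surface fields (temperature, salinity,
fluorescence), east-west transect tracks with per-kilometre detection
conditions and underway water properties, zero-inflated negative binomial
bird counts driven by known habitat coefficients, CTD station casts,
monthly climate-index series with daily upwelling, and scored human-
activity footprints.  Everything is deterministic given the seed carried
by :class:`~seabirdmsp.config.SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import survey_prep
from .config import (
    COVARIATE_STATS,
    VESSEL_STRIP_WIDTH_M,
    CovariateSpec,
    DEFAULT_ACTIVITY_SCORES,
    SimulationConfig,
    standardize,
)
from .human_use import ActivityFootprint
from .region import StudyRegion

__all__ = [
    "EnvironmentField",
    "generate_environment_fields",
    "generate_transect_survey",
    "generate_counts_zinb",
    "scatter_sightings",
    "generate_ctd_stations",
    "generate_climate_indices",
    "generate_human_activities",
    "simulate_dataset",
    "SyntheticDataset",
    "zinb_true_moments",
]

FIELD_VARIABLES = ("sst", "sss", "ssf")

#: covariates the inflation (detection) part may draw on
DETECTION_VARIABLES = ("sea_state", "cloud_cover", "swell_height_m", "visibility", "time_hours")


class EnvironmentField:
    """Smooth scalar field from low-rank random Fourier features.

    Approximates a stationary Gaussian random field with squared-
    exponential correlation of length-scale ``spec.range_m``; values are
    transformed (identity or lognormal) to match the covariate's marginal
    mean/SD and clipped to its stated min-max window.  ``sd = 0``
    degenerates to a constant field equal to the mean.
    """

    def __init__(self, spec: CovariateSpec, rng: np.random.Generator, n_features: int = 96):
        if spec.range_m <= 0:
            raise ValueError(f"{spec.name}: spatial range must be > 0")
        self.spec = spec
        if spec.transform == "lognormal":
            if spec.mean <= 0:
                raise ValueError("lognormal transform requires a positive mean")
            if spec.sd == 0:
                self._mu, self._sigma = np.log(spec.mean), 0.0
            else:
                s2 = np.log1p((spec.sd / spec.mean) ** 2)
                self._mu, self._sigma = np.log(spec.mean) - s2 / 2.0, np.sqrt(s2)
        elif spec.transform == "normal":
            self._mu, self._sigma = spec.mean, spec.sd
        else:
            raise ValueError(f"unknown transform {spec.transform!r}")
        k = n_features
        self._omega = rng.normal(0.0, 1.0 / spec.range_m, size=(k, 2))
        self._phase = rng.uniform(0.0, 2.0 * np.pi, size=k)
        self._scale = np.sqrt(2.0 / k)

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pts = np.stack([np.ravel(x), np.ravel(y)], axis=1)
        g = self._scale * np.cos(pts @ self._omega.T + self._phase).sum(axis=1)
        latent = self._mu + self._sigma * g
        vals = np.exp(latent) if self.spec.transform == "lognormal" else latent
        vals = np.clip(vals, self.spec.vmin, self.spec.vmax)
        return vals.reshape(np.shape(x)) if np.shape(x) else float(vals[0])


def generate_environment_fields(
    config: SimulationConfig, region: StudyRegion
) -> dict[tuple[str, str], EnvironmentField]:
    """One field per (cruise, variable), keyed ``(cruise_id, variable)``."""
    fields = {}
    for i in range(region.n_cruises):
        cid = region.cruise_id(i)
        for var, spec in config.covariates.items():
            rng = config.rng(f"field:{var}:{cid}")
            fields[(cid, var)] = EnvironmentField(spec, rng)
    return fields


# --------------------------------------------------------------------- survey
_DAY_START_H = 6.5
_DAY_LEN_H = 13.5
_SPEED_KMH = 18.52  # 10 knots
_TRANSIT_H = 1.0 / 3.0  # repositioning between transect lines


def _hours_to_hhmmss(hours: float) -> int:
    h = int(hours)
    m = int((hours - h) * 60)
    s = int(round(((hours - h) * 60 - m) * 60))
    if s == 60:
        s, m = 0, m + 1
    return h * 10000 + m * 100 + s


def missing_ssf_cruises(config: SimulationConfig, region: StudyRegion) -> set[str]:
    """Cruise ids whose vessel lacks a thermosalinograph (no underway SSF)."""
    n_missing = int(round(config.ssf_missing_fraction * region.n_cruises))
    order = config.rng("missing-ssf").permutation(region.n_cruises)
    return {region.cruise_id(i) for i in order[:n_missing]}


def generate_transect_survey(
    config: SimulationConfig,
    region: StudyRegion,
    fields: dict[tuple[str, str], EnvironmentField],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw per-cruise effort lines and per-kilometre track segments.

    Returns ``(effort, segments)``.  Effort has one row per transect
    line; segments carry along-track detection conditions (Beaufort sea
    state 0-6, cloud 0-9, visibility 0-9, swell height, time of day),
    the vessel's strip width (narrowed under poor visibility, never
    below 50 m) and underway surface water records.  ``ssf`` is missing
    for cruises without a thermosalinograph; ``ssf_true`` retains the
    generating field value.
    """
    for i in range(region.n_cruises):
        cid = region.cruise_id(i)
        for var in config.covariates:
            if (cid, var) not in fields:
                raise ValueError(f"missing field for cruise {cid}, variable {var}")
    no_tsg = missing_ssf_cruises(config, region)
    n_t = config.n_transects
    if n_t == 0:
        cols_e = ["cruise_id", "year", "month", "end_day", "transect_id", "vessel",
                  "start_x", "start_y", "end_x", "end_y", "length_km"]
        cols_s = ["cruise_id", "transect_id", "seg_index", "along_mid_km", "mid_x", "mid_y",
                  "sea_state", "cloud_cover", "swell_height_m", "visibility",
                  "strip_width_m", "time_hhmmss", "time_hours", "sst", "sss", "ssf",
                  "ssf_true"]
        return pd.DataFrame(columns=cols_e), pd.DataFrame(columns=cols_s)
    northings = np.linspace(5_000, 40_000, n_t)
    x_east = 54_000.0
    st = COVARIATE_STATS
    effort_rows, seg_rows = [], []
    for i in range(region.n_cruises):
        cid = region.cruise_id(i)
        year, month = region.calendar[i]
        end_day = region.cruise_end_day(i)
        vessel = config.vessel_cycle[i % len(config.vessel_cycle)]
        base_width = VESSEL_STRIP_WIDTH_M[vessel]
        rng = config.rng(f"survey:{cid}")
        hours = 0.0  # cumulative survey hours across the cruise
        for t in range(n_t):
            length = float(
                config.transect_lengths_km[t % len(config.transect_lengths_km)]
                + rng.uniform(-config.length_jitter_km, config.length_jitter_km)
            )
            y = float(northings[t])
            eastward = t % 2 == 1  # boustrophedon track
            sx, ex = (x_east - 1000 * length, x_east) if eastward else (x_east, x_east - 1000 * length)
            effort_rows.append(dict(
                cruise_id=cid, year=year, month=month, end_day=end_day,
                transect_id=f"T{t + 1}", vessel=vessel,
                start_x=sx, start_y=y, end_x=ex, end_y=y, length_km=length,
            ))
            n_seg = int(np.ceil(length - 1e-9))
            # AR(1) latent states give conditions that drift along the track
            z = np.zeros((4, n_seg))
            z[:, 0] = rng.normal(size=4)
            rho = 0.85
            for j in range(1, n_seg):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(size=4)
            for j in range(n_seg):
                a0, a1 = float(j), float(min(j + 1.0, length))
                mid_along = (a0 + a1) / 2.0
                mx = sx + (1.0 if eastward else -1.0) * 1000.0 * mid_along
                sea = int(np.clip(np.rint(st["sea_state"]["mean"] + st["sea_state"]["sd"] * z[0, j]), 0, 6))
                cloud = int(np.clip(np.rint(st["cloud_cover"]["mean"] + st["cloud_cover"]["sd"] * z[1, j]), 0, 9))
                vis = int(np.clip(np.rint(st["visibility"]["mean"] + st["visibility"]["sd"] * z[2, j]), 0, 9))
                swell = float(np.clip(st["swell_height_m"]["mean"] + st["swell_height_m"]["sd"] * z[3, j], 0.0, 8.0))
                width = base_width if vis > 2 else max(50.0, base_width / 2.0)
                tod = _DAY_START_H + hours % _DAY_LEN_H
                sstv = fields[(cid, "sst")](mx, y)
                sssv = fields[(cid, "sss")](mx, y)
                ssfv = fields[(cid, "ssf")](mx, y)
                seg_rows.append(dict(
                    cruise_id=cid, transect_id=f"T{t + 1}", seg_index=j,
                    along_mid_km=mid_along, mid_x=mx, mid_y=y,
                    sea_state=sea, cloud_cover=cloud, swell_height_m=swell,
                    visibility=vis, strip_width_m=width,
                    time_hhmmss=_hours_to_hhmmss(tod), time_hours=tod,
                    sst=float(sstv), sss=float(sssv),
                    ssf=(np.nan if cid in no_tsg else float(ssfv)),
                    ssf_true=float(ssfv),
                ))
                hours += (a1 - a0) / _SPEED_KMH
            hours += _TRANSIT_H
    return pd.DataFrame(effort_rows), pd.DataFrame(seg_rows)


# --------------------------------------------------------------------- counts
def _species_linpred(truth, bins: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(log mean without offset, inflation logit) per bin from the truth
    coefficients, on the reference standardized covariate scale."""
    eta = np.full(len(bins), truth.intercept, dtype=float)
    for name, (lin, quad) in truth.beta.items():
        z = standardize(name, bins[name])
        eta += lin * z
        if quad is not None:
            eta += quad * z**2
    w = np.full(len(bins), truth.infl_intercept, dtype=float)
    for name, g in truth.gamma.items():
        w += g * standardize(name, bins[name])
    return eta, w


def zinb_true_moments(config: SimulationConfig, bins: pd.DataFrame) -> pd.DataFrame:
    """Closed-form per-bin true mean (1-pi)*mu and inflation probability
    pi for every species (oracle for generative checks)."""
    out = {}
    area = bins["area_km2"].to_numpy(dtype=float)
    for code, truth in config.species.items():
        eta, w = _species_linpred(truth, bins)
        mu = np.exp(eta + np.log(area))
        pi = expit(w)
        out[f"mu_{code}"] = mu
        out[f"pi_{code}"] = pi
        out[f"mean_{code}"] = (1.0 - pi) * mu
    return pd.DataFrame(out, index=bins.index)


def generate_counts_zinb(config: SimulationConfig, bins: pd.DataFrame) -> pd.DataFrame:
    """Draw per-bin, per-species counts from the configured ZINB truth.

    The count mean uses the exposure offset log(area); the zero-inflation
    probability is a logistic function of the detection-bias covariates.
    """
    area = bins["area_km2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area <= 0):
        raise ValueError("all bins must have positive surveyed area")
    needed = {n for t in config.species.values() for n in t.beta} | {
        n for t in config.species.values() for n in t.gamma
    }
    for name in needed:
        if bins[name].isna().any():
            raise ValueError(f"bins carry missing values for covariate {name!r}")
    out = pd.DataFrame(index=bins.index)
    for code, truth in config.species.items():
        if truth.alpha <= 0:
            raise ValueError(f"{code}: dispersion must be > 0")
        rng = config.rng(f"counts:{code}")
        eta, w = _species_linpred(truth, bins)
        mu = np.exp(eta + np.log(area))
        pi = expit(w)
        size = 1.0 / truth.alpha
        nb = rng.negative_binomial(size, size / (size + mu))
        zero = rng.uniform(size=len(bins)) < pi
        out[f"count_{code}"] = np.where(zero, 0, nb).astype(np.int64)
    return out


_ACTIVE_BEHAVIORS = ("foraging", "feeding", "sitting")
_ACTIVE_P = (0.5, 0.2, 0.3)


def scatter_sightings(
    config: SimulationConfig, bins: pd.DataFrame, counts: pd.DataFrame
) -> pd.DataFrame:
    """Turn per-bin counts into individual sighting records.

    Bin totals are split into groups (geometric sizes, configurable
    mean — the survey protocol does not pin down a clustering law) with
    active behaviours; decoy flying / ship-attracted records are added
    on top and must be filtered out downstream.
    """
    rng = config.rng("sightings")
    rows = []
    sid = 0
    species = list(config.species)
    p_geo = min(1.0, 1.0 / max(config.mean_group_size, 1.0))
    for i, b in enumerate(bins.itertuples(index=False)):
        for code in species:
            c = int(counts[f"count_{code}"].iloc[i])
            while c > 0:
                size = min(int(rng.geometric(p_geo)), c)
                behavior = _ACTIVE_BEHAVIORS[rng.choice(3, p=_ACTIVE_P)]
                rows.append(dict(
                    sighting_id=f"s{sid:07d}", cruise_id=b.cruise_id,
                    transect_id=b.transect_id,
                    along_km=float(b.along_start_km + rng.uniform() * b.length_km),
                    species=code, count=size, behavior=behavior,
                    vessel=getattr(b, "vessel", ""), strip_width_m=b.strip_width_m,
                    sea_state=b.sea_state, cloud_cover=b.cloud_cover,
                    swell_height_m=b.swell_height_m, visibility=b.visibility,
                    time_hhmmss=b.time_hhmmss,
                ))
                sid += 1
                c -= size
        for _ in range(rng.poisson(config.decoy_rate)):
            code = species[rng.integers(len(species))]
            behavior = "flying" if rng.uniform() < 0.8 else "ship-attract"
            rows.append(dict(
                sighting_id=f"s{sid:07d}", cruise_id=b.cruise_id,
                transect_id=b.transect_id,
                along_km=float(b.along_start_km + rng.uniform() * b.length_km),
                species=code, count=int(rng.geometric(p_geo)), behavior=behavior,
                vessel=getattr(b, "vessel", ""), strip_width_m=b.strip_width_m,
                sea_state=b.sea_state, cloud_cover=b.cloud_cover,
                swell_height_m=b.swell_height_m, visibility=b.visibility,
                time_hhmmss=b.time_hhmmss,
            ))
            sid += 1
    cols = ["sighting_id", "cruise_id", "transect_id", "along_km", "species", "count",
            "behavior", "vessel", "strip_width_m", "sea_state", "cloud_cover",
            "swell_height_m", "visibility", "time_hhmmss"]
    return pd.DataFrame(rows, columns=cols)


# ------------------------------------------------------------------------ CTD
def _default_stations(region: StudyRegion, n: int = 18) -> pd.DataFrame:
    ys = np.linspace(7_000, 38_000, 6)
    xs = np.array([18_000.0, 30_000.0, 42_000.0])
    pts = [(x, y) for y in ys for x in xs][:n]
    return pd.DataFrame(
        {"station_id": [f"st{i + 1:02d}" for i in range(len(pts))],
         "x": [p[0] for p in pts], "y": [p[1] for p in pts]}
    )


def generate_ctd_stations(
    config: SimulationConfig,
    region: StudyRegion,
    fields: dict[tuple[str, str], EnvironmentField],
    stations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cruise CTD casts at 15-18 of the fixed station locations.

    ``ssf_1_6m`` is the cast's near-surface (1-6-m layer) fluorescence:
    the SSF field value at the station plus measurement noise.
    """
    if stations is None:
        stations = _default_stations(region)
    from shapely.geometry import Point

    for rec in stations.itertuples(index=False):
        if not region.boundary.covers(Point(rec.x, rec.y)):
            raise ValueError(f"CTD station {rec.station_id} lies outside the region boundary")
    rows = []
    for i in range(region.n_cruises):
        cid = region.cruise_id(i)
        year, month = region.calendar[i]
        rng = config.rng(f"ctd:{cid}")
        n = int(rng.integers(config.ctd_stations_min, config.ctd_stations_max + 1))
        chosen = rng.permutation(len(stations))[:n]
        for k in sorted(chosen):
            srec = stations.iloc[k]
            ssf = fields[(cid, "ssf")](srec["x"], srec["y"])
            sst = fields[(cid, "sst")](srec["x"], srec["y"])
            rows.append(dict(
                cruise_id=cid, station_id=srec["station_id"], year=year, month=month,
                x=float(srec["x"]), y=float(srec["y"]),
                ssf_1_6m=float(max(0.0, ssf + rng.normal(0.0, config.ctd_noise_sd))),
                sst=float(sst + rng.normal(0.0, config.ctd_noise_sd * 0.5)),
            ))
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- climate
def generate_climate_indices(
    config: SimulationConfig, region: StudyRegion
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly NPGO/PDO/SOI series and a daily upwelling-index series.

    AR(1) processes on the standardized scale, rescaled to each index's
    marginal mean/SD and clipped to its stated min-max window; the series
    cover every calendar year of the cruise program end to end.
    """
    years = sorted({y for y, _ in region.calendar})
    y0, y1 = min(years), max(years)
    months = [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]
    st = COVARIATE_STATS
    monthly = pd.DataFrame(months, columns=["year", "month"])
    for name in ("npgo", "pdo", "soi"):
        rng = config.rng(f"index:{name}")
        z = np.zeros(len(months))
        z[0] = rng.normal()
        r = config.index_rho_monthly
        for j in range(1, len(months)):
            z[j] = r * z[j - 1] + np.sqrt(1 - r**2) * rng.normal()
        s = st[name]
        monthly[name] = np.clip(s["mean"] + s["sd"] * z, s["vmin"], s["vmax"])
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    rng = config.rng("index:ui")
    z = np.zeros(len(dates))
    z[0] = rng.normal()
    r = config.ui_rho_daily
    eps = rng.normal(size=len(dates))
    for j in range(1, len(dates)):
        z[j] = r * z[j - 1] + np.sqrt(1 - r**2) * eps[j]
    s = st["ui"]
    daily = pd.DataFrame({"date": dates, "ui": np.clip(s["mean"] + s["sd"] * z, s["vmin"], s["vmax"])})
    return monthly, daily


# ----------------------------------------------------------------- activities
def generate_human_activities(
    region: StudyRegion,
    mode: str = "default",
    scores: dict[str, int] | None = None,
) -> list[ActivityFootprint]:
    """Dominant footprints for the six consolidated activities.

    ``mode='overlap'`` makes every footprint span the whole region (so
    some cell intersects all six); ``mode='disjoint'`` places six
    non-overlapping boxes; ``mode='default'`` is a plausible layout with
    shipping lanes crossing the shelf and viewing near the colony.
    """
    scores = dict(DEFAULT_ACTIVITY_SCORES, **(scores or {}))
    from shapely.geometry import box

    minx, miny, maxx, maxy = region.boundary.bounds
    if mode == "overlap":
        geoms = {name: region.boundary for name in scores}
    elif mode == "disjoint":
        w = (maxx - minx) / 7.0
        geoms = {
            name: box(minx + (i + 0.1) * w, miny + 1_000, minx + (i + 0.9) * w, miny + 6_000)
            for i, name in enumerate(scores)
        }
    elif mode == "default":
        geoms = {
            "military": box(minx, 28_000, minx + 15_000, maxy),
            "wildlife_viewing": region.colony.buffer(8_000),
            "benthic_fishing_mobile": box(30_000, miny, 58_000, 14_000),
            "benthic_fishing_fixed": box(48_000, 8_000, maxx, 38_000),
            "industrial_shipping": box(20_000, 18_000, maxx, 26_000),
            "oil_gas_shipping": box(10_000, 22_000, maxx, 28_000),
        }
    else:
        raise ValueError(f"unknown activity layout mode {mode!r}")
    return [ActivityFootprint(name=n, geometry=g, score=scores[n]) for n, g in geoms.items()]


# ------------------------------------------------------------------- pipeline
@dataclass
class SyntheticDataset:
    """Everything one simulated survey program produces."""

    config: SimulationConfig
    region: StudyRegion
    fields: dict = dc_field(repr=False, default_factory=dict)
    effort: pd.DataFrame = None
    segments: pd.DataFrame = None
    sightings: pd.DataFrame = None
    ctd: pd.DataFrame = None
    monthly_indices: pd.DataFrame = None
    daily_upwelling: pd.DataFrame = None
    activities: list = dc_field(default_factory=list)
    truth_bins: pd.DataFrame = None  # bins with true covariates + true counts

    def save(self, outdir) -> None:
        """Write the raw survey products as plain-text files."""
        import json
        from pathlib import Path

        from .human_use import footprints_to_geojson

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.effort.to_csv(out / "effort.csv", index=False)
        self.segments.drop(columns=["ssf_true"], errors="ignore").to_csv(
            out / "segments.csv", index=False)
        self.sightings.to_csv(out / "sightings.csv", index=False)
        self.ctd.to_csv(out / "ctd.csv", index=False)
        self.monthly_indices.to_csv(out / "monthly_indices.csv", index=False)
        self.daily_upwelling.to_csv(out / "daily_upwelling.csv", index=False)
        self.region.save(out / "region.geojson")
        with open(out / "activities.geojson", "w") as fh:
            json.dump(footprints_to_geojson(self.activities), fh)


def simulate_dataset(
    config: SimulationConfig, region: StudyRegion | None = None
) -> SyntheticDataset:
    """Run the whole generator: fields -> survey -> counts -> sightings,
    plus CTD casts, climate series and activity footprints."""
    from .region import default_region

    if region is None:
        region = default_region()
    fields = generate_environment_fields(config, region)
    effort, segments = generate_transect_survey(config, region, fields)
    monthly, daily = generate_climate_indices(config, region)
    ctd = generate_ctd_stations(config, region, fields)
    activities = generate_human_activities(region)

    # Bin the track with *true* surface values (the birds respond to the
    # actual environment, not to what the thermosalinograph recorded).
    seg_true = segments.copy()
    seg_true["ssf"] = seg_true["ssf_true"]
    bins = survey_prep.bin_transects(effort, seg_true)
    bins = survey_prep.compute_distances(bins, region)
    bins = survey_prep.attach_indices(bins, monthly, daily)
    bins["time_hours"] = _hhmmss_to_hours(bins["time_hhmmss"].to_numpy())
    counts = generate_counts_zinb(config, bins)
    # vessel lookup for sighting records
    vmap = effort.drop_duplicates("cruise_id").set_index("cruise_id")["vessel"]
    bins = bins.assign(vessel=bins["cruise_id"].map(vmap))
    sightings = scatter_sightings(config, bins, counts)
    truth = pd.concat([bins, counts, zinb_true_moments(config, bins)], axis=1)
    return SyntheticDataset(
        config=config, region=region, fields=fields, effort=effort,
        segments=segments, sightings=sightings, ctd=ctd,
        monthly_indices=monthly, daily_upwelling=daily,
        activities=activities, truth_bins=truth,
    )


def _hhmmss_to_hours(t) -> np.ndarray:
    t = np.asarray(t, dtype=np.int64)
    return t // 10000 + (t // 100 % 100) / 60.0 + (t % 100) / 3600.0
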