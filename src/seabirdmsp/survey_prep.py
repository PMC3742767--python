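"""From raw track and sighting records to the 3-km binned model table.

The survey protocol counts birds continuously along straight east-west
transect lines from a moving vessel.  For modelling, each transect is cut
into consecutive 3-km bins (terminal remainders shorter than 1 km are
discarded), counts of actively foraging/feeding/sitting birds are totalled
per bin, surface water properties are averaged per bin, distances to the
mainland / shelf break / colony are measured from bin midpoints, monthly
climate indices and a 10-day trailing upwelling average are attached per
cruise, and missing surface fluorescence is gap-filled from CTD casts.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm

from .region import StudyRegion

__all__ = [
    "bin_transects",
    "aggregate_counts",
    "compute_distances",
    "fill_missing_ssf",
    "attach_indices",
    "drop_missing_surface",
    "build_model_table",
    "RETAINED_BEHAVIORS",
]

logger = logging.getLogger(__name__)

#: Behaviours retained for habitat modelling: birds actively using the
#: water surface.  Flying/commuting and ship-attracted birds are excluded.
RETAINED_BEHAVIORS = frozenset({"foraging", "feeding", "sitting"})

_BIN_KM = 3.0
_MIN_BIN_KM = 1.0


def _split_lengths(total_km: float, bin_km: float, min_km: float) -> list[float]:
    """Consecutive bin lengths from the transect start; remainder kept iff
    it is at least ``min_km`` long."""
    n_full = int(np.floor(total_km / bin_km + 1e-9))
    lengths = [bin_km] * n_full
    rem = total_km - n_full * bin_km
    if rem >= min_km - 1e-9:
        lengths.append(rem)
    return lengths


def bin_transects(
    effort: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    bin_length_km: float = _BIN_KM,
    min_bin_km: float = _MIN_BIN_KM,
) -> pd.DataFrame:
    """Cut each straight transect into consecutive bins laid from its
    western terminus.

    Parameters
    ----------
    effort:
        One row per (cruise, transect) with columns ``cruise_id, year,
        month, end_day, transect_id, vessel, start_x, start_y, end_x,
        end_y, length_km``.
    segments:
        Optional per-kilometre track records carrying detection
        conditions and underway surface water values (``along_mid_km,
        sea_state, cloud_cover, swell_height_m, visibility,
        strip_width_m, time_hhmmss, sst, sss, ssf``).  Surface water
        values are averaged over the bin; detection conditions are taken
        from the segment containing the bin midpoint.

    Returns
    -------
    DataFrame with one row per bin: geometry (midpoint), along-track
    window, bin length, and — when ``segments`` is given — per-bin
    conditions and the surveyed area in km2 (length x strip width).
    """
    rows = []
    seg_groups = (
        {k: g.sort_values("along_mid_km") for k, g in segments.groupby(["cruise_id", "transect_id"])}
        if segments is not None
        else {}
    )
    for rec in effort.itertuples(index=False):
        length = float(rec.length_km)
        if length < min_bin_km:
            logger.warning(
                "transect %s/%s shorter than %.0f km (%.2f km): no bins",
                rec.cruise_id, rec.transect_id, min_bin_km, length,
            )
            continue
        # lay bins from the western terminus
        p0 = np.array([rec.start_x, rec.start_y], dtype=float)
        p1 = np.array([rec.end_x, rec.end_y], dtype=float)
        if p1[0] < p0[0]:
            p0, p1 = p1, p0
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)
        lengths = _split_lengths(length, bin_length_km, min_bin_km)
        start = 0.0
        seg = seg_groups.get((rec.cruise_id, rec.transect_id))
        for b, blen in enumerate(lengths):
            mid_along = start + blen / 2.0
            mid = p0 + direction * mid_along * 1000.0
            row = dict(
                cruise_id=rec.cruise_id,
                year=int(rec.year),
                month=int(rec.month),
                end_day=int(rec.end_day),
                transect_id=rec.transect_id,
                bin_index=b,
                along_start_km=start,
                along_end_km=start + blen,
                length_km=blen,
                mid_x=mid[0],
                mid_y=mid[1],
            )
            if seg is not None:
                inside = (seg["along_mid_km"] >= start) & (seg["along_mid_km"] < start + blen)
                sub = seg.loc[inside]
                if sub.empty:  # degenerate short remainder: nearest segment
                    sub = seg.iloc[[int((seg["along_mid_km"] - mid_along).abs().argmin())]]
                nearest = sub.iloc[int((sub["along_mid_km"] - mid_along).abs().argmin())]
                for c in ("sea_state", "cloud_cover", "swell_height_m", "visibility",
                          "strip_width_m", "time_hhmmss"):
                    row[c] = nearest[c]
                for c in ("sst", "sss", "ssf"):
                    if c in sub:
                        row[c] = float(sub[c].mean())
                row["area_km2"] = blen * row["strip_width_m"] / 1000.0
            rows.append(row)
            start += blen
    out = pd.DataFrame(rows)
    if not out.empty:
        out.insert(0, "bin_id", np.arange(len(out)))
    return out


def aggregate_counts(
    sightings: pd.DataFrame,
    bins: pd.DataFrame,
    species: list[str],
    retained_behaviors=RETAINED_BEHAVIORS,
) -> tuple[pd.DataFrame, dict]:
    """Total retained sightings per bin and species.

    Sightings are assigned along-track (columns ``cruise_id,
    transect_id, along_km, species, count, behavior, sighting_id``);
    positions exactly on a bin boundary go to the earlier bin.  Returns
    the bins table with one ``count_<SP>`` column per species and an
    exclusion report (behaviour-filtered birds and out-of-bin records).
    """
    if sightings["sighting_id"].duplicated().any():
        dup = sightings.loc[sightings["sighting_id"].duplicated(), "sighting_id"].iloc[0]
        raise ValueError(f"duplicate sighting id: {dup!r}")
    out = bins.copy()
    for sp in species:
        out[f"count_{sp}"] = 0
    report = {"behavior_filtered_records": 0, "behavior_filtered_birds": 0,
              "out_of_bin_records": 0, "out_of_bin_birds": 0,
              "retained_records": 0, "retained_birds": 0}
    if sightings.empty or bins.empty:
        return out, report

    keep = sightings["behavior"].isin(retained_behaviors)
    report["behavior_filtered_records"] = int((~keep).sum())
    report["behavior_filtered_birds"] = int(sightings.loc[~keep, "count"].sum())
    retained = sightings.loc[keep]

    bin_lookup = {k: g for k, g in bins.groupby(["cruise_id", "transect_id"])}
    counts = {sp: np.zeros(len(bins), dtype=np.int64) for sp in species}
    for key, g in retained.groupby(["cruise_id", "transect_id"]):
        tb = bin_lookup.get(key)
        if tb is None:
            report["out_of_bin_records"] += len(g)
            report["out_of_bin_birds"] += int(g["count"].sum())
            continue
        tb = tb.sort_values("bin_index")
        edges = np.concatenate([[tb["along_start_km"].iloc[0]], tb["along_end_km"].to_numpy()])
        pos = g["along_km"].to_numpy(dtype=float)
        # ties at a boundary -> earlier bin; position 0 -> first bin
        idx = np.searchsorted(edges[1:], pos, side="left")
        ok = (pos >= edges[0]) & (pos <= edges[-1]) & (idx < len(tb))
        report["out_of_bin_records"] += int((~ok).sum())
        report["out_of_bin_birds"] += int(g.loc[~ok, "count"].sum())
        gg = g.loc[ok]
        rows = tb["bin_id"].to_numpy()[idx[ok]]
        sp_arr = gg["species"].to_numpy()
        cnt_arr = gg["count"].to_numpy()
        for sp in species:
            m = sp_arr == sp
            if m.any():
                np.add.at(counts[sp], rows[m], cnt_arr[m])
    for sp in species:
        out[f"count_{sp}"] = counts[sp][out["bin_id"].to_numpy()]
    report["retained_records"] = int(len(retained)) - report["out_of_bin_records"]
    report["retained_birds"] = int(retained["count"].sum()) - report["out_of_bin_birds"]
    return out, report


def compute_distances(bins: pd.DataFrame, region: StudyRegion) -> pd.DataFrame:
    """Euclidean distances (m) from bin midpoints to the mainland, the
    200-m isobath, and the colony."""
    layers = {
        "dist_land_m": region.mainland,
        "dist_200_m": region.isobath_200m,
        "dist_sefi_m": region.colony,
    }
    pts = shapely.points(bins["mid_x"].to_numpy(), bins["mid_y"].to_numpy())
    out = bins.copy()
    for col, geom in layers.items():
        if geom is None or geom.is_empty:
            raise ValueError(f"region layer for {col} is empty")
        out[col] = shapely.distance(pts, geom)
    return out


def fill_missing_ssf(bins: pd.DataFrame, ctd: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Gap-fill missing surface fluorescence from CTD station records.

    Station near-surface fluorescence (mean over the 1-6-m depth layer)
    is regressed on station SST and year by ordinary least squares; the
    fit predicts SSF for bins lacking an underway record.  With a single
    CTD year the design is rank deficient and an SST-only fit is used.
    """
    out = bins.copy()
    missing = out["ssf"].isna()
    out["ssf_imputed"] = False
    if not missing.any():
        return out, {"n_imputed": 0}
    if ctd is None or len(ctd) == 0:
        raise ValueError("missing SSF but no CTD records available for gap-fill")
    n_years = ctd["year"].nunique()
    use_year = n_years >= 2
    if not use_year:
        warnings.warn("single CTD year: falling back to SST-only SSF regression")
    cols = ["sst", "year"] if use_year else ["sst"]
    X = sm.add_constant(ctd[cols].astype(float))
    fit = sm.OLS(ctd["ssf_1_6m"].astype(float), X).fit()
    Xp = sm.add_constant(out.loc[missing, cols].astype(float), has_constant="add")
    out.loc[missing, "ssf"] = fit.predict(Xp).to_numpy()
    out.loc[missing, "ssf_imputed"] = True
    report = {
        "n_imputed": int(missing.sum()),
        "n_ctd_records": int(len(ctd)),
        "predictors": cols,
        "coefficients": dict(zip(fit.params.index, fit.params.to_numpy())),
        "r_squared": float(fit.rsquared),
    }
    return out, report


def attach_indices(
    bins: pd.DataFrame,
    monthly_indices: pd.DataFrame,
    daily_upwelling: pd.DataFrame,
) -> pd.DataFrame:
    """Attach monthly climate indices (NPGO, PDO, SOI) by cruise month and
    the upwelling index as the mean of exactly the 10 daily values ending
    on the cruise's last day."""
    out = bins.copy()
    monthly = monthly_indices.set_index(["year", "month"])
    daily = daily_upwelling.set_index("date")["ui"]
    npgo, pdo, soi, ui = [], [], [], []
    cache: dict[tuple, tuple] = {}
    for rec in out[["year", "month", "end_day"]].itertuples(index=False):
        key = (rec.year, rec.month, rec.end_day)
        if key not in cache:
            try:
                mrow = monthly.loc[(rec.year, rec.month)]
            except KeyError:
                raise KeyError(f"no monthly climate index for (year={rec.year}, month={rec.month})")
            end = pd.Timestamp(rec.year, rec.month, rec.end_day)
            window = pd.date_range(end - pd.Timedelta(days=9), end, freq="D")
            try:
                vals = daily.loc[window]
            except KeyError:
                raise KeyError(f"daily upwelling series does not cover the 10 days ending {end.date()}")
            cache[key] = (float(mrow["npgo"]), float(mrow["pdo"]), float(mrow["soi"]),
                          float(vals.mean()))
        a, b, c, d = cache[key]
        npgo.append(a); pdo.append(b); soi.append(c); ui.append(d)
    out["npgo"], out["pdo"], out["soi"], out["ui"] = npgo, pdo, soi, ui
    return out


def drop_missing_surface(bins: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop bins missing SST or SSS (no gap-fill exists for these)."""
    bad = bins["sst"].isna() | bins["sss"].isna()
    return bins.loc[~bad].reset_index(drop=True), int(bad.sum())


def build_model_table(
    effort: pd.DataFrame,
    segments: pd.DataFrame,
    sightings: pd.DataFrame,
    ctd: pd.DataFrame,
    monthly_indices: pd.DataFrame,
    daily_upwelling: pd.DataFrame,
    region: StudyRegion,
    species: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Run the full preparation chain and return the model table plus a
    processing report (exclusions, drops, imputation diagnostics)."""
    bins = bin_transects(effort, segments)
    bins, excl = aggregate_counts(sightings, bins, species)
    bins = compute_distances(bins, region)
    bins, n_dropped = drop_missing_surface(bins)
    bins, impute = fill_missing_ssf(bins, ctd)
    bins = attach_indices(bins, monthly_indices, daily_upwelling)
    t = bins["time_hhmmss"].astype(np.int64)
    bins["time_hours"] = t // 10000 + (t // 100 % 100) / 60.0 + (t % 100) / 3600.0
    report = {"exclusions": excl, "n_dropped_missing_surface": n_dropped, "ssf_imputation": impute}
    return bins, report
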