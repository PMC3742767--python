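"""Prediction grid, per-cruise abundance prediction, and standardized
habitat-selection maps.

Fitted count models are projected onto a regular 1-km2 grid covering the
study region plus a 5-km buffer: each cruise's kriged surface values,
static distances and climate indices fill the prediction matrix
(detection-bias covariates are set to their modal observed values), and
the model's mixture expectation (1-pi)*exp(x'beta) at 1-km2 exposure
gives a per-cell expected abundance.  Per-cruise predictions are
standardized to a relative-use index (cell value / cross-cell mean, so
every surface averages exactly 1), averaged within month and then across
months and years, and combined across species with equal contribution
into a composite map ordered by percent rank and classed into deciles.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from shapely.geometry import Point

from . import survey_prep
from .region import StudyRegion
from .zinb import DETECTION_CANDIDATES, ZINBFit, predict_mean

logger = logging.getLogger(__name__)

__all__ = [
    "build_grid", "modal_detection_values", "cruise_prediction_frame",
    "predict_abundance", "standardize_cruises", "monthly_layers",
    "across_months_years", "composite_multispecies", "percent_rank",
    "decile_class", "build_habitat_maps",
]


def build_grid(region: StudyRegion, resolution_m: float = 1000.0,
               buffer_m: float = 5000.0) -> pd.DataFrame:
    """Regular prediction grid of ``resolution_m`` square cells.

    Cells are aligned to the region's minimum corner; a cell is included
    when its centroid lies in the region or its buffer (boundary points
    count as inside).  Returns ``cell_id, cx, cy, in_region``.
    """
    if region.boundary.is_empty:
        raise ValueError("region polygon is empty")
    buffered = region.boundary.buffer(buffer_m) if buffer_m > 0 else region.boundary
    minx, miny, maxx, maxy = buffered.bounds
    # align to the region's own minimum corner
    rminx, rminy, _, _ = region.boundary.bounds
    x0 = rminx - np.ceil((rminx - minx) / resolution_m) * resolution_m
    y0 = rminy - np.ceil((rminy - miny) / resolution_m) * resolution_m
    xs = np.arange(x0 + resolution_m / 2, maxx, resolution_m)
    ys = np.arange(y0 + resolution_m / 2, maxy, resolution_m)
    cx, cy = np.meshgrid(xs, ys)
    cx, cy = cx.ravel(), cy.ravel()
    import shapely

    pts = shapely.points(cx, cy)
    inside_buf = shapely.covers(buffered, pts)
    inside_reg = shapely.covers(region.boundary, pts)
    keep = inside_buf
    out = pd.DataFrame({
        "cell_id": np.arange(int(keep.sum())),
        "cx": cx[keep], "cy": cy[keep],
        "in_region": inside_reg[keep],
    })
    return out


def modal_detection_values(model_table: pd.DataFrame) -> dict[str, float]:
    """Most frequently recorded value of each detection-bias covariate.

    Continuous covariates (swell height, time of day) are rounded to a
    practical reporting precision before taking the mode.
    """
    out = {}
    for name in DETECTION_CANDIDATES:
        v = model_table[name]
        if name in ("swell_height_m", "time_hours"):
            v = v.round(1)
        out[name] = float(v.mode().iloc[0])
    return out


def flag_extrapolation(cells: pd.DataFrame, model_table: pd.DataFrame,
                       max_km: float = 25.0) -> pd.DataFrame:
    """Flag cells farther than ``max_km`` from the nearest surveyed bin."""
    tree = cKDTree(model_table[["mid_x", "mid_y"]].to_numpy())
    d, _ = tree.query(cells[["cx", "cy"]].to_numpy(), k=1)
    out = cells.copy()
    out["extrapolated"] = d > max_km * 1000.0
    return out


def cruise_prediction_frame(
    cells: pd.DataFrame,
    surfaces: dict,
    cruise_id: str,
    model_table: pd.DataFrame,
    region: StudyRegion,
) -> pd.DataFrame:
    """Per-cell covariate matrix for one cruise at 1-km2 exposure."""
    cruise_rows = model_table.loc[model_table["cruise_id"] == cruise_id]
    if cruise_rows.empty:
        raise ValueError(f"cruise {cruise_id!r} not present in the model table")
    first = cruise_rows.iloc[0]
    frame = cells.copy()
    for var in ("sst", "sss", "ssf"):
        key = (cruise_id, var)
        if key not in surfaces:
            raise ValueError(f"no kriged surface for {key}")
        grid = surfaces[key].grid
        if len(grid) != len(cells):
            raise ValueError("surface grid does not match the cell matrix")
        frame[var] = grid["pred"].to_numpy()
    frame = frame.rename(columns={"cx": "mid_x", "cy": "mid_y"})
    frame = survey_prep.compute_distances(frame, region)
    frame = frame.rename(columns={"mid_x": "cx", "mid_y": "cy"})
    for name in ("npgo", "pdo", "soi", "ui"):
        frame[name] = float(first[name])
    frame["year"] = int(first["year"])
    frame["month"] = int(first["month"])
    for name, val in modal_detection_values(model_table).items():
        frame[name] = val
    frame["area_km2"] = 1.0
    frame["cruise_id"] = cruise_id
    return frame


def predict_abundance(fit: ZINBFit, frame: pd.DataFrame,
                      training_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Expected count per cell at 1-km2 exposure under the fitted model.

    ZINB fits use the mixture mean (1-pi)*mu; NB/Poisson fits use mu.
    Cells with any covariate beyond 3x the training range are still
    predicted but flagged ``covariate_extrapolated``.
    """
    if not fit.converged:
        raise ValueError(f"model for {fit.spec.species} did not converge")
    pred = predict_mean(fit, frame, area_km2=1.0)
    out = frame[["cell_id", "cruise_id", "year", "month"]].copy()
    out["species"] = fit.spec.species
    out["pred"] = np.clip(pred, 0.0, None)
    if training_table is not None:
        flag = np.zeros(len(frame), dtype=bool)
        for t in fit.spec.count_terms:
            tr = training_table[t.name].astype(float)
            lo, hi = tr.min(), tr.max()
            span = (hi - lo) if hi > lo else 1.0
            v = frame[t.name].astype(float)
            flag |= (v < lo - span) | (v > hi + span)
        out["covariate_extrapolated"] = flag
    return out


def standardize_cruises(predictions: pd.DataFrame) -> pd.DataFrame:
    """Relative-use index per (species, cruise): cell value divided by
    the cross-cell mean, so each surface has mean exactly 1.  All-zero
    surfaces are dropped with a warning."""
    out = []
    for (sp, cid), g in predictions.groupby(["species", "cruise_id"]):
        m = g["pred"].mean()
        if m <= 0:
            warnings.warn(f"all-zero prediction surface for {sp}/{cid}: dropped")
            continue
        gg = g.copy()
        gg["std"] = gg["pred"] / m
        out.append(gg)
    if not out:
        raise ValueError("no non-degenerate prediction surfaces")
    return pd.concat(out, ignore_index=True)


def monthly_layers(standardized: pd.DataFrame, months=(5, 7, 9)) -> pd.DataFrame:
    """Per-species monthly habitat-use layers: the mean standardized
    value per cell over all cruises in each requested calendar month."""
    present = set(standardized["month"].unique())
    out = []
    for m in months:
        if m not in present:
            warnings.warn(f"no cruises in month {m}: skipped")
            continue
        sub = standardized.loc[standardized["month"] == m]
        layer = (sub.groupby(["species", "cell_id"], as_index=False)["std"].mean()
                 .assign(month=m))
        out.append(layer)
    if not out:
        warnings.warn("no requested month present: no monthly maps")
        return pd.DataFrame(columns=["species", "cell_id", "std", "month"])
    res = pd.concat(out, ignore_index=True)
    res["decile"] = res.groupby(["species", "month"])["std"].transform(
        lambda v: decile_class(percent_rank(v.to_numpy())))
    return res


def across_months_years(standardized: pd.DataFrame) -> pd.DataFrame:
    """Across-months-and-years habitat use: first the mean standardized
    value per cell within each month (across years), then the mean over
    months, rescaled so every species' map again averages exactly 1
    (equal contribution across species)."""
    monthly = (standardized.groupby(["species", "month", "cell_id"], as_index=False)["std"]
               .mean())
    overall = monthly.groupby(["species", "cell_id"], as_index=False)["std"].mean()
    overall["std"] = overall.groupby("species")["std"].transform(lambda v: v / v.mean())
    return overall.rename(columns={"std": "amount"})


def percent_rank(values: np.ndarray) -> np.ndarray:
    """Rank scaled to [0, 1]: (rank - 1)/(n - 1), average ranks on ties."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 1:
        return np.array([0.5])
    r = rankdata(values, method="average")
    return (r - 1.0) / (n - 1.0)


def decile_class(pr: np.ndarray) -> np.ndarray:
    """Decile class 1..10 from percent ranks (each step a 10% band)."""
    return np.minimum(9, np.floor(np.asarray(pr) * 10.0)).astype(int) + 1


def composite_multispecies(species_maps: pd.DataFrame) -> pd.DataFrame:
    """Cellwise mean of species-standardized maps -> one multi-species
    value per cell, with percent ranks and decile classes.

    ``species_maps`` is long (species, cell_id, amount); every species
    must cover an identical cell set.
    """
    counts = species_maps.groupby("species")["cell_id"].apply(frozenset)
    if len(set(counts)) > 1:
        raise ValueError("species maps are not on identical grids")
    comp = species_maps.groupby("cell_id", as_index=False)["amount"].mean()
    comp = comp.rename(columns={"amount": "composite"})
    comp["percent_rank"] = percent_rank(comp["composite"].to_numpy())
    comp["decile"] = decile_class(comp["percent_rank"].to_numpy())
    return comp


def plot_decile_map(cells: pd.DataFrame, value_col: str = "decile",
                    path=None, title: str | None = None):
    """Render a decile-classed (or any per-cell) map to a matplotlib
    figure; each colour step spans one 10% band of habitat selection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5.5))
    sc = ax.scatter(cells["cx"], cells["cy"], c=cells[value_col], s=8,
                    marker="s", cmap="viridis")
    fig.colorbar(sc, ax=ax, label=value_col)
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def build_habitat_maps(
    fits: dict[str, ZINBFit],
    model_table: pd.DataFrame,
    surfaces: dict,
    region: StudyRegion,
    cells: pd.DataFrame | None = None,
    months=(5, 7, 9),
) -> dict:
    """Full mapping stage: predict per cruise, standardize, compose.

    Returns a dict with the cells table (per-species amounts + composite
    percent ranks, ready for prioritization), the per-month layers, and
    the raw per-cruise standardized predictions.
    """
    if cells is None:
        cells = build_grid(region)
    cells = flag_extrapolation(cells, model_table)
    preds = []
    for cid in model_table["cruise_id"].unique():
        frame = cruise_prediction_frame(cells, surfaces, cid, model_table, region)
        for sp, fit in fits.items():
            preds.append(predict_abundance(fit, frame, training_table=model_table))
    predictions = pd.concat(preds, ignore_index=True)
    standardized = standardize_cruises(predictions)
    species_maps = across_months_years(standardized)
    composite = composite_multispecies(species_maps)
    monthly = monthly_layers(standardized, months=months)
    table = cells.merge(
        species_maps.pivot(index="cell_id", columns="species", values="amount")
        .rename(columns=lambda s: f"amount_{s}").reset_index(),
        on="cell_id", how="inner",
    ).merge(composite, on="cell_id")
    return {"cells": table, "species_maps": species_maps, "monthly": monthly,
            "standardized": standardized, "composite": composite}
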