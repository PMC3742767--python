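"""Ordinary kriging of per-cruise ocean surface fields.

Each cruise's binned surface values (SST, SSS, SSF at 3-km bin
midpoints) are interpolated to the prediction grid by ordinary kriging:
the empirical semivariogram (half mean squared difference by separation
lag) is fitted with an isotropic exponential, spherical or gaussian
model, the family and parameters are chosen to minimize leave-one-out
cross-validation mean squared error, and predictions solve the usual
constrained system whose weights sum to one.  Surfaces with a
significant first-order spatial trend (or an unbounded empirical
semivariogram) are detrended first and the plane is added back after
kriging residuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramModel", "KrigedSurface",
    "empirical_variogram", "fit_variogram", "detrend", "trend_trigger",
    "krige", "loo_rmse", "surface_suite",
]

FAMILIES = ("exponential", "spherical", "gaussian")


def _gamma(family: str, h: np.ndarray, nugget: float, psill: float, rng: float):
    """Semivariogram value at lag h (practical-range convention)."""
    h = np.asarray(h, dtype=float)
    if family == "exponential":
        s = 1.0 - np.exp(-3.0 * h / rng)
    elif family == "gaussian":
        s = 1.0 - np.exp(-3.0 * (h / rng) ** 2)
    elif family == "spherical":
        r = np.minimum(h / rng, 1.0)
        s = 1.5 * r - 0.5 * r**3
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    out = nugget + psill * s
    return np.where(h == 0, 0.0, out)  # gamma(0) = 0 by definition


@dataclass
class VariogramModel:
    """Isotropic semivariogram for one (cruise, variable) surface."""

    family: str
    nugget: float
    psill: float
    range_: float
    trend: np.ndarray | None = None  # (a, b, c) of plane a + b*x + c*y
    cruise_id: str = ""
    variable: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("nugget/psill must be >= 0 and range > 0")

    def __call__(self, h):
        return _gamma(self.family, h, self.nugget, self.psill, self.range_)

    @property
    def degenerate(self) -> bool:
        return self.nugget + self.psill <= 0


@dataclass
class KrigedSurface:
    """One interpolated surface on the prediction grid."""

    variable: str
    cruise_id: str
    grid: pd.DataFrame  # x, y, pred, variance, extrapolated
    model: VariogramModel
    rmse: float
    detrended: bool = False
    notes: list[str] = field(default_factory=list)


def empirical_variogram(points: np.ndarray, values: np.ndarray, n_lags: int = 12):
    """Binned empirical semivariogram.

    Pairwise half squared differences are averaged over ``n_lags``
    equal-width separation bins spanning (0, half the maximum pairwise
    distance].  Returns (lag centers, semivariance, pair counts).
    """
    d = cdist(points, points)
    iu = np.triu_indices(len(points), k=1)
    h = d[iu]
    g = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    hmax = h.max() / 2.0
    edges = np.linspace(0.0, hmax, n_lags + 1)
    idx = np.digitize(h, edges[1:-1])
    keep = h <= hmax
    centers = 0.5 * (edges[:-1] + edges[1:])
    gamma = np.full(n_lags, np.nan)
    counts = np.zeros(n_lags, dtype=int)
    for k in range(n_lags):
        m = keep & (idx == k)
        counts[k] = int(m.sum())
        if counts[k]:
            gamma[k] = float(g[m].mean())
    return centers, gamma, counts


def _wls_fit(family, centers, gamma, counts, var0, hmax):
    ok = np.isfinite(gamma) & (counts > 0)
    h, g, w = centers[ok], gamma[ok], counts[ok].astype(float)

    def f(hh, nugget, psill, rng):
        return _gamma(family, hh, nugget, psill, rng)

    p0 = (max(g[0] * 0.5, 1e-12), max(var0 - g[0] * 0.5, 1e-12), hmax / 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                f, h, g, p0=p0, sigma=1.0 / np.sqrt(w), absolute_sigma=False,
                bounds=([0, 0, 1e-6], [np.inf, np.inf, 10 * hmax]), maxfev=5000)
        return tuple(float(v) for v in popt)
    except Exception:
        return p0


def _krige_point(model, pts, vals, target, jitter=1e-10):
    n = len(pts)
    G = model(cdist(pts, pts))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = model(np.linalg.norm(pts - target, axis=1))
    b[n] = 1.0
    try:
        sol = np.linalg.solve(A + np.eye(n + 1) * 0.0, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
    w = sol[:n]
    pred = float(w @ vals)
    var = float(max(0.0, w @ b[:n] + sol[n]))
    return pred, var, w


def _dedupe(points, values):
    df = pd.DataFrame({"x": points[:, 0], "y": points[:, 1], "v": values})
    g = df.groupby(["x", "y"], as_index=False)["v"].mean()
    if len(g) < len(df):
        logger.info("averaged %d duplicate locations", len(df) - len(g))
    return g[["x", "y"]].to_numpy(), g["v"].to_numpy()


def loo_cv_sqerr(points, values, model, n_neighbors: int = 16) -> np.ndarray:
    """Leave-one-out squared prediction errors under a variogram model."""
    n = len(points)
    tree = cKDTree(points)
    k = min(n_neighbors + 1, n)
    _, nbrs = tree.query(points, k=k)
    errs = np.empty(n)
    for i in range(n):
        idx = [j for j in np.atleast_1d(nbrs[i]) if j != i]
        pred, _, _ = _krige_point(model, points[idx], values[idx], points[i])
        errs[i] = (pred - values[i]) ** 2
    return errs


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    families=FAMILIES,
    n_lags: int = 12,
    n_neighbors: int = 16,
    cruise_id: str = "",
    variable: str = "",
) -> VariogramModel:
    """Fit candidate families and keep the one minimizing LOO CV MSE.

    Per family, parameters come from a pair-count-weighted least squares
    fit to the binned empirical semivariogram; the family choice (the
    "optimization" step) minimizes leave-one-out mean squared prediction
    error, mirroring an automated interpolation-parameter search.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 20:
        raise ValueError(f"variogram fit needs >= 20 points, got {len(points)}")
    points, values = _dedupe(points, values)
    if len(np.unique(points, axis=0)) < 2:
        raise ValueError("need at least 2 distinct locations")
    var0 = float(values.var())
    if var0 <= 1e-12 * (1.0 + float(np.mean(values)) ** 2):
        warnings.warn("all values identical: degenerate variogram (sill 0)")
        return VariogramModel(family="exponential", nugget=0.0, psill=0.0,
                              range_=1.0, cruise_id=cruise_id, variable=variable)
    centers, gamma, counts = empirical_variogram(points, values, n_lags=n_lags)
    hmax = float(centers[-1])
    best = None
    for fam in families:
        nugget, psill, rng = _wls_fit(fam, centers, gamma, counts, var0, hmax)
        if nugget + psill <= 0:
            continue
        model = VariogramModel(family=fam, nugget=nugget, psill=psill, range_=max(rng, 1e-6),
                               cruise_id=cruise_id, variable=variable)
        mse = float(loo_cv_sqerr(points, values, model, n_neighbors).mean())
        if best is None or mse < best[0]:
            best = (mse, model)
    if best is None:  # all fits collapsed; fall back to pure nugget
        return VariogramModel(family="exponential", nugget=var0, psill=0.0, range_=hmax,
                              cruise_id=cruise_id, variable=variable)
    return best[1]


def detrend(points: np.ndarray, values: np.ndarray):
    """First-order (plane) trend surface by least squares.

    Returns ``(residuals, coefs, fit)`` where ``coefs`` = (a, b, c) of
    a + b*x + c*y.  A collinear point layout (all points on a line)
    cannot support a plane; the trend is skipped with a warning.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("detrending needs >= 10 points")
    X = sm.add_constant(points)
    if np.linalg.matrix_rank(X) < 3:
        warnings.warn("collinear point layout: trend surface skipped")
        return np.asarray(values, dtype=float).copy(), np.array([np.mean(values), 0.0, 0.0]), None
    fit = sm.OLS(np.asarray(values, dtype=float), X).fit()
    return np.asarray(fit.resid), np.asarray(fit.params), fit


def trend_trigger(points, values, n_lags: int = 12) -> bool:
    """Decide whether a surface needs detrending before kriging.

    Triggers when the first-order plane fit is significant (F test at
    0.05) or when the empirical semivariogram keeps growing unboundedly
    at the largest lags (last three lags strictly increasing and the
    final one more than twice the sample variance).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.var() == 0:
        return False
    X = sm.add_constant(points)
    if np.linalg.matrix_rank(X) >= 3:
        fit = sm.OLS(values, X).fit()
        if fit.f_pvalue < 0.05:
            return True
    _, gamma, counts = empirical_variogram(points, values, n_lags=n_lags)
    ok = np.isfinite(gamma)
    g = gamma[ok]
    if len(g) >= 3:
        tail = g[-3:]
        if np.all(np.diff(tail) > 0) and tail[-1] > 2.0 * values.var():
            return True
    return False


def krige(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    grid: np.ndarray,
    n_neighbors: int = 16,
    extrapolation_km: float = 25.0,
) -> KrigedSurface:
    """Ordinary kriging of ``values`` onto ``grid`` nodes.

    Weights solve the constrained system (sum to 1); with a zero nugget
    the predictor interpolates the data exactly.  When the model carries
    a plane trend the residuals are kriged and the plane is added back.
    Grid nodes farther than ``extrapolation_km`` from the nearest datum
    are flagged ``extrapolated``.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid nodes must be finite")
    points, values = _dedupe(points, values)
    resid = values
    if model.trend is not None:
        a, b, c = model.trend
        resid = values - (a + b * points[:, 0] + c * points[:, 1])
    n = len(points)
    preds = np.empty(len(grid))
    variances = np.empty(len(grid))
    if model.degenerate:
        preds[:] = float(resid.mean())
        variances[:] = 0.0
    else:
        tree = cKDTree(points)
        k = min(n_neighbors, n)
        _, nbrs = tree.query(grid, k=k)
        nbrs = np.atleast_2d(nbrs)
        if nbrs.shape[0] != len(grid):
            nbrs = nbrs.reshape(len(grid), -1)
        for i in range(len(grid)):
            idx = nbrs[i]
            p, v, _ = _krige_point(model, points[idx], resid[idx], grid[i])
            preds[i] = p
            variances[i] = v
    if model.trend is not None:
        a, b, c = model.trend
        preds = preds + a + b * grid[:, 0] + c * grid[:, 1]
    tree = cKDTree(points)
    dist_near, _ = tree.query(grid, k=1)
    out = pd.DataFrame({
        "x": grid[:, 0], "y": grid[:, 1], "pred": preds, "variance": variances,
        "extrapolated": dist_near > extrapolation_km * 1000.0,
    })
    return KrigedSurface(variable=model.variable, cruise_id=model.cruise_id,
                         grid=out, model=model, rmse=np.nan,
                         detrended=model.trend is not None)


def loo_rmse(points, values, model, n_neighbors: int = 16) -> float:
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    points, values = _dedupe(points, values)
    resid = values
    if model.trend is not None:
        a, b, c = model.trend
        resid = values - (a + b * points[:, 0] + c * points[:, 1])
    if model.degenerate:
        return float(np.sqrt(np.mean((resid - resid.mean()) ** 2)))
    return float(np.sqrt(loo_cv_sqerr(points, resid, model, n_neighbors).mean()))


def _surface_for(df, var, grid, cruise_id, force_detrend=False, n_neighbors=16):
    pts = df[["mid_x", "mid_y"]].to_numpy()
    vals = df[var].to_numpy(dtype=float)
    use_trend = force_detrend or trend_trigger(pts, vals)
    trend_coefs = None
    fit_vals = vals
    if use_trend:
        resid, coefs, tf = detrend(pts, vals)
        if tf is not None:
            trend_coefs, fit_vals = coefs, resid
    model = fit_variogram(pts, fit_vals, cruise_id=cruise_id, variable=var,
                          n_neighbors=n_neighbors)
    model.trend = trend_coefs
    surf = krige(pts, vals, model, grid, n_neighbors=n_neighbors)
    surf.rmse = loo_rmse(pts, vals, model, n_neighbors=n_neighbors)
    return surf


def surface_suite(
    model_table: pd.DataFrame,
    grid: np.ndarray,
    variables=("sst", "sss", "ssf"),
    min_points: int = 20,
    n_neighbors: int = 16,
) -> tuple[dict, dict]:
    """Krige every (variable, cruise) surface and summarize RMSE.

    Returns ``(surfaces, summary)``: surfaces keyed ``(cruise_id,
    variable)``; the summary reports per-variable leave-one-out RMSE
    mean +/- SD, cruises skipped for insufficient data, and outlying
    surfaces (RMSE > mean + 2 SD) that were re-kriged with detrending.
    """
    surfaces: dict = {}
    summary: dict = {"skipped": [], "outliers_detrended": [], "rmse": {}}
    for var in variables:
        for cid, sub in model_table.groupby("cruise_id", sort=True):
            sub = sub.loc[np.isfinite(sub[var].astype(float))]
            if len(sub) < min_points:
                summary["skipped"].append({"cruise_id": cid, "variable": var, "n": len(sub)})
                logger.warning("cruise %s: only %d %s points; surface skipped", cid, len(sub), var)
                continue
            surfaces[(cid, var)] = _surface_for(sub, var, grid, cid, n_neighbors=n_neighbors)
        rmses = {cid: s.rmse for (cid, v), s in surfaces.items() if v == var}
        if rmses:
            arr = np.array(list(rmses.values()))
            mean, sd = float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            for cid, r in rmses.items():
                if len(arr) > 2 and r > mean + 2 * sd and not surfaces[(cid, var)].detrended:
                    sub = model_table.loc[model_table["cruise_id"] == cid]
                    sub = sub.loc[np.isfinite(sub[var].astype(float))]
                    redo = _surface_for(sub, var, grid, cid, force_detrend=True,
                                        n_neighbors=n_neighbors)
                    if redo.rmse < r:
                        surfaces[(cid, var)] = redo
                        summary["outliers_detrended"].append({"cruise_id": cid, "variable": var})
            arr = np.array([s.rmse for (c, v), s in surfaces.items() if v == var])
            summary["rmse"][var] = {"mean": float(arr.mean()),
                                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                                    "n_surfaces": int(len(arr))}
    summary["n_surfaces"] = len(surfaces)
    return surfaces, summary
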