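"""Zero-inflated negative binomial habitat models.

The count model for a species' per-bin abundance y is the NB2 negative
binomial with mean mu = exp(x'beta + log area) and variance
mu + alpha*mu^2 (the log surveyed area enters as an exposure offset with
coefficient fixed at 1, making the model an implicit density model).
Zero inflation mixes in a point mass at zero with probability
pi = logistic(z'gamma), where z holds detection-bias covariates (cloud,
sea state, swell, visibility, time of day) that can generate false
zeros:

    P(y=0) = pi + (1-pi) * NB(0 | mu, alpha)
    P(y=k) = (1-pi) * NB(k | mu, alpha),   k > 0.

Fitting is by maximum likelihood (quasi-Newton with analytic gradients,
Poisson-GLM starting values for the count part).  The module also
implements the model-building battery used with such data: VIF
screening, backward stepwise simplification at the 0.05 level, the
boundary-corrected likelihood-ratio test for overdispersion (NB over
Poisson), the Vuong test for preferring ZINB over plain NB, selection of
a year x oceanography interaction by likelihood ratio, and n-fold
cross-validation scored by the observed-on-predicted regression F test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import digamma, expit, gammaln, log_expit

logger = logging.getLogger(__name__)

__all__ = [
    "Term", "ModelSpec", "ZINBFit", "TestResult",
    "nb_logpmf", "zinb_obs_loglik", "zinb_loglik",
    "fit", "lr_test_alpha", "vuong_test", "vif_screen",
    "backward_stepwise", "select_detection_terms", "select_interaction",
    "cross_validate", "predict_mean",
]

#: oceanographic covariates eligible for a year interaction
OCEANOGRAPHIC = ("sst", "sss", "ssf")

#: detection-bias covariate candidates (inflation part only)
DETECTION_CANDIDATES = ("cloud_cover", "sea_state", "swell_height_m",
                        "visibility", "time_hours")


# ------------------------------------------------------------------ spec
@dataclass(frozen=True)
class Term:
    """One count-part habitat term: a covariate and its form."""

    name: str
    form: str = "linear"  # "linear" | "quadratic"

    def __post_init__(self):
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown term form {self.form!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one species' ZINB habitat model.

    A quadratic term always includes its linear component.  Month and
    year enter the count part as categorical controls and are never
    dropped by stepwise simplification.  ``interaction`` crosses year
    (categorical) with one standardized oceanographic covariate.
    """

    species: str
    count_terms: tuple[Term, ...] = ()
    inflation_terms: tuple[str, ...] = ()
    controls: tuple[str, ...] = ("month", "year")
    interaction: str | None = None
    offset_col: str = "area_km2"

    def __post_init__(self):
        if self.interaction is not None and self.interaction not in OCEANOGRAPHIC:
            raise ValueError(f"interaction covariate must be one of {OCEANOGRAPHIC}")

    def drop_term(self, name: str) -> "ModelSpec":
        new = []
        for t in self.count_terms:
            if t.name == name:
                if t.form == "quadratic":
                    new.append(Term(name, "linear"))  # quadratic drops first
                continue
            new.append(t)
        return replace(self, count_terms=tuple(new))


# --------------------------------------------------------------- design
@dataclass
class Design:
    """Realized design matrices plus the scalers needed for prediction."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None
    offset: np.ndarray
    x_names: list[str]
    z_names: list[str]
    scalers: dict[str, tuple[float, float]]
    levels: dict[str, list]


def _zscore(data, name, scalers):
    mu, sd = scalers[name]
    return (np.asarray(data[name], dtype=float) - mu) / sd


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    scalers: dict | None = None,
    levels: dict | None = None,
    response: bool = True,
) -> Design:
    """Build count-part (X) and inflation-part (Z) matrices.

    Covariates are standardized to the training mean/SD; quadratic terms
    square the centered covariate (reducing collinearity with the linear
    term).  When ``scalers``/``levels`` are supplied (prediction on new
    cells), training standardization and categorical levels are reused.
    """
    fit_scalers = scalers is None
    scalers = dict(scalers or {})
    levels = dict(levels or {})

    def z(name):
        if fit_scalers and name not in scalers:
            v = np.asarray(data[name], dtype=float)
            sd = float(v.std())
            scalers[name] = (float(v.mean()), sd if sd > 0 else 1.0)
        return _zscore(data, name, scalers)

    cols, names = [np.ones(len(data))], ["const"]
    for t in spec.count_terms:
        zv = z(t.name)
        cols.append(zv)
        names.append(t.name)
        if t.form == "quadratic":
            cols.append(zv**2)
            names.append(f"{t.name}^2")
    for ctrl in spec.controls:
        if fit_scalers and ctrl not in levels:
            levels[ctrl] = sorted(pd.unique(data[ctrl]))
        for lv in levels[ctrl][1:]:
            cols.append((np.asarray(data[ctrl]) == lv).astype(float))
            names.append(f"{ctrl}[{lv}]")
    if spec.interaction is not None:
        zv = z(spec.interaction)
        for lv in levels["year"][1:]:
            cols.append(zv * (np.asarray(data["year"]) == lv))
            names.append(f"{spec.interaction}:year[{lv}]")
    X = np.column_stack(cols)
    # Small cruise sets can make month/year dummies (or interaction
    # columns) linearly dependent; prune dependent control columns so
    # the habitat terms themselves stay estimable.
    rank = np.linalg.matrix_rank(X) if fit_scalers else X.shape[1]
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        dependent = set(piv[rank:])
        protected = {i for i, nm in enumerate(names)
                     if nm == "const" or ("[" not in nm)}
        drop = sorted(dependent - protected)
        if drop:
            logger.info("dropping %d dependent control columns: %s",
                        len(drop), [names[i] for i in drop])
            keep = [i for i in range(X.shape[1]) if i not in drop]
            X = X[:, keep]
            names = [names[i] for i in keep]

    Z, z_names = None, []
    if spec.inflation_terms is not None:
        zcols, z_names = [np.ones(len(data))], ["const"]
        for name in spec.inflation_terms:
            zcols.append(z(name))
            z_names.append(name)
        Z = np.column_stack(zcols)

    y = np.asarray(data[spec.species] if spec.species in data else
                   data[f"count_{spec.species}"], dtype=np.int64) if response else None
    offset = np.log(np.asarray(data[spec.offset_col], dtype=float))
    return Design(y=y, X=X, Z=Z, offset=offset, x_names=names, z_names=z_names,
                  scalers=scalers, levels=levels)


# ----------------------------------------------------------- likelihood
def nb_logpmf(y, mu, alpha):
    """NB2 log pmf with mean mu and variance mu + alpha*mu^2."""
    a = 1.0 / alpha
    return (gammaln(y + a) - gammaln(a) - gammaln(y + 1)
            + a * (np.log(a) - np.log(a + mu))
            + y * (np.log(mu) - np.log(a + mu)))


def zinb_obs_loglik(params, y, X, Z, offset):
    """Per-observation ZINB log density (Z=None gives plain NB)."""
    p = X.shape[1]
    beta = params[:p]
    eta = X @ beta + offset
    mu = np.exp(eta)
    alpha = np.exp(params[-1])
    lnb = nb_logpmf(y, mu, alpha)
    if Z is None:
        return lnb
    gamma = params[p:-1]
    w = Z @ gamma
    # log pi = log_expit(w); log(1-pi) = log_expit(-w)
    out = log_expit(-w) + lnb
    zero = y == 0
    out[zero] = np.logaddexp(log_expit(w[zero]), log_expit(-w[zero]) + lnb[zero])
    return out


def zinb_loglik(params, y, X, Z, offset):
    """Total log likelihood; -inf for non-positive dispersion inputs."""
    if not np.all(np.isfinite(params)):
        return -np.inf
    return float(np.sum(zinb_obs_loglik(params, y, X, Z, offset)))


def _negloglik_grad(params, y, X, Z, offset):
    """(negative loglik, negative gradient) for the quasi-Newton fitter.

    The dispersion is parameterized as log(alpha), so the optimization
    is unconstrained and alpha > 0 is automatic.
    """
    p = X.shape[1]
    beta = params[:p]
    logalpha = params[-1]
    alpha = np.exp(logalpha)
    a = 1.0 / alpha
    eta = X @ beta + offset
    mu = np.exp(eta)
    lnb = nb_logpmf(y, mu, alpha)
    # d logNB / d eta and d logNB / d a
    dnb_deta = y - (a + y) * mu / (a + mu)
    dnb_da = (digamma(y + a) - digamma(a) + np.log(a) + 1.0
              - np.log(a + mu) - (a + y) / (a + mu))
    if Z is None:
        ll = np.sum(lnb)
        gbeta = X.T @ dnb_deta
        ga = np.sum(dnb_da)
        glogalpha = ga * (-a)  # da/dlogalpha = -a
        grad = np.concatenate([gbeta, [glogalpha]])
        return -ll, -grad
    gamma = params[p:-1]
    w = Z @ gamma
    pi = expit(w)
    zero = y == 0
    p0 = np.exp(a * (np.log(a) - np.log(a + mu)))  # NB(0)
    denom0 = pi + (1.0 - pi) * p0
    ll = np.sum(log_expit(-w)[~zero] + lnb[~zero]) + np.sum(np.log(denom0[zero]))
    # gradients
    deta = np.where(zero, (1.0 - pi) * p0 * (-a * mu / (a + mu)) / denom0, dnb_deta)
    dw = np.where(zero, pi * (1.0 - pi) * (1.0 - p0) / denom0, -pi)
    dlogp0_da = np.log(a) + 1.0 - np.log(a + mu) - a / (a + mu)
    da = np.where(zero, (1.0 - pi) * p0 * dlogp0_da / denom0, dnb_da)
    gbeta = X.T @ deta
    ggamma = Z.T @ dw
    glogalpha = np.sum(da) * (-a)
    grad = np.concatenate([gbeta, ggamma, [glogalpha]])
    return -ll, -grad


# ------------------------------------------------------------------ fits
@dataclass
class ZINBFit:
    """A fitted count model (ZINB, NB, or Poisson)."""

    spec: ModelSpec
    kind: str  # "zinb" | "nb" | "poisson"
    params: np.ndarray
    cov: np.ndarray
    llf: float
    n: int
    converged: bool
    x_names: list[str]
    z_names: list[str]
    scalers: dict
    levels: dict
    design: Design = field(repr=False, default=None)

    @property
    def beta(self):
        return self.params[: len(self.x_names)]

    @property
    def gamma(self):
        if self.kind != "zinb":
            return np.array([])
        return self.params[len(self.x_names):-1]

    @property
    def alpha(self):
        return float(np.exp(self.params[-1])) if self.kind != "poisson" else 0.0

    @property
    def bse(self):
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def pvalues(self) -> pd.Series:
        names = self.all_names
        se = self.bse
        with np.errstate(divide="ignore", invalid="ignore"):
            zv = self.params / np.where(se > 0, se, np.nan)
        return pd.Series(2 * stats.norm.sf(np.abs(zv)), index=names)

    @property
    def all_names(self):
        if self.kind == "zinb":
            return (self.x_names + [f"inflate:{n}" for n in self.z_names] + ["log_alpha"])
        if self.kind == "nb":
            return self.x_names + ["log_alpha"]
        return list(self.x_names)

    def obs_loglik(self) -> np.ndarray:
        d = self.design
        if self.kind == "poisson":
            mu = np.exp(d.X @ self.params + d.offset)
            return stats.poisson.logpmf(d.y, mu)
        Z = d.Z if self.kind == "zinb" else None
        return zinb_obs_loglik(self.params, d.y, d.X, Z, d.offset)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "p": self.pvalues.to_numpy()
        }, index=self.all_names)


@dataclass
class TestResult:
    """Outcome of one model-comparison diagnostic."""

    name: str  # LR-alpha | Vuong | LR-nested | CV-F
    statistic: float
    df: float
    p_value: float
    preferred: str
    degenerate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _hessian_cov(fun, params, args):
    from statsmodels.tools.numdiff import approx_hess1
    H = approx_hess1(params, lambda th: fun(th, *args)[0])
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    # negative variances from numerical Hessians signal non-convergence
    return cov


def _poisson_start(y, X, offset):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=50)
        if np.all(np.isfinite(res.params)):
            return np.asarray(res.params)
    except Exception:  # pragma: no cover - defensive
        pass
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(np.mean(y) + 0.1) - np.mean(offset)
    return beta


def fit(spec: ModelSpec, data: pd.DataFrame, kind: str = "zinb",
        design: Design | None = None, maxiter: int = 500) -> ZINBFit:
    """Maximum-likelihood fit of the specified model.

    ``kind='zinb'`` fits the mixture; ``'nb'`` the plain negative
    binomial (inflation part ignored); ``'poisson'`` a Poisson GLM.
    Non-convergence is flagged on the result, never silent.
    """
    d = design if design is not None else build_design(spec, data)
    y, X, offset = d.y, d.X, d.offset
    n, p = X.shape
    if n < 10 * (p + (d.Z.shape[1] if (kind == "zinb" and d.Z is not None) else 0) + 1):
        logger.warning("few observations (%d) for the number of parameters", n)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("count design matrix is rank deficient")

    if kind == "poisson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(maxiter=200)
        llf = float(np.sum(stats.poisson.logpmf(y, np.exp(X @ res.params + offset))))
        return ZINBFit(spec=spec, kind="poisson", params=np.asarray(res.params),
                       cov=np.asarray(res.cov_params()), llf=llf, n=n,
                       converged=bool(res.converged), x_names=d.x_names, z_names=[],
                       scalers=d.scalers, levels=d.levels, design=d)

    beta0 = _poisson_start(y, X, offset)
    Z = d.Z if kind == "zinb" else None
    if kind == "zinb":
        if Z is None:
            raise ValueError("ZINB fit requires an inflation design")
        zero_frac = float(np.mean(y == 0))
        g0 = np.zeros(Z.shape[1])
        g0[0] = np.log(max(zero_frac, 0.05) / max(1 - zero_frac, 0.05))
        # structural zeros are only part of the observed zeros
        g0[0] -= 1.0
        start = np.concatenate([beta0, g0, [0.0]])
    else:
        start = np.concatenate([beta0, [0.0]])

    args = (y, X, Z, offset)
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        s = start if attempt == 0 else start + rng.normal(0, 0.2 * (attempt), len(start))
        res = optimize.minimize(_negloglik_grad, s, args=args, jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun - 1e-9):
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun + 1e-9 else best
            break
    params = np.asarray(best.x)
    llf = -float(best.fun)
    converged = bool(best.success and np.isfinite(llf))
    if not converged:
        logger.warning("%s fit for %s did not converge: %s", kind, spec.species, best.message)
    cov = _hessian_cov(_negloglik_grad, params, args)
    # perfect separation in the inflation part shows up as huge gamma SEs
    if kind == "zinb":
        gse = np.sqrt(np.clip(np.diag(cov), 0, None))[X.shape[1]:-1]
        if np.any(~np.isfinite(gse)) or np.any(np.abs(params[X.shape[1]:-1]) > 15):
            logger.warning("possible separation in inflation part for %s", spec.species)
            converged = False
    return ZINBFit(spec=spec, kind=kind, params=params, cov=cov, llf=llf, n=n,
                   converged=converged, x_names=d.x_names,
                   z_names=d.z_names if kind == "zinb" else [],
                   scalers=d.scalers, levels=d.levels, design=d)


def predict_mean(fit_: ZINBFit, data: pd.DataFrame, area_km2: float | np.ndarray = 1.0):
    """Expected count at the given exposure: (1-pi)*exp(x'beta + log area).

    For an NB/Poisson fit the expectation is exp(x'beta + log area).
    """
    spec = fit_.spec
    d = build_design(spec, data.assign(**{spec.offset_col: area_km2}),
                     scalers=fit_.scalers, levels=fit_.levels, response=False)
    if d.x_names != fit_.x_names:  # training pruned dependent controls
        idx = [d.x_names.index(nm) for nm in fit_.x_names]
        X = d.X[:, idx]
    else:
        X = d.X
    mu = np.exp(X @ fit_.beta + d.offset)
    if fit_.kind != "zinb":
        return mu
    pi = expit(d.Z @ fit_.gamma)
    return (1.0 - pi) * mu


# ------------------------------------------------------------------ tests
def _check_same_data(a: ZINBFit, b: ZINBFit):
    if a.n != b.n or not np.array_equal(a.design.y, b.design.y):
        raise ValueError("model comparison requires identical observations")


def lr_test_alpha(nb_fit: ZINBFit, poisson_fit: ZINBFit) -> TestResult:
    """Boundary-corrected LR test of overdispersion (NB over Poisson).

    Under H0 (alpha = 0, on the boundary) the LR statistic is a 50:50
    mixture of a point mass at 0 and chi-square(1); p = 0.5 at statistic
    0 and 0.5 * P(chi2_1 > stat) otherwise.
    """
    _check_same_data(nb_fit, poisson_fit)
    stat = max(0.0, 2.0 * (nb_fit.llf - poisson_fit.llf))
    p = 0.5 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, 1))
    return TestResult(name="LR-alpha", statistic=stat, df=1, p_value=p,
                      preferred="nb" if p < 0.05 else "poisson")


def vuong_test(zinb_fit: ZINBFit, nb_fit: ZINBFit) -> TestResult:
    """Vuong's non-nested test: per-observation log density ratios
    m_i = log f_zinb(y_i) - log f_nb(y_i); V = sqrt(n) * mean(m)/sd(m).
    Positive V favours the zero-inflated model; one-sided p reported."""
    _check_same_data(zinb_fit, nb_fit)
    m = zinb_fit.obs_loglik() - nb_fit.obs_loglik()
    sd = float(np.std(m, ddof=1))
    n = len(m)
    if sd < 1e-12:
        return TestResult(name="Vuong", statistic=0.0, df=n, p_value=0.5,
                          preferred="nb", degenerate=True)
    v = float(np.sqrt(n) * np.mean(m) / sd)
    p = float(stats.norm.sf(v))
    return TestResult(name="Vuong", statistic=v, df=n, p_value=p,
                      preferred="zinb" if p < 0.05 else "nb")


def vif_screen(data: pd.DataFrame, covariates: list[str], threshold: float = 10.0):
    """Variance inflation factors: VIF_j = 1/(1-R2_j) from regressing
    covariate j on the others.  Returns (Series of VIFs, pass flag)."""
    if len(covariates) < 3:
        raise ValueError("VIF screen needs at least 3 covariates")
    Xall = data[covariates].astype(float).to_numpy()
    if len(Xall) <= len(covariates):
        raise ValueError("need more observations than covariates")
    vifs = {}
    for j, name in enumerate(covariates):
        yj = Xall[:, j]
        Xj = np.column_stack([np.ones(len(Xall)), np.delete(Xall, j, axis=1)])
        bhat, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ bhat
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0 or ss_res / ss_tot < 1e-12:
            vifs[name] = np.inf
        else:
            vifs[name] = 1.0 / (ss_res / ss_tot)
    s = pd.Series(vifs)
    return s, bool((s < threshold).all())


def _droppable_pvalues(f: ZINBFit) -> dict[str, float]:
    """Map count-part term name -> decision p-value: quadratic terms are
    judged on the squared coefficient (it drops before its linear
    partner); linear terms on their own coefficient."""
    pv = f.pvalues
    out = {}
    for t in f.spec.count_terms:
        out[t.name] = float(pv[f"{t.name}^2"]) if t.form == "quadratic" else float(pv[t.name])
    return out


def backward_stepwise(spec: ModelSpec, data: pd.DataFrame, level: float = 0.05,
                      kind: str = "nb") -> tuple[ModelSpec, ZINBFit]:
    """Manual backward stepwise simplification at the given level.

    Each iteration refits and removes the single term with the largest
    p-value above ``level`` (a quadratic component drops before its
    linear partner; month/year controls are never candidates).  Ties are
    broken by dropping the term whose removal loses the least log
    likelihood.  Returns the reduced spec and its fit.
    """
    current = spec
    f = fit(current, data, kind=kind)
    while current.count_terms:
        pvals = _droppable_pvalues(f)
        worst_p = max(pvals.values())
        if worst_p <= level:
            break
        candidates = [n for n, p in pvals.items() if np.isclose(p, worst_p, atol=1e-12)]
        if len(candidates) == 1:
            drop = candidates[0]
        else:  # tie: drop the term costing the least likelihood
            losses = {}
            for name in candidates:
                losses[name] = fit(current.drop_term(name), data, kind=kind).llf
            drop = max(losses, key=losses.get)
        current = current.drop_term(drop)
        f = fit(current, data, kind=kind)
    if not current.count_terms:
        warnings.warn(f"{spec.species}: no habitat terms survive stepwise selection; "
                      "returning intercept + controls model")
    return current, f


def select_detection_terms(spec: ModelSpec, data: pd.DataFrame,
                           level: float = 0.05) -> tuple[ModelSpec, ZINBFit]:
    """Backward selection of the inflation-part detection covariates in
    the ZINB model: refit and drop the least significant detection term
    until all retained ones hold the 0.05 level."""
    current = spec
    f = fit(current, data, kind="zinb")
    while current.inflation_terms:
        pv = f.pvalues
        infl = {n: float(pv[f"inflate:{n}"]) for n in current.inflation_terms}
        worst = max(infl, key=infl.get)
        if infl[worst] <= level:
            break
        current = replace(current, inflation_terms=tuple(
            n for n in current.inflation_terms if n != worst))
        f = fit(current, data, kind="zinb")
    return current, f


def select_interaction(spec: ModelSpec, data: pd.DataFrame, level: float = 0.05,
                       kind: str = "zinb") -> tuple[ModelSpec, ZINBFit, list[TestResult]]:
    """Try a year x covariate interaction for each significant
    oceanographic covariate in the spec; keep the one with the largest
    significant LR statistic, or none."""
    base_fit = fit(spec, data, kind=kind)
    ocean = [t.name for t in spec.count_terms if t.name in OCEANOGRAPHIC]
    results: list[TestResult] = []
    best: tuple[float, ModelSpec, ZINBFit] | None = None
    year_counts = data["year"].value_counts()
    for cov in ocean:
        if (year_counts < 2).any():
            warnings.warn(f"year level with <2 observations: skipping {cov} x year")
            continue
        cand = replace(spec, interaction=cov)
        try:
            cf = fit(cand, data, kind=kind)
        except ValueError:
            continue
        df = len(cf.params) - len(base_fit.params)
        stat = max(0.0, 2.0 * (cf.llf - base_fit.llf))
        p = float(stats.chi2.sf(stat, df))
        results.append(TestResult(name="LR-nested", statistic=stat, df=df, p_value=p,
                                  preferred=f"{cov}:year" if p < level else "base"))
        if p < level and (best is None or stat > best[0]):
            best = (stat, cand, cf)
    if best is None:
        return spec, base_fit, results
    return best[1], best[2], results


def cross_validate(spec: ModelSpec, data: pd.DataFrame, folds: int = 10,
                   kind: str = "zinb", seed: int = 0) -> TestResult:
    """n-fold cross-validation of model fit.

    Observations are randomly split into ``folds`` mutually exclusive
    subsets; each is predicted from a model fitted on the others, and
    observed counts are regressed on the out-of-fold predictions.  The
    regression F(1, n-2) statistic and its p-value summarize predictive
    skill."""
    n = len(data)
    if folds < 2 or folds > n:
        raise ValueError("need 2 <= folds <= n")
    rng = np.random.default_rng(seed)
    assign = rng.permutation(np.arange(n) % folds)
    pred = np.full(n, np.nan)
    skipped = 0
    for k in range(folds):
        test = assign == k
        train = ~test
        try:
            f = fit(spec, data.loc[train], kind=kind)
        except ValueError:
            skipped += 1
            continue
        if not f.converged:
            skipped += 1
            logger.warning("fold %d fit non-convergent; skipped", k)
            continue
        pred[test] = predict_mean(f, data.loc[test],
                                  area_km2=data.loc[test, spec.offset_col].to_numpy())
    ok = np.isfinite(pred)
    y = np.asarray(data[f"count_{spec.species}"] if f"count_{spec.species}" in data
                   else data[spec.species], dtype=float)[ok]
    res = sm.OLS(y, sm.add_constant(pred[ok])).fit()
    return TestResult(name="CV-F", statistic=float(res.fvalue), df=float(res.df_resid),
                      p_value=float(res.f_pvalue),
                      preferred="predictive" if res.f_pvalue < 0.05 else "null",
                      degenerate=skipped > 0)
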