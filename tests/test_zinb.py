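"""Likelihood oracles, fitting, and the model-comparison battery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit, gammaln

from seabirdmsp import zinb as Z


# ----------------------------------------------------------- helpers
def _frame(rng, n, beta=(0.3, 0.4, -0.3), gamma=(-0.2, 0.5), alpha=0.8, pi_off=None):
    """Simulated ZINB data with one inflation covariate and exposure."""
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    z1 = rng.normal(size=n)
    area = rng.uniform(0.1, 0.9, n)
    mu = np.exp(beta[0] + beta[1] * x1 + beta[2] * x2 + np.log(area))
    size = 1.0 / alpha
    y = rng.negative_binomial(size, size / (size + mu))
    if pi_off is None:
        pi = expit(gamma[0] + gamma[1] * z1)
        y = np.where(rng.uniform(size=n) < pi, 0, y)
    return pd.DataFrame({"count_SP": y, "x1": x1, "x2": x2, "z1": z1,
                         "area_km2": area, "month": 5, "year": 2004})


SPEC = Z.ModelSpec(species="SP", count_terms=(Z.Term("x1"), Z.Term("x2")),
                   inflation_terms=("z1",), controls=())
SPEC_NB = Z.ModelSpec(species="SP", count_terms=(Z.Term("x1"), Z.Term("x2")),
                      inflation_terms=(), controls=())


# --------------------------------------------------------- likelihood
def test_single_zero_observation_closed_form():
    """pi=0.5 and NB(0)=0.2 give density 0.6, log = -0.5108."""
    y = np.array([0])
    X = np.ones((1, 1))
    Zm = np.ones((1, 1))
    off = np.zeros(1)
    # choose mu so that NB(0) = 0.2 at alpha = 1: 1/(1+mu) = 0.2 -> mu = 4
    params = np.array([np.log(4.0), 0.0, 0.0])  # beta, gamma (pi=0.5), log alpha=0
    ll = Z.zinb_loglik(params, y, X, Zm, off)
    assert ll == pytest.approx(np.log(0.5 + 0.5 * 0.2), abs=1e-12)


def test_vectorized_loglik_equals_naive_sum_over_random_draws(rng):
    """The vectorized likelihood equals naive per-observation summation
    to 1e-10 across 100 random parameter vectors."""
    n = 60
    d = _frame(rng, n)
    y = d["count_SP"].to_numpy()
    X = np.column_stack([np.ones(n), d["x1"], d["x2"]])
    Zm = np.column_stack([np.ones(n), d["z1"]])
    off = np.log(d["area_km2"].to_numpy())
    for _ in range(100):
        th = rng.normal(0, 0.7, 6)
        b, g, la = th[:3], th[3:5], th[5]
        a = 1.0 / np.exp(la)
        total = 0.0
        for i in range(n):
            mu = np.exp(X[i] @ b + off[i])
            pi = 1.0 / (1.0 + np.exp(-(Zm[i] @ g)))
            nb = np.exp(gammaln(y[i] + a) - gammaln(a) - gammaln(y[i] + 1)) \
                * (a / (a + mu)) ** a * (mu / (a + mu)) ** y[i]
            dens = pi + (1 - pi) * nb if y[i] == 0 else (1 - pi) * nb
            total += np.log(dens)
        assert Z.zinb_loglik(th, y, X, Zm, off) == pytest.approx(total, abs=1e-10)


def test_analytic_gradient_matches_numerical(rng):
    n = 80
    d = _frame(rng, n)
    y = d["count_SP"].to_numpy()
    X = np.column_stack([np.ones(n), d["x1"], d["x2"]])
    Zm = np.column_stack([np.ones(n), d["z1"]])
    off = np.log(d["area_km2"].to_numpy())
    th = np.array([0.2, 0.3, -0.1, 0.1, 0.3, np.log(0.6)])
    f = lambda t: Z._negloglik_grad(t, y, X, Zm, off)[0]
    num = approx_fprime(th, f, 1e-6)
    ana = Z._negloglik_grad(th, y, X, Zm, off)[1]
    assert np.abs(num - ana).max() < 1e-3


def test_inflation_sent_to_zero_recovers_plain_nb_loglik(rng):
    """gamma -> -inf (pi -> 0) collapses the mixture onto plain NB."""
    n = 50
    d = _frame(rng, n)
    y = d["count_SP"].to_numpy()
    X = np.column_stack([np.ones(n), d["x1"], d["x2"]])
    Zm = np.ones((n, 1))
    off = np.log(d["area_km2"].to_numpy())
    beta = np.array([0.3, 0.4, -0.3])
    la = np.log(0.8)
    ll_zinb = Z.zinb_loglik(np.concatenate([beta, [-40.0], [la]]), y, X, Zm, off)
    ll_nb = float(Z.nb_logpmf(y, np.exp(X @ beta + off), 0.8).sum())
    assert ll_zinb == pytest.approx(ll_nb, abs=1e-8)


def test_loglik_agrees_with_statsmodels_zinb(rng):
    """Independent implementation cross-check: statsmodels' ZINB (NB2)
    likelihood evaluated at our MLE equals our likelihood there."""
    import statsmodels.discrete.count_model as cm

    d = _frame(rng, 600)
    fit = Z.fit(SPEC, d)
    des = fit.design
    model = cm.ZeroInflatedNegativeBinomialP(
        des.y, des.X, exog_infl=des.Z, offset=des.offset, p=2)
    # statsmodels parameter order: inflation, count, alpha (not log alpha)
    sm_params = np.concatenate([fit.gamma, fit.beta, [fit.alpha]])
    assert model.loglike(sm_params) == pytest.approx(fit.llf, abs=1e-4)


# ----------------------------------------------------------- fitting
def test_fit_recovers_generating_parameters(rng):
    d = _frame(rng, 4000)
    fit = Z.fit(SPEC, d)
    assert fit.converged
    est = dict(zip(fit.all_names, fit.params))
    # design standardizes x by sample sd ~ 1
    assert est["x1"] == pytest.approx(0.4, abs=0.1)
    assert est["x2"] == pytest.approx(-0.3, abs=0.1)
    assert fit.alpha == pytest.approx(0.8, rel=0.35)


def test_fit_on_uninflated_data_drives_inflation_intercept_down(rng):
    d = _frame(rng, 3000, pi_off=True)  # pure NB data
    fit = Z.fit(SPEC, d)
    est = dict(zip(fit.all_names, fit.params))
    assert est["inflate:const"] < -1.0
    assert fit.alpha == pytest.approx(0.8, rel=0.4)


def test_refits_from_perturbed_starts_do_not_beat_optimum(rng):
    d = _frame(rng, 800)
    fit = Z.fit(SPEC, d)
    design = fit.design
    args = (design.y, design.X, design.Z, design.offset)
    from scipy.optimize import minimize

    better = 0
    for _ in range(20):
        s = fit.params + rng.normal(0, 0.5, len(fit.params))
        res = minimize(Z._negloglik_grad, s, args=args, jac=True, method="L-BFGS-B")
        if -res.fun > fit.llf + 1e-6:
            better += 1
    assert better <= 1  # >= 95% of restarts reach equal or worse likelihood


def test_offset_contract_doubling_area_doubles_predictions(rng):
    d = _frame(rng, 500)
    fit = Z.fit(SPEC, d)
    p1 = Z.predict_mean(fit, d, area_km2=d["area_km2"].to_numpy())
    p2 = Z.predict_mean(fit, d, area_km2=2.0 * d["area_km2"].to_numpy())
    assert np.allclose(p2, 2.0 * p1, rtol=1e-10)


def test_rank_deficient_habitat_design_rejected(rng):
    d = _frame(rng, 200)
    d["x2"] = d["x1"]  # duplicated habitat covariate
    with pytest.raises(ValueError, match="rank deficient"):
        Z.fit(SPEC, d)


# ------------------------------------------------------------- tests
def test_lr_alpha_zero_statistic_gives_half(rng):
    d = _frame(rng, 300)
    nb = Z.fit(SPEC_NB, d, kind="nb")
    fake = Z.fit(SPEC_NB, d, kind="nb")
    fake.llf = nb.llf  # identical log likelihoods
    res = Z.lr_test_alpha(nb, fake)
    assert res.statistic == 0.0 and res.p_value == 0.5


def test_lr_alpha_detects_overdispersion(rng):
    d = _frame(rng, 2000, alpha=1.0, pi_off=True)
    nb = Z.fit(SPEC_NB, d, kind="nb")
    po = Z.fit(SPEC_NB, d, kind="poisson")
    res = Z.lr_test_alpha(nb, po)
    assert res.p_value < 1e-6 and res.preferred == "nb"


def test_lr_alpha_requires_identical_data(rng):
    nb = Z.fit(SPEC_NB, _frame(rng, 300), kind="nb")
    po = Z.fit(SPEC_NB, _frame(rng, 301), kind="poisson")
    with pytest.raises(ValueError, match="identical"):
        Z.lr_test_alpha(nb, po)


def test_vuong_identical_models_degenerate(rng):
    d = _frame(rng, 300)
    nb = Z.fit(SPEC_NB, d, kind="nb")
    res = Z.vuong_test(nb, nb)
    assert res.statistic == 0.0 and res.p_value == 0.5 and res.degenerate


def test_vuong_prefers_zinb_under_strong_inflation(rng):
    d = _frame(rng, 2000, gamma=(0.0, 0.4))  # pi ~ 0.5
    zf = Z.fit(SPEC, d)
    nf = Z.fit(SPEC_NB, d, kind="nb")
    res = Z.vuong_test(zf, nf)
    assert res.statistic > 0 and res.p_value < 0.05 and res.preferred == "zinb"


# ---------------------------------------------------------------- VIF
def test_vif_orthogonal_covariates_near_one(rng):
    n = 5000
    d = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    vifs, ok = Z.vif_screen(d, ["a", "b", "c"])
    assert ok and np.allclose(vifs, 1.0, atol=0.05)


def test_vif_duplicated_covariate_infinite(rng):
    d = pd.DataFrame({"a": rng.normal(size=100)})
    d["b"] = d["a"]
    d["c"] = rng.normal(size=100)
    vifs, ok = Z.vif_screen(d, ["a", "b", "c"])
    assert not ok and np.isinf(vifs["a"]) and np.isinf(vifs["b"])


def test_vif_correlated_pair_matches_closed_form(rng):
    """Correlation 0.95 implies VIF ~ 1/(1-0.95^2) ~ 10.26 > 10."""
    n = 200_000
    a = rng.normal(size=n)
    b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=n)
    d = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})
    vifs, ok = Z.vif_screen(d, ["a", "b", "c"])
    assert not ok
    assert vifs["a"] == pytest.approx(1.0 / (1 - 0.95**2), rel=0.05)


# ----------------------------------------------------------- stepwise
def test_stepwise_retains_true_effect_and_drops_nulls(rng):
    """Only x1 has a true effect; x2/x3 are null and should drop."""
    n = 3000
    x1, x2, x3 = rng.normal(size=(3, n))
    area = rng.uniform(0.1, 0.9, n)
    mu = np.exp(0.5 + 0.8 * x1 + np.log(area))
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    d = pd.DataFrame({"count_SP": y, "x1": x1, "x2": x2, "x3": x3,
                      "area_km2": area, "month": 5, "year": 2004})
    spec = Z.ModelSpec(species="SP", inflation_terms=(), controls=(),
                       count_terms=(Z.Term("x1"), Z.Term("x2"), Z.Term("x3")))
    reduced, f = Z.backward_stepwise(spec, d, kind="nb")
    names = {t.name for t in reduced.count_terms}
    assert "x1" in names
    assert all(float(f.pvalues[t.name]) <= 0.05 for t in reduced.count_terms)


def test_stepwise_single_significant_covariate_is_identity(rng):
    n = 2000
    x1 = rng.normal(size=n)
    area = rng.uniform(0.1, 0.9, n)
    mu = np.exp(0.5 + 0.9 * x1 + np.log(area))
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    d = pd.DataFrame({"count_SP": y, "x1": x1, "area_km2": area,
                      "month": 5, "year": 2004})
    spec = Z.ModelSpec(species="SP", count_terms=(Z.Term("x1"),),
                       inflation_terms=(), controls=())
    reduced, _ = Z.backward_stepwise(spec, d, kind="nb")
    assert reduced.count_terms == spec.count_terms


def test_stepwise_null_covariate_retained_at_about_level(rng):
    """Each null covariate survives with probability ~ the 0.05 level."""
    retained = 0
    trials = 40
    n_cov = 3
    for t in range(trials):
        n = 600
        X = rng.normal(size=(n, n_cov))
        area = rng.uniform(0.1, 0.9, n)
        mu = np.exp(0.3 + np.log(area))
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        d = pd.DataFrame({"count_SP": y, "area_km2": area, "month": 5, "year": 2004})
        for j in range(n_cov):
            d[f"x{j}"] = X[:, j]
        spec = Z.ModelSpec(species="SP", inflation_terms=(), controls=(),
                           count_terms=tuple(Z.Term(f"x{j}") for j in range(n_cov)))
        reduced, _ = Z.backward_stepwise(spec, d, kind="nb")
        retained += len(reduced.count_terms)
    rate = retained / (trials * n_cov)
    # binomial 99.9% band around 0.05 with 120 draws
    assert rate < 0.14


def test_quadratic_drops_before_its_linear_partner():
    spec = Z.ModelSpec(species="SP", count_terms=(Z.Term("x1", "quadratic"),),
                       inflation_terms=())
    dropped = spec.drop_term("x1")
    assert dropped.count_terms == (Z.Term("x1", "linear"),)


# -------------------------------------------------------- interaction
def test_no_oceanographic_covariate_means_no_interaction(rng):
    d = _frame(rng, 600)
    spec = Z.ModelSpec(species="SP", count_terms=(Z.Term("x1"),),
                       inflation_terms=("z1",), controls=())
    out, fit, tests = Z.select_interaction(spec, d)
    assert out.interaction is None and tests == []


def test_year_varying_sst_slope_selects_interaction(rng):
    n = 3000
    sst = rng.normal(size=n)
    year = rng.choice([2004, 2005, 2006], n)
    slope = {2004: -0.5, 2005: 0.2, 2006: 0.8}
    area = rng.uniform(0.1, 0.9, n)
    mu = np.exp(0.4 + np.vectorize(slope.get)(year) * sst + np.log(area))
    y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
    d = pd.DataFrame({"count_SP": y, "sst": sst, "year": year, "month": 5,
                      "area_km2": area})
    spec = Z.ModelSpec(species="SP", count_terms=(Z.Term("sst"),),
                       inflation_terms=(), controls=("year",))
    out, fit, tests = Z.select_interaction(spec, d, kind="nb")
    assert out.interaction == "sst"
    assert any(t.p_value < 0.05 for t in tests)


# ---------------------------------------------------------------- CV
def test_cross_validation_leave_one_out_partitions(rng):
    d = _frame(rng, 120)
    res = Z.cross_validate(SPEC_NB, d, folds=len(d), kind="nb", seed=0)
    assert res.name == "CV-F"
    assert np.isfinite(res.statistic)


def test_cross_validation_detects_true_signal(rng):
    d = _frame(rng, 2000, beta=(0.3, 0.9, -0.6))
    res = Z.cross_validate(SPEC, d, folds=10, kind="zinb", seed=1)
    assert res.p_value < 0.05 and res.preferred == "predictive"


def test_cross_validation_fold_bounds(rng):
    d = _frame(rng, 50)
    with pytest.raises(ValueError):
        Z.cross_validate(SPEC_NB, d, folds=1, kind="nb")
    with pytest.raises(ValueError):
        Z.cross_validate(SPEC_NB, d, folds=51, kind="nb")
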