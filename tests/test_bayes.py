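import numpy as np
import pytest
from scipy import stats

from resurvey import bayes, errors


def _chains(**kw):
    defaults = dict(chains=2, draws=500, warmup=500)
    defaults.update(kw)
    return defaults


# ---- univariate Gibbs sampler --------------------------------------------

def test_noiseless_line_recovers_slope():
    x = np.linspace(0, 1, 40)
    y = 1.0 + 2.0 * x + np.random.default_rng(0).normal(0, 1e-3, 40)
    X = np.column_stack([np.ones(40), x])
    fit = bayes.fit_normal_lm(y, X, coef_names=["a", "b"], seed=1, **_chains())
    slope = fit.get("b")
    assert abs(slope.mean() - 2.0) < 3 * slope.std()


def test_intercept_only_matches_conjugate_closed_form():
    """Posterior mean of the intercept against the exact conjugate formula
    (known sigma^2: here we fix a very tight variance prior instead)."""
    rng = np.random.default_rng(2)
    y = rng.normal(5.0, 1.0, 50)
    X = np.ones((50, 1))
    prior = bayes.Priors(
        coef_mean=np.array([0.0]),
        coef_sd=np.array([10.0]),
        sigma2_shape=500.0,  # pins sigma^2 ~ 1
        sigma2_scale=500.0,
    )
    fit = bayes.fit_normal_lm(y, X, coef_names=["mu"], priors=prior, seed=3,
                              **_chains())
    # conjugate posterior with sigma^2 = 1: precision n + 1/100
    post_mean = y.sum() / (len(y) + 0.01)
    mu = fit.get("mu")
    assert mu.mean() == pytest.approx(post_mean, abs=4 * mu.std() / np.sqrt(200))


def test_data_free_fit_samples_the_prior():
    """With no observations the Gibbs chain reproduces the prior (KS < 0.1)."""
    prior = bayes.Priors(
        coef_mean=np.array([1.0]),
        coef_sd=np.array([2.0]),
        sigma2_shape=3.0,
        sigma2_scale=2.0,
    )
    fit = bayes.fit_normal_lm(
        np.empty(0), np.empty((0, 1)), coef_names=["b"], priors=prior,
        chains=2, draws=2000, warmup=100, seed=4,
    )
    ks_b = stats.kstest(fit.get("b"), stats.norm(1.0, 2.0).cdf).statistic
    ks_s2 = stats.kstest(
        fit.get("sigma") ** 2, stats.invgamma(3.0, scale=2.0).cdf
    ).statistic
    assert ks_b < 0.1 and ks_s2 < 0.1


def test_sampler_determinism():
    rng = np.random.default_rng(5)
    y = rng.normal(size=30)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    a = bayes.fit_normal_lm(y, X, seed=42, **_chains(draws=100, warmup=50))
    b = bayes.fit_normal_lm(y, X, seed=42, **_chains(draws=100, warmup=50))
    np.testing.assert_array_equal(a.draws, b.draws)
    np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)


def test_rank_deficient_design_rejected():
    y = np.zeros(10)
    X = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(errors.DesignError):
        bayes.fit_normal_lm(y, X, seed=0)


def test_random_intercept_shrinks_residual_sd():
    rng = np.random.default_rng(6)
    G = 30
    u = rng.normal(0, 1.0, G)
    groups = np.repeat(np.arange(G), 2)
    y = 2.0 + u[groups] + rng.normal(0, 0.3, 2 * G)
    X = np.ones((2 * G, 1))
    fit = bayes.fit_normal_lm(y, X, coef_names=["mu"], groups=groups, seed=7,
                              **_chains())
    assert fit.get("sigma").mean() < 0.6  # near 0.3, far below total sd ~1.05
    assert fit.get("tau").mean() > 0.6


# ---- multivariate hierarchical model --------------------------------------

def _mv_data(seed, G=60, time_effect_c=-0.5, rho=0.6):
    rng = np.random.default_rng(seed)
    n = 2 * G
    plot = np.repeat(np.arange(G), 2)
    t = np.tile([0.0, 1.0], G)
    infert = np.repeat((np.arange(G) >= G // 2).astype(float), 2)
    X = np.column_stack([np.ones(n), t, infert, t * infert])
    B = np.array([
        [0.3, -0.2],
        [time_effect_c, 0.4],   # fertile time effects on (logitC, logitS)
        [-0.5, 0.4],
        [-time_effect_c, -0.4],  # cancels the time effect for infertile
    ])
    cov_e = np.array([[0.09, rho * 0.09], [rho * 0.09, 0.09]])
    U = rng.multivariate_normal([0, 0], np.diag([0.04, 0.04]), size=G)
    E = rng.multivariate_normal([0, 0], cov_e, size=n)
    return X @ B + U[plot] + E, X, plot


def test_mv_single_period_not_identifiable():
    Y = np.zeros((4, 2))
    X = np.ones((4, 1))
    with pytest.raises(errors.DesignError):
        bayes.fit_mv_hierarchical(Y, X, groups=np.arange(4), seed=0)


def test_mv_null_time_effect_covered():
    hits = 0
    for seed in range(5):
        Y, X, plot = _mv_data(seed, time_effect_c=0.0)
        fit = bayes.fit_mv_hierarchical(
            Y, X, plot, coef_names=["Intercept", "time", "infertile", "ti"],
            chains=1, draws=400, warmup=300, seed=seed,
        )
        t = fit.get("logitC:time")
        lo, hi = np.percentile(t, [2.5, 97.5])
        hits += lo <= 0.0 <= hi
    assert hits >= 4


def test_mv_recovers_residual_correlation():
    Y, X, plot = _mv_data(11, G=100, rho=0.6)
    fit = bayes.fit_mv_hierarchical(
        Y, X, plot, chains=2, draws=500, warmup=500, seed=1
    )
    assert 0.4 <= fit.get("cor_e").mean() <= 0.8


def test_mv_determinism():
    Y, X, plot = _mv_data(1, G=20)
    a = bayes.fit_mv_hierarchical(Y, X, plot, chains=1, draws=50, warmup=50,
                                  seed=9)
    b = bayes.fit_mv_hierarchical(Y, X, plot, chains=1, draws=50, warmup=50,
                                  seed=9)
    np.testing.assert_array_equal(a.draws, b.draws)


# ---- PSIS-LOO -------------------------------------------------------------

def test_psis_identical_likelihoods_degenerate():
    L = np.full((1000, 8), -1.3)
    loo = bayes.psis_loo(L)
    np.testing.assert_allclose(loo.pointwise, -1.3, atol=1e-10)
    assert loo.n_high_k == 0


def test_psis_rejects_nonfinite():
    L = np.zeros((100, 3))
    L[5, 1] = np.inf
    with pytest.raises(errors.ValidationError, match="1"):
        bayes.psis_loo(L)


def test_psis_matches_arviz_smoothing():
    """Cross-check smoothed weights against the reference implementation."""
    import arviz as az

    rng = np.random.default_rng(0)
    L = stats.norm.logpdf(
        rng.normal(size=(2000, 10)), loc=rng.normal(size=10), scale=1.2
    )
    ours = bayes.psis_loo(L)
    lw_ref, k_ref = az.psislw(-L.T[:, None, :], reff=1.0)
    elpd_ref = float(
        np.sum(
            [np.logaddexp.reduce(lw_ref[i, 0] + L[:, i]) for i in range(10)]
        )
    )
    assert ours.elpd_loo == pytest.approx(elpd_ref, abs=0.1)
    np.testing.assert_allclose(ours.pareto_k, k_ref[:, 0], atol=0.12)


def _conjugate_normal_model(n=20, S=4000, seed=0, tau0=2.0, sigma0=1.0):
    """Normal-known-variance model: mu ~ N(0, tau0^2), y_i ~ N(mu, sigma0^2).

    Returns (y, posterior mu draws, loglik matrix)."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.7, sigma0, n)
    prec = n / sigma0**2 + 1 / tau0**2
    post_mean = y.sum() / sigma0**2 / prec
    mu = rng.normal(post_mean, np.sqrt(1 / prec), S)
    L = stats.norm.logpdf(y[None, :], loc=mu[:, None], scale=sigma0)
    return y, mu, L


def _exact_loo(y, tau0=2.0, sigma0=1.0):
    """Exact LOO predictive density by n conjugate refits."""
    n = len(y)
    total = 0.0
    pointwise = []
    for i in range(n):
        rest = np.delete(y, i)
        prec = len(rest) / sigma0**2 + 1 / tau0**2
        m = rest.sum() / sigma0**2 / prec
        pred_sd = np.sqrt(sigma0**2 + 1 / prec)
        lp = stats.norm.logpdf(y[i], m, pred_sd)
        pointwise.append(lp)
        total += lp
    return total, np.asarray(pointwise)


def test_psis_loo_matches_exact_loo_on_conjugate_model():
    y, mu, L = _conjugate_normal_model(n=20, S=4000, seed=1)
    loo = bayes.psis_loo(L)
    exact, _ = _exact_loo(y)
    assert abs(loo.elpd_loo - exact) <= 2 * loo.se_elpd


def test_psis_approaches_exact_loo_as_draws_grow():
    """Mean |PSIS - exact| over seeds shrinks as the draw count grows."""
    mean_errs = []
    for S in (1000, 4000, 16000):
        errs = []
        for seed in range(10):
            y, mu, L = _conjugate_normal_model(n=20, S=S, seed=seed)
            exact, _ = _exact_loo(y)
            errs.append(abs(bayes.psis_loo(L).elpd_loo - exact))
        mean_errs.append(np.mean(errs))
    assert mean_errs[2] < mean_errs[0]


def test_model_comparison_prefers_true_model():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 1.5 * x + rng.normal(0, 1.0, n)
        X1 = np.ones((n, 1))
        X2 = np.column_stack([np.ones(n), x])
        kw = dict(chains=1, draws=500, warmup=300)
        f1 = bayes.fit_normal_lm(y, X1, coef_names=["a"], seed=seed, **kw)
        f2 = bayes.fit_normal_lm(y, X2, coef_names=["a", "b"], seed=seed, **kw)
        l1 = bayes.psis_loo(f1.pointwise_loglik)
        l2 = bayes.psis_loo(f2.pointwise_loglik)
        hits += l2.elpd_loo >= l1.elpd_loo
    assert hits >= 9


def test_compare_models_duplicate_and_mismatch():
    _, _, L = _conjugate_normal_model()
    loo = bayes.psis_loo(L)
    table = bayes.compare_models([("m1", loo), ("m2", loo)])
    assert table.iloc[1]["d_elpd"] == 0.0
    assert table.iloc[1]["se_diff"] == 0.0
    short = bayes.psis_loo(L[:, :5])
    with pytest.raises(errors.ValidationError):
        bayes.compare_models([("m1", loo), ("m3", short)])


# ---- Bayesian R^2 ---------------------------------------------------------

def test_bayes_r2_limits():
    rng = np.random.default_rng(4)
    x = np.linspace(0, 1, 50)
    X = np.column_stack([np.ones(50), x])
    kw = dict(chains=1, draws=300, warmup=300)
    # near-noiseless: R^2 -> 1
    y = 2.0 + 3.0 * x + rng.normal(0, 1e-4, 50)
    fit = bayes.fit_normal_lm(y, X, coef_names=["a", "b"], seed=1, **kw)
    assert np.median(bayes.bayes_r2(fit, X)) > 0.99
    # intercept-only: fitted values constant, R^2 = 0 every draw
    fit0 = bayes.fit_normal_lm(y, np.ones((50, 1)), coef_names=["a"], seed=2,
                               **kw)
    r2 = bayes.bayes_r2(fit0, np.ones((50, 1)))
    assert np.max(r2) < 1e-12


def test_bayes_r2_in_unit_interval():
    rng = np.random.default_rng(8)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(0, 1.0, 40)
    X = np.column_stack([np.ones(40), x])
    fit = bayes.fit_normal_lm(y, X, seed=3, **_chains(draws=200, warmup=200))
    r2 = bayes.bayes_r2(fit, X)
    assert np.all((r2 >= 0) & (r2 <= 1))


# ---- orthogonal polynomial basis ------------------------------------------

def test_ortho_poly_orthonormal_and_deterministic():
    x = np.asarray([33.0, 34.0, 39.0, 42.0, 44.0, 56.0, 57.0, 45.0])
    B = bayes.ortho_poly(x, 2)
    G = B.T @ B / len(x)
    np.testing.assert_allclose(G, np.eye(2), atol=1e-9)
    np.testing.assert_array_equal(B, bayes.ortho_poly(x, 2))
    # degree-1 basis is monotone in x
    order = np.argsort(x)
    assert np.all(np.diff(B[order, 0]) > 0)
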