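"""Beta-regression likelihood, sampler, and posterior summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from nkassay import (BetaRegression, false_sign_rate, fold_change,
                     group_mean_draws, log_posterior, prepare_response,
                     sample_posterior, summarize)
from nkassay.inference import PosteriorDraws, RegressionData


# ---------------------------------------------------------------------------
# Response preparation
# ---------------------------------------------------------------------------

def test_prepare_response_clamps_and_counts():
    y, n = prepare_response([0.22, -0.046, 1.0], epsilon=0.005)
    assert y.tolist() == [0.22, 0.005, 0.995]
    assert n == 2
    y2, n2 = prepare_response([0.22], epsilon=0.005)
    assert n2 == 0
    with pytest.raises(ValueError):
        prepare_response([0.5], epsilon=0.1)


# ---------------------------------------------------------------------------
# Log-posterior
# ---------------------------------------------------------------------------

def _simple_data(y, groups=("a", "a", "b")):
    cat = pd.Categorical(groups)
    return RegressionData(np.asarray(y), cat.codes, tuple(cat.categories))


def test_uniform_beta_density_contributes_zero():
    """mu = 0.5, phi = 2 is the Beta(1,1) = uniform likelihood, so the
    posterior and the prior differ by exactly zero at any interior y."""
    data = RegressionData(np.array([0.37]), np.zeros(1, int), ("all",))
    theta = np.array([0.0, np.log(2.0)])  # logit(0.5) = 0
    with_lik = log_posterior(theta, data)
    prior_only = log_posterior(theta, data, likelihood=False)
    assert with_lik == pytest.approx(prior_only, abs=1e-12)


def test_log_posterior_matches_independent_computation():
    y = np.array([0.2, 0.3, 0.4])
    data = _simple_data(y)
    theta = np.array([-1.0, 0.4, 2.0])  # alpha, beta_b, log_phi

    def reference(th):
        alpha, beta_b, log_phi = th
        phi = np.exp(log_phi)
        mu = expit(np.array([alpha, alpha, alpha + beta_b]))
        ll = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi).sum()
        lp = (stats.norm.logpdf(alpha, 0, 2.5)
              + stats.norm.logpdf(beta_b, 0, 2.5)
              + stats.norm.logpdf(log_phi, 3, 1.5))
        return ll + lp

    theta2 = theta + np.array([0.3, -0.2, 0.5])
    delta_pkg = log_posterior(theta, data) - log_posterior(theta2, data)
    delta_ref = reference(theta) - reference(theta2)
    assert delta_pkg == pytest.approx(delta_ref, abs=1e-10)


def test_log_posterior_rejects_boundary_response():
    with pytest.raises(ValueError):
        _simple_data([0.2, 1.0, 0.4])


def test_posterior_mean_matches_grid_quadrature():
    """Intercept-only model on 3 observations: MCMC posterior mean of mu
    against dense 2-D quadrature over (alpha, log phi)."""
    y = np.array([0.2, 0.3, 0.25])
    data = RegressionData(y, np.zeros(3, int), ("all",))

    a = np.linspace(-6, 3, 451)
    f = np.linspace(-2, 9, 276)
    A, F = np.meshgrid(a, f, indexing="ij")
    mu, phi = expit(A), np.exp(F)
    lp = stats.norm.logpdf(A, 0, 2.5) + stats.norm.logpdf(F, 3, 1.5)
    for yi in y:
        lp = lp + stats.beta.logpdf(yi, mu * phi, (1 - mu) * phi)
    w = np.exp(lp - lp.max())
    grid_mean = float((w * mu).sum() / w.sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = sample_posterior(data, n_chains=2, n_warmup=800, n_kept=800,
                                thin=5, seed=5)
    mcmc_mean = group_mean_draws(post, "all").mean()
    assert abs(mcmc_mean - grid_mean) < 0.02


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def test_default_sampler_configuration():
    y = np.linspace(0.2, 0.4, 8)
    data = _simple_data(y, ["a", "b"] * 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = sample_posterior(data, seed=1)
    assert post.draws.shape == (4, 2500, 3)
    assert post.n_chains * post.n_kept == 10_000
    assert set(post.rhat) == {0, 1, 2}


def test_prior_only_sampling_matches_prior_quantiles():
    data = RegressionData(np.array([0.3, 0.4]), np.zeros(2, int), ("all",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = sample_posterior(data, n_chains=2, n_warmup=500, n_kept=1500,
                                thin=5, seed=6, prior_only=True)
    alpha = post.draws[..., 0].ravel()
    log_phi = post.draws[..., 1].ravel()
    assert alpha.mean() == pytest.approx(0.0, abs=0.2)
    assert alpha.std() == pytest.approx(2.5, abs=0.2)
    assert np.quantile(alpha, 0.975) == pytest.approx(1.96 * 2.5, abs=0.4)
    assert log_phi.mean() == pytest.approx(3.0, abs=0.15)
    assert log_phi.std() == pytest.approx(1.5, abs=0.15)


def test_posterior_recovers_simulated_mean(rng):
    mu_true, phi = 0.3, 60.0
    y = rng.beta(mu_true * phi, (1 - mu_true) * phi, size=50)
    data = RegressionData(y, np.zeros(50, int), ("all",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = sample_posterior(data, n_chains=2, n_warmup=800, n_kept=800,
                                thin=5, seed=7)
    med = np.median(group_mean_draws(post, "all"))
    assert med == pytest.approx(mu_true, abs=0.03)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_summarize_constant_vector():
    s = summarize(np.full(10, 3.2))
    assert (s.median, s.ci_low, s.ci_high) == (3.2, 3.2, 3.2)


def test_summarize_linear_interpolation_quantiles():
    s = summarize(np.arange(1.0, 101.0))
    assert s.median == pytest.approx(50.5)
    assert s.ci_low == pytest.approx(3.475)
    assert s.ci_high == pytest.approx(97.525)


def test_summarize_affine_equivariance(rng):
    d = rng.normal(size=500)
    s = summarize(d)
    s2 = summarize(2.5 * d + 1.0)
    assert s2.median == pytest.approx(2.5 * s.median + 1.0)
    assert s2.ci_low == pytest.approx(2.5 * s.ci_low + 1.0)
    assert s2.ci_high == pytest.approx(2.5 * s.ci_high + 1.0)


def test_false_sign_rate_cases():
    assert false_sign_rate([0.1, 0.5, 2.0]) == 0.0
    assert false_sign_rate([-2.0, -1.0, 1.0, 2.0]) == 0.5  # median exactly 0
    d = [-0.1, -0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
    assert false_sign_rate(d) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        false_sign_rate([])


# ---------------------------------------------------------------------------
# Group means and fold changes on hand-built draws
# ---------------------------------------------------------------------------

def _draws_from_group_means(pairs_of_means):
    """PosteriorDraws whose two group means take prescribed per-draw values
    (two groups, no pair effects)."""
    cat = pd.Categorical(["a", "b"])
    data = RegressionData(np.array([0.3, 0.3]), cat.codes,
                          tuple(cat.categories))
    rows = []
    for ma, mb in pairs_of_means:
        alpha = logit(ma)
        rows.append([alpha, logit(mb) - alpha, 2.0])
    draws = np.asarray(rows)[None, :, :]  # one chain
    return PosteriorDraws(draws=draws, param_names=data.param_names,
                          data=data, n_warmup=0, accept_rate=1.0)


def test_fold_change_on_hand_computed_draws():
    post = _draws_from_group_means([(0.25, 0.17), (0.27, 0.18)])
    fc = fold_change(post, ("a", "b"))
    assert fc.median == pytest.approx((0.25 / 0.17 + 0.27 / 0.18) / 2, abs=1e-9)
    assert fc.median == pytest.approx(1.4853, abs=1e-4)


def test_identical_groups_give_unit_fold_change():
    post = _draws_from_group_means([(0.2, 0.2), (0.31, 0.31)])
    fc = fold_change(post, ("a", "b"))
    assert fc.median == pytest.approx(1.0)
    assert fc.fsr == 0.5


def test_fold_change_of_reversed_contrast_is_reciprocal():
    post = _draws_from_group_means([(0.25, 0.17), (0.27, 0.18), (0.2, 0.3)])
    fwd = fold_change(post, ("a", "b")).draws
    rev = fold_change(post, ("b", "a")).draws
    assert np.allclose(fwd * rev, 1.0)


def test_group_mean_draws_single_pair_reduces_to_inverse_logit():
    post = _draws_from_group_means([(0.25, 0.17)])
    assert group_mean_draws(post, "a")[0] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        group_mean_draws(post, "zzz")


def test_pair_marginalization_obeys_jensen():
    """With pair effects +/-c the marginal group mean is the average of the
    two inverse-logits, strictly below the inverse-logit of the midpoint."""
    cat = pd.Categorical(["a", "a", "b", "b"])
    pairs = pd.Categorical(["p1", "p2", "p1", "p2"])
    data = RegressionData(np.full(4, 0.3), cat.codes, tuple(cat.categories),
                          pairs.codes, tuple(pairs.categories))
    c = 1.2
    # theta = [alpha, beta_b, gamma_p2, log_phi]; gamma_p1 = 0 by coding,
    # so center the pair effects at +/- c via alpha.
    theta = np.array([[[0.5 - (-c), 0.0, -2 * c, 2.0]]])
    post = PosteriorDraws(draws=theta, param_names=data.param_names,
                          data=data, n_warmup=0, accept_rate=1.0)
    got = group_mean_draws(post, "a")[0]
    want = 0.5 * (expit(0.5 + c) + expit(0.5 - c))
    assert got == pytest.approx(want, abs=1e-12)
    assert got < expit(0.5)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

def test_beta_regression_sklearn_contract():
    from sklearn.base import clone
    m = BetaRegression(n_warmup=300, n_draws=300, thin=2, random_state=0)
    m2 = clone(m)
    assert m2.get_params() == m.get_params()

    X = pd.DataFrame({"group": ["high"] * 5 + ["low"] * 5,
                      "pair": list("ABCDE") * 2})
    y = [0.25, 0.27, 0.24, 0.26, 0.25, 0.18, 0.17, 0.19, 0.18, 0.16]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(X, y)
    assert m.clamp_count_ == 0
    fc = m.fold_change(("high", "low"))
    assert fc.ci_low <= fc.median <= fc.ci_high
    assert 0.0 <= fc.fsr <= 0.5
    pred = m.predict(pd.DataFrame({"group": ["high", "low"]}))
    assert pred[0] > pred[1]


def test_beta_regression_requires_group_column():
    with pytest.raises(ValueError, match="group"):
        BetaRegression().fit(pd.DataFrame({"x": [1, 2]}), [0.2, 0.3])
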