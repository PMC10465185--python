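"""Bayesian Beta regression for killing proportions with a paired design.

Model: each observed proportion ``y_i`` (specific killing or spontaneous
death, squeezed into (0, 1)) follows

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i) = alpha + beta_{g(i)} + gamma_{p(i)}

with ``g(i)`` the group of interest (cell type, proliferative stratum, or
assay day) and ``p(i)`` the donor/sample pair; both use reference-level
coding (first level fixed at 0), and pair effects are fixed effects.  Priors
are weakly informative: Normal(0, 2.5) on the logit-scale coefficients and
Normal(3, 1.5) on ``log(phi)``.

Posteriors are summarized by the median and equal-tailed 95% credible
interval; uncertainty about an effect's direction is the false sign rate
(FSR) — the posterior mass on the side of zero opposite the median.  Group
contrasts are reported as per-draw fold changes between pair-marginalized
group means.

Sampling uses an adaptive random-walk Metropolis sampler initialized at the
posterior mode (Laplace proposal covariance), with split-R-hat convergence
diagnostics; the defaults (4 chains, 2500 warmup + 2500 kept draws) mirror
the usual HMC configuration for this model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

__all__ = [
    "prepare_response", "RegressionData", "log_posterior", "sample_posterior",
    "PosteriorDraws", "PosteriorSummary", "group_mean_draws", "fold_change",
    "false_sign_rate", "summarize", "BetaRegression",
]


def prepare_response(values, epsilon: float = 0.005) -> tuple[np.ndarray, int]:
    """Squeeze raw proportions (possibly negative or >= 1, e.g. negative
    specific-killing values) into the open interval required by the Beta
    likelihood.

    Values are clamped into ``[epsilon, 1 - epsilon]``; the number of clamped
    observations is returned alongside and should be logged.
    """
    if not 0.0 < epsilon < 0.05:
        raise ValueError("epsilon must lie in (0, 0.05)")
    y = np.asarray(values, dtype=float)
    clipped = np.clip(y, epsilon, 1.0 - epsilon)
    n_clamped = int((clipped != y).sum())
    return clipped, n_clamped


@dataclass
class RegressionData:
    """Design for one Beta-regression fit.

    ``y`` must already lie strictly inside (0, 1) (see
    :func:`prepare_response`); ``group_idx``/``pair_idx`` are integer codes
    into ``group_levels``/``pair_levels``, reference level 0.
    """

    y: np.ndarray
    group_idx: np.ndarray
    group_levels: tuple
    pair_idx: np.ndarray | None = None
    pair_levels: tuple = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.y <= 0.0) or np.any(self.y >= 1.0):
            raise ValueError("response values must lie strictly inside (0, 1)")
        if len(self.group_levels) < 1:
            raise ValueError("group factor needs at least 1 level")
        self.group_idx = np.asarray(self.group_idx, dtype=int)
        if self.pair_idx is not None:
            self.pair_idx = np.asarray(self.pair_idx, dtype=int)

    @classmethod
    def from_vectors(cls, y, group, pair=None, epsilon: float = 0.005):
        """Build from raw response values and categorical label vectors.
        Returns ``(data, n_clamped)``."""
        yy, n_clamped = prepare_response(y, epsilon)
        group = pd.Categorical(np.asarray(group).astype(str))
        if pair is not None:
            pairc = pd.Categorical(np.asarray(pair).astype(str))
            counts = pd.Series(pairc).value_counts()
            if (counts < 1).any():
                raise ValueError("every pair level needs >= 1 observation")
            data = cls(yy, group.codes, tuple(group.categories),
                       pairc.codes, tuple(pairc.categories))
        else:
            data = cls(yy, group.codes, tuple(group.categories))
        return data, n_clamped

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_levels)

    @property
    def n_params(self) -> int:
        # alpha + (G-1) group + (P-1) pair + log_phi
        return 1 + (self.n_groups - 1) + max(self.n_pairs - 1, 0) + 1

    @property
    def param_names(self) -> list:
        names = ["alpha"]
        names += [f"beta[{lv}]" for lv in self.group_levels[1:]]
        names += [f"gamma[{lv}]" for lv in self.pair_levels[1:]]
        names += ["log_phi"]
        return names

    def unpack(self, theta: np.ndarray):
        """Split a parameter vector into (alpha, beta_full, gamma_full,
        log_phi) with reference-level zeros prepended."""
        G, P = self.n_groups, self.n_pairs
        alpha = theta[..., 0]
        beta = np.concatenate(
            [np.zeros(theta.shape[:-1] + (1,)), theta[..., 1:G]], axis=-1
        )
        if P > 0:
            gamma = np.concatenate(
                [np.zeros(theta.shape[:-1] + (1,)), theta[..., G:G + P - 1]],
                axis=-1,
            )
        else:
            gamma = np.zeros(theta.shape[:-1] + (0,))
        log_phi = theta[..., -1]
        return alpha, beta, gamma, log_phi


def _beta_logpdf(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))


def log_posterior(theta, data: RegressionData, *,
                  prior_scale: float = 2.5,
                  prior_logphi_loc: float = 3.0,
                  prior_logphi_scale: float = 1.5,
                  likelihood: bool = True) -> float:
    """Unnormalized log-posterior of the Beta regression at one parameter
    point ``theta = [alpha, beta_1.., gamma_1.., log_phi]``."""
    theta = np.asarray(theta, dtype=float)
    alpha, beta, gamma, log_phi = data.unpack(theta)
    lp = (-0.5 * (alpha / prior_scale) ** 2
          - 0.5 * float(np.sum((beta[..., 1:] / prior_scale) ** 2))
          - 0.5 * float(np.sum((gamma[..., 1:] / prior_scale) ** 2))
          - 0.5 * ((log_phi - prior_logphi_loc) / prior_logphi_scale) ** 2)
    if likelihood:
        eta = alpha + beta[data.group_idx]
        if data.pair_idx is not None:
            eta = eta + gamma[data.pair_idx]
        mu = expit(eta)
        phi = np.exp(log_phi)
        lp = lp + float(np.sum(_beta_logpdf(data.y, mu, phi)))
    return float(lp)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """MCMC output: ``draws`` has shape (n_chains, n_kept, n_params)."""

    draws: np.ndarray
    param_names: list
    data: RegressionData
    n_warmup: int
    accept_rate: float
    rhat: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def flat(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.draws[..., j].reshape(-1)


def _split_rhat(draws: np.ndarray) -> dict:
    """Split-R-hat per parameter via arviz; draws (chains, kept, params)."""
    import arviz as az
    r = az.rhat(az.convert_to_dataset({"theta": draws}))["theta"].values
    return {j: float(r[j]) for j in range(draws.shape[-1])}


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h ** 2)
    return H


def _find_map(data, logpost_kw):
    """Posterior mode and Laplace covariance (inverse numeric Hessian)."""
    d = data.n_params
    x0 = np.zeros(d)
    x0[-1] = logpost_kw.get("prior_logphi_loc", 3.0)

    def nlp(t):
        return -log_posterior(t, data, **logpost_kw)

    res = optimize.minimize(nlp, x0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    cov = None
    try:
        H = _numeric_hessian(nlp, np.asarray(res.x, dtype=float))
        cov = np.linalg.inv(0.5 * (H + H.T))
        cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(d)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = None
    if cov is None or not np.all(np.isfinite(cov)):
        cov = np.asarray(res.hess_inv, dtype=float)
        cov = 0.5 * (cov + cov.T) + 1e-9 * np.eye(d)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = np.eye(d) * 0.01
    return np.asarray(res.x, dtype=float), cov


def sample_posterior(data: RegressionData, n_chains: int = 4,
                     n_warmup: int = 2500, n_kept: int = 2500,
                     seed=None, prior_only: bool = False,
                     rhat_threshold: float = 1.01, thin: int = 10,
                     **logpost_kw) -> PosteriorDraws:
    """Draw from the Beta-regression posterior with an adaptive random-walk
    Metropolis sampler.

    Each chain starts at a jittered posterior mode; during warmup the
    proposal covariance tracks the empirical covariance of the chain
    (scaled 2.38^2/d, seeded with the Laplace covariance at the mode) and a
    global step-size factor is tuned toward a 0.234 acceptance rate, then
    both are frozen.  ``thin`` internal steps are taken per kept draw to
    decorrelate the random walk, so each chain keeps ``n_kept`` draws from
    ``n_kept * thin`` post-warmup steps.  Split-R-hat is computed for every
    parameter; values above ``rhat_threshold`` attach a convergence warning
    (they do not raise).
    """
    logpost_kw = dict(logpost_kw)
    logpost_kw["likelihood"] = not prior_only
    d = data.n_params
    rng = np.random.default_rng(seed)

    if prior_only:
        theta_map = np.zeros(d)
        theta_map[-1] = logpost_kw.get("prior_logphi_loc", 3.0)
        cov0 = np.eye(d)
    else:
        theta_map, cov0 = _find_map(data, logpost_kw)
    base_scale = 2.38 ** 2 / d

    all_draws = np.empty((n_chains, n_kept, d))
    n_accept = 0
    chain_seeds = rng.integers(0, 2 ** 31 - 1, size=n_chains)
    for c in range(n_chains):
        crng = np.random.default_rng(chain_seeds[c])
        L = np.linalg.cholesky(cov0)
        theta = theta_map + 0.1 * (L @ crng.standard_normal(d))
        lp = log_posterior(theta, data, **logpost_kw)
        if not np.isfinite(lp):
            theta = theta_map.copy()
            lp = log_posterior(theta, data, **logpost_kw)
        log_lam = 0.0
        mean = theta.copy()
        m2 = cov0 * 1.0  # running scatter, seeded with the Laplace covariance
        for t in range(1, n_warmup + 1):
            step = np.exp(0.5 * log_lam) * np.sqrt(base_scale)
            prop = theta + step * (L @ crng.standard_normal(d))
            lp_prop = log_posterior(prop, data, **logpost_kw)
            acc = np.exp(min(0.0, lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
            if crng.random() < acc:
                theta, lp = prop, lp_prop
            log_lam += (acc - 0.234) / t ** 0.6
            delta = theta - mean
            mean += delta / (t + 1)
            m2 += np.outer(delta, theta - mean)
            if t % 250 == 0 and t >= max(100, 2 * d):
                cov_emp = m2 / t + 1e-9 * np.eye(d)
                try:
                    L = np.linalg.cholesky(cov_emp)
                except np.linalg.LinAlgError:
                    pass
        step = np.exp(0.5 * log_lam) * np.sqrt(base_scale)
        for t in range(n_kept):
            for _ in range(max(thin, 1)):
                prop = theta + step * (L @ crng.standard_normal(d))
                lp_prop = log_posterior(prop, data, **logpost_kw)
                acc = (np.exp(min(0.0, lp_prop - lp))
                       if np.isfinite(lp_prop) else 0.0)
                if crng.random() < acc:
                    theta, lp = prop, lp_prop
                    n_accept += 1
            all_draws[c, t] = theta

    rhat = _split_rhat(all_draws)
    out = PosteriorDraws(
        draws=all_draws,
        param_names=data.param_names,
        data=data,
        n_warmup=n_warmup,
        accept_rate=n_accept / (n_chains * n_kept * max(thin, 1)),
        rhat=rhat,
    )
    if out.rhat_max > rhat_threshold:
        warnings.warn(
            f"convergence warning: max split-R-hat = {out.rhat_max:.4f} "
            f"> {rhat_threshold}"
        )
    return out


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Median, equal-tailed 95% credible interval and (optionally) the false
    sign rate of an effect; ``draws`` keeps the per-draw values."""

    median: float
    ci_low: float
    ci_high: float
    fsr: float | None = None
    draws: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {"median": self.median, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "fsr": self.fsr}


def summarize(effect_draws) -> PosteriorSummary:
    """Median and equal-tailed (2.5%, 97.5%) interval, linear-interpolation
    quantiles."""
    d = np.asarray(effect_draws, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 draws")
    lo, med, hi = np.quantile(d, [0.025, 0.5, 0.975])
    return PosteriorSummary(float(med), float(lo), float(hi), draws=d)


def false_sign_rate(effect_draws) -> float:
    """Posterior support for an effect sign opposite to the median's sign.

    Ranges over [0, 0.5]; a median of exactly 0 returns total sign
    uncertainty, 0.5.
    """
    d = np.asarray(effect_draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty draw vector")
    med = np.median(d)
    if med == 0.0:
        return 0.5
    return float(np.mean(np.sign(d) == -np.sign(med)))


def group_mean_draws(draws: PosteriorDraws, level) -> np.ndarray:
    """Per-draw posterior mean killing proportion of one group level,
    marginalized over the observed pair levels with equal weight."""
    data = draws.data
    level = str(level)
    if level not in data.group_levels:
        raise ValueError(
            f"unknown group level {level!r}; levels: {data.group_levels}"
        )
    g = data.group_levels.index(level)
    alpha, beta, gamma, _ = data.unpack(draws.draws)
    eta = alpha + beta[..., g]
    if data.n_pairs > 0:
        mu = expit(eta[..., None] + gamma).mean(axis=-1)
    else:
        mu = expit(eta)
    return mu.reshape(-1)


def fold_change(draws: PosteriorDraws, contrast: tuple) -> PosteriorSummary:
    """Posterior fold change between two group levels.

    ``contrast = (numerator, denominator)``.  The ratio of pair-marginalized
    group means is formed draw by draw (so the median fold change is not the
    ratio of medians); the FSR is that of the per-draw log-ratio.
    """
    num, den = contrast
    ratio = group_mean_draws(draws, num) / group_mean_draws(draws, den)
    s = summarize(ratio)
    s.fsr = false_sign_rate(np.log(ratio))
    return s


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class BetaRegression(BaseEstimator):
    """Bayesian Beta regression with group and optional donor-pair fixed
    effects, scikit-learn style.

    Parameters
    ----------
    epsilon : float, default 0.005
        Half-width of the boundary squeeze applied to raw responses.
    n_chains, n_warmup, n_draws : int
        Sampler configuration (defaults 4, 2500, 2500).
    prior_scale : float, default 2.5
        SD of the Normal(0, .) priors on logit-scale coefficients.
    prior_logphi_loc, prior_logphi_scale : float
        Normal prior on log(phi), default Normal(3, 1.5).
    prior_only : bool, default False
        Sample the prior instead of the posterior (diagnostic).
    random_state : int or None

    Attributes
    ----------
    data_ : RegressionData
    clamp_count_ : int
        Number of responses moved to the boundary by the squeeze.
    posterior_ : PosteriorDraws
    rhat_max_ : float
    converged_ : bool

    Examples
    --------
    >>> model = BetaRegression(n_warmup=500, n_draws=500, random_state=0)
    >>> X = pd.DataFrame({"group": ["high"] * 5 + ["low"] * 5,
    ...                   "pair": list("ABCDE") * 2})
    >>> _ = model.fit(X, [0.25, 0.27, 0.24, 0.26, 0.25,
    ...                   0.18, 0.17, 0.19, 0.18, 0.16])
    >>> fc = model.fold_change(("high", "low"))
    """

    def __init__(self, epsilon: float = 0.005, n_chains: int = 4,
                 n_warmup: int = 2500, n_draws: int = 2500,
                 prior_scale: float = 2.5, prior_logphi_loc: float = 3.0,
                 prior_logphi_scale: float = 1.5, prior_only: bool = False,
                 rhat_threshold: float = 1.01, thin: int = 10,
                 random_state=None):
        self.epsilon = epsilon
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.prior_scale = prior_scale
        self.prior_logphi_loc = prior_logphi_loc
        self.prior_logphi_scale = prior_logphi_scale
        self.prior_only = prior_only
        self.rhat_threshold = rhat_threshold
        self.thin = thin
        self.random_state = random_state

    @staticmethod
    def _design_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if "group" not in X.columns:
                raise ValueError("design frame needs a 'group' column")
            return X
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] not in (1, 2):
            raise ValueError(
                "X must be a DataFrame with 'group' (and optional 'pair') "
                "columns, or an (n, 1)/(n, 2) array"
            )
        cols = ["group", "pair"][: X.shape[1]]
        return pd.DataFrame(X, columns=cols)

    def fit(self, X, y):
        """Fit on a design ``X`` (column ``group``, optional ``pair``) and
        raw proportion responses ``y``."""
        frame = self._design_frame(X)
        pair = frame["pair"] if "pair" in frame.columns else None
        self.data_, self.clamp_count_ = RegressionData.from_vectors(
            np.asarray(y, dtype=float), frame["group"], pair,
            epsilon=self.epsilon,
        )
        self.posterior_ = sample_posterior(
            self.data_, n_chains=self.n_chains, n_warmup=self.n_warmup,
            n_kept=self.n_draws, seed=self.random_state,
            prior_only=self.prior_only, rhat_threshold=self.rhat_threshold,
            thin=self.thin, prior_scale=self.prior_scale,
            prior_logphi_loc=self.prior_logphi_loc,
            prior_logphi_scale=self.prior_logphi_scale,
        )
        self.rhat_max_ = self.posterior_.rhat_max
        self.converged_ = self.rhat_max_ <= self.rhat_threshold
        return self

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise ValueError("model is not fitted")

    def group_means(self, level) -> np.ndarray:
        """Per-draw pair-marginalized mean proportion for one group level."""
        self._check_fitted()
        return group_mean_draws(self.posterior_, level)

    def group_summary(self, level) -> PosteriorSummary:
        self._check_fitted()
        return summarize(self.group_means(level))

    def fold_change(self, contrast: tuple) -> PosteriorSummary:
        """Posterior fold change numerator/denominator between group levels."""
        self._check_fitted()
        return fold_change(self.posterior_, contrast)

    def predict(self, X) -> np.ndarray:
        """Posterior-mean killing proportion for new group(/pair) labels."""
        self._check_fitted()
        frame = self._design_frame(X)
        out = np.empty(len(frame))
        for i, row in enumerate(frame.itertuples(index=False)):
            out[i] = group_mean_draws(self.posterior_, row.group).mean()
        return out
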