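"""Dye-dilution deconvolution and proliferation indices.

A proliferation dye halves its fluorescence with each division, so the log10
intensity histogram of a stimulated population is a mixture of equally spaced
Gaussian peaks, one per generation.  :class:`DyePeakMixture` fits that mixture
with the spacing pinned at log10(2) and a shared per-peak SD — only the
undivided-peak position ``mu0``, the SD and the generation weights are free —
and assigns each cell the generation with maximal posterior responsibility.

From per-generation cell counts ``n_g`` the module derives the precursor
(founder) counts ``P_g = n_g / 2**g`` and the two standard summary indices:

* division index (DI): average number of divisions per cell of the original
  precursor population, ``sum(g * P_g) / sum(P_g)``;
* proliferation index (PI): the same average restricted to precursors that
  divided at least once; PI >= DI always, and PI is undefined when nothing
  divided.

Percent divided is computed over acquired cells (``sum_{g>=1} n_g / sum n_g``),
not precursors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import UndefinedResultError
from .simulate import LOG10_2

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d intensity vector, got shape {x.shape}")
    if np.isnan(x).any():
        raise ValueError("intensity vector contains missing values")
    return x


class DyePeakMixture(BaseEstimator):
    """Constrained Gaussian-mixture model of dye-dilution peaks.

    Component ``g`` has mean ``mu0 - g * log10(2)`` (perfect dye halving; the
    spacing is not a free parameter) and all components share one SD.  Fitted
    by expectation-maximization on the log10 intensities.

    Parameters
    ----------
    g_max : int, default 6
        Maximum modelled generation; cells dimmer than generation ``g_max``
        are absorbed by the top component.
    mu0_init : float, optional
        Starting value for the undivided-peak position.  By default the mode
        of the upper-quartile intensities (the brightest peak is generation
        0).
    tol : float, default 1e-8
        EM stops when successive log-likelihoods differ by less than this.
    max_iter : int, default 500
    min_obs : int, default 50
        Minimum number of observations required to fit.

    Attributes
    ----------
    mu0_ : float
    sigma_ : float
    weights_ : ndarray of shape (g_max + 1,)
    means_ : ndarray of shape (g_max + 1,)
    converged_ : bool
        False (with a warning, not an exception) when EM hit ``max_iter``.
    n_iter_ : int
    log_likelihood_ : float
        Total log-likelihood at the final iterate.
    """

    def __init__(self, g_max: int = 6, mu0_init: float | None = None,
                 tol: float = 1e-8, max_iter: int = 500, min_obs: int = 50):
        self.g_max = g_max
        self.mu0_init = mu0_init
        self.tol = tol
        self.max_iter = max_iter
        self.min_obs = min_obs

    # ------------------------------------------------------------------
    def _mu0_candidates(self, x: np.ndarray) -> list:
        """Starting values for the undivided-peak position.

        The mode of the upper-quartile intensities is the natural anchor
        (the brightest peak is generation 0), but when few cells are
        undivided that mode sits on a later peak, so shifted copies
        (+1, +2 peak spacings) are offered as alternative starts and the
        best short-run likelihood decides.
        """
        upper = x[x >= np.quantile(x, 0.75)]
        nbins = min(60, max(10, upper.size // 20))
        counts, edges = np.histogram(upper, bins=nbins)
        k = int(np.argmax(counts))
        mode = float(0.5 * (edges[k] + edges[k + 1]))
        ceiling = float(x.max()) + 0.1
        return [mode + j * LOG10_2
                for j in range(3) if mode + j * LOG10_2 <= ceiling] or [mode]

    def _em(self, x, mu0, sigma, weights, n_iter, tol):
        """Run EM; returns (mu0, sigma, weights, trace, converged)."""
        G = self.g_max + 1
        g_arange = np.arange(G)
        ll_prev = -np.inf
        trace = []
        converged = False
        for _ in range(n_iter):
            logc = self._log_components(x, mu0, sigma, weights)
            norm = logsumexp(logc, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            r = np.exp(logc - norm[:, None])  # responsibilities
            # M-step (closed form under the fixed-spacing constraint)
            nk = r.sum(axis=0)
            weights = nk / x.size
            mu0 = float((r @ g_arange * LOG10_2 + x).sum() / x.size)
            means = mu0 - g_arange * LOG10_2
            sigma = float(np.sqrt(
                (r * (x[:, None] - means[None, :]) ** 2).sum() / x.size
            ))
            sigma = max(sigma, 1e-4)
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        return mu0, sigma, weights, trace, converged

    def _log_components(self, x, mu0, sigma, weights):
        """(n, G+1) matrix of log(w_g * N(x; mu0 - g*log10(2), sigma))."""
        means = mu0 - np.arange(self.g_max + 1) * LOG10_2
        z = (x[:, None] - means[None, :]) / sigma
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.where(weights > 0, weights, 1.0)),
                            -np.inf)
        return logw[None, :] - 0.5 * z * z - np.log(sigma) - _HALF_LOG_2PI

    def fit(self, X, y=None):
        """Fit the mixture to log10 dye intensities (1-d or column vector)."""
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        x = _as_1d(X)
        if x.size < self.min_obs:
            raise ValueError(
                f"need at least {self.min_obs} observations, got {x.size}"
            )
        G = self.g_max + 1
        weights0 = np.full(G, 1.0 / G)
        sigma0 = 0.1

        if self.mu0_init is not None:
            candidates = [float(self.mu0_init)]
        else:
            candidates = self._mu0_candidates(x)
        if len(candidates) > 1:
            # short-run each start, keep the best likelihood
            burn = 30
            short = [self._em(x, c, sigma0, weights0, burn, self.tol)
                     for c in candidates]
            best = max(range(len(short)), key=lambda j: short[j][3][-1])
            mu0, sigma, weights, trace, converged = short[best]
            used = len(trace)
        else:
            mu0, sigma, weights = candidates[0], sigma0, weights0
            trace, converged, used = [], False, 0
        if not converged:
            mu0, sigma, weights, tail, converged = self._em(
                x, mu0, sigma, weights, self.max_iter - used, self.tol
            )
            trace = trace + tail
        if not converged:
            change = abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.inf
            warnings.warn(
                f"EM did not converge in {self.max_iter} iterations "
                f"(last log-likelihood change {change:.3g})"
            )
        self.mu0_ = mu0
        self.sigma_ = sigma
        self.weights_ = np.asarray(weights)
        self.converged_ = converged
        self.n_iter_ = len(trace)
        self.log_likelihood_ = float(trace[-1])
        self.loglik_trace_ = np.asarray(trace)
        return self

    @property
    def means_(self) -> np.ndarray:
        return self.mu0_ - np.arange(self.g_max + 1) * LOG10_2

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibility of each generation for each cell."""
        if not hasattr(self, "mu0_"):
            raise ValueError("model is not fitted")
        x = _as_1d(X)
        logc = self._log_components(x, self.mu0_, self.sigma_, self.weights_)
        return np.exp(logc - logsumexp(logc, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        """Generation with maximal responsibility; ties go to the lower
        generation (responsibilities within 1e-9 of the maximum count as
        tied)."""
        r = self.predict_proba(X)
        tied = r >= r.max(axis=1, keepdims=True) - 1e-9
        return tied.argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-cell log-likelihood."""
        x = _as_1d(X)
        logc = self._log_components(x, self.mu0_, self.sigma_, self.weights_)
        return float(logsumexp(logc, axis=1).mean())


def fit_peaks(log_intensities, g_max: int = 6,
              mu0_init: float | None = None, **kw) -> DyePeakMixture:
    """Fit a :class:`DyePeakMixture` to a vector of log10 intensities."""
    return DyePeakMixture(g_max=g_max, mu0_init=mu0_init, **kw).fit(log_intensities)


def assign_generations(events: pd.DataFrame, model: DyePeakMixture) -> np.ndarray:
    """Assign a division generation to each event-table row via the fitted
    peak model.  Rows with missing dye intensity are an error (gate NK rows
    out first)."""
    dye = events["dye_log_intensity"]
    missing = dye.isna()
    if missing.any():
        rows = list(events.index[missing][:20])
        raise ValueError(
            f"{int(missing.sum())} rows have no dye intensity "
            f"(first offenders: {rows})"
        )
    return model.predict(dye.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Generation profiles and indices
# ---------------------------------------------------------------------------

def _counts(profile) -> np.ndarray:
    c = np.asarray(profile, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("generation profile must be a non-empty 1-d vector")
    if np.any(c < 0):
        raise ValueError("generation counts must be non-negative")
    if c.sum() <= 0:
        raise ValueError("generation profile is empty (total count 0)")
    return c


def generation_counts(generations, g_max: int = 6) -> np.ndarray:
    """Tally per-generation cell counts ``n_g`` for g = 0..g_max."""
    g = np.asarray(generations, dtype=int)
    if np.any(g < 0) or np.any(g > g_max):
        raise ValueError("generation labels outside 0..g_max")
    return np.bincount(g, minlength=g_max + 1).astype(float)


def precursor_counts(profile) -> np.ndarray:
    """Founder-cohort counts ``P_g = n_g / 2**g``."""
    c = _counts(profile)
    return c / 2.0 ** np.arange(c.size)


def percent_divided(profile) -> float:
    """Fraction of acquired cells that divided at least once."""
    c = _counts(profile)
    return float(c[1:].sum() / c.sum())


def division_index(profile) -> float:
    """Average divisions per precursor cell of the original population."""
    p = precursor_counts(profile)
    g = np.arange(p.size)
    return float((g * p).sum() / p.sum())


def proliferation_index(profile) -> float:
    """Average divisions among precursors that divided at least once."""
    p = precursor_counts(profile)
    g = np.arange(p.size)
    divided = p[1:].sum()
    if divided <= 0:
        raise UndefinedResultError(
            "proliferation index undefined: no divided cells"
        )
    return float((g[1:] * p[1:]).sum() / divided)


@dataclass(frozen=True)
class ProliferationStats:
    percent_divided: float
    division_index: float
    proliferation_index: float | None  # None when no cell divided


def proliferation_stats(profile) -> ProliferationStats:
    """All three summary statistics of one generation profile."""
    try:
        pi = proliferation_index(profile)
    except UndefinedResultError:
        pi = None
    return ProliferationStats(
        percent_divided=percent_divided(profile),
        division_index=division_index(profile),
        proliferation_index=pi,
    )


def compare_indices(values_a, values_b) -> tuple[float, float]:
    """Two-tailed paired t-test between matched index measurements.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))``, ``d = a - b``,
    ``df = n - 1``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-d vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t-test degenerate")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
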