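"""Count-distribution models for per-division mutation tallies.

Replication-error counts per cell division are classically modelled as
Poisson.  A mutator phenotype whose strength fluctuates between divisions
produces *overdispersed* counts (variance > mean), which this module
quantifies and models three ways:

* a single Poisson (``lambda``; the constant-rate null),
* a K-component Poisson mixture fitted by EM (discrete mutator states),
* a negative binomial (``mu``, ``theta``), equivalently a gamma-Poisson
  compound: the division-to-division rate ``lambda ~ Gamma(shape=theta,
  scale=mu/theta)`` with Poisson counts given the rate.

Model classes follow the statsmodels convention: a model object holds the
data, ``fit()`` returns a results object carrying estimates, log-likelihood,
AIC/BIC and a ``summary()`` table.  Non-nested candidates are compared by
Akaike weights, ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` with
``delta_i = AIC_i - min AIC``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.optimize import minimize_scalar

__all__ = [
    "poisson_pmf", "poisson_mixture_pmf", "negbin_pmf",
    "index_of_dispersion", "dispersion_from_moments",
    "information_criteria", "akaike_weights", "nb_to_gamma",
    "DispersionSummary", "GammaParams",
    "PoissonMixture", "PoissonMixtureResults",
    "NegativeBinomialCounts", "NegBinResults",
    "fit_poisson_mixture", "fit_negbin", "model_selection",
]

_THETA_LO, _THETA_HI = 1e-3, 1e6


# ---------------------------------------------------------------------------
# probability mass functions (log-space)

def poisson_log_pmf(x, lam) -> np.ndarray:
    x = np.asarray(x)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a non-negative integer")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lam must be positive")
    return x * np.log(lam) - lam - gammaln(x + 1.0)


def poisson_pmf(x, lam):
    """Poisson pmf ``lam**x * exp(-lam) / x!`` computed in log space."""
    return np.exp(poisson_log_pmf(x, lam))


def poisson_mixture_pmf(x, p, lam):
    """Pmf of a finite Poisson mixture, ``sum_k p_k Poisson(x; lam_k)``."""
    p = np.asarray(p, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if p.shape != lam.shape:
        raise ValueError("mixture weights and rates differ in length")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("mixture weights must sum to 1")
    x = np.asarray(x)
    logs = poisson_log_pmf(x[..., None], lam[None, :]) + np.log(p)[None, :]
    return np.exp(logsumexp(logs, axis=-1))


def negbin_log_pmf(x, mu, theta) -> np.ndarray:
    x = np.asarray(x)
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a non-negative integer")
    return (
        gammaln(x + theta) - gammaln(x + 1.0) - gammaln(theta)
        + theta * np.log(theta / (theta + mu))
        + x * np.log(mu / (theta + mu))
    )


def negbin_pmf(x, mu, theta):
    """Negative-binomial pmf in the (mu, theta) parameterisation.

    ``Gamma(x+theta) / (x! Gamma(theta)) * (theta/(theta+mu))**theta
    * (mu/(theta+mu))**x``; mean ``mu``, variance ``mu + mu**2/theta``.
    As ``theta -> inf`` this reduces to Poisson(mu).
    """
    return np.exp(negbin_log_pmf(x, mu, theta))


# ---------------------------------------------------------------------------
# moments, information criteria, gamma equivalence

@dataclass(frozen=True)
class DispersionSummary:
    """Mean, variance (n-1 denominator) and index of dispersion of counts."""
    n: int
    mean: float
    variance: float

    @property
    def dispersion(self) -> float:
        return self.variance / self.mean


def index_of_dispersion(counts) -> DispersionSummary:
    """Index of dispersion ``D = s^2 / xbar`` of a count sample.

    The sample variance uses the unbiased (n-1) denominator.  ``D`` is 1 for
    Poisson data; values above 1 indicate overdispersion.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two observations")
    mean = float(c.mean())
    if mean == 0:
        raise ValueError("index of dispersion undefined for zero mean")
    return DispersionSummary(n=c.size, mean=mean, variance=float(c.var(ddof=1)))


def dispersion_from_moments(mean: float, sd: float) -> float:
    """``D = sd**2 / mean`` from summary moments."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return sd * sd / mean


def information_criteria(log_likelihood: float, n_params: int, n: int):
    """Return ``(AIC, BIC) = (2k - 2lnL, k ln n - 2lnL)``."""
    aic = 2.0 * n_params - 2.0 * log_likelihood
    bic = n_params * np.log(n) - 2.0 * log_likelihood
    return aic, bic


def akaike_weights(aic_values) -> np.ndarray:
    """Akaike weights: relative likelihood of each model in a candidate set.

    Invariant to adding a constant to every AIC.
    """
    aic = np.asarray(aic_values, dtype=float)
    if aic.size == 0:
        raise ValueError("need at least one AIC value")
    if not np.all(np.isfinite(aic)):
        raise ValueError("AIC values must be finite")
    rel = np.exp(-0.5 * (aic - aic.min()))
    return rel / rel.sum()


@dataclass(frozen=True)
class GammaParams:
    """Gamma mixing distribution equivalent to a negative binomial.

    ``shape = theta`` and ``scale = mu/theta`` (equivalently ``v/mu`` with
    ``v = mu**2/theta``), so the gamma mean is ``mu`` and its variance ``v``.
    """
    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2


def nb_to_gamma(mu: float, theta: float) -> GammaParams:
    """Gamma mixing density of the gamma-Poisson view of negbin(mu, theta)."""
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    return GammaParams(shape=theta, scale=mu / theta)


# ---------------------------------------------------------------------------
# model / results classes

class _CountModel:
    def __init__(self, counts):
        c = np.asarray(counts)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-d array")
        if np.any(c < 0) or np.any(c != np.floor(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        self.nobs = c.size


@dataclass
class PoissonMixtureResults:
    """MLE of a K-component Poisson mixture (components sorted by rate)."""
    k: int
    weights: np.ndarray
    rates: np.ndarray
    log_likelihood: float
    nobs: int
    n_iter: int
    converged: bool
    n_params: int = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        self.n_params = 2 * self.k - 1
        self.aic, self.bic = information_criteria(
            self.log_likelihood, self.n_params, self.nobs
        )

    @property
    def name(self) -> str:
        return f"poisson_k{self.k}"

    def pmf(self, x):
        return poisson_mixture_pmf(x, self.weights, self.rates)

    def summary(self) -> str:
        lines = [
            f"Poisson mixture (K={self.k})",
            f"  nobs:            {self.nobs}",
            f"  log-likelihood:  {self.log_likelihood:.4f}",
            f"  AIC / BIC:       {self.aic:.2f} / {self.bic:.2f}",
            f"  converged:       {self.converged} ({self.n_iter} iterations)",
        ]
        for i, (p, lam) in enumerate(zip(self.weights, self.rates), 1):
            lines.append(f"  component {i}: p={p:.4f}  lambda={lam:.4f}")
        return "\n".join(lines)


@dataclass
class NegBinResults:
    """MLE of an intercept-only negative binomial (mu = sample mean)."""
    mu: float
    theta: float
    log_likelihood: float
    nobs: int
    theta_at_bound: bool
    n_params: int = 2
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        self.aic, self.bic = information_criteria(
            self.log_likelihood, self.n_params, self.nobs
        )

    @property
    def name(self) -> str:
        return "negbin"

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.theta

    def gamma_params(self) -> GammaParams:
        return nb_to_gamma(self.mu, self.theta)

    def pmf(self, x):
        return negbin_pmf(x, self.mu, self.theta)

    def summary(self) -> str:
        g = self.gamma_params()
        return "\n".join([
            "Negative binomial (gamma-Poisson)",
            f"  nobs:            {self.nobs}",
            f"  mu (rate):       {self.mu:.4f}",
            f"  theta (shape):   {self.theta:.4f}"
            + ("  [at bound: effectively Poisson]" if self.theta_at_bound else ""),
            f"  model variance:  {self.variance:.4f}",
            f"  gamma mixing:    shape={g.shape:.4f} scale={g.scale:.4f}",
            f"  log-likelihood:  {self.log_likelihood:.4f}",
            f"  AIC / BIC:       {self.aic:.2f} / {self.bic:.2f}",
        ])


class PoissonMixture(_CountModel):
    """Finite Poisson mixture model for a sample of counts.

    Fitted by expectation-maximisation with multiple jittered restarts;
    the best restart by log-likelihood is returned.  The observed-data
    log-likelihood is checked to be non-decreasing across EM iterations.
    """

    def __init__(self, counts, k: int = 1):
        super().__init__(counts)
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.nobs < k:
            raise ValueError("need at least k observations")
        self.k = k

    def _em(self, lam0: np.ndarray, p0: np.ndarray, tol: float, max_iter: int):
        x = self.counts[:, None].astype(float)
        p, lam = p0.copy(), np.maximum(lam0, 1e-12)
        ll_prev = -np.inf
        for it in range(1, max_iter + 1):
            logpost = poisson_log_pmf(x, lam[None, :]) + np.log(p)[None, :]
            norm = logsumexp(logpost, axis=1)
            ll = float(norm.sum())
            # EM guarantees monotone log-likelihood; tolerate float jitter
            assert ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), \
                "EM log-likelihood decreased"
            resp = np.exp(logpost - norm[:, None])
            nk = resp.sum(axis=0)
            p = nk / self.nobs
            lam = np.maximum((resp * x).sum(axis=0) / np.maximum(nk, 1e-300), 1e-12)
            if ll - ll_prev < tol * max(1.0, abs(ll)):
                return p, lam, ll, it, True
            ll_prev = ll
        return p, lam, ll, max_iter, False

    def fit(self, n_restarts: int = 10, tol: float = 1e-8,
            max_iter: int = 500, seed=None) -> PoissonMixtureResults:
        k = self.k
        if k == 1:
            lam = max(float(self.counts.mean()), 1e-12)
            ll = float(poisson_log_pmf(self.counts, lam).sum())
            return PoissonMixtureResults(1, np.array([1.0]), np.array([lam]),
                                         ll, self.nobs, 0, True)
        rng = np.random.default_rng(seed)
        # initial rates at evenly spaced sample quantiles, uniform weights
        qs = np.linspace(0.0, 1.0, k + 2)[1:-1]
        base = np.maximum(np.quantile(self.counts, qs), 1e-6)
        best = None
        for r in range(max(1, n_restarts)):
            lam0 = base if r == 0 else base * rng.uniform(0.5, 1.5, size=k)
            p0 = np.full(k, 1.0 / k)
            p, lam, ll, it, conv = self._em(lam0, p0, tol, max_iter)
            if best is None or ll > best[2]:
                best = (p, lam, ll, it, conv)
        p, lam, ll, it, conv = best
        order = np.argsort(lam)
        p, lam = p[order], lam[order]
        if np.any(np.diff(lam) < 1e-6 * np.maximum(lam[1:], 1.0)):
            warnings.warn(
                "Poisson mixture converged to (near-)duplicate component "
                "rates; the effective number of components is below K",
                stacklevel=2,
            )
        return PoissonMixtureResults(k, p, lam, ll, self.nobs, it, conv)


class NegativeBinomialCounts(_CountModel):
    """Intercept-only negative-binomial model for a sample of counts.

    ``mu`` is the sample mean (the intercept-only MLE); ``theta`` maximises
    the profile log-likelihood, searched on a log scale within
    ``[1e-3, 1e6]``.  Equi- or underdispersed samples drive ``theta`` to the
    upper bound, the Poisson limit, and a warning is emitted.
    """

    def __init__(self, counts):
        super().__init__(counts)
        if self.nobs < 2:
            raise ValueError("need at least two observations")
        if self.counts.var(ddof=1) == 0:
            raise ValueError("sample variance is zero; fit a Poisson instead")
        if self.counts.mean() == 0:
            raise ValueError("all-zero counts cannot be fitted")

    def fit(self) -> NegBinResults:
        mu = float(self.counts.mean())

        def nll(log_theta: float) -> float:
            return -float(negbin_log_pmf(self.counts, mu, np.exp(log_theta)).sum())

        res = minimize_scalar(
            nll, bounds=(np.log(_THETA_LO), np.log(_THETA_HI)), method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        at_bound = theta > 0.99 * _THETA_HI
        if at_bound:
            warnings.warn(
                "theta at upper bound: data are not overdispersed "
                "(effectively Poisson)", stacklevel=2,
            )
        return NegBinResults(mu, theta, -float(res.fun), self.nobs, at_bound)


# spec-surface convenience wrappers ----------------------------------------

def fit_poisson_mixture(counts, k: int, n_restarts: int = 10, tol: float = 1e-8,
                        max_iter: int = 500, seed=None) -> PoissonMixtureResults:
    return PoissonMixture(counts, k).fit(n_restarts=n_restarts, tol=tol,
                                         max_iter=max_iter, seed=seed)


def fit_negbin(counts) -> NegBinResults:
    return NegativeBinomialCounts(counts).fit()


def model_selection(counts, k_max: int = 4, seed=None) -> pd.DataFrame:
    """Fit Poisson mixtures (K=1..k_max) and a negative binomial; rank by AIC.

    Mixture order grows only while AIC keeps improving: the first K whose AIC
    exceeds that of K-1 ends the ladder and is not reported.  Akaike weights
    are computed across all retained models.  BIC is reported alongside but
    AIC drives the ranking.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits = []
    prev_aic = np.inf
    for k in range(1, k_max + 1):
        fit = fit_poisson_mixture(counts, k, seed=seed)
        if fit.aic > prev_aic:
            break
        fits.append(fit)
        prev_aic = fit.aic
    try:
        fits.append(fit_negbin(counts))
    except ValueError:
        pass  # zero-variance samples: Poisson ladder only
    weights = akaike_weights([f.aic for f in fits])
    rows = []
    for f, w in zip(fits, weights):
        if isinstance(f, NegBinResults):
            params = f"mu={f.mu:.4g}, theta={f.theta:.4g}"
        else:
            params = ", ".join(
                f"p{i}={p:.3g}, lam{i}={l:.4g}"
                for i, (p, l) in enumerate(zip(f.weights, f.rates), 1)
            )
        rows.append({
            "model": f.name, "n_params": f.n_params, "params": params,
            "log_likelihood": f.log_likelihood, "aic": f.aic, "bic": f.bic,
            "akaike_weight": w, "fit": f,
        })
    df = pd.DataFrame(rows).sort_values("aic", ignore_index=True)
    return df
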