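"""Stochastic simulators of mutator volatility and mitotic segregation.

Three families of simulation, mirroring the questions they answer:

1. Mother/daughter mismatch pairs.  ``simulate_replicon_variant_pairs``
   draws the two sides independently from a negative binomial (rate varies
   *within* a genome, so sides decouple); ``simulate_division_variant_pairs``
   draws a shared per-division rate ``lambda ~ Gamma(theta, mu/theta)`` and
   then two conditional Poisson counts (rate varies *between* divisions, so
   sides co-vary).  Regression of the simulated pairs separates the two.

2. The Poisson-binomial division: per chromosome copy, a Poisson number of
   mismatches at rate ``rate * f_c`` (``f_c`` the copy's haploid genome
   fraction), then an all-or-none Bernoulli(1/2) mask per copy modelling the
   mitotic segregation of the mutation-bearing duplex.  The
   gamma-Poisson-binomial variant draws the genome-wide rate per division
   from a gamma before the per-copy Poisson step.

3. Cohort summaries: the index of dispersion of simulated cohorts, cumulative
   burden trajectories over many divisions, and a dispersion-versus-rate scan.

Closed-form moments used as test oracles: for the Poisson-binomial process
with mismatch rate ``r`` per haploid genome on a karyotype with squared
fraction sum ``s = sum_i f_i**2``, the inherited total has mean ``r * p/2``
(``p`` = ploidy) and index of dispersion ``D = 1 + (r/4) * sum_copies f_c**2
= 1 + (r * p / 4) * s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ChromosomeSet

__all__ = [
    "DivisionDraw", "simulate_replicon_variant_pairs",
    "simulate_division_variant_pairs", "pair_regression", "cohort_dispersion",
    "simulate_division", "inherited_totals", "process_dispersion",
    "cumulative_burden", "dispersion_rate_scan",
]

PAIR_MODELS = ("replicon_variant", "division_variant")
PROCESS_MODELS = ("poisson", "poisson_binomial", "gamma_poisson_binomial")


@dataclass(frozen=True)
class DivisionDraw:
    """One simulated division: per-copy mismatch counts and their fate."""
    lambda_division: float
    per_copy_counts: np.ndarray
    segregation_mask: np.ndarray

    @property
    def inherited_total(self) -> int:
        return int(np.sum(self.per_copy_counts * self.segregation_mask))


def _negbin_rvs(mu: float, theta: float, size, rng) -> np.ndarray:
    # numpy's negative_binomial(n, p) with n=theta, p=theta/(theta+mu)
    return rng.negative_binomial(theta, theta / (theta + mu), size=size)


def simulate_replicon_variant_pairs(mu: float, theta: float, n_pairs: int,
                                    seed=None) -> np.ndarray:
    """(Dm, Mm) pairs with both sides independent negbin(mu, theta) draws.

    Under this model the within-genome rate variation is free to differ
    between the two nascent genomes, so the pair is uncorrelated.
    """
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    rng = np.random.default_rng(seed)
    return _negbin_rvs(mu, theta, (int(n_pairs), 2), rng)


def simulate_division_variant_pairs(mu: float, theta: float, n_pairs: int,
                                    seed=None):
    """(Dm, Mm, lambda) with a shared per-division gamma-distributed rate.

    ``lambda ~ Gamma(shape=theta, scale=mu/theta)`` once per division;
    ``Dm, Mm ~ Poisson(lambda)`` independently given ``lambda``.  The shared
    rate induces correlation ``rho = (mu/theta) / (1 + mu/theta)``.
    """
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=theta, scale=mu / theta, size=int(n_pairs))
    pairs = rng.poisson(lam[:, None], size=(int(n_pairs), 2))
    return pairs, lam


def pair_regression(pairs: np.ndarray):
    """OLS of Mm on Dm for simulated or observed pairs.

    Returns the full scipy ``linregress`` result; ``result.rvalue**2`` is the
    coefficient of determination.
    """
    pairs = np.asarray(pairs)
    return stats.linregress(pairs[:, 0], pairs[:, 1])


# ---------------------------------------------------------------------------
# per-division Poisson-binomial process

def _copy_rates(chromset: ChromosomeSet, rate_haploid) -> np.ndarray:
    """Per-chromosome-copy Poisson rates ``rate * f_c`` (f = haploid
    fraction; a diploid karyotype contributes two copies per chromosome)."""
    return np.asarray(rate_haploid)[..., None] * chromset.copy_fractions()


def simulate_division(chromset: ChromosomeSet, mismatch_rate_haploid: float,
                      model: str = "poisson_binomial", theta: float | None = None,
                      rng=None) -> DivisionDraw:
    """Simulate one cell division on a karyotype.

    ``poisson_binomial``: per copy ``c``, count ~ Poisson(rate * f_c), then
    an independent Bernoulli(1/2) mask per copy (all-or-none inheritance of
    that copy's new mutations).  ``gamma_poisson_binomial``: the rate is a
    fresh draw ``lambda ~ Gamma(shape=theta, mean=mismatch_rate_haploid)``.
    ``poisson``: no segregation mask; the rate is then interpreted as the
    *observed* mutation rate per haploid genome (half the mismatch rate) and
    the total is Poisson(rate * ploidy).
    """
    if mismatch_rate_haploid <= 0:
        raise ValueError("rate must be positive")
    if model not in PROCESS_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {PROCESS_MODELS}")
    rng = np.random.default_rng(rng)
    n_copies = chromset.n_chromosomes * chromset.ploidy
    if model == "poisson":
        lam = mismatch_rate_haploid
        counts = rng.poisson(_copy_rates(chromset, lam))
        mask = np.ones(n_copies, dtype=np.int8)
        return DivisionDraw(float(lam), counts, mask)
    if model == "gamma_poisson_binomial":
        if theta is None or theta <= 0:
            raise ValueError("gamma model needs a positive theta")
        lam = float(rng.gamma(shape=theta, scale=mismatch_rate_haploid / theta))
    else:
        lam = float(mismatch_rate_haploid)
    counts = rng.poisson(_copy_rates(chromset, lam))
    mask = rng.integers(0, 2, size=n_copies).astype(np.int8)
    return DivisionDraw(lam, counts, mask)


def inherited_totals(chromset: ChromosomeSet, mismatch_rate_haploid: float,
                     model: str, size, theta: float | None = None,
                     rng=None) -> np.ndarray:
    """Vectorised per-cell inherited mutation totals (shape ``size``)."""
    if model not in PROCESS_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {PROCESS_MODELS}")
    rng = np.random.default_rng(rng)
    size = tuple(np.atleast_1d(size).astype(int))
    if model == "poisson":
        return rng.poisson(mismatch_rate_haploid * chromset.ploidy, size=size)
    if model == "gamma_poisson_binomial":
        if theta is None or theta <= 0:
            raise ValueError("gamma model needs a positive theta")
        lam = rng.gamma(shape=theta, scale=mismatch_rate_haploid / theta, size=size)
    else:
        lam = np.broadcast_to(float(mismatch_rate_haploid), size)
    rates = _copy_rates(chromset, lam)
    counts = rng.poisson(rates)
    mask = rng.integers(0, 2, size=rates.shape)
    return (counts * mask).sum(axis=-1)


def _dispersion_rows(samples: np.ndarray) -> np.ndarray:
    """Index of dispersion of each row (n-1 variance denominator)."""
    return samples.var(axis=1, ddof=1) / samples.mean(axis=1)


def cohort_dispersion(model: str, params: dict, cohort_size: int,
                      iterations: int, seed=None):
    """Ensemble of cohort dispersion indices under a named model.

    Per iteration, ``cohort_size`` full replication-error counts are drawn
    and their index of dispersion computed; returns ``(mean, sd, sample)``
    over iterations.  For the pair models the full count is ``Dm + Mm``.

    ``params``: ``mu``/``theta`` for the pair models; ``mu`` (mean full
    count) for ``poisson``; ``chromset``/``rate`` (mismatch rate per haploid
    genome) plus ``theta`` for the chromosome-level segregation models.
    """
    if cohort_size < 2:
        raise ValueError("cohort_size must be >= 2")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (int(iterations), int(cohort_size))
    if model == "replicon_variant":
        full = (_negbin_rvs(params["mu"], params["theta"], shape, rng)
                + _negbin_rvs(params["mu"], params["theta"], shape, rng))
    elif model == "division_variant":
        lam = rng.gamma(params["theta"], params["mu"] / params["theta"], shape)
        full = rng.poisson(lam) + rng.poisson(lam)
    elif model == "poisson":
        full = rng.poisson(params["mu"], size=shape)
    elif model in ("poisson_binomial", "gamma_poisson_binomial"):
        full = inherited_totals(params["chromset"], params["rate"], model,
                                shape, theta=params.get("theta"), rng=rng)
    else:
        raise ValueError(f"unknown model {model!r}")
    d = _dispersion_rows(full)
    return float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0, d


def process_dispersion(chromset: ChromosomeSet, observed_rate: float,
                       model: str, cohort_size: int, iterations: int,
                       seed=None, theta: float | None = None):
    """Cohort dispersion of the per-division segregation process.

    ``observed_rate`` is in observed mutations per haploid genome per
    division; the segregation models run at mismatch rate ``2 *
    observed_rate`` (each mismatch survives segregation with probability
    1/2), while the Poisson control accumulates at the observed rate with no
    segregation step.  Returns ``(mean D, sd D, D sample)``.
    """
    if observed_rate <= 0:
        raise ValueError("observed_rate must be positive")
    rate = observed_rate if model == "poisson" else 2.0 * observed_rate
    params = {"chromset": chromset, "rate": rate, "theta": theta, "mu": rate * chromset.ploidy}
    if model == "poisson":
        # Poisson control: diploid totals at observed_rate * ploidy
        return cohort_dispersion("poisson", params, cohort_size, iterations, seed)
    return cohort_dispersion(model, params, cohort_size, iterations, seed)


def cumulative_burden(chromset: ChromosomeSet, observed_rate: float,
                      model: str, n_divisions: int, n_cells: int,
                      seed=None, theta: float | None = None) -> np.ndarray:
    """Per-cell cumulative mutation burden over successive divisions.

    Each cell accumulates independent per-division inherited totals;
    returns the ``(n_cells, n_divisions)`` matrix of running totals.
    """
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    rng = np.random.default_rng(seed)
    rate = observed_rate if model == "poisson" else 2.0 * observed_rate
    per_div = inherited_totals(chromset, rate, model,
                               (int(n_cells), int(n_divisions)),
                               theta=theta, rng=rng)
    return np.cumsum(per_div, axis=1)


def dispersion_rate_scan(chromset: ChromosomeSet, observed_rates,
                         model: str, cohort_size: int, iterations: int,
                         seed=None, theta: float | None = None) -> pd.DataFrame:
    """Mean cohort dispersion at each observed mutation rate.

    For the Poisson-binomial model the expected dispersion is affine in the
    rate: ``D = 1 + (rate * ploidy / 2) * sum_i f_i**2`` at mismatch rate
    ``2 * rate``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rate in observed_rates:
        sub = int(rng.integers(0, 2**31 - 1))
        mean_d, sd_d, _ = process_dispersion(
            chromset, float(rate), model, cohort_size, iterations,
            seed=sub, theta=theta,
        )
        rows.append({"observed_rate": float(rate),
                     "mean_dispersion": mean_d, "sd_dispersion": sd_d})
    return pd.DataFrame(rows)
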