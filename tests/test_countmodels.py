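import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mutlineage as ml
from mutlineage.countmodels import negbin_log_pmf
from mutlineage.synth import generate_count_sample


# -- probability mass functions --------------------------------------------

def test_poisson_pmf_closed_form():
    assert ml.poisson_pmf(0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)


def test_poisson_pmf_normalizes():
    x = np.arange(0, 500)
    assert ml.poisson_pmf(x, 100.0).sum() == pytest.approx(1.0, abs=1e-12)


def test_poisson_pmf_large_argument_vs_arbitrary_precision():
    # exact oracle: 276^276 * e^-276 / 276! with 60-digit decimals
    getcontext().prec = 60
    exact = (Decimal(276) ** 276 * (-Decimal(276)).exp()
             / Decimal(math.factorial(276)))
    assert ml.poisson_pmf(276, 276.0) == pytest.approx(float(exact), rel=1e-10)


def test_poisson_pmf_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ml.poisson_pmf(-1, 2.0)
    with pytest.raises(ValueError):
        ml.poisson_pmf(2, -1.0)


def test_mixture_reduces_to_poisson():
    x = np.arange(30)
    assert np.allclose(ml.poisson_mixture_pmf(x, [1.0], [2.0]),
                       ml.poisson_pmf(x, 2.0))
    # degenerate two-component mixture with equal rates
    assert np.allclose(ml.poisson_mixture_pmf(x, [0.5, 0.5], [2.0, 2.0]),
                       ml.poisson_pmf(x, 2.0))


def test_mixture_direct_summation():
    expected = 0.3 * math.exp(-2) + 0.7 * math.exp(-10)
    assert ml.poisson_mixture_pmf(np.array([0]), [0.3, 0.7], [2.0, 10.0])[0] \
        == pytest.approx(expected, rel=1e-12)


def test_mixture_rejects_mismatched_lengths():
    with pytest.raises(ValueError):
        ml.poisson_mixture_pmf(np.array([1]), [0.5, 0.5], [1.0])


def test_negbin_pmf_at_zero_and_geometric():
    mu, theta = 5.0, 2.0
    assert ml.negbin_pmf(0, mu, theta) == pytest.approx(
        (theta / (theta + mu)) ** theta, rel=1e-12)
    # mu = theta = 1 is geometric with success probability 1/2
    for x in range(11):
        assert ml.negbin_pmf(x, 1.0, 1.0) == pytest.approx(
            0.5 ** (x + 1), rel=1e-10)


def test_negbin_poisson_limit():
    x = np.arange(31)
    assert np.max(np.abs(ml.negbin_pmf(x, 5.0, 1e6)
                         - ml.poisson_pmf(x, 5.0))) < 1e-4


def test_negbin_pmf_normalizes_and_matches_scipy():
    mu, theta = 138.0, 60.42
    x = np.arange(0, 1000)
    pmf = ml.negbin_pmf(x, mu, theta)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
    # independent parameterisation: scipy nbinom(n=theta, p=theta/(theta+mu))
    assert np.allclose(pmf, stats.nbinom.pmf(x, theta, theta / (theta + mu)),
                       rtol=1e-9)


def test_negbin_rejects_nonpositive():
    with pytest.raises(ValueError):
        ml.negbin_pmf(1, -1.0, 2.0)
    with pytest.raises(ValueError):
        ml.negbin_pmf(1, 1.0, 0.0)


# -- dispersion -------------------------------------------------------------

def test_index_of_dispersion_hand_computed():
    d = ml.index_of_dispersion([1, 2, 3])
    assert d.mean == 2.0
    assert d.variance == 1.0  # n-1 denominator
    assert d.dispersion == 0.5


def test_dispersion_zero_variance_and_zero_mean():
    assert ml.index_of_dispersion([4, 4, 4]).dispersion == 0.0
    with pytest.raises(ValueError):
        ml.index_of_dispersion([0, 0, 0])


def test_dispersion_from_printed_moments():
    # the study's headline statistic: 37.7^2 / 276
    assert round(ml.dispersion_from_moments(276, 37.7), 2) == 5.15


def test_poisson_sample_dispersion_near_one():
    counts = generate_count_sample("poisson", {"lam": 276.0}, 20000, seed=5)
    d = ml.index_of_dispersion(counts)
    se = math.sqrt(2.0 / d.n)  # large-sample s.e. of D-hat under Poisson
    assert abs(d.dispersion - 1.0) < 3 * se


# -- information criteria ---------------------------------------------------

def test_information_criteria_formulas():
    aic, bic = ml.information_criteria(-100.0, 3, 50)
    assert aic == 206.0
    assert bic == pytest.approx(3 * math.log(50) + 200.0)


def test_akaike_weights_symmetry_and_single():
    assert np.allclose(ml.akaike_weights([10.0, 10.0]), [0.5, 0.5])
    assert ml.akaike_weights([123.4]) == pytest.approx([1.0])
    with pytest.raises(ValueError):
        ml.akaike_weights([])


@settings(max_examples=50, deadline=None)
@given(shift=st.floats(-1e3, 1e3),
       aics=st.lists(st.floats(0, 100), min_size=1, max_size=6))
def test_akaike_weights_shift_invariant(shift, aics):
    w1 = ml.akaike_weights(aics)
    w2 = ml.akaike_weights([a + shift for a in aics])
    assert np.allclose(w1, w2, atol=1e-12)
    assert w1.sum() == pytest.approx(1.0, abs=1e-12)


# -- gamma equivalence ------------------------------------------------------

def test_nb_to_gamma_methods_arithmetic():
    g = ml.nb_to_gamma(138.0, 60.42)
    assert g.shape == 60.42
    assert g.scale == pytest.approx(138.0 / 60.42)  # ~2.2840
    assert g.mean == pytest.approx(138.0)
    assert g.variance == pytest.approx(138.0**2 / 60.42)


def test_gamma_poisson_compound_matches_negbin():
    counts = generate_count_sample("gamma_poisson",
                                   {"mu": 138.0, "theta": 60.42},
                                   100_000, seed=11)
    edges = np.arange(60, 240, 10)
    observed, _ = np.histogram(counts, bins=edges)
    x = np.arange(0, 600)
    pmf = ml.negbin_pmf(x, 138.0, 60.42)
    expected = np.array([
        pmf[(x >= lo) & (x < hi)].sum() for lo, hi in zip(edges, edges[1:])
    ]) * counts.size
    keep = expected > 5
    chi2, p = stats.chisquare(observed[keep],
                              expected[keep] * observed[keep].sum()
                              / expected[keep].sum())
    assert p > 0.01


# -- fitting ----------------------------------------------------------------

def test_poisson_k1_mle_is_sample_mean():
    counts = [3, 5, 7, 9]
    fit = ml.fit_poisson_mixture(counts, 1)
    assert fit.rates[0] == pytest.approx(6.0)
    assert fit.n_params == 1


def test_mixture_loglik_nested_monotone():
    counts = generate_count_sample("negbin", {"mu": 20.0, "theta": 2.0},
                                   300, seed=3)
    f1 = ml.fit_poisson_mixture(counts, 1)
    f2 = ml.fit_poisson_mixture(counts, 2, seed=0)
    assert f2.log_likelihood >= f1.log_likelihood - 1e-9


def test_mixture_parameter_recovery_well_separated():
    # two rates separated 10-fold, as in the earlier two-state analysis
    p_true, lam_true = (0.5, 0.5), (4.0, 40.0)
    counts = generate_count_sample(
        "poisson_mixture", {"p": p_true, "lam": lam_true}, 2000, seed=7)
    fit = ml.fit_poisson_mixture(counts, 2, seed=0)
    assert np.allclose(fit.weights, p_true, atol=0.05)
    assert np.allclose(fit.rates, lam_true, rtol=0.05)
    assert fit.n_params == 3


def test_mixture_duplicate_rate_warning():
    with pytest.warns(UserWarning, match="duplicate"):
        ml.fit_poisson_mixture([5] * 30, 2, seed=0)


def test_mixture_rejects_bad_k_and_counts():
    with pytest.raises(ValueError):
        ml.fit_poisson_mixture([1, 2, 3], 0)
    with pytest.raises(ValueError):
        ml.fit_poisson_mixture([1.5, 2.2], 1)


def test_negbin_recovery():
    counts = generate_count_sample("negbin", {"mu": 138.0, "theta": 60.42},
                                   10_000, seed=13)
    fit = ml.fit_negbin(counts)
    assert fit.mu == pytest.approx(138.0, rel=0.02)
    assert fit.theta == pytest.approx(60.42, rel=0.15)
    assert fit.mu == pytest.approx(np.mean(counts), abs=1e-8)
    # variance identity on a large sample
    assert fit.variance == pytest.approx(np.var(counts, ddof=1), rel=0.1)


def test_negbin_matches_statsmodels_oracle():
    import statsmodels.api as sm
    counts = generate_count_sample("negbin", {"mu": 50.0, "theta": 8.0},
                                   4000, seed=17)
    fit = ml.fit_negbin(counts)
    res = sm.NegativeBinomial(counts, np.ones_like(counts)).fit(disp=0)
    assert fit.mu == pytest.approx(float(np.exp(res.params[0])), rel=1e-3)
    assert fit.theta == pytest.approx(1.0 / float(res.params[1]), rel=1e-2)
    assert fit.log_likelihood == pytest.approx(float(res.llf), abs=0.01)


def test_negbin_underdispersed_hits_bound():
    counts = np.tile([9, 10, 11], 40)  # variance << mean
    with pytest.warns(UserWarning, match="bound"):
        fit = ml.fit_negbin(counts)
    assert fit.theta_at_bound


def test_negbin_beats_poisson_on_overdispersed():
    counts = generate_count_sample("negbin", {"mu": 30.0, "theta": 8.0},
                                   50, seed=23)
    assert ml.index_of_dispersion(counts).dispersion > 2  # strongly overdispersed
    nb = ml.fit_negbin(counts)
    p1 = ml.fit_poisson_mixture(counts, 1)
    assert nb.aic < p1.aic


def test_summaries_render():
    counts = generate_count_sample("negbin", {"mu": 30.0, "theta": 8.0},
                                   200, seed=2)
    assert "theta" in ml.fit_negbin(counts).summary()
    assert "component" in ml.fit_poisson_mixture(counts, 2, seed=0).summary()


# -- model selection --------------------------------------------------------

def test_model_selection_gamma_poisson_sample():
    counts = generate_count_sample("gamma_poisson",
                                   {"mu": 138.0, "theta": 60.42}, 5000, seed=29)
    table = ml.model_selection(counts, k_max=4, seed=0)
    assert table.iloc[0]["model"] == "negbin"
    assert table["akaike_weight"].sum() == pytest.approx(1.0)


def test_model_selection_poisson_sample_near_optimal():
    counts = generate_count_sample("poisson", {"lam": 276.0}, 5000, seed=31)
    table = ml.model_selection(counts, k_max=3, seed=0)
    best = table["aic"].min()
    row = table[table["model"] == "poisson_k1"]
    assert float(row["aic"].iloc[0]) - best <= 2.0


def test_model_selection_two_state_sample():
    counts = generate_count_sample(
        "poisson_mixture", {"p": (0.5, 0.5), "lam": (4.0, 40.0)},
        500, seed=37)
    table = ml.model_selection(counts, k_max=2, seed=0)
    aic = dict(zip(table["model"], table["aic"]))
    assert aic["poisson_k2"] < aic["poisson_k1"]


def test_model_selection_drops_unimproving_k():
    counts = generate_count_sample("poisson", {"lam": 10.0}, 400, seed=41)
    table = ml.model_selection(counts, k_max=4, seed=0)
    models = set(table["model"])
    # the mixture ladder stops as soon as AIC worsens
    assert "poisson_k1" in models and "negbin" in models
    assert "poisson_k4" not in models


def test_em_monotonicity_asserted_internally():
    # the EM loop asserts non-decreasing log-likelihood on every iteration;
    # a fit on awkward data exercises it
    counts = generate_count_sample("negbin", {"mu": 5.0, "theta": 0.5},
                                   500, seed=43)
    fit = ml.fit_poisson_mixture(counts, 3, seed=1)
    assert np.isfinite(fit.log_likelihood)


def test_negbin_log_pmf_matches_pmf():
    x = np.arange(0, 50)
    assert np.allclose(np.exp(negbin_log_pmf(x, 10.0, 3.0)),
                       ml.negbin_pmf(x, 10.0, 3.0))
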