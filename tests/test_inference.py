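"""Likelihood, CMA-ES, adaptive MCMC and chain post-processing, each against
an independent oracle or closed form."""

import numpy as np
import pytest
from scipy import stats

import cardiouq as cq
from cardiouq.inference import (
    PosteriorChain,
    Prior,
    TraceLikelihood,
    cmaes_minimize,
    credible_interval,
    log_likelihood,
    mape_metric,
    postprocess,
    run_mcmc,
)
from cardiouq.simulation import VoltageTrace, run


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_loglik_zero_residuals_closed_form(br_model):
    """Identical data and simulation at sigma = 1: -(N/2) log 2 pi."""
    proto = cq.make_protocol("single_ap")
    clean = run(br_model, None, proto)
    ll = log_likelihood(clean, br_model, proto, br_model.defaults, sigma=1.0)
    n = len(clean)
    assert ll == pytest.approx(-(n / 2) * np.log(2 * np.pi))


def test_loglik_matches_per_point_normal_densities(br_model):
    """Brute-force oracle: sum of independently evaluated Normal log-pdfs."""
    proto = cq.make_protocol("single_ap", sample_interval=20.0)  # 51 samples
    clean = run(br_model, None, proto)
    rng = np.random.default_rng(42)
    resid = rng.normal(0, 0.7, size=len(clean))
    data = VoltageTrace(0.0, 20.0, clean.voltages + resid)
    sigma = 0.6
    ll = log_likelihood(data, br_model, proto, br_model.defaults, sigma=sigma)
    oracle = stats.norm.logpdf(data.voltages, loc=clean.voltages, scale=sigma).sum()
    assert ll == pytest.approx(oracle, rel=1e-12)


def test_loglik_requires_matching_grid(br_model):
    proto = cq.make_protocol("single_ap")
    bad = VoltageTrace(0.0, 0.2, np.zeros(100))
    with pytest.raises(ValueError, match="grid"):
        TraceLikelihood(br_model, proto, bad)


# ---------------------------------------------------------------------------
# CMA-ES
# ---------------------------------------------------------------------------


def test_cmaes_finds_quadratic_optimum():
    c = np.array([0.3, -1.2, 2.0, 0.7])
    f = lambda x: float(np.sum((x - c) ** 2))
    lo, hi = np.full(4, -5.0), np.full(4, 5.0)
    x, fb, _ = cmaes_minimize(f, lo, hi, seed=1)
    assert np.allclose(x, c, atol=1e-6)


def test_cmaes_deterministic_given_seed():
    f = lambda x: float(np.sum(x ** 2))
    lo, hi = np.full(3, -2.0), np.full(3, 2.0)
    x1, f1, i1 = cmaes_minimize(f, lo, hi, seed=7)
    x2, f2, i2 = cmaes_minimize(f, lo, hi, seed=7)
    assert np.array_equal(x1, x2) and f1 == f2
    assert i1["history"] == i2["history"]


def test_cmaes_respects_bounds():
    # optimum of the unconstrained objective lies outside the box
    f = lambda x: float(np.sum((x - 10.0) ** 2))
    lo, hi = np.zeros(2), np.ones(2)
    x, fb, _ = cmaes_minimize(f, lo, hi, seed=3)
    assert np.all(x >= lo) and np.all(x <= hi)
    assert np.allclose(x, 1.0, atol=1e-3)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def test_mcmc_recovers_2d_gaussian_moments():
    lp = lambda x: -0.5 * float(x @ x)
    chain = run_mcmc(lp, np.array([3.0, -3.0]), 50_000, seed=2)
    s = postprocess(chain, burn_in=0.25, stride=1).samples
    assert np.allclose(s.mean(axis=0), 0.0, atol=0.05)
    assert np.allclose(s.var(axis=0), 1.0, atol=0.1)
    assert 0.1 < chain.acceptance_rate < 0.5


def test_mcmc_deterministic_given_seed():
    lp = lambda x: -0.5 * float(x @ x)
    a = run_mcmc(lp, np.zeros(2), 2000, seed=5)
    b = run_mcmc(lp, np.zeros(2), 2000, seed=5)
    assert np.array_equal(a.samples, b.samples)


def test_mcmc_uniform_box_target():
    lo, hi = np.array([1.0, -2.0]), np.array([2.0, 0.0])
    lp = lambda x: 0.0 if np.all(x > lo) and np.all(x < hi) else -np.inf
    chain = run_mcmc(lp, np.array([1.5, -1.0]), 40_000, seed=6)
    s = postprocess(chain, 0.25, 1).samples
    assert np.all(s[:, 0] > 1.0) and np.all(s[:, 0] < 2.0)
    assert np.all(s[:, 1] > -2.0) and np.all(s[:, 1] < 0.0)
    assert np.allclose(s.mean(axis=0), [1.5, -1.0], atol=0.06)


def test_mcmc_visit_frequencies_match_enumeration():
    """1-D discretised posterior: bin frequencies track exact probabilities,
    so density ratios between any two in-support regions converge to the
    likelihood ratio (the shape of Bayes' rule up to normalisation)."""
    mu, sd, lo, hi = 1.0, 0.7, -2.0, 4.0
    lp = lambda x: (-0.5 * ((x[0] - mu) / sd) ** 2) if lo < x[0] < hi else -np.inf
    chain = run_mcmc(lp, np.array([0.0]), 60_000, seed=9)
    s = postprocess(chain, 0.25, 1).samples[:, 0]
    edges = np.linspace(lo, hi, 13)
    freq, _ = np.histogram(s, bins=edges)
    freq = freq / freq.sum()
    cdf = stats.truncnorm.cdf(edges, (lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)
    exact = np.diff(cdf)
    assert np.allclose(freq, exact, atol=0.02)


def test_mcmc_rejects_bad_start():
    lp = lambda x: -np.inf
    with pytest.raises(ValueError, match="start"):
        run_mcmc(lp, np.zeros(1), 10, seed=1)


# ---------------------------------------------------------------------------
# post-processing, intervals and the identifiability metric
# ---------------------------------------------------------------------------


def _chain(values):
    v = np.asarray(values, float)
    return PosteriorChain(("a",), v[:, None], np.zeros(v.size), 1.0)


def test_postprocess_default_lengths():
    assert len(postprocess(_chain(np.arange(1000.0)))) == 75
    # non-divisible case: floor((N (1 - burn)) / stride)
    assert len(postprocess(_chain(np.arange(1001.0)))) == 75


def test_postprocess_identity():
    ch = _chain(np.arange(100.0))
    pp = postprocess(ch, burn_in=0.0, stride=1)
    assert np.array_equal(pp.samples, ch.samples)


def test_postprocess_extreme_stride():
    pp = postprocess(_chain(np.arange(100.0)), burn_in=0.0, stride=100)
    assert len(pp) == 1


def test_postprocess_validation():
    with pytest.raises(ValueError):
        postprocess(_chain(np.arange(10.0)), burn_in=1.0)
    with pytest.raises(ValueError):
        postprocess(_chain(np.arange(10.0)), stride=0)


def test_credible_interval_nearest_rank():
    """1..1000 -> [26, 975]: discard the outermost 25 samples each side."""
    lo, hi = credible_interval(np.arange(1.0, 1001.0))
    assert (lo, hi) == (26.0, 975.0)


def test_credible_interval_degenerate_and_symmetry():
    lo, hi = credible_interval(np.full(100, 3.14))
    assert lo == hi == pytest.approx(3.14)
    x = np.concatenate([np.linspace(-1, 1, 500), -np.linspace(-1, 1, 500)])
    lo, hi = credible_interval(x + 5.0)
    assert lo - 5.0 == pytest.approx(-(hi - 5.0), abs=1e-12)


def test_credible_interval_needs_samples():
    with pytest.raises(ValueError):
        credible_interval(np.arange(10.0))


def test_mape_closed_forms():
    truth = np.array([2.0])
    assert mape_metric(np.full((50, 1), 2.0), truth)[0] == pytest.approx(0.0)
    assert mape_metric(np.full((50, 1), 2.1), truth)[0] == pytest.approx(0.05)
    alternating = np.tile([[1.8], [2.2]], (25, 1))
    assert mape_metric(alternating, truth)[0] == pytest.approx(0.10)


def test_mape_undefined_for_zero_truth():
    with pytest.raises(ValueError):
        mape_metric(np.ones((50, 1)), np.array([0.0]))


def test_prior_for_model_bounds(br_model):
    prior = Prior.for_model(br_model)
    theta = br_model.defaults.to_array()
    assert np.allclose(prior.lower[:-1], 0.1 * theta)
    assert np.allclose(prior.upper[:-1], 10.0 * theta)
    assert prior.lower[-1] == 0.0 and prior.upper[-1] == 25.0
    assert prior.contains(np.append(theta, 0.25))
    assert not prior.contains(np.append(theta * 11, 0.25))
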