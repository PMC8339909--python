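"""Likelihoods, posterior assembly, and the ensemble sampler machinery."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from rcemu.calibration import (
    CalibrationProblem,
    CurveObservations,
    ERPBracket,
    ERPLikelihoodSpec,
    _erp_loglik_terms,
    loglik_curve,
    loglik_erp,
    run_ensemble,
)
from rcemu.curves import CurveBasis
from rcemu.emulator import RCE
from rcemu.gp import GaussianProcess, GPHyperparams


def _toy_rce(d=21, C=2, seed=0, box_m=2):
    """A small but genuine RCE over a [0,1]^m box."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(100.0, 300.0, d)
    X = rng.random((20, box_m))
    comp = np.linalg.qr(rng.standard_normal((d, C)))[0].T
    basis = CurveBasis(grid=grid, mean=50.0 + 0.2 * grid, components=comp,
                       explained_variance_ratio=np.array([0.9, 0.09][:C]),
                       n_train=20)
    gps = []
    for c in range(C):
        y = np.sin(3 * X[:, 0] + c) + 0.1 * rng.standard_normal(20)
        gps.append(GaussianProcess(X, y, hyper=GPHyperparams(np.full(box_m, 0.5), 0.1)))
    return RCE(basis=basis, gps=gps, box=np.array([[0.0, 1.0]] * box_m), label="toy")


# -- curve likelihood ------------------------------------------------------

def test_single_observation_with_zero_emulator_variance_is_standard_normal(monkeypatch):
    rce = _toy_rce()
    x = np.array([0.5, 0.5])
    monkeypatch.setattr(rce, "predict_components",
                        lambda X: (np.zeros((np.atleast_2d(X).shape[0], 2)),
                                   np.zeros((np.atleast_2d(X).shape[0], 2))))
    j = 7
    s2 = rce.basis.grid[j]
    M = rce.basis.mean[j]
    sigma = 2.5
    y = M + 1.3
    obs = CurveObservations(s2=np.array([s2]), values=np.array([y]), channel="cv")
    got = loglik_curve(x, obs, rce, sigma)
    assert got == pytest.approx(norm.logpdf(y, loc=M, scale=sigma), abs=1e-10)


def test_curve_loglik_matches_dense_multivariate_normal_oracle():
    rce = _toy_rce(seed=4)
    x = np.array([0.3, 0.7])
    idx = np.array([2, 5, 9, 14, 19])
    s2 = rce.basis.grid[idx]
    rng = np.random.default_rng(9)
    y = 50.0 + 0.2 * s2 + rng.standard_normal(5)
    obs = CurveObservations(s2=s2, values=y, channel="apd")
    sigma = 1.7
    got = loglik_curve(x, obs, rce, sigma)
    # dense oracle
    means, varis = rce.predict_components(x)
    Psi = rce.basis.components[:, idx]
    mean = rce.basis.mean[idx] + Psi.T @ means[0]
    cov = Psi.T @ np.diag(varis[0]) @ Psi + sigma**2 * np.eye(5)
    r = y - mean
    expected = -0.5 * (5 * np.log(2 * np.pi) + np.linalg.slogdet(cov)[1]
                       + r @ np.linalg.inv(cov) @ r)
    assert got == pytest.approx(expected, abs=1e-8)


def test_curve_loglik_decreases_moving_an_observation_away_from_the_mean():
    rce = _toy_rce(seed=2)
    x = np.array([0.4, 0.4])
    idx = np.array([3, 8, 12])
    s2 = rce.basis.grid[idx]
    means, varis = rce.predict_components(x)
    base = rce.basis.mean[idx] + rce.basis.components[:, idx].T @ means[0]
    prev = np.inf
    for shift in (0.0, 1.0, 2.0, 4.0, 8.0):
        y = base.copy()
        y[1] += shift
        ll = loglik_curve(x, CurveObservations(s2=s2, values=y, channel="cv"), rce, 1.0)
        assert ll < prev or shift == 0.0
        prev = ll


def test_observations_off_the_grid_are_rejected():
    rce = _toy_rce()
    obs = CurveObservations(s2=np.array([123.456]), values=np.array([1.0]), channel="cv")
    with pytest.raises(ValueError):
        loglik_curve(np.array([0.5, 0.5]), obs, rce, 1.0)


# -- ERP likelihood --------------------------------------------------------

def _erp_density(y, M, V, bracket, spec):
    mi = spec.means(bracket.width)
    s2 = spec.sd(bracket.width) ** 2 + V
    return np.sum(norm.pdf(y + mi, loc=M, scale=np.sqrt(s2))) / spec.n_terms


def test_erp_likelihood_is_an_exact_density_in_y():
    """Quadrature over Y recovers unit mass to 1e-6."""
    spec = ERPLikelihoodSpec(n_terms=10)
    bracket = ERPBracket(s1=600.0, lower=230.0, width=10.0)
    for V in (0.0, 4.0):
        M = 236.0
        mass, _ = quad(lambda y: _erp_density(y, M, V, bracket, spec),
                       M - 10 * (bracket.width + np.sqrt(V) + 1),
                       M + 10 * (bracket.width + np.sqrt(V) + 1), limit=200)
        assert mass == pytest.approx(1.0, abs=1e-6)


def test_single_term_mixture_reduces_to_one_normal_centered_mid_bracket():
    spec = ERPLikelihoodSpec(n_terms=1)
    bracket = ERPBracket(s1=600.0, lower=230.0, width=10.0)
    M, V = 236.0, 1.0
    got = _erp_loglik_terms(np.array([M]), np.array([V]), bracket, spec)[0]
    # one term: delta ~ N(width/2, (width)^2), so Y ~ N(M - width/2, s^2 + V)
    expected = norm.logpdf(bracket.lower, loc=M - 5.0,
                           scale=np.sqrt(spec.sd(10.0) ** 2 + V))
    assert got == pytest.approx(expected, abs=1e-10)


def test_erp_likelihood_nearly_flat_inside_the_bracket():
    """With V=0 the log likelihood varies by < 0.5 while the predicted ERP
    sweeps the central 80% of a 10 ms bracket."""
    spec = ERPLikelihoodSpec(n_terms=10)
    bracket = ERPBracket(s1=600.0, lower=230.0, width=10.0)
    sweep = np.linspace(231.0, 239.0, 81)
    ll = _erp_loglik_terms(sweep, np.zeros_like(sweep), bracket, spec)
    assert ll.max() - ll.min() < 0.5


def test_erp_loglik_logsumexp_equals_naive_sum_where_it_does_not_underflow():
    spec = ERPLikelihoodSpec(n_terms=10)
    bracket = ERPBracket(s1=500.0, lower=240.0, width=10.0)
    for M, V in [(245.0, 0.5), (250.0, 2.0), (238.0, 0.1)]:
        got = _erp_loglik_terms(np.array([M]), np.array([V]), bracket, spec)[0]
        naive = np.log(_erp_density(bracket.lower, M, V, bracket, spec))
        assert got == pytest.approx(naive, abs=1e-10)


def test_erp_loglik_finite_far_outside_the_bracket():
    """Infinite support: no -inf even when the prediction is far away."""
    spec = ERPLikelihoodSpec()
    bracket = ERPBracket(s1=400.0, lower=200.0, width=10.0)
    ll = _erp_loglik_terms(np.array([350.0]), np.array([0.0]), bracket, spec)[0]
    assert np.isfinite(ll)


def test_erp_error_distribution_mass_inside_bracket():
    """The delta-density puts at least 75% of its mass inside the bracket."""
    spec = ERPLikelihoodSpec(n_terms=10)
    width = 10.0
    mi = spec.means(width)
    s = spec.sd(width)
    mass = np.mean(norm.cdf((width - mi) / s) - norm.cdf((0.0 - mi) / s))
    assert mass >= 0.75


def test_erp_loglik_through_rce_slice():
    rce = _toy_rce(seed=6)
    bracket = ERPBracket(s1=rce.basis.grid[4], lower=90.0, width=10.0)
    ll = loglik_erp(np.array([0.5, 0.5]), bracket, rce)
    M, V = rce.predict_scalar(np.array([0.5, 0.5]), bracket.s1)
    expected = _erp_loglik_terms(np.array([M]), np.array([V]), bracket,
                                 ERPLikelihoodSpec())[0]
    assert ll == pytest.approx(expected, abs=1e-12)


# -- posterior assembly ----------------------------------------------------

@pytest.fixture
def toy_problem():
    rce = _toy_rce(seed=8)
    idx = np.array([3, 9, 15])
    s2 = rce.basis.grid[idx]
    means, _ = rce.predict_components(np.array([0.5, 0.5]))
    y = rce.basis.mean[idx] + rce.basis.components[:, idx].T @ means[0]
    obs = CurveObservations(s2=s2, values=y, channel="cv")
    bracket = ERPBracket(s1=rce.basis.grid[6], lower=100.0, width=10.0)
    return CalibrationProblem(curve_obs=[(obs, rce)], erp_brackets=[bracket],
                              rce_erp=rce), obs, rce, bracket


def test_posterior_is_minus_infinity_outside_the_box(toy_problem):
    prob, *_ = toy_problem
    assert prob.log_posterior(np.array([1.5, 0.5]), {"cv": 0.1}) == -np.inf
    assert np.isfinite(prob.log_posterior(np.array([0.5, 0.5]), {"cv": 0.1}))


def test_posterior_is_sum_of_channel_likelihoods_plus_priors(toy_problem):
    prob, obs, rce, bracket = toy_problem
    x = np.array([0.4, 0.6])
    sigma = 0.3
    lp = prob.log_posterior(x, {"cv": sigma})
    expected = (loglik_curve(x, obs, rce, sigma)
                + loglik_erp(x, bracket, rce)
                - np.log(sigma))
    assert lp == pytest.approx(expected, abs=1e-10)


def test_posterior_invariant_to_observation_ordering(toy_problem):
    prob, obs, rce, bracket = toy_problem
    perm = np.array([2, 0, 1])
    obs2 = CurveObservations(s2=obs.s2[perm], values=obs.values[perm], channel="cv")
    prob2 = CalibrationProblem(curve_obs=[(obs2, rce)], erp_brackets=[bracket],
                               rce_erp=rce)
    x = np.array([0.35, 0.55])
    assert prob.log_posterior(x, {"cv": 0.2}) == pytest.approx(
        prob2.log_posterior(x, {"cv": 0.2}), abs=1e-10)


def test_batched_posterior_matches_pointwise(toy_problem):
    prob, *_ = toy_problem
    rng = np.random.default_rng(0)
    X = rng.random((8, 2))
    X[0] = [2.0, 0.5]   # outside
    batch = prob.log_posterior_batch(X, {"cv": 0.25})
    for i in range(8):
        single = prob.log_posterior_batch(X[i:i + 1], {"cv": 0.25})[0]
        assert batch[i] == pytest.approx(single, abs=1e-10) or (
            np.isneginf(batch[i]) and np.isneginf(single))


# -- sampler machinery -----------------------------------------------------

def test_ensemble_sampler_recovers_a_known_truncated_normal_target():
    """Sampling a 5-d truncated normal through the same machinery recovers
    its mean within 3 standard errors."""
    mu = np.array([0.4, 0.5, 0.6, 0.45, 0.55])
    sd = 0.08

    def log_prob(X):
        out = -0.5 * np.sum(((X - mu) / sd) ** 2, axis=1)
        out[np.any((X < 0) | (X > 1), axis=1)] = -np.inf
        return out

    rng = np.random.default_rng(14)
    x0 = mu + 0.01 * rng.standard_normal((32, 5))
    res = run_ensemble(log_prob, x0, n_steps=2000, burn=1000, thin=5, seed=14)
    assert res.samples.shape[1] == 5
    # truncation negligible: target sd known
    n_eff = res.samples.shape[0] / 10.0    # generous autocorrelation allowance
    se = sd / np.sqrt(n_eff)
    np.testing.assert_allclose(res.samples.mean(axis=0), mu, atol=3 * se)
    assert 0.05 < res.acceptance_fraction < 0.95


def test_ensemble_sampler_is_deterministic_given_seed():
    def log_prob(X):
        return -0.5 * np.sum(X**2, axis=1)

    x0 = 0.1 + 0.01 * np.random.default_rng(0).standard_normal((8, 2))
    a = run_ensemble(log_prob, x0, n_steps=50, burn=10, thin=2, seed=3)
    b = run_ensemble(log_prob, x0, n_steps=50, burn=10, thin=2, seed=3)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_mcmc_samples_stay_inside_the_prior_box(toy_problem):
    prob, *_ = toy_problem
    map_res = prob.map_estimate(seed=2, n_starts=4)
    res = prob.run_mcmc(map_res, n_walkers=16, n_steps=200, burn=100, thin=2, seed=2)
    assert np.all(res.samples >= prob.box[:, 0])
    assert np.all(res.samples <= prob.box[:, 1])


def test_map_estimate_is_deterministic_given_seed(toy_problem):
    prob, *_ = toy_problem
    a = prob.map_estimate(seed=5, n_starts=4)
    b = prob.map_estimate(seed=5, n_starts=4)
    np.testing.assert_array_equal(a.x, b.x)
    assert a.sigmas == b.sigmas
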