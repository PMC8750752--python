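"""Bayesian cost decomposition: log-posterior, sampler, diagnostics, oracle."""

import numpy as np
import pytest
from scipy.stats import norm

from hcedecomp import (
    McmcConfig,
    PriorSpec,
    cell_log_posterior,
    fit_all_cells,
    fit_cell,
    grid_posterior,
    rhat,
)
from hcedecomp.panel import DISEASES, IND_COLS

PRIOR = PriorSpec()


def _log_priors(mu, sigma2, prior=PRIOR):
    lp = sum(norm.logpdf(m, prior.mu_loc, prior.mu_sd) for m in mu)
    lp += sum(
        norm.logpdf(np.log(v), prior.logvar_loc, prior.logvar_sd) - np.log(v)
        for v in sigma2
    )
    return lp


def _single(y, disease="circulatory"):
    ind = np.zeros((len(y), 5), int)
    ind[:, DISEASES.index(disease)] = 1
    return np.asarray(y, float), ind


def test_log_posterior_zero_residual_closed_form():
    """One record, one disease, y = mu: the density is the Normal peak."""
    y, ind = _single([2.5])
    sigma2 = 1.7
    got = cell_log_posterior([2.5], [sigma2], y, ind)
    assert got == pytest.approx(-0.5 * np.log(2 * np.pi * sigma2) + _log_priors([2.5], [sigma2]))


def test_log_posterior_additivity_of_components():
    """Two active diseases with mu=(2,5), sigma2=(1,1): the record's
    marginal is Normal(7, 2), so y=7 again hits the density peak."""
    ind = np.zeros((1, 5), int)
    ind[0, 0] = ind[0, 1] = 1
    got = cell_log_posterior([2.0, 5.0], [1.0, 1.0], np.array([7.0]), ind)
    assert got == pytest.approx(-0.5 * np.log(2 * np.pi * 2.0) + _log_priors([2.0, 5.0], [1.0, 1.0]))


def test_log_posterior_matches_per_record_loop():
    rng = np.random.default_rng(8)
    ind = rng.integers(0, 2, size=(40, 5))
    ind[ind.sum(axis=1) == 0, 2] = 1
    y = rng.gamma(2.0, 1.5, size=40)
    mu = rng.normal(2, 1, size=5)
    s2 = rng.uniform(0.5, 3.0, size=5)
    expected = _log_priors(mu, s2)
    for yi, row in zip(y, ind):
        m = float(row @ mu)
        v = float(row @ s2)
        expected += norm.logpdf(yi, m, np.sqrt(v))
    assert cell_log_posterior(mu, s2, y, ind) == pytest.approx(expected)


def test_log_posterior_rejects_empty_indicator_records():
    y = np.array([1.0, 0.0])
    ind = np.array([[1, 0, 0, 0, 0], [0, 0, 0, 0, 0]])
    with pytest.raises(ValueError, match="all indicators zero"):
        cell_log_posterior([1.0], [1.0], y, ind)


# -- R-hat ------------------------------------------------------------------


def test_rhat_constant_chains_is_one():
    with pytest.warns(UserWarning, match="zero-variance"):
        assert rhat(np.full((4, 100), 3.14)) == 1.0


def test_rhat_iid_chains_near_one():
    rng = np.random.default_rng(1)
    draws = rng.normal(size=(4, 4000))
    assert rhat(draws) < 1.01


def test_rhat_separated_chains_diverges():
    rng = np.random.default_rng(2)
    draws = rng.normal(size=(2, 2000))
    draws[1] += 10.0
    assert rhat(draws) > 1.05 * 2


def test_rhat_agrees_with_reference_implementation():
    """Classic split R-hat should track arviz's rank-normalized variant
    closely on well-behaved chains."""
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(3)
    draws = rng.normal(size=(4, 2000)) + rng.normal(scale=0.05, size=(4, 1))
    ours = rhat(draws)
    theirs = float(az.rhat(draws))
    assert ours == pytest.approx(theirs, abs=0.01)


# -- sampler ----------------------------------------------------------------


def test_fit_cell_recovers_single_disease_mean():
    """2000 records from Normal(3, 1): with the weak prior the posterior
    mean must land inside the 99% frequentist CI of the sample mean."""
    rng = np.random.default_rng(12)
    y, ind = _single(rng.normal(3.0, 1.0, size=2000), "neoplasms")
    cp = fit_cell(y, ind, mcmc=McmcConfig(seed=0))
    mu_hat = cp.mu_mean["neoplasms"]
    half = 2.576 * y.std(ddof=1) / np.sqrt(len(y))
    assert abs(mu_hat - y.mean()) < half
    assert cp.converged
    assert cp.absent == [d for d in DISEASES if d != "neoplasms"]


def test_fit_cell_draw_count_matches_settings():
    rng = np.random.default_rng(4)
    y, ind = _single(rng.normal(2, 1, size=50))
    cp = fit_cell(y, ind, mcmc=McmcConfig(n_chains=4, n_iter=6000, n_warmup=2000, seed=1))
    assert cp.mu_draws.shape == (4, 4000, 1)
    assert cp.mu_draws.reshape(-1, 1).shape[0] == 16000


def test_fit_cell_summary_consistency():
    rng = np.random.default_rng(5)
    y, ind = _single(rng.normal(2, 1, size=100))
    cp = fit_cell(y, ind, mcmc=McmcConfig(n_iter=1500, n_warmup=500, seed=2))
    s = cp.summary()
    flat = cp.mu_draws.reshape(-1)
    assert s["mu_mean"].iloc[0] == pytest.approx(flat.mean())
    assert s["mu_q2.5"].iloc[0] == pytest.approx(np.percentile(flat, 2.5))
    assert s["mu_q97.5"].iloc[0] == pytest.approx(np.percentile(flat, 97.5))


def test_fit_cell_deterministic_given_seed():
    rng = np.random.default_rng(6)
    y, ind = _single(rng.normal(1, 0.3, size=80))
    a = fit_cell(y, ind, mcmc=McmcConfig(n_iter=1200, n_warmup=400, seed=7))
    b = fit_cell(y, ind, mcmc=McmcConfig(n_iter=1200, n_warmup=400, seed=7))
    np.testing.assert_array_equal(a.mu_draws, b.mu_draws)


def test_fit_cell_flags_rank_deficient_design():
    """Two diseases that only ever co-occur cannot be separated by the
    likelihood; the fit proceeds but carries a design warning."""
    rng = np.random.default_rng(9)
    ind = np.zeros((60, 5), int)
    ind[:, 0] = ind[:, 1] = 1
    y = rng.normal(6.0, 1.0, size=60)
    cp = fit_cell(y, ind, mcmc=McmcConfig(n_iter=1500, n_warmup=500, seed=3))
    assert any("rank-deficient" in w for w in cp.warnings_)


@pytest.mark.parametrize("case", ["one_disease", "two_disease"])
def test_mcmc_matches_grid_quadrature(case):
    """Posterior means from MCMC agree with deterministic grid integration
    on small instances (<= 2 active diseases) within 2% relative error."""
    rng = np.random.default_rng(31)
    if case == "one_disease":
        y, ind = _single(rng.normal(3.0, 1.0, size=25), "ckd")
    else:
        ind = np.zeros((30, 5), int)
        ind[:12, 0] = 1
        ind[12:22, 3] = 1
        ind[22:, 0] = ind[22:, 3] = 1
        y = ind[:, 0] * 2.0 + ind[:, 3] * 5.0 + rng.normal(0, 1.0, size=30)
    g = grid_posterior(y, ind)
    cp = fit_cell(y, ind, mcmc=McmcConfig(seed=13))
    mcmc_mu = np.array([cp.mu_mean[d] for d in g["diseases"]])
    np.testing.assert_allclose(mcmc_mu, g["mu_mean"], rtol=0.02)


def test_fit_all_cells_covers_and_reproduces(tiny_panel):
    panel, _ = tiny_panel
    mcmc = McmcConfig(n_iter=800, n_warmup=300, seed=5)
    post = fit_all_cells(panel, "none", mcmc=mcmc)
    assert len(post) == 24
    assert post.skipped_ == []
    post2 = fit_all_cells(panel, "none", mcmc=mcmc)
    for key in post:
        np.testing.assert_array_equal(post[key].mu_draws, post2[key].mu_draws)


def test_posterior_means_nonnegative_on_defaults(tiny_panel):
    """On default synthetic panels the estimated component costs stay
    non-negative even though the model does not force positivity."""
    panel, _ = tiny_panel
    post = fit_all_cells(panel, "none", mcmc=McmcConfig(n_iter=800, n_warmup=300, seed=6))
    for cp in post.values():
        for mu in cp.mu_mean.values():
            assert np.isfinite(mu) and mu >= 0
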