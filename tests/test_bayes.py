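"""Hierarchical-inference machinery: distributions, likelihood, diagnostics,
subsampling, and sampler correctness on closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from translearn.bayes import (
    Distribution,
    HierarchicalModel,
    IndividualData,
    PriorSpec,
    gelman_rubin,
    log_likelihood,
    posterior_subsample,
    run_mcmc,
)
from translearn.pbpk.types import ConcentrationProfile, ValidationError


def _profile(conc, iid="i1", compound="c"):
    conc = np.asarray(conc, float)
    return ConcentrationProfile(iid, compound, np.arange(1.0, conc.size + 1), conc)


class TestDistribution:
    def test_truncated_density_renormalizes_to_one(self):
        d = Distribution("normal", 0.0, 1.0, lower_bound=-1.0, upper_bound=2.0)
        mass, _ = quad(lambda x: math.exp(float(d.logpdf(x))), -1.0, 2.0)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_lognormal_parameters_are_on_log_scale(self):
        d = Distribution("lognormal", location=math.log(5.0), scale=0.25)
        assert d.mean() == pytest.approx(5.0 * math.exp(0.25**2 / 2))
        rng = np.random.default_rng(0)
        x = d.sample(rng, 20_000)
        assert np.mean(np.log(x)) == pytest.approx(math.log(5.0), abs=0.01)

    def test_uniform_requires_finite_bounds(self):
        with pytest.raises(ValidationError):
            Distribution("uniform", lower_bound=0.0, upper_bound=math.inf)

    def test_truncated_sampling_respects_bounds(self):
        d = Distribution("normal", 0.0, 1.0, lower_bound=0.5, upper_bound=1.0)
        x = d.sample(np.random.default_rng(1), 1000)
        assert np.all((x >= 0.5) & (x <= 1.0))


class TestLogLikelihood:
    def test_zero_residuals_maximize_density_for_fixed_sigma(self):
        obs = {"c": _profile([1.0, 2.0, 4.0])}
        exact = log_likelihood({"c": np.array([1.0, 2.0, 4.0])}, obs, sigma=0.2)
        off = log_likelihood({"c": np.array([1.1, 2.0, 4.0])}, obs, sigma=0.2)
        assert exact > off

    def test_sigma_doubling_changes_density_by_closed_form(self):
        pred = np.array([1.2, 1.8, 4.4])
        obs = {"c": _profile([1.0, 2.0, 4.0])}
        sigma = 0.3
        ssr = float(np.sum((np.log(pred) - np.log([1.0, 2.0, 4.0])) ** 2))
        expected_delta = (ssr / (2 * sigma**2) - ssr / (2 * (2 * sigma) ** 2)
                          - 3 * math.log(2.0))
        delta = (log_likelihood({"c": pred}, obs, 2 * sigma)
                 - log_likelihood({"c": pred}, obs, sigma))
        assert delta == pytest.approx(expected_delta, rel=1e-12)

    def test_nonpositive_observation_rejected(self):
        obs = {"c": _profile([1.0, 0.0, 4.0])}
        with pytest.raises(ValidationError, match="positive"):
            log_likelihood({"c": np.ones(3)}, obs, 0.2)

    def test_mismatched_grids_rejected(self):
        obs = {"c": _profile([1.0, 2.0, 4.0])}
        with pytest.raises(ValidationError, match="grid"):
            log_likelihood({"c": np.ones(2)}, obs, 0.2)


class TestGelmanRubin:
    def test_identical_long_chains_give_unity(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((4000, 2))
        rhat = gelman_rubin(chain)
        assert np.all(np.abs(rhat - 1.0) < 0.01)

    def test_separated_chains_detected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((1000, 1))
        b = rng.standard_normal((1000, 1)) + 5.0
        rhat = gelman_rubin(np.stack([a, b]))
        assert rhat[0] > 3.0  # far beyond any convergence threshold

    def test_agrees_with_reference_implementation_on_white_noise(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 800, 1))
        ours = gelman_rubin(chains)[0]
        theirs = float(arviz.rhat(chains[:, :, 0]))
        assert ours == pytest.approx(theirs, abs=0.05)
        assert abs(ours - 1.0) < 0.02

    def test_constant_chain_yields_nan(self):
        chain = np.ones((400, 1))
        assert np.isnan(gelman_rubin(chain)[0])


class TestPosteriorSubsample:
    def _result(self, n_iter=100_000, burn_in=0):
        from translearn.bayes import McmcResult

        rng = np.random.default_rng(0)
        chains = rng.standard_normal((n_iter, 1))
        return McmcResult(
            chains=chains, columns=("x",), acceptance={}, rhat={"x": 1.0},
            burn_in=burn_in, log_posterior=np.zeros(n_iter), seed=0,
            param_names=("x",), log_scale={"x": False},
        )

    def test_full_subsample_is_a_permutation(self):
        res = self._result(n_iter=512)
        sub = posterior_subsample(res, n=512, seed=3)
        assert np.array_equal(np.sort(sub[:, 0]), np.sort(res.chains[:, 0]))

    def test_default_stride_from_long_chain(self):
        res = self._result(n_iter=100_000)
        sub = posterior_subsample(res, n=500, seed=0)
        assert sub.shape == (500, 1)
        # stride floor(100000/500)=200: one draw per block of 200
        sub2 = posterior_subsample(res, n=500, seed=0)
        assert np.array_equal(sub, sub2)

    def test_subsample_mean_tracks_chain_mean(self):
        res = self._result(n_iter=20_000)
        sub = posterior_subsample(res, n=500, seed=1)
        se = res.chains.std() / math.sqrt(500)
        assert abs(sub.mean() - res.chains.mean()) < 2 * se

    def test_insufficient_length_reported(self):
        res = self._result(n_iter=512)
        with pytest.raises(ValidationError, match="600"):
            posterior_subsample(res, n=600, seed=0)


def _toy_model(y_log, omega, sigma, prior=("normal", 0.0, 1.0)):
    """Hierarchy on a constant-prediction model: log y_ij ~ N(θ_i, σ²),
    θ_i ~ N(µ, ω²) — fully conjugate, closed-form marginal for µ."""
    n_ind, n_obs = y_log.shape
    data = [
        IndividualData(f"i{i}", {"c": _profile(np.exp(y_log[i]), iid=f"i{i}")})
        for i in range(n_ind)
    ]
    predict_fns = [
        (lambda theta, _n=n_obs: {"c": np.full(_n, math.exp(theta[0]))})
        for _ in range(n_ind)
    ]
    priors = PriorSpec(entries={"theta": Distribution(*prior)})
    return HierarchicalModel(
        param_names=("theta",), priors=priors, predict_fns=predict_fns, data=data,
        fixed_omega={"theta": omega}, fixed_sigma=sigma,
    )


class TestSampler:
    def test_fixed_seed_reproduces_chains_bitwise(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.3, 0.2, size=(3, 4))
        model = _toy_model(y, omega=0.3, sigma=0.2)
        r1 = run_mcmc(model, n_iter=400, seed=11)
        r2 = run_mcmc(model, n_iter=400, seed=11)
        assert np.array_equal(r1.chains, r2.chains)
        r3 = run_mcmc(model, n_iter=400, seed=12)
        assert not np.array_equal(r1.chains, r3.chains)

    def test_conjugate_toy_matches_closed_form_posterior(self):
        m0, s0 = 0.2, 1.0
        omega, sigma = 0.4, 0.3
        rng = np.random.default_rng(7)
        n_ind, n_obs = 6, 5
        y = rng.normal(0.8, 0.5, size=(n_ind, n_obs))
        model = _toy_model(y, omega=omega, sigma=sigma, prior=("normal", m0, s0))
        result = run_mcmc(model, n_iter=20_000, seed=3)
        mu_chain = result.column("mu__theta")[result.burn_in:]
        # closed form: precision-weighted combination of the prior and the
        # individual means, each carrying variance ω² + σ²/J
        v_i = omega**2 + sigma**2 / n_obs
        prec = 1 / s0**2 + n_ind / v_i
        mean = (m0 / s0**2 + y.mean(axis=1).sum() / v_i) / prec
        sd = math.sqrt(1 / prec)
        assert mu_chain.mean() == pytest.approx(mean, abs=0.15 * sd)
        assert mu_chain.std() == pytest.approx(sd, rel=0.10)

    def test_prior_recovered_when_no_data(self):
        """With zero observations the marginal of the population mean must
        reproduce its prior (Kolmogorov–Smirnov)."""
        prior_loc, prior_scale = 1.0, 0.7
        data = [IndividualData("i0", {})]
        model = HierarchicalModel(
            param_names=("theta",),
            priors=PriorSpec(entries={"theta": Distribution("normal", prior_loc, prior_scale)}),
            predict_fns=[lambda theta: {}],
            data=data,
            fixed_sigma=0.2,
        )
        result = run_mcmc(model, n_iter=300_000, seed=21)
        sub = posterior_subsample(result, n=5000, seed=1)
        mu = sub[:, result.columns.index("mu__theta")]
        ks = stats.kstest(mu, "norm", args=(prior_loc, prior_scale))
        assert ks.pvalue > 0.01

    def test_posterior_concentrates_with_informative_data(self):
        rng = np.random.default_rng(9)
        y = rng.normal(1.5, 0.1, size=(8, 6))
        model = _toy_model(y, omega=0.2, sigma=0.1, prior=("normal", 0.0, 1.0))
        result = run_mcmc(model, n_iter=4000, seed=2)
        mu = result.column("mu__theta")[result.burn_in:]
        assert abs(mu.mean() - 1.5) < 0.2  # data pull the mean off the prior
        assert mu.std() < 0.5  # and sharpen it relative to the prior

    def test_more_individuals_do_not_widen_population_mean_posterior(self):
        """Adding individuals sharpens (never widens) the posterior of an
        identifiable population mean, up to Monte-Carlo noise."""
        rng = np.random.default_rng(17)
        y_big = rng.normal(0.8, 0.35, size=(16, 5))
        sds = {}
        for n_ind in (4, 16):
            model = _toy_model(y_big[:n_ind], omega=0.3, sigma=0.25)
            res = run_mcmc(model, n_iter=6000, seed=1)
            sds[n_ind] = res.column("mu__theta")[res.burn_in:].std()
        assert sds[16] < sds[4] * 1.1

    def test_uniform_prior_stays_inside_bounds(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0.5, 0.3, size=(3, 4))
        model = _toy_model(y, omega=0.3, sigma=0.3,
                           prior=("uniform", 0.0, 1.0, -1.0, 1.0))
        result = run_mcmc(model, n_iter=1500, seed=4)
        mu = result.column("mu__theta")
        assert np.all((mu >= -1.0) & (mu <= 1.0))
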