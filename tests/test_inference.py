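import numpy as np
import pytest
from scipy.special import gammaln

from countpower.distributions import CountFamily
from countpower.inference import (
    FAST_MCMC,
    McmcConfig,
    ModelSpec,
    PriorSpec,
    build_evaluator,
    detect_effect,
    estimate_log_bml,
    log_likelihood,
    posterior_model_probs,
    run_mcmc,
    sample_posterior,
)
from countpower.simulate import (
    CountDataset,
    EffectSpec,
    simulate_dataset,
    to_frequency,
)

POISSON = CountFamily("poisson")


# ---------------------------------------------------------------------------
# conjugate models with closed-form marginal likelihoods (oracles)
# ---------------------------------------------------------------------------

class ConjugatePoissonGamma:
    """y_i ~ Poisson(lam * f_i), lam ~ Gamma(a, rate b), parameter u = log lam.

    Implements the evaluator interface used by the sampler and the
    importance-sampling BML, with an analytic marginal likelihood.
    """

    def __init__(self, y, f, a, b):
        self.y = np.asarray(y, dtype=float)
        self.f = np.asarray(f, dtype=float)
        self.a, self.b = float(a), float(b)
        self.dim = 1
        self.names = ["log_lam"]
        self._init_loc = np.array([np.log(max(self.y.sum() / self.f.sum(), 1e-3))])
        self._init_scale = np.array([0.5])

    def log_likelihood(self, theta):
        u = theta[..., 0]
        return (
            self.y * (u[..., None] + np.log(self.f))
            - np.exp(u)[..., None] * self.f
            - gammaln(self.y + 1)
        ).sum(-1)

    def log_prior(self, theta):
        u = theta[..., 0]
        # Gamma(a, b) density at e^u, plus the log-transform Jacobian
        return (
            self.a * np.log(self.b) - gammaln(self.a) + self.a * u - self.b * np.exp(u)
        )

    def log_post(self, theta):
        lp = self.log_prior(theta) + self.log_likelihood(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def init_positions(self, rng, n, jitter=1.0):
        return self._init_loc + jitter * self._init_scale * rng.standard_normal((n, 1))

    def closed_form_log_marginal(self):
        Y, F = self.y.sum(), self.f.sum()
        return (
            (self.y * np.log(self.f)).sum()
            - gammaln(self.y + 1).sum()
            + self.a * np.log(self.b)
            - gammaln(self.a)
            + gammaln(self.a + Y)
            - (self.a + Y) * np.log(self.b + F)
        )


class ConjugateExponentialGamma:
    """x_i ~ Exponential(rate r), r ~ Gamma(a, rate b), parameter u = log r.

    The conjugate analogue for the continuous part of the frequency model.
    """

    def __init__(self, x, a, b):
        self.x = np.asarray(x, dtype=float)
        self.a, self.b = float(a), float(b)
        self.dim = 1
        self.names = ["log_rate"]
        self._init_loc = np.array([np.log(1.0 / max(self.x.mean(), 1e-3))])
        self._init_scale = np.array([0.5])

    def log_likelihood(self, theta):
        u = theta[..., 0]
        n = self.x.size
        return n * u - np.exp(u) * self.x.sum()

    def log_prior(self, theta):
        u = theta[..., 0]
        return self.a * np.log(self.b) - gammaln(self.a) + self.a * u - self.b * np.exp(u)

    def log_post(self, theta):
        lp = self.log_prior(theta) + self.log_likelihood(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def init_positions(self, rng, n, jitter=1.0):
        return self._init_loc + jitter * self._init_scale * rng.standard_normal((n, 1))

    def closed_form_log_marginal(self):
        n, S = self.x.size, self.x.sum()
        return (
            self.a * np.log(self.b)
            - gammaln(self.a)
            + gammaln(self.a + n)
            - (self.a + n) * np.log(self.b + S)
        )


def _single_row_dataset():
    return CountDataset(flowers=np.array([100]), visits=np.array([0]),
                        x=np.array([0.0]))


# ---------------------------------------------------------------------------
# ModelSpec / likelihood
# ---------------------------------------------------------------------------

class TestModelSpec:
    def test_count_rejects_zi_gamma(self):
        with pytest.raises(ValueError):
            ModelSpec("count", "zi_gamma", "none", "fixed_linear")

    def test_count_rejects_mean_and_zi(self):
        with pytest.raises(ValueError):
            ModelSpec("count", "poisson", "mean_and_zi", "fixed_linear")

    def test_frequency_requires_zi_gamma(self):
        with pytest.raises(ValueError):
            ModelSpec("frequency", "poisson", "none", "fixed_linear")

    def test_effect_flag(self):
        assert not ModelSpec("count", "poisson", "none", "fixed_linear").is_effect_model
        assert ModelSpec("count", "poisson", "mean_only", "fixed_linear").is_effect_model


class TestLogLikelihood:
    def test_null_poisson_single_row(self):
        model = ModelSpec("count", "poisson", "none", "fixed_categorical")
        theta = np.array([np.log(0.02)])
        assert log_likelihood(model, _single_row_dataset(), theta) == pytest.approx(-2.0)

    def test_row_permutation_invariance(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 3)
        model = ModelSpec("count", "negbinom", "mean_only", "fixed_categorical")
        theta = np.array([np.log(0.02), 0.4, np.log(8.0)])
        base = log_likelihood(model, ds, theta)
        perm = np.random.default_rng(0).permutation(30)
        shuffled = CountDataset(flowers=ds.flowers[perm], visits=ds.visits[perm],
                                x=ds.x[perm])
        assert log_likelihood(model, shuffled, theta) == pytest.approx(base, rel=1e-12)

    def test_zinb_with_zero_inflation_off_equals_nb(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 3)
        zinb = ModelSpec("count", "zi_negbinom", "mean_only", "fixed_categorical")
        nb = ModelSpec("count", "negbinom", "mean_only", "fixed_categorical")
        theta_nb = np.array([np.log(0.02), 0.4, np.log(8.0)])
        theta_zinb = np.concatenate([theta_nb, [-38.0]])  # logit p_zi -> p_zi ~ 0
        assert log_likelihood(zinb, ds, theta_zinb) == pytest.approx(
            log_likelihood(nb, ds, theta_nb), abs=1e-9
        )

    def test_frequency_model_ignores_exposure(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 3)
        fds = to_frequency(ds)
        model = ModelSpec("frequency", "zi_gamma", "mean_only", "fixed_categorical")
        theta = np.array([np.log(0.02), 0.4, np.log(1.5), 2.0])
        base = log_likelihood(model, fds, theta)
        fds.meta["flowers"] = fds.meta["flowers"] * 10  # metadata only
        assert log_likelihood(model, fds, theta) == base

    def test_batched_theta(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 3)
        model = ModelSpec("count", "poisson", "mean_only", "fixed_categorical")
        thetas = np.array([[np.log(0.02), 0.0], [np.log(0.02), 0.5]])
        out = log_likelihood(model, ds, thetas)
        assert out.shape == (2,)
        assert out[0] == pytest.approx(log_likelihood(model, ds, thetas[0]))

    def test_dimension_mismatch(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 3)
        model = ModelSpec("count", "poisson", "mean_only", "fixed_categorical")
        with pytest.raises(ValueError, match="last axis"):
            log_likelihood(model, ds, np.zeros(5))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

class TestMcmc:
    def test_parameter_recovery_null_poisson(self, exposure):
        spec = EffectSpec("fixed_categorical", strength=0.0, effect_present=False)
        ds = simulate_dataset(POISSON, spec, exposure, 1000, 17)
        model = ModelSpec("count", "poisson", "none", "fixed_categorical")
        chains = run_mcmc(model, ds, config=FAST_MCMC, seed=1)
        lam = np.exp(chains.flat[:, 0]).mean()
        assert lam == pytest.approx(0.02, rel=0.10)
        assert chains.converged

    def test_determinism(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 17)
        model = ModelSpec("count", "negbinom", "mean_only", "fixed_categorical")
        a = run_mcmc(model, ds, config=FAST_MCMC, seed=7)
        b = run_mcmc(model, ds, config=FAST_MCMC, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_nb_on_poisson_data_concentrates_on_large_k(self, exposure):
        spec = EffectSpec("fixed_categorical", strength=0.0, effect_present=False)
        ds = simulate_dataset(POISSON, spec, exposure, 500, 23)
        model = ModelSpec("count", "negbinom", "none", "fixed_categorical")
        chains = run_mcmc(model, ds, config=McmcConfig(n_iter=1500, n_chains=4), seed=2)
        k = np.exp(chains.flat[:, chains.names.index("log_k")])
        assert np.quantile(k, 0.05) > 10.0

    def test_burnin_must_leave_samples(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 17)
        model = ModelSpec("count", "poisson", "none", "fixed_categorical")
        with pytest.raises(ValueError, match="burn-in"):
            run_mcmc(model, ds, config=McmcConfig(n_iter=100, burn_frac=1.0), seed=0)

    def test_diagnostics_populated(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 17)
        model = ModelSpec("count", "poisson", "mean_only", "fixed_categorical")
        chains = run_mcmc(model, ds, config=FAST_MCMC, seed=3)
        assert chains.rhat.shape == (2,)
        assert np.all(np.isfinite(chains.rhat))
        assert 0.05 < chains.accept_rate < 0.6
        assert np.all(np.isfinite(chains.draws))


class TestCredibleCoverage:
    def test_fixed_effect_posterior_covers_truth(self, exposure):
        """90% credible intervals for beta cover the truth at roughly the
        nominal rate (scaled-down replicate count)."""
        model = ModelSpec("count", "poisson", "mean_only", "fixed_categorical")
        spec = EffectSpec("fixed_categorical", strength=0.6)
        hits = 0
        n_rep = 40
        for r in range(n_rep):
            ds = simulate_dataset(POISSON, spec, exposure, 30, 1000 + r)
            chains = run_mcmc(model, ds, config=FAST_MCMC, seed=r)
            beta = chains.flat[:, chains.names.index("beta")]
            lo, hi = np.quantile(beta, [0.05, 0.95])
            hits += lo <= 0.6 <= hi
        # binomial(40, 0.9): central 99.9% range is about [30, 40]
        assert hits >= 30


# ---------------------------------------------------------------------------
# BML estimation
# ---------------------------------------------------------------------------

class TestBml:
    def test_conjugate_poisson_gamma(self):
        rng = np.random.default_rng(1)
        for i in range(5):
            n = rng.integers(3, 10)
            f = rng.integers(5, 200, n).astype(float)
            y = rng.poisson(rng.gamma(2.0, 0.02) * f)
            ev = ConjugatePoissonGamma(y, f, a=rng.uniform(0.5, 3), b=rng.uniform(5, 50))
            chains = sample_posterior(ev, FAST_MCMC, seed=i)
            est = estimate_log_bml(chains, n_draws=2000, seed=100 + i)
            assert est.log_bml == pytest.approx(
                ev.closed_form_log_marginal(), abs=3 * est.mc_se
            )

    def test_conjugate_exponential_gamma(self):
        rng = np.random.default_rng(2)
        for i in range(5):
            x = rng.exponential(0.5, size=rng.integers(5, 20))
            ev = ConjugateExponentialGamma(x, a=rng.uniform(1, 4), b=rng.uniform(0.5, 3))
            chains = sample_posterior(ev, FAST_MCMC, seed=i)
            est = estimate_log_bml(chains, n_draws=2000, seed=200 + i)
            assert est.log_bml == pytest.approx(
                ev.closed_form_log_marginal(), abs=3 * est.mc_se
            )

    def test_mc_se_scaling_with_draws(self):
        rng = np.random.default_rng(3)
        f = rng.integers(5, 200, 8).astype(float)
        y = rng.poisson(0.02 * f)
        ev = ConjugatePoissonGamma(y, f, a=2.0, b=20.0)
        chains = sample_posterior(ev, FAST_MCMC, seed=0)
        se1 = np.mean([estimate_log_bml(chains, n_draws=1000, seed=s).mc_se
                       for s in range(12)])
        se2 = np.mean([estimate_log_bml(chains, n_draws=2000, seed=100 + s).mc_se
                       for s in range(12)])
        assert se1 / se2 == pytest.approx(np.sqrt(2.0), rel=0.15)

    def test_loglik_shift_shifts_bml_by_constant(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 5)
        model = ModelSpec("count", "poisson", "mean_only", "fixed_categorical")
        ev = build_evaluator(model, ds)

        class Shifted:
            dim = ev.dim
            names = ev.names
            _init_loc = ev._init_loc
            _init_scale = ev._init_scale

            def log_likelihood(self, th):
                return ev.log_likelihood(th) + 7.5

            def log_prior(self, th):
                return ev.log_prior(th)

            def log_post(self, th):
                return ev.log_post(th) + 7.5

            def init_positions(self, rng, n, jitter=1.0):
                return ev.init_positions(rng, n, jitter)

        a = estimate_log_bml(sample_posterior(ev, FAST_MCMC, 11), n_draws=500, seed=4)
        b = estimate_log_bml(sample_posterior(Shifted(), FAST_MCMC, 11), n_draws=500, seed=4)
        assert b.log_bml - a.log_bml == pytest.approx(7.5, abs=1e-9)

    def test_reports_mc_se_and_ess(self, exposure, binary_effect):
        ds = simulate_dataset(POISSON, binary_effect, exposure, 30, 5)
        model = ModelSpec("count", "poisson", "none", "fixed_categorical")
        chains = run_mcmc(model, ds, config=FAST_MCMC, seed=0)
        est = estimate_log_bml(chains, n_draws=800, seed=0)
        assert est.mc_se > 0
        assert 0 < est.ess <= 800
        assert est.n_draws == 800


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

class TestPosteriorModelProbs:
    def test_equal_bmls_equal_priors(self):
        probs = posterior_model_probs([-10.0, -10.0, -10.0, -10.0])
        np.testing.assert_allclose(probs, 0.25)

    def test_log3_difference(self):
        probs = posterior_model_probs([np.log(3.0), 0.0])
        np.testing.assert_allclose(probs, [0.75, 0.25], rtol=1e-12)

    def test_zero_prior_gives_zero_posterior(self):
        probs = posterior_model_probs([0.0, 0.0], [1.0, 0.0])
        np.testing.assert_allclose(probs, [1.0, 0.0])

    def test_sums_to_one_and_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        log_bmls = rng.normal(-50, 5, size=6)
        probs = posterior_model_probs(log_bmls)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        perm = rng.permutation(6)
        np.testing.assert_allclose(posterior_model_probs(log_bmls[perm]), probs[perm])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            posterior_model_probs([])

    def test_bad_prior_sum(self):
        with pytest.raises(ValueError):
            posterior_model_probs([0.0, 0.0], [0.7, 0.7])


class TestDetectEffect:
    def test_tie_is_no_effect(self):
        res = detect_effect([-5.0], [-5.0], prior_odds_threshold=1.0)
        assert res.score == 0.0
        assert not res.found

    def test_score_uses_best_of_each_group(self):
        res = detect_effect([-10.0, -4.0], [-6.0, -12.0])
        assert res.score == pytest.approx(2.0)
        assert res.found

    def test_constant_shift_invariance(self):
        a = detect_effect([-10.0, -4.0], [-6.0, -12.0])
        b = detect_effect([90.0, 96.0], [94.0, 88.0])
        assert a.score == pytest.approx(b.score)

    def test_threshold_limits(self):
        assert not detect_effect([0.0], [-3.0], prior_odds_threshold=1e12).found
        assert detect_effect([-3.0], [0.0], prior_odds_threshold=1e-12).found

    def test_empty_groups_raise(self):
        with pytest.raises(ValueError):
            detect_effect([], [0.0])
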