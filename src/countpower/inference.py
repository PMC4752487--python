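"""Bayesian estimation and model comparison.

For every dataset the analysis fits a small set of models by adaptive
random-walk Metropolis on the unconstrained parameter scale, estimates the
Bayesian model likelihood (the marginal likelihood, BML) by importance
sampling from a moment-matched multivariate-t density, and declares an
effect found when the best effect model beats the best no-effect model by
more than a prior-odds threshold.

Count models use ``log(flowers)`` as an offset; frequency models never see
the exposure.  Random effects enter as explicit latent parameters, so the
importance-sampling integral marginalizes them together with everything
else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln, logsumexp

from .distributions import zi_gamma_loglik
from .simulate import CountDataset, FrequencyDataset

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "McmcConfig",
    "PosteriorChains",
    "BMLEstimate",
    "ModelEvaluator",
    "build_evaluator",
    "log_likelihood",
    "run_mcmc",
    "sample_posterior",
    "estimate_log_bml",
    "model_log_bml",
    "posterior_model_probs",
    "detect_effect",
    "DetectResult",
]

COUNT_FAMILIES = ("poisson", "negbinom", "zi_negbinom")
EFFECT_STRUCTURES = ("none", "mean_only", "mean_and_zi")

_CLIP = 40.0  # bound on log-scale linear predictors to keep exp() finite


@dataclass(frozen=True)
class ModelSpec:
    """One analysis model: data representation x family x effect structure."""

    data_kind: str  # "count" | "frequency"
    family: str  # count: poisson | negbinom | zi_negbinom; frequency: zi_gamma
    effect_structure: str  # none | mean_only | mean_and_zi
    effect_type: str  # as simulate.EffectSpec
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.data_kind not in ("count", "frequency"):
            raise ValueError("data_kind must be 'count' or 'frequency'")
        if self.effect_structure not in EFFECT_STRUCTURES:
            raise ValueError(f"unknown effect_structure {self.effect_structure!r}")
        if self.data_kind == "count":
            if self.family not in COUNT_FAMILIES:
                raise ValueError(f"count family must be one of {COUNT_FAMILIES}")
            if self.effect_structure == "mean_and_zi":
                raise ValueError("mean_and_zi is only defined for frequency models")
        else:
            if self.family != "zi_gamma":
                raise ValueError("frequency family must be 'zi_gamma'")

    @property
    def is_effect_model(self) -> bool:
        return self.effect_structure != "none"

    @property
    def label(self) -> str:
        return f"{self.data_kind}:{self.family}:{self.effect_structure}"


@dataclass(frozen=True)
class PriorSpec:
    """Wide-but-informative priors, centered at the simulation operating point.

    Each entry is (location, scale) of a normal on the unconstrained scale,
    except ``sigma_scale`` which is the scale of a half-normal on
    random-effect standard deviations.
    """

    log_lambda0: tuple[float, float] = (np.log(0.02), 2.0)
    beta: tuple[float, float] = (0.0, 2.0)
    sigma_scale: float = 1.0
    log_k: tuple[float, float] = (np.log(10.0), 2.0)
    zi_logit: tuple[float, float] = (-2.0, 2.0)
    log_shape: tuple[float, float] = (0.0, 2.0)
    g: tuple[float, float] = (0.0, 3.0)
    zi_effect: tuple[float, float] = (0.0, 2.0)


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 10_000
    n_chains: int = 2
    burn_frac: float = 0.5
    target_accept: float = 0.234
    adapt_interval: int = 100
    init_jitter: float = 1.0

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_frac)


#: fast preset used by the batch experiments (many small fits)
FAST_MCMC = McmcConfig(n_iter=700, n_chains=4, burn_frac=0.5)


@dataclass
class PosteriorChains:
    draws: np.ndarray  # (n_chains, n_kept, dim)
    log_post: np.ndarray  # (n_chains, n_kept)
    accept_rate: float
    rhat: np.ndarray  # (dim,)
    names: list[str]
    evaluator: "ModelEvaluator"

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat < 1.1))


@dataclass
class BMLEstimate:
    log_bml: float
    mc_se: float
    n_draws: int
    ess: float
    degenerate: bool = False


@dataclass(frozen=True)
class DetectResult:
    found: bool
    score: float


# ---------------------------------------------------------------------------
# model evaluator: log likelihood / prior on the unconstrained scale
# ---------------------------------------------------------------------------

class ModelEvaluator:
    """Vectorized log-likelihood/log-prior for one model on one dataset.

    ``theta`` may have any leading shape ``(..., dim)``; all evaluations
    broadcast, which lets the sampler run an ensemble of chains and the
    importance sampler score thousands of draws in one call.
    """

    def __init__(self, model: ModelSpec, dataset, prior: PriorSpec | None = None,
                 zi_link: str = "corrected"):
        prior = prior or PriorSpec()
        self.model = model
        self.prior = prior
        self.zi_link = zi_link
        if model.data_kind == "count":
            if not isinstance(dataset, CountDataset):
                raise TypeError("count models require a CountDataset")
            self._y = dataset.visits.astype(float)
            self._logf = np.log(dataset.flowers.astype(float))
            self._gammaln_y1 = gammaln(self._y + 1.0)
        else:
            if not isinstance(dataset, FrequencyDataset):
                raise TypeError("frequency models require a FrequencyDataset")
            self._freq = dataset.freq.astype(float)
        self._x = None if dataset.x is None else dataset.x.astype(float)
        self._cat = None if dataset.category is None else dataset.category.astype(np.intp)
        self._layout(dataset)

    # -- parameter layout ---------------------------------------------------
    def _layout(self, dataset) -> None:
        m, prior = self.model, self.prior
        names: list[str] = []
        loc: list[float] = []
        scale: list[float] = []
        init: list[float] = []

        def add(name, prior_pair, init_val=None):
            names.append(name)
            loc.append(prior_pair[0])
            scale.append(prior_pair[1])
            init.append(prior_pair[0] if init_val is None else init_val)

        if m.data_kind == "count":
            lam_hat = max(float(self._y.sum()) / float(np.exp(self._logf).sum()), 1e-4)
            add("log_lambda0", prior.log_lambda0, np.log(lam_hat))
        else:
            mu_hat = max(float(np.mean(self._freq)), 1e-4)
            add("log_mu0", prior.log_lambda0, np.log(mu_hat))

        self._i_eff = None
        self._i_sigma = None
        self._sl_latent = None
        if m.is_effect_model:
            if m.effect_type in ("fixed_categorical", "fixed_linear"):
                self._i_eff = len(names)
                add("beta", prior.beta, 0.0)
            else:
                self._i_sigma = len(names)
                # half-normal prior handled separately; loc/scale entries unused
                add("log_sigma", (0.0, 1.0), np.log(0.3))
                start = len(names)
                base = "eps" if m.effect_type == "random_intercept" else "slope"
                for j in range(m.n_categories):
                    add(f"{base}_{j}", (0.0, 1.0), 0.0)
                self._sl_latent = slice(start, start + m.n_categories)

        self._i_logk = None
        self._i_zilogit = None
        self._i_logshape = None
        self._i_g = None
        self._i_zicoef = None
        if m.data_kind == "count":
            if m.family in ("negbinom", "zi_negbinom"):
                self._i_logk = len(names)
                add("log_k", prior.log_k)
            if m.family == "zi_negbinom":
                self._i_zilogit = len(names)
                add("zi_logit", prior.zi_logit)
        else:
            self._i_logshape = len(names)
            add("log_shape", prior.log_shape)
            self._i_g = len(names)
            zero_frac = float(np.mean(self._freq == 0.0))
            p0 = min(max(zero_frac, 0.02), 0.98)
            mu_hat = float(np.exp(init[0]))
            g0 = float(np.log((1.0 - p0) / (p0 * mu_hat)))
            add("g", prior.g, g0)
            if m.effect_structure == "mean_and_zi":
                self._i_zicoef = len(names)
                add("zi_coef", prior.zi_effect, 0.0)

        # plain-normal prior mask (everything except log_sigma + latents)
        mask = np.ones(len(names), dtype=bool)
        if self._i_sigma is not None:
            mask[self._i_sigma] = False
            mask[self._sl_latent] = False
        self.names = names
        self.dim = len(names)
        self._prior_loc = np.asarray(loc)
        self._prior_scale = np.asarray(scale)
        self._normal_mask = mask
        self._init_loc = np.asarray(init)
        self._init_scale = np.where(mask, 0.5, 0.3)

    # -- effect terms -------------------------------------------------------
    def _effect_term(self, theta):
        """Per-row contribution of the effect to the log mean, shape (..., n)."""
        m = self.model
        if not m.is_effect_model:
            return 0.0
        if m.effect_type in ("fixed_categorical", "fixed_linear"):
            return theta[..., self._i_eff, None] * self._x
        lat = theta[..., self._sl_latent]
        if m.effect_type == "random_intercept":
            return lat[..., self._cat]
        return lat[..., self._cat] * self._x

    # -- log likelihood -----------------------------------------------------
    def log_likelihood(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.dim:
            raise ValueError(f"theta last axis must be {self.dim}, got {theta.shape[-1]}")
        if self.model.data_kind == "count":
            return self._count_loglik(theta)
        return self._freq_loglik(theta)

    def _count_loglik(self, theta):
        eta = np.clip(theta[..., 0, None] + self._effect_term(theta), -_CLIP, _CLIP)
        log_m = self._logf + eta
        mean = np.exp(log_m)
        y = self._y
        fam = self.model.family
        if fam == "poisson":
            ll = y * log_m - mean - self._gammaln_y1
            return ll.sum(axis=-1)
        k = np.exp(np.clip(theta[..., self._i_logk, None], -_CLIP, _CLIP))
        log_kpm = np.log(k + mean)
        nb = (
            gammaln(y + k)
            - gammaln(k)
            - self._gammaln_y1
            + k * (np.log(k) - log_kpm)
            + y * (log_m - log_kpm)
        )
        if fam == "negbinom":
            return nb.sum(axis=-1)
        zl = theta[..., self._i_zilogit, None]
        lse = np.logaddexp(0.0, zl)
        log_pzi = zl - lse
        log_1mpzi = -lse
        body = log_1mpzi + nb
        ll = np.where(y == 0, np.logaddexp(np.broadcast_to(log_pzi, body.shape), body), body)
        return ll.sum(axis=-1)

    def _freq_loglik(self, theta):
        eff = self._effect_term(theta)
        log_mu = np.clip(theta[..., 0, None] + eff, -_CLIP, _CLIP)
        eta0 = theta[..., self._i_g, None] + self._zi_shift(theta, eff)
        log_shape = np.clip(theta[..., self._i_logshape, None], -_CLIP, _CLIP)
        ll = zi_gamma_loglik(self._freq, log_mu, eta0, log_shape, link=self.zi_link)
        return ll.sum(axis=-1)

    def _zi_shift(self, theta, eff):
        if self.model.effect_structure != "mean_and_zi":
            return 0.0
        c = theta[..., self._i_zicoef, None]
        if self.model.effect_type in ("fixed_categorical", "fixed_linear"):
            return c * self._x  # additive covariate shift on the p0 predictor
        return c * eff  # random effects: scaled shared latents

    # -- log prior ----------------------------------------------------------
    def log_prior(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        z = (theta - self._prior_loc) / self._prior_scale
        term = -0.5 * z**2 - np.log(self._prior_scale) - 0.5 * np.log(2.0 * np.pi)
        lp = term[..., self._normal_mask].sum(axis=-1)
        if self._i_sigma is not None:
            s = self.prior.sigma_scale
            u = theta[..., self._i_sigma]
            sigma = np.exp(np.clip(u, -_CLIP, _CLIP))
            # half-normal on sigma, plus the log-transform Jacobian
            lp = lp + (
                np.log(2.0)
                - 0.5 * np.log(2.0 * np.pi * s**2)
                - sigma**2 / (2.0 * s**2)
                + u
            )
            lat = theta[..., self._sl_latent]
            kcat = lat.shape[-1]
            lp = lp + (
                -0.5 * kcat * np.log(2.0 * np.pi)
                - kcat * u
                - 0.5 * (lat**2).sum(axis=-1) * np.exp(-2.0 * np.clip(u, -_CLIP, _CLIP))
            )
        return lp

    def log_post(self, theta) -> np.ndarray:
        lp = self.log_prior(theta) + self.log_likelihood(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def init_positions(self, rng: np.random.Generator, n: int, jitter: float = 1.0):
        return self._init_loc + jitter * self._init_scale * rng.standard_normal((n, self.dim))


def build_evaluator(model: ModelSpec, dataset, prior: PriorSpec | None = None,
                    zi_link: str = "corrected") -> ModelEvaluator:
    return ModelEvaluator(model, dataset, prior, zi_link)


def log_likelihood(model: ModelSpec, dataset, theta, zi_link: str = "corrected"):
    """Log likelihood of ``theta`` (last axis = parameter vector) for a model."""
    return build_evaluator(model, dataset, zi_link=zi_link).log_likelihood(theta)


# ---------------------------------------------------------------------------
# MCMC: adaptive random-walk Metropolis over an ensemble of chains
# ---------------------------------------------------------------------------

def sample_posterior(evaluator: ModelEvaluator, config: McmcConfig = McmcConfig(),
                     seed: int | np.random.SeedSequence = 0) -> PosteriorChains:
    """Adaptive random-walk Metropolis on the unconstrained scale.

    All chains advance in lock-step through vectorized likelihood calls.
    During burn-in the proposal covariance is re-estimated from the pooled
    chain history and the global step size tuned toward the target
    acceptance rate; both are frozen for the sampling phase.
    """
    rng = np.random.default_rng(seed)
    d = evaluator.dim
    C = max(config.n_chains, 2)
    n_iter, n_burn = config.n_iter, config.n_burn
    if n_iter <= n_burn:
        raise ValueError("n_iter must exceed the burn-in length")

    theta = evaluator.init_positions(rng, C, jitter=config.init_jitter)
    lp = evaluator.log_post(theta)
    # chains that start at -inf get nudged to the init center
    bad = ~np.isfinite(lp)
    if bad.any():
        theta[bad] = evaluator._init_loc
        lp[bad] = evaluator.log_post(theta[bad])
        if not np.all(np.isfinite(lp)):
            raise RuntimeError("non-finite log posterior at the initial positions")

    log_step = np.log(2.38 / np.sqrt(d))
    chol = np.diag(evaluator._init_scale.astype(float))
    history = np.empty((n_burn, C, d))
    n_keep = n_iter - n_burn
    draws = np.empty((C, n_keep, d))
    log_posts = np.empty((C, n_keep))
    n_accept = 0

    for t in range(n_iter):
        step = np.exp(log_step)
        prop = theta + step * (rng.standard_normal((C, d)) @ chol.T)
        lpp = evaluator.log_post(prop)
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.random(C)) < (lpp - lp)
        theta[accept] = prop[accept]
        lp[accept] = lpp[accept]
        if t < n_burn:
            history[t] = theta
            # Robbins-Monro step-size tuning toward the target acceptance
            gamma = 1.0 / (1.0 + t) ** 0.6
            log_step += gamma * (accept.mean() - config.target_accept)
            if (t + 1) % config.adapt_interval == 0 and t + 1 >= max(50, 5 * d):
                pool = history[(t + 1) // 2: t + 1].reshape(-1, d)
                cov = np.cov(pool, rowvar=False).reshape(d, d)
                cov[np.diag_indices_from(cov)] += 1e-8 + 1e-6 * np.diag(cov)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            i = t - n_burn
            draws[:, i] = theta
            log_posts[:, i] = lp
            n_accept += int(accept.sum())

    accept_rate = n_accept / (C * n_keep)
    if accept_rate == 0.0:
        raise RuntimeError("sampler accepted no proposals after burn-in")
    return PosteriorChains(
        draws=draws,
        log_post=log_posts,
        accept_rate=accept_rate,
        rhat=_gelman_rubin(draws),
        names=list(evaluator.names),
        evaluator=evaluator,
    )


def run_mcmc(model: ModelSpec, dataset, prior: PriorSpec | None = None,
             config: McmcConfig = McmcConfig(), seed=0,
             zi_link: str = "corrected") -> PosteriorChains:
    """Fit one model to one dataset; see :func:`sample_posterior`."""
    return sample_posterior(build_evaluator(model, dataset, prior, zi_link), config, seed)


def _gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter across chains."""
    C, T, d = draws.shape
    means = draws.mean(axis=1)  # (C, d)
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    var_hat = (T - 1) / T * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return np.where(W > 0, rhat, 1.0)


# ---------------------------------------------------------------------------
# Bayesian model likelihood by importance sampling
# ---------------------------------------------------------------------------

def estimate_log_bml(chains: PosteriorChains, n_draws: int = 2000, df: float = 5.0,
                     seed: int | np.random.SeedSequence = 0,
                     ess_warn_frac: float = 0.02) -> BMLEstimate:
    """Importance-sampled log marginal likelihood.

    A multivariate t (default 5 df) is moment-matched to the posterior
    draws on the unconstrained scale and used as the importance density:
    ``BML = E_q[ prior * likelihood / q ]``.  The Monte Carlo standard
    error of the log estimate comes from the delta method; an effective
    sample size below ``ess_warn_frac * n_draws`` raises a warning and sets
    the ``degenerate`` flag.
    """
    rng = np.random.default_rng(seed)
    ev = chains.evaluator
    flat = chains.flat
    d = flat.shape[1]
    mu = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False).reshape(d, d)
    cov[np.diag_indices_from(cov)] += 1e-10 + 1e-8 * np.diag(cov)
    if df <= 2:
        raise ValueError("df must exceed 2 so the t has a covariance to match")
    scale_mat = cov * (df - 2.0) / df
    L = np.linalg.cholesky(scale_mat)

    z = rng.standard_normal((n_draws, d)) @ L.T
    u = rng.chisquare(df, size=n_draws) / df
    samples = mu + z / np.sqrt(u)[:, None]

    # multivariate-t log pdf at the samples
    diff = samples - mu
    q = solve_triangular(L, diff.T, lower=True)
    maha = (q**2).sum(axis=0)
    log_det = np.sum(np.log(np.diag(L)))
    log_q = (
        gammaln((df + d) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * d * np.log(df * np.pi)
        - log_det
        - 0.5 * (df + d) * np.log1p(maha / df)
    )

    log_w = ev.log_prior(samples) + ev.log_likelihood(samples) - log_q
    log_w = np.where(np.isfinite(log_w), log_w, -np.inf)
    m = np.max(log_w)
    if not np.isfinite(m):
        raise RuntimeError("all importance weights are zero")
    w = np.exp(log_w - m)
    w_bar = w.mean()
    log_bml = m + np.log(w_bar)
    mc_se = float(w.std(ddof=1) / (w_bar * np.sqrt(n_draws)))
    ess = float(w.sum() ** 2 / (w**2).sum())
    degenerate = ess < ess_warn_frac * n_draws
    if degenerate:
        warnings.warn(
            f"importance-weight degeneracy: ESS {ess:.1f} of {n_draws} draws",
            RuntimeWarning,
            stacklevel=2,
        )
    return BMLEstimate(float(log_bml), mc_se, n_draws, ess, degenerate)


def model_log_bml(model: ModelSpec, dataset, prior: PriorSpec | None = None,
                  mcmc: McmcConfig = McmcConfig(), n_is_draws: int = 2000,
                  seed=0, zi_link: str = "corrected") -> BMLEstimate:
    """Convenience: MCMC fit followed by the importance-sampling BML."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_mcmc, s_is = ss.spawn(2)
    chains = run_mcmc(model, dataset, prior, mcmc, s_mcmc, zi_link)
    return estimate_log_bml(chains, n_draws=n_is_draws, seed=s_is)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def posterior_model_probs(log_bmls, prior_probs=None) -> np.ndarray:
    """Posterior model probabilities from log marginal likelihoods.

    ``P(M_i | D) = P(D | M_i) P(M_i) / sum_j P(D | M_j) P(M_j)``, computed
    in log space.  ``prior_probs`` defaults to equal and must sum to 1.
    """
    log_bmls = np.asarray(log_bmls, dtype=float)
    if log_bmls.size == 0:
        raise ValueError("need at least one model")
    if prior_probs is None:
        prior_probs = np.full(log_bmls.shape, 1.0 / log_bmls.size)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if not np.isclose(prior_probs.sum(), 1.0):
        raise ValueError("prior_probs must sum to 1")
    with np.errstate(divide="ignore"):
        log_post = log_bmls + np.log(prior_probs)
    log_post -= logsumexp(log_post)
    return np.exp(log_post)


def detect_effect(effect_log_bmls, noeffect_log_bmls,
                  prior_odds_threshold: float = 1.0) -> DetectResult:
    """Effect-vs-no-effect decision from per-model log BMLs.

    ``score = max(effect log BMLs) - max(no-effect log BMLs)``; an effect
    is declared found when ``score > log(threshold)`` (strict, so a tie at
    threshold 1 counts as no effect).  Threshold 1 reproduces selection of
    the single best model under equal prior model probabilities.
    """
    effect_log_bmls = np.asarray(effect_log_bmls, dtype=float)
    noeffect_log_bmls = np.asarray(noeffect_log_bmls, dtype=float)
    if effect_log_bmls.size == 0 or noeffect_log_bmls.size == 0:
        raise ValueError("need at least one effect and one no-effect model")
    if prior_odds_threshold <= 0:
        raise ValueError("prior_odds_threshold must be > 0")
    score = float(effect_log_bmls.max() - noeffect_log_bmls.max())
    return DetectResult(found=score > np.log(prior_odds_threshold), score=score)
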