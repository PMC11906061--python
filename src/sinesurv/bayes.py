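"""Priors, posterior and MCMC sampling for Sine-G PH models.

Priors follow the package's default weakly-informative setup: Gamma(10, 10)
on the positive baseline parameters lambda and alpha (prior mean 1, sd
~0.316) and independent Normal(0, 10^2) on each regression coefficient.

Sampling runs on the unconstrained scale (log lambda, log alpha, beta) with
the log-Jacobian added, using Hamiltonian Monte Carlo: each transition draws
a Gaussian momentum, advances L leapfrog steps of size eps, and accepts with
the Metropolis probability min(1, exp(H_current - H_proposal)).  Step size
is tuned by dual averaging during warmup and a diagonal mass matrix is
estimated from the warmup draws.  An adaptive random-walk Metropolis sampler
is available as a fallback through ``sampler="adaptive_metropolis"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import diagnostics
from ._numdiff import approx_gradient
from .model import SineGPH

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorSamples",
    "log_prior",
    "log_posterior",
    "sample_posterior",
    "fit_bayes",
    "BayesianPHResults",
]


@dataclass
class PriorConfig:
    """Hyperparameters: Gamma(a1,b1) on lam, Gamma(a2,b2) on alpha, Normal(a3, b3^2) on each beta."""

    a1: float = 10.0
    b1: float = 10.0
    a2: float = 10.0
    b2: float = 10.0
    beta_mean: float = 0.0
    beta_sd: float = 10.0

    def __post_init__(self):
        for name in ("a1", "b1", "a2", "b2", "beta_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


def _gamma_logpdf(x, a, b):
    return a * math.log(b) - gammaln(a) + (a - 1.0) * np.log(x) - b * x


def _normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def log_prior(params, priors: PriorConfig, has_shape: bool, n_coef: int) -> float:
    """Joint log prior density on the natural scale; -inf outside the domain."""
    params = np.asarray(params, dtype=float)
    k = 2 if has_shape else 1
    if params.size != k + n_coef:
        raise ValueError(f"expected {k + n_coef} parameters, got {params.size}")
    theta = params[:k]
    if np.any(theta <= 0) or not np.all(np.isfinite(params)):
        return -np.inf
    lp = _gamma_logpdf(theta[0], priors.a1, priors.b1)
    if has_shape:
        lp += _gamma_logpdf(theta[1], priors.a2, priors.b2)
    for b in params[k:]:
        lp += _normal_logpdf(b, priors.beta_mean, priors.beta_sd)
    return float(lp)


def log_posterior(params, model: SineGPH, priors: Optional[PriorConfig] = None) -> float:
    """Unnormalized log posterior = log-likelihood + log prior."""
    priors = priors or PriorConfig()
    lp = log_prior(params, priors, model._has_shape, model.data.n_covariates)
    if not np.isfinite(lp):
        return -np.inf
    return model.loglike(params) + lp


@dataclass
class McmcConfig:
    """Sampler settings; warmup draws are always discarded from summaries."""

    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    sampler: str = "hmc"
    step_size: Optional[float] = None  # None = dual-averaging auto-tune
    n_leapfrog: Optional[int] = None  # None = derived from step size
    target_accept: float = 0.8

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 2:
            raise ValueError("chains >= 1 and iterations >= 2 required")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("warmup must satisfy 0 <= warmup < iterations")
        if self.sampler not in ("hmc", "adaptive_metropolis"):
            raise ValueError("sampler must be 'hmc' or 'adaptive_metropolis'")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class PosteriorSamples:
    """Post-warmup draws: (chains, draws, parameters), on the natural scale."""

    draws: np.ndarray
    param_names: List[str]
    seed: int
    config: McmcConfig
    divergences: np.ndarray = None  # per chain
    accept_rate: np.ndarray = None  # per chain

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, iterations, parameters)")
        if self.draws.shape[2] != len(self.param_names):
            raise ValueError("parameter-name count does not match draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, parameter: str) -> np.ndarray:
        """Draws for one parameter as a (chains, iterations) array."""
        try:
            j = self.param_names.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}; have {self.param_names}") from None
        return self.draws[:, :, j]

    def flat(self, parameter: str) -> np.ndarray:
        return self.get(parameter).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format with chain and iteration columns, one column per parameter."""
        c, n, p = self.draws.shape
        out = pd.DataFrame(self.draws.reshape(c * n, p), columns=self.param_names)
        out.insert(0, "iteration", np.tile(np.arange(n), c))
        out.insert(0, "chain", np.repeat(np.arange(c), n))
        return out

    # -- diagnostics ---------------------------------------------------
    def rhat(self, parameter: str) -> float:
        return diagnostics.rhat(self.get(parameter))

    def ess(self, parameter: str) -> float:
        return diagnostics.ess(self.get(parameter))

    def mcse(self, parameter: str) -> float:
        return diagnostics.mcse(self.get(parameter))

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: Estimate, SE, SD, 2.5%, Medium, 97.5%, N_eff, Rhat."""
        rows = []
        for name in self.param_names:
            x = self.flat(parameter=name)
            rows.append(
                {
                    "Estimate": x.mean(),
                    "SE": self.mcse(name),
                    "SD": x.std(ddof=1),
                    "2.5%": np.quantile(x, 0.025),
                    "Medium": np.quantile(x, 0.5),
                    "97.5%": np.quantile(x, 0.975),
                    "N_eff": self.ess(name),
                    "Rhat": self.rhat(name),
                }
            )
        return pd.DataFrame(rows, index=self.param_names)


# ---------------------------------------------------------------------
# generic samplers on an unconstrained log density
# ---------------------------------------------------------------------


def sample_unconstrained(
    logpost: Callable[[np.ndarray], float],
    ndim: int,
    mcmc: McmcConfig,
    inits: np.ndarray,
) -> tuple:
    """Run the configured sampler on an arbitrary log density.

    Returns (draws, divergences, accept_rates) with draws of shape
    (chains, iterations - warmup, ndim).  Used directly by the posterior
    samplers and by sanity checks against known targets.
    """
    inits = np.atleast_2d(np.asarray(inits, dtype=float))
    if inits.shape != (mcmc.chains, ndim):
        raise ValueError(f"inits must have shape ({mcmc.chains}, {ndim})")
    ss = np.random.SeedSequence(mcmc.seed)
    child_seeds = ss.spawn(mcmc.chains)
    draws = np.empty((mcmc.chains, mcmc.iterations - mcmc.warmup, ndim))
    divergences = np.zeros(mcmc.chains, dtype=int)
    accept = np.zeros(mcmc.chains)
    for c in range(mcmc.chains):
        rng = np.random.default_rng(child_seeds[c])
        if mcmc.sampler == "hmc":
            out, ndiv, acc = _hmc_chain(logpost, inits[c], mcmc, rng)
        else:
            out, ndiv, acc = _am_chain(logpost, inits[c], mcmc, rng)
        draws[c] = out
        divergences[c] = ndiv
        accept[c] = acc
        if acc == 0.0:
            raise RuntimeError(f"chain {c} rejected every proposal; sampler failed")
    return draws, divergences, accept


def _hmc_chain(logpost, z0, mcmc: McmcConfig, rng):
    d = z0.size
    grad = lambda z: approx_gradient(logpost, z, h=1e-5)
    z = z0.astype(float).copy()
    lp = logpost(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    inv_mass = np.ones(d)  # posterior variances (inverse metric)

    eps = mcmc.step_size or _find_reasonable_eps(logpost, grad, z, inv_mass, rng)
    # dual averaging state
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    warm_buf = []
    n_keep = mcmc.iterations - mcmc.warmup
    kept = np.empty((n_keep, d))
    ndiv = 0
    n_accept = 0.0
    window_end = mcmc.warmup // 2  # mass estimated at mid-warmup

    for it in range(mcmc.iterations):
        adapting = it < mcmc.warmup
        if mcmc.n_leapfrog is not None:
            L_max = mcmc.n_leapfrog
        else:
            L_max = int(np.clip(round(1.5 / eps), 1, 48))
        L = int(rng.integers(max(1, L_max // 2), L_max + 1))

        p = rng.standard_normal(d) / np.sqrt(inv_mass)
        H0 = -lp + 0.5 * np.sum(inv_mass * p**2)
        z_new, p_new, lp_new = _leapfrog(logpost, grad, z, p, eps, L, inv_mass)
        if lp_new is None or not np.isfinite(lp_new):
            divergent, accept_prob = True, 0.0
        else:
            H1 = -lp_new + 0.5 * np.sum(inv_mass * p_new**2)
            dH = H0 - H1
            divergent = dH < -50.0
            accept_prob = 0.0 if divergent else min(1.0, math.exp(min(dH, 0.0)))
        if not divergent and rng.uniform() < accept_prob:
            z, lp = z_new, lp_new
        if divergent and not adapting:
            ndiv += 1

        if adapting:
            if mcmc.step_size is None:
                # Nesterov dual averaging towards the target acceptance rate
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (mcmc.target_accept - accept_prob) / (m + t0)
                log_eps = mu - math.sqrt(m) / gamma * h_bar
                w = m ** (-kappa)
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = math.exp(log_eps)
            if window_end // 2 <= it < window_end:
                warm_buf.append(z.copy())
            if it == window_end - 1 and len(warm_buf) >= 10:
                var = np.var(np.asarray(warm_buf), axis=0, ddof=1)
                inv_mass = np.maximum(var, 1e-8)
                if mcmc.step_size is None:
                    eps = _find_reasonable_eps(logpost, grad, z, inv_mass, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
            if it == mcmc.warmup - 1 and mcmc.step_size is None:
                eps = math.exp(log_eps_bar)
        else:
            n_accept += accept_prob
            kept[it - mcmc.warmup] = z
    return kept, ndiv, n_accept / max(n_keep, 1)


def _leapfrog(logpost, grad, z, p, eps, L, inv_mass):
    z = z.copy()
    p = p.copy()
    g = grad(z)
    for _ in range(L):
        p = p + 0.5 * eps * g
        z = z + eps * inv_mass * p
        lp = logpost(z)
        if not np.isfinite(lp):
            return z, p, None
        g = grad(z)
        p = p + 0.5 * eps * g
    return z, p, lp


def _find_reasonable_eps(logpost, grad, z, inv_mass, rng):
    """Double/halve eps until one leapfrog step has ~50% acceptance."""
    eps = 0.1
    p = rng.standard_normal(z.size) / np.sqrt(inv_mass)
    lp = logpost(z)
    H0 = -lp + 0.5 * np.sum(inv_mass * p**2)
    for _ in range(50):
        z1, p1, lp1 = _leapfrog(logpost, grad, z, p, eps, 1, inv_mass)
        if lp1 is None:
            eps *= 0.5
            continue
        dH = H0 - (-lp1 + 0.5 * np.sum(inv_mass * p1**2))
        if dH > math.log(0.5):
            break
        eps *= 0.5
    else:
        raise RuntimeError("could not find a workable HMC step size")
    return eps


def _am_chain(logpost, z0, mcmc: McmcConfig, rng):
    """Adaptive random-walk Metropolis (Haario-style covariance adaptation)."""
    d = z0.size
    z = z0.astype(float).copy()
    lp = logpost(z)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    scale = 2.38**2 / d
    cov = np.eye(d) * 0.1
    chol = np.linalg.cholesky(scale * cov)
    history = [z.copy()]
    n_keep = mcmc.iterations - mcmc.warmup
    kept = np.empty((n_keep, d))
    n_accept = 0.0
    for it in range(mcmc.iterations):
        prop = z + chol @ rng.standard_normal(d)
        lp_prop = logpost(prop)
        a = math.exp(min(0.0, lp_prop - lp)) if np.isfinite(lp_prop) else 0.0
        if rng.uniform() < a:
            z, lp = prop, lp_prop
        if it < mcmc.warmup:
            history.append(z.copy())
            if it >= 20 and it % 20 == 0:
                emp = np.cov(np.asarray(history[len(history) // 2 :]).T).reshape(d, d)
                cov = emp + 1e-8 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(scale * cov)
                except np.linalg.LinAlgError:
                    pass
        else:
            n_accept += a
            kept[it - mcmc.warmup] = z
    return kept, 0, n_accept / max(n_keep, 1)


# ---------------------------------------------------------------------
# posterior sampling for the PH model
# ---------------------------------------------------------------------


def _prior_draw(priors: PriorConfig, has_shape: bool, n_coef: int, rng) -> np.ndarray:
    theta = [rng.gamma(priors.a1, 1.0 / priors.b1)]
    if has_shape:
        theta.append(rng.gamma(priors.a2, 1.0 / priors.b2))
    beta = priors.beta_mean + 0.5 * priors.beta_sd * rng.standard_normal(n_coef)
    return np.concatenate([theta, beta])


def sample_posterior(
    model: SineGPH,
    priors: Optional[PriorConfig] = None,
    mcmc: Optional[McmcConfig] = None,
) -> PosteriorSamples:
    """Draw from the joint posterior of (lam, [alpha], beta).

    Initial points are drawn from the prior (one per chain); sampling runs
    on the unconstrained scale and draws are returned on the natural scale.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    k = model.k_baseline
    ndim = model.k_params

    def logpost_z(z):
        params = model._to_natural(z)
        lp = log_prior(params, priors, model._has_shape, model.data.n_covariates)
        if not np.isfinite(lp):
            return -np.inf
        return model.loglike(params) + lp + float(np.sum(z[:k]))  # + log-Jacobian

    init_rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed).spawn(1)[0])
    inits = np.empty((mcmc.chains, ndim))
    for c in range(mcmc.chains):
        for _ in range(100):
            p0 = _prior_draw(priors, model._has_shape, model.data.n_covariates, init_rng)
            z0 = model._to_unconstrained(p0)
            if np.isfinite(logpost_z(z0)):
                inits[c] = z0
                break
        else:
            raise RuntimeError("could not find a finite-density initial point")

    z_draws, ndiv, acc = sample_unconstrained(logpost_z, ndim, mcmc, inits)
    nat = z_draws.copy()
    nat[:, :, :k] = np.exp(nat[:, :, :k])
    return PosteriorSamples(
        draws=nat,
        param_names=model.param_names,
        seed=mcmc.seed,
        config=mcmc,
        divergences=ndiv,
        accept_rate=acc,
    )


def fit_bayes(model: SineGPH, priors=None, mcmc=None) -> "BayesianPHResults":
    samples = sample_posterior(model, priors=priors, mcmc=mcmc)
    return BayesianPHResults(model, samples, priors or PriorConfig())


class BayesianPHResults:
    """Posterior results for a Sine-G PH model."""

    def __init__(self, model: SineGPH, samples: PosteriorSamples, priors: PriorConfig):
        self.model = model
        self.samples = samples
        self.priors = priors

    @property
    def param_names(self):
        return self.samples.param_names

    @property
    def params(self):
        """Posterior means on the natural scale."""
        return self.samples.draws.reshape(-1, len(self.param_names)).mean(axis=0)

    def summary(self) -> pd.DataFrame:
        return self.samples.summary()

    def diagnostics_ok(self, rhat_max=1.01, ess_min=400, mcse_frac=0.05) -> bool:
        """The convergence contract: Rhat, ESS and MCSE thresholds for all parameters."""
        s = self.summary()
        return bool(
            (s["Rhat"] <= rhat_max).all()
            and (s["N_eff"] > ess_min).all()
            and (s["SE"] < mcse_frac * s["SD"]).all()
        )

    def pointwise_loglik(self, thin: int = 1) -> np.ndarray:
        """(draws, subjects) matrix of log p(y_i | params_s) for WAIC/LOOIC."""
        flat = self.samples.draws.reshape(-1, len(self.param_names))[::thin]
        out = np.empty((flat.shape[0], self.model.data.n))
        for s, p in enumerate(flat):
            out[s] = self.model.loglike_obs(p, check=False)
        return out

    def waic(self, thin: int = 1) -> float:
        from . import compare

        return compare.waic(self.pointwise_loglik(thin=thin))

    def looic(self, thin: int = 1) -> float:
        from . import compare

        return compare.loo(self.pointwise_loglik(thin=thin)).looic

    def __repr__(self):
        est = dict(zip(self.param_names, np.round(self.params, 4)))
        return f"<BayesianPHResults {self.model.family}, posterior means={est}>"
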