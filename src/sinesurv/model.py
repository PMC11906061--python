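"""Fully parametric proportional-hazards regression with Sine-G baselines.

The model for subject i with covariate row x_i is

    h(t | x_i) = h0(t; theta) * exp(x_i' beta),

where h0 is the hazard of a Sine-G distribution (exponential, Weibull,
Lomax, exponentiated-exponential or Gompertz baseline) and beta carries no
intercept, which keeps the baseline scale identifiable.  The right-censored
log-likelihood is

    l(theta, beta) = sum_i delta_i [log h0(t_i) + x_i' beta]
                     - sum_i H0(t_i) exp(x_i' beta).

``SineGPH`` follows the statsmodels convention: the model object holds the
data and likelihood machinery, ``fit()`` maximizes the likelihood and
returns a results object with estimates, observed-information standard
errors and a ``summary()`` table, and ``fit_bayes()`` returns a posterior
results object (see :mod:`sinesurv.bayes`).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._numdiff import approx_hessian
from .data import SurvivalDataset
from .families import BASELINE_FAMILIES, SineG, get_baseline

__all__ = ["SineGPH", "SineGPHResults", "LikelihoodError"]


class LikelihoodError(ValueError):
    """Raised when the log-likelihood is non-finite at valid parameters."""


class SineGPH:
    """Sine-G proportional-hazards model bound to a right-censored dataset.

    Parameters
    ----------
    time, event : array-like
        Observed times and event indicators (1 = event, 0 = censored).
    exog : array-like, shape (n, J), optional
        Covariate matrix without an intercept column.
    family : str
        Baseline family name (``exponential``, ``weibull``, ``lomax``,
        ``exponentiated_exponential``, ``gompertz``) or its two-letter
        sine alias (``se``, ``sw``, ``sl``, ``see``, ``sg``).
    exog_names : sequence of str, optional
        Covariate labels; defaults to x1, x2, ...
    """

    def __init__(self, time, event, exog=None, family: str = "weibull", exog_names=None):
        self.data = SurvivalDataset(
            time=time,
            event=event,
            covariates=exog,
            covariate_names=list(exog_names) if exog_names is not None else [],
        )
        # resolve family through the registry so aliases work
        probe = get_baseline(family, 1.0) if _n_shape(family) == 0 else get_baseline(family, 1.0, 1.0)
        self.family = probe.name
        self._family_cls = BASELINE_FAMILIES[self.family]
        self._has_shape = len(probe.param_names) == 2

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataset(cls, dataset: SurvivalDataset, family: str = "weibull") -> "SineGPH":
        return cls(
            dataset.time,
            dataset.event,
            exog=dataset.covariates,
            family=family,
            exog_names=dataset.covariate_names,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        event: str = "event",
        covariates: Optional[Sequence[str]] = None,
        family: str = "weibull",
    ) -> "SineGPH":
        return cls.from_dataset(
            SurvivalDataset.from_frame(df, time=time, event=event, covariates=covariates),
            family=family,
        )

    # -- parameter bookkeeping ----------------------------------------
    @property
    def k_baseline(self) -> int:
        return 2 if self._has_shape else 1

    @property
    def k_params(self) -> int:
        return self.k_baseline + self.data.n_covariates

    @property
    def param_names(self):
        names = ["lam"] + (["alpha"] if self._has_shape else [])
        return names + [f"beta_{c}" for c in self.data.covariate_names]

    def _split(self, params):
        params = np.asarray(params, dtype=float)
        if params.size != self.k_params:
            raise ValueError(
                f"expected {self.k_params} parameters {self.param_names}, got {params.size}"
            )
        theta = params[: self.k_baseline]
        beta = params[self.k_baseline :]
        return theta, beta

    def distribution(self, params) -> SineG:
        """The baseline Sine-G distribution at the given parameter vector."""
        theta, _ = self._split(params)
        return SineG(self._family_cls(*theta))

    # -- transforms between natural and unconstrained scales -----------
    def _to_unconstrained(self, params):
        theta, beta = self._split(params)
        return np.concatenate([np.log(theta), beta])

    def _to_natural(self, z):
        z = np.asarray(z, dtype=float)
        with np.errstate(over="ignore"):
            return np.concatenate([np.exp(z[: self.k_baseline]), z[self.k_baseline :]])

    # -- model functions ----------------------------------------------
    def hazard(self, params, t, x=None):
        """PH hazard h0(t) * exp(x'beta) at covariate vector x."""
        dist = self.distribution(params)
        return dist.hazard(t) * np.exp(self._linpred_single(params, x))

    def survival(self, params, t, x=None):
        """PH survival exp(-H0(t) exp(x'beta))."""
        return np.exp(-self.cumhaz(params, t, x))

    def cumhaz(self, params, t, x=None):
        """PH cumulative hazard H0(t) * exp(x'beta)."""
        dist = self.distribution(params)
        return dist.cumhaz(t) * np.exp(self._linpred_single(params, x))

    def _linpred_single(self, params, x):
        _, beta = self._split(params)
        if beta.size == 0:
            return 0.0
        if x is None:
            raise ValueError("covariate vector x required when the model has coefficients")
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != beta.size:
            raise ValueError(f"covariate vector has length {x.shape[-1]}, expected {beta.size}")
        return x @ beta

    # -- likelihood ----------------------------------------------------
    def loglike_obs(self, params, check: bool = True):
        """Per-subject log density contributions.

        Entry i is ``delta_i * log h(t_i|x_i) - H(t_i|x_i)``, i.e. the log of
        f^delta * S^(1-delta).  With ``check=True`` a non-finite entry raises
        :class:`LikelihoodError` naming the offending subject.
        """
        theta, beta = self._split(params)
        dist = SineG(self._family_cls(*theta))
        eta = self.data.covariates @ beta if beta.size else np.zeros(self.data.n)
        H = dist.cumhaz(self.data.time) * np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            logh = dist.loghazard(self.data.time) + eta
        contrib = np.where(self.data.event == 1, logh, 0.0) - H
        if check and not np.all(np.isfinite(contrib)):
            bad = int(np.flatnonzero(~np.isfinite(contrib))[0])
            raise LikelihoodError(
                f"non-finite log-likelihood contribution for subject {bad} "
                f"(t={self.data.time[bad]:g}, delta={self.data.event[bad]})"
            )
        return contrib

    def loglike(self, params):
        """Total right-censored log-likelihood; -inf outside the domain."""
        try:
            contrib = self.loglike_obs(params, check=False)
        except ValueError:
            raise
        total = float(np.sum(contrib))
        return total if np.isfinite(total) else -np.inf

    def _negloglike_unconstrained(self, z):
        params = self._to_natural(z)
        if not np.all(np.isfinite(params)):
            return np.inf
        return -self.loglike(params)

    # -- estimation ----------------------------------------------------
    def _default_start(self):
        # crude moment start: exponential rate from the event rate, unit shape
        t = self.data.time
        lam0 = max(self.data.event.sum(), 1) / max(t.sum(), 1e-12)
        theta0 = [lam0] + ([1.0] if self._has_shape else [])
        return np.array(theta0 + [0.0] * self.data.n_covariates)

    def fit(self, start=None, maxiter: int = 500) -> "SineGPHResults":
        """Maximize the censored log-likelihood.

        Optimization runs on the unconstrained scale (log lam, log alpha,
        beta); estimates are reported on the natural scale with standard
        errors from the inverse observed information (numerical Hessian).
        """
        z0 = self._to_unconstrained(np.asarray(start, dtype=float) if start is not None else self._default_start())
        res = optimize.minimize(
            self._negloglike_unconstrained, z0, method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-8},
        )
        if not res.success:
            res2 = optimize.minimize(
                self._negloglike_unconstrained, res.x, method="Nelder-Mead",
                options={"maxiter": 4 * maxiter, "xatol": 1e-10, "fatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res = res2
        params = self._to_natural(res.x)
        grad = _grad_norm(self._negloglike_unconstrained, res.x)
        # finite-difference noise in the gradient scales with |llf|, so the
        # stationarity check is relative to the objective's magnitude
        converged = bool(np.isfinite(res.fun) and grad < 1e-5 * max(1.0, abs(res.fun)))

        # observed information on the natural scale
        cov = None
        try:
            H = approx_hessian(lambda p: -self.loglike(p), params)
            cov = np.linalg.inv(H)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                cov = None
        except (np.linalg.LinAlgError, ValueError):
            cov = None
        return SineGPHResults(
            model=self,
            params=params,
            cov_params=cov,
            llf=-float(res.fun),
            converged=converged,
            grad_norm=grad,
            n_iter=int(res.get("nit", -1)) if hasattr(res, "get") else -1,
        )

    def fit_bayes(self, priors=None, mcmc=None) -> "bayes.BayesianPHResults":
        """Sample the posterior; see :func:`sinesurv.bayes.sample_posterior`."""
        from . import bayes

        return bayes.fit_bayes(self, priors=priors, mcmc=mcmc)


def _grad_norm(f, x, h=1e-4):
    from ._numdiff import approx_gradient

    g = approx_gradient(f, x, h=h)
    return float(np.max(np.abs(g)))


def _n_shape(family: str) -> int:
    key = family.strip().lower().replace("-", "_")
    return 0 if key in ("exponential", "se") else 1


class SineGPHResults:
    """Maximum-likelihood results for a Sine-G PH model."""

    def __init__(self, model, params, cov_params, llf, converged, grad_norm, n_iter):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = cov_params
        self.llf = llf
        self.converged = converged
        self.grad_norm = grad_norm
        self.n_iter = n_iter

    @property
    def param_names(self):
        return self.model.param_names

    @property
    def bse(self):
        """Observed-information standard errors (NaN when unavailable)."""
        if self.cov_params is None:
            return np.full(self.params.size, np.nan)
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05):
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "SE": self.bse,
                "2.5%": ci[:, 0],
                "97.5%": ci[:, 1],
            },
            index=self.param_names,
        )

    def loglike_obs(self):
        return self.model.loglike_obs(self.params)

    def __repr__(self):
        status = "converged" if self.converged else "NOT converged"
        return (
            f"<SineGPHResults {self.model.family} {status}, llf={self.llf:.3f}, "
            f"params={dict(zip(self.param_names, np.round(self.params, 4)))}>"
        )
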