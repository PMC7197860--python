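"""Parametric Weibull survival estimation for right-censored data.

The residual constructions in :mod:`teres.residuals` all start from an
estimated survival function.  Here that estimate is a two-parameter Weibull,

.. math::

    S(t) = \\exp\\{-(t/\\lambda)^k\\}, \\qquad
    \\mathrm{CHF}(t) = -\\log S(t) = (t/\\lambda)^k,

fitted by maximum likelihood to right-censored observations: uncensored
individuals contribute the density :math:`f(t) = h(t) S(t)` and censored
individuals contribute :math:`S(t)`.  A Kaplan-Meier estimator is provided
for goodness-of-fit diagnostics.

Two conveniences matter downstream.  The median survival time has the closed
form :math:`\\tilde t = \\lambda (\\ln 2)^{1/k}`, and the conditional median
given survival past a censoring time ``c`` -- the solution of
``S(t) = S(c)/2`` -- is :math:`\\lambda[(c/\\lambda)^k + \\ln 2]^{1/k}`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import optimize, special
from sklearn.base import BaseEstimator

__all__ = [
    "EstimationError",
    "ConvergenceError",
    "WeibullFit",
    "KMEstimate",
    "WeibullMLE",
    "KaplanMeier",
    "fit_weibull",
    "km_estimate",
    "conditional_median",
]

LN2 = math.log(2.0)


class EstimationError(ValueError):
    """The data do not identify the model (e.g. no uncensored events)."""


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed to reach a stationary point."""


def _check_time_status(time, status):
    t = np.asarray(time, dtype=float).ravel()
    d = np.asarray(status, dtype=float).ravel()
    if t.shape != d.shape:
        raise ValueError(f"time and status have different lengths ({t.size} vs {d.size})")
    if t.size == 0:
        raise EstimationError("empty sample")
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be strictly positive and finite")
    if not np.all((d == 0) | (d == 1)):
        raise ValueError("status must be coded 0 (censored) / 1 (event)")
    return t, d


@dataclass(frozen=True)
class WeibullFit:
    """A fitted (or postulated) Weibull survival model.

    Parameters
    ----------
    scale : float
        Weibull scale :math:`\\lambda` in years.
    shape : float
        Weibull shape :math:`k` (dimensionless).
    level : object, optional
        Covariate level the model was fitted on, if any.
    n_total, n_events : int
        Sample size and number of uncensored events behind the fit.
    loglik : float
        Censored-data log-likelihood at the optimum.
    """

    scale: float
    shape: float
    level: object = None
    n_total: int = 0
    n_events: int = 0
    loglik: float = field(default=math.nan)

    def __post_init__(self):
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError("Weibull scale and shape must be positive")
        if self.n_events > self.n_total:
            raise ValueError("n_events cannot exceed n_total")

    def survival(self, t):
        """S(t) = exp{-(t/lambda)^k}; defined for t >= 0, S(0) = 1."""
        return np.exp(-self.chf(t))

    def chf(self, t):
        """Cumulative hazard (t/lambda)^k; domain error for negative t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = (t / self.scale) ** self.shape
        return out if out.ndim else float(out)

    @property
    def median(self) -> float:
        """Median survival time lambda * (ln 2)^(1/k)."""
        return self.scale * LN2 ** (1.0 / self.shape)

    def predicted_median(self, t_cens):
        """Conditional median event time given survival past ``t_cens``.

        Solves ``S(t) = S(t_cens) / 2`` in closed form:
        ``lambda * ((t_cens/lambda)^k + ln 2)^(1/k)``.  Equals the
        unconditional median at ``t_cens = 0`` and is strictly increasing
        in ``t_cens``.
        """
        t_cens = np.asarray(t_cens, dtype=float)
        if np.any(t_cens < 0):
            raise ValueError("censoring time must be non-negative")
        out = self.scale * ((t_cens / self.scale) ** self.shape + LN2) ** (1.0 / self.shape)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "shape": self.shape,
            "level": self.level,
            "n_total": self.n_total,
            "n_events": self.n_events,
            "loglik": self.loglik,
        }


def _weibull_loglik_grad(logparams, t, d):
    """Censored Weibull log-likelihood and its gradient in (log lambda, log k)."""
    a, c = logparams
    lam, k = math.exp(a), math.exp(c)
    w = np.log(t) - a  # log(t/lambda)
    u = np.exp(k * w)  # (t/lambda)^k
    n_events = d.sum()
    ll = np.sum(d * (math.log(k) + (k - 1.0) * np.log(t) - k * a)) - u.sum()
    g_a = k * (u.sum() - n_events)
    g_c = n_events + k * np.sum(d * w) - k * np.sum(u * w)
    return ll, np.array([g_a, g_c])


def _moment_init(t_events):
    """Moment-matched starting values from uncensored times only.

    Uses the standard coefficient-of-variation approximation
    k ~ (s/m)^(-1.086), then lambda = m / Gamma(1 + 1/k).
    """
    m = float(np.mean(t_events))
    s = float(np.std(t_events, ddof=1))
    if s == 0.0:
        raise ConvergenceError(
            "degenerate sample: all uncensored times identical (zero variance)"
        )
    k0 = float(np.clip((s / m) ** -1.086, 0.05, 100.0))
    lam0 = m / special.gamma(1.0 + 1.0 / k0)
    return math.log(lam0), math.log(k0)


class WeibullMLE(BaseEstimator):
    """Maximum-likelihood Weibull survival model for right-censored data.

    Follows the scikit-learn estimator protocol: ``fit`` takes an ``(n, 2)``
    array-like (or DataFrame) whose columns are observed time and event
    status (1 = event, 0 = censored), and exposes fitted attributes with a
    trailing underscore.

    Parameters
    ----------
    gtol : float
        Gradient-norm convergence tolerance for the optimizer, applied on
        the unconstrained (log lambda, log k) scale.
    max_iter : int
        Maximum BFGS iterations.

    Attributes
    ----------
    scale_, shape_ : float
        The MLE of lambda (years) and k.
    loglik_ : float
        Censored log-likelihood at the optimum.
    n_total_, n_events_ : int
    covariance_ : ndarray of shape (2, 2)
        Asymptotic covariance of (scale_, shape_) from the inverse observed
        information (delta method from the log scale).
    fit_ : WeibullFit
        Immutable summary of the fitted model.
    """

    def __init__(self, gtol: float = 1e-8, max_iter: int = 500):
        self.gtol = gtol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, level=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns [time, status]")
        t, d = _check_time_status(X[:, 0], X[:, 1])
        if t.size < 2:
            raise EstimationError("need at least 2 observations")
        if d.sum() < 1:
            raise EstimationError(
                "no uncensored observations: the Weibull likelihood is "
                "unbounded in scale and cannot be maximized"
            )
        x0 = np.array(_moment_init(t[d == 1]))
        n = t.size

        def objective(p):  # mean negative log-likelihood: gtol is n-invariant
            ll, grad = _weibull_loglik_grad(p, t, d)
            return -ll / n, -grad / n

        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="BFGS",
            options={"gtol": self.gtol, "maxiter": self.max_iter},
        )
        grad_norm = float(np.linalg.norm(res.jac))
        # BFGS may report precision loss at an already-stationary point
        if grad_norm > 1e-6 or not np.all(np.isfinite(res.x)):
            raise ConvergenceError(
                f"Weibull MLE did not converge: {res.message} "
                f"(per-observation |grad| = {grad_norm:.3g}, x = {res.x})"
            )
        self.scale_ = float(math.exp(res.x[0]))
        self.shape_ = float(math.exp(res.x[1]))
        self.loglik_ = float(-res.fun * n)
        self.n_total_ = int(t.size)
        self.n_events_ = int(d.sum())
        self.covariance_ = self._covariance(res.x, t, d)
        self.fit_ = WeibullFit(
            scale=self.scale_,
            shape=self.shape_,
            level=level,
            n_total=self.n_total_,
            n_events=self.n_events_,
            loglik=self.loglik_,
        )
        return self

    def _covariance(self, xopt, t, d, eps=1e-6):
        """Observed-information covariance via central differences of the
        analytic gradient, then delta method exp(.) to the natural scale."""
        hess = np.zeros((2, 2))
        for j in range(2):
            step = np.zeros(2)
            step[j] = eps
            _, gp = _weibull_loglik_grad(xopt + step, t, d)
            _, gm = _weibull_loglik_grad(xopt - step, t, d)
            hess[:, j] = (gp - gm) / (2.0 * eps)
        hess = 0.5 * (hess + hess.T)
        cov_log = np.linalg.inv(-hess)
        jac = np.diag(np.exp(xopt))
        return jac @ cov_log @ jac

    @property
    def standard_errors_(self):
        return np.sqrt(np.diag(self.covariance_))

    def survival_function(self, t):
        return self.fit_.survival(t)

    def cumulative_hazard(self, t):
        return self.fit_.chf(t)

    def predict_median(self, t_cens=0.0):
        """Median event time conditional on survival past ``t_cens``."""
        return self.fit_.predicted_median(t_cens)


def fit_weibull(time, status, level=None, include=None, **kwargs) -> WeibullFit:
    """Fit a censored Weibull model and return the :class:`WeibullFit`.

    Parameters
    ----------
    time, status : array-like
        Observed times (event time if ``status == 1``, censoring time
        otherwise) and 0/1 event indicators.
    level : object, optional
        Covariate-level label recorded on the fit.
    include : boolean array-like, optional
        Mask of individuals to use for estimation (e.g. to restrict to
        unrelated individuals); residuals may still be computed for all.
    """
    time = np.asarray(time, dtype=float).ravel()
    status = np.asarray(status, dtype=float).ravel()
    if include is not None:
        include = np.asarray(include, dtype=bool).ravel()
        if include.shape != time.shape:
            raise ValueError("include mask length mismatch")
        time, status = time[include], status[include]
    est = WeibullMLE(**kwargs).fit(np.column_stack([time, status]), level=level)
    return est.fit_


# ---------------------------------------------------------------------------
# Kaplan-Meier diagnostics


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: step values at the distinct event times.

    ``survival[i]`` is the estimate just after ``times[i]``; the usual
    convention that events precede censorings at tied times applies.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("KM survival values must be non-increasing within [0, 1]")

    def evaluate(self, t):
        """Right-continuous step evaluation of S_KM(t); S(t) = 1 before the
        first event time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])[idx]
        return vals if vals.ndim else float(vals)


class KaplanMeier(BaseEstimator):
    """Kaplan-Meier product-limit estimator (thin wrapper over lifelines).

    ``fit`` takes the same ``(n, 2)`` [time, status] layout as
    :class:`WeibullMLE`.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns [time, status]")
        t, d = _check_time_status(X[:, 0], X[:, 1])
        if d.sum() < 1:
            raise EstimationError("Kaplan-Meier needs at least one uncensored record")
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=d)
        table = kmf.event_table
        mask = table["observed"] > 0
        times = np.asarray(table.index[mask], dtype=float)
        surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
        self.estimate_ = KMEstimate(
            times=times,
            survival=surv,
            at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=int),
            events=table.loc[mask, "observed"].to_numpy(dtype=int),
        )
        return self

    def survival_function(self, t):
        return self.estimate_.evaluate(t)


def km_estimate(time, status) -> KMEstimate:
    """Product-limit estimate of S(t) from right-censored data."""
    return KaplanMeier().fit(np.column_stack([
        np.asarray(time, dtype=float).ravel(),
        np.asarray(status, dtype=float).ravel(),
    ])).estimate_


def conditional_median(survival_fn, t_cens, upper=None, tol=1e-9):
    """Median event time given survival past ``t_cens`` for an arbitrary
    survival function, by bisection on ``S(t) = S(t_cens) / 2``.

    The Weibull case has a closed form (:meth:`WeibullFit.predicted_median`);
    this generic root-finder supports other survival-function providers.
    """
    if t_cens < 0:
        raise ValueError("censoring time must be non-negative")
    target = survival_fn(t_cens) / 2.0
    lo = t_cens
    hi = upper if upper is not None else max(2.0 * t_cens, 1.0)
    while survival_fn(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the conditional median")
    return optimize.brentq(lambda t: survival_fn(t) - target, lo, hi, xtol=tol)
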