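"""Survival-analysis residuals: Martingale, deviance, and the OTE family.

For individual *i* with observed time ``t`` and event indicator ``delta``
(1 = event, 0 = censored), the classical residuals under an estimated
cumulative hazard CHF are

* Martingale residual ``MR = delta - CHF(t)``, with range ``(-inf, 1]``;
* deviance residual
  ``DR = sign(MR) * sqrt(-2 * (MR + delta * log(delta - MR)))``, a signed
  square-root transform that symmetrizes MR.

Neither behaves like a linear-regression residual: DR = 0 does not mean the
individual's event time equals its expectation, censored and uncensored
individuals at the same time are forced one MR unit apart, and censored
individuals are evaluated at the (arbitrary, for this purpose) censoring
time.

The ordinary time-to-event (OTE) residual repairs all three.  Every
individual is evaluated at ``t* = t_fail`` if uncensored or at the
conditional median ``t_pred`` if censored, the event count is replaced by
the constant ``b = -log(0.5) = ln 2`` (the cumulative hazard at the median
of any distribution), and the deviance transform is applied to the modified
Martingale residual ``MMR = b - CHF(t*)``:

    OTE = sign(MMR) * sqrt(-2 * (MMR - b*log(b) + b*log(b - MMR)))
        = sign(b - x) * sqrt(-2 * g(x)),   x = CHF(t*),

where ``g(x) = b - x - b*log(b) + b*log(x)`` is non-positive with its
maximum of 0 at ``x = b``.  OTE is therefore zero exactly when ``t*`` is
the median survival time, decreases monotonically in ``t*``, and places
censored and uncensored individuals on one scale.  The naive comparison
residual OLRR is simply ``median - t*`` on the raw time scale.

With a categorical covariate, every step (fitting, medians, residuals, and
the final standardization to mean 0 / s.d. 1) is carried out separately
within each covariate level, so that the standardized residuals can be
pooled across levels free of the covariate effect.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .survival import LN2, WeibullFit, fit_weibull

__all__ = [
    "RESIDUAL_KINDS",
    "g_function",
    "martingale",
    "deviance",
    "modified_martingale",
    "ote",
    "olrr",
    "evaluation_time",
    "compute_residuals",
    "standardize",
    "SurvivalResidualizer",
]

#: residual kinds in canonical column order
RESIDUAL_KINDS = ("mr", "dr", "mmr", "ote", "olrr")

_SQRT_CLIP = 1e-12  # tiny negative sqrt arguments from roundoff are clipped to 0


def _sqrt_nonneg(arg):
    arg = np.asarray(arg, dtype=float)
    bad = arg < -_SQRT_CLIP
    if np.any(bad):
        raise FloatingPointError(
            f"negative argument under the deviance square root (min {arg[bad].min():.3g})"
        )
    return np.sqrt(np.clip(arg, 0.0, None))


def g_function(x, b=LN2):
    """g(x) = b - x - b*log(b) + b*log(x); <= 0, with maximum 0 at x = b."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("g is defined for positive cumulative hazard only")
    out = b - x - b * math.log(b) + b * np.log(x)
    return out if out.ndim else float(out)


def martingale(delta, chf_value):
    """Martingale residual ``delta - CHF`` at the observed time."""
    delta = np.asarray(delta, dtype=float)
    chf_value = np.asarray(chf_value, dtype=float)
    if np.any(chf_value < 0):
        raise ValueError("cumulative hazard must be non-negative")
    out = delta - chf_value
    return out if out.ndim else float(out)


def deviance(mr, delta):
    """Deviance residual from the Martingale residual.

    ``sign(mr) * sqrt(-2 * (mr + delta * log(delta - mr)))`` with the usual
    convention that the ``delta * log`` term vanishes for censored
    individuals.  Preserves the sign and rank order of ``mr`` within each
    censoring stratum.
    """
    mr = np.asarray(mr, dtype=float)
    delta = np.asarray(delta, dtype=float)
    mr, delta = np.broadcast_arrays(mr, delta)
    if np.any((delta == 1) & (mr >= 1)):
        raise ValueError("uncensored MR must be < 1 (positive cumulative hazard)")
    if np.any((delta == 0) & (mr > 0)):
        raise ValueError("censored MR cannot be positive")
    logterm = np.zeros_like(mr)
    unc = delta == 1
    logterm[unc] = np.log(1.0 - mr[unc])
    out = np.sign(mr) * _sqrt_nonneg(-2.0 * (mr + delta * logterm))
    return out if out.ndim else float(out)


def modified_martingale(chf_at_tstar):
    """Modified Martingale residual ``-log(0.5) - CHF(t*)``; zero exactly
    when the evaluation time ``t*`` is the fitted median."""
    chf_at_tstar = np.asarray(chf_at_tstar, dtype=float)
    if np.any(chf_at_tstar < 0):
        raise ValueError("cumulative hazard must be non-negative")
    out = LN2 - chf_at_tstar
    return out if out.ndim else float(out)


def ote(mmr):
    """OTE residual: the deviance-style transform of the modified
    Martingale residual with constant event count ``b = -log(0.5)``.

    Raises for ``mmr >= b`` (i.e. CHF(t*) <= 0): an evaluation time of
    exactly zero is outside the data model, where event times are strictly
    positive.
    """
    mmr = np.asarray(mmr, dtype=float)
    if np.any(mmr >= LN2):
        raise ValueError(
            "OTE undefined for CHF(t*) <= 0 (evaluation time at or before 0)"
        )
    arg = -2.0 * (mmr - LN2 * math.log(LN2) + LN2 * np.log(LN2 - mmr))
    out = np.sign(mmr) * _sqrt_nonneg(arg)
    return out if out.ndim else float(out)


def olrr(median, t_star):
    """Naive linear-regression-style residual ``median - t*`` on the raw
    time scale (expected minus observed, so early events are positive, for
    sign comparability with OTE)."""
    t_star = np.asarray(t_star, dtype=float)
    if np.any(t_star <= 0):
        raise ValueError("evaluation time must be strictly positive")
    out = np.asarray(median, dtype=float) - t_star
    return out if out.ndim else float(out)


def evaluation_time(fit: WeibullFit, time, status):
    """The OTE evaluation time t*: the observed event time for uncensored
    individuals, the conditional median ``t_pred`` for censored ones."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=float)
    return np.where(status == 1, time, fit.predicted_median(time))


def compute_residuals(
    data: pd.DataFrame,
    fits: dict,
    kinds=RESIDUAL_KINDS,
    *,
    time_col="time",
    status_col="status",
    covariate_col="covariate",
) -> pd.DataFrame:
    """Attach residual columns to ``data``, one fitted model per covariate level.

    MR and DR are evaluated at each individual's own observed time with its
    own event indicator; MMR, OTE and OLRR are evaluated at ``t*`` with the
    common constant ``b = -log(0.5)`` in place of the indicator.  All
    per-level quantities (median, t_pred, CHF) come from that level's fit.

    Parameters
    ----------
    data : DataFrame
        Must contain ``time_col``, ``status_col`` and ``covariate_col``.
    fits : dict
        Maps each covariate level present in ``data`` to a
        :class:`~teres.survival.WeibullFit` (or any object exposing
        ``chf``, ``median`` and ``predicted_median``).
    kinds : iterable of {"mr", "dr", "mmr", "ote", "olrr"}
    """
    kinds = _check_kinds(kinds)
    levels = data[covariate_col].unique()
    missing = [lv for lv in levels if lv not in fits]
    if missing:
        raise KeyError(f"no fitted survival model for covariate level(s) {missing}")
    out = data.copy()
    need_tstar = bool({"mmr", "ote", "olrr"} & set(kinds))
    for col in ("t_star",) + tuple(kinds):
        out[col] = np.nan
    for lv in levels:
        idx = data[covariate_col] == lv
        fit = fits[lv]
        t = data.loc[idx, time_col].to_numpy(dtype=float)
        d = data.loc[idx, status_col].to_numpy(dtype=float)
        t_star = evaluation_time(fit, t, d)
        out.loc[idx, "t_star"] = t_star
        if "mr" in kinds or "dr" in kinds:
            mr = martingale(d, fit.chf(t))
            if "mr" in kinds:
                out.loc[idx, "mr"] = mr
            if "dr" in kinds:
                out.loc[idx, "dr"] = deviance(mr, d)
        if need_tstar:
            mmr = modified_martingale(fit.chf(t_star))
            if "mmr" in kinds:
                out.loc[idx, "mmr"] = mmr
            if "ote" in kinds:
                out.loc[idx, "ote"] = ote(mmr)
            if "olrr" in kinds:
                out.loc[idx, "olrr"] = olrr(fit.median, t_star)
    return out


def standardize(
    table: pd.DataFrame,
    kinds=RESIDUAL_KINDS,
    *,
    covariate_col="covariate",
    suffix="_std",
) -> pd.DataFrame:
    """Standardize each residual column to mean 0 / s.d. 1 within each
    covariate level (sample standard deviation, n-1 denominator), so that
    residuals can be pooled across levels on a common scale."""
    kinds = _check_kinds(kinds)
    out = table.copy()
    for kind in kinds:
        out[kind + suffix] = np.nan
    for lv, sub in table.groupby(covariate_col, sort=False):
        if len(sub) < 2:
            raise ValueError(f"covariate level {lv!r} has fewer than 2 individuals")
        for kind in kinds:
            vals = sub[kind].to_numpy(dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"residual {kind!r} has zero variance within covariate level {lv!r}"
                )
            out.loc[sub.index, kind + suffix] = (vals - vals.mean()) / sd
    return out


def _check_kinds(kinds):
    if isinstance(kinds, str):
        kinds = RESIDUAL_KINDS if kinds == "all" else (kinds,)
    kinds = tuple(kinds)
    unknown = set(kinds) - set(RESIDUAL_KINDS)
    if unknown:
        raise ValueError(f"unknown residual kind(s) {sorted(unknown)}")
    return kinds


class SurvivalResidualizer(TransformerMixin, BaseEstimator):
    """Covariate-stratified residual transformer for right-censored data.

    ``fit`` estimates one censored Weibull survival model per covariate
    level; ``transform`` appends the requested residual columns (and their
    within-level standardized versions) to the input table.  The residual
    columns of censored individuals use the conditional-median evaluation
    time, so the transformer is usable directly as a phenotype constructor
    for downstream association analysis.

    Parameters
    ----------
    kinds : "all" or iterable of {"mr", "dr", "mmr", "ote", "olrr"}
    standardize : bool
        Append ``<kind>_std`` columns standardized within covariate level.
    time_col, status_col, covariate_col : str
        Column names in the input DataFrame.
    fit_mask_col : str, optional
        Boolean column restricting which rows enter estimation (e.g. one
        individual per family); residuals are still computed for all rows.

    Attributes
    ----------
    fits_ : dict
        Covariate level -> :class:`~teres.survival.WeibullFit`.
    levels_ : ndarray
        Levels seen during ``fit``.
    """

    def __init__(
        self,
        kinds="all",
        standardize=True,
        time_col="time",
        status_col="status",
        covariate_col="covariate",
        fit_mask_col=None,
    ):
        self.kinds = kinds
        self.standardize = standardize
        self.time_col = time_col
        self.status_col = status_col
        self.covariate_col = covariate_col
        self.fit_mask_col = fit_mask_col

    def _validate(self, X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame")
        needed = [self.time_col, self.status_col, self.covariate_col]
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise KeyError(f"missing required column(s) {missing}")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.fits_ = {}
        for lv, sub in X.groupby(self.covariate_col, sort=False):
            mask = sub[self.fit_mask_col].to_numpy(bool) if self.fit_mask_col else None
            self.fits_[lv] = fit_weibull(
                sub[self.time_col], sub[self.status_col], level=lv, include=mask
            )
        self.levels_ = np.array(list(self.fits_))
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "fits_"):
            raise RuntimeError("SurvivalResidualizer is not fitted")
        X = self._validate(X)
        kinds = _check_kinds(self.kinds)
        out = compute_residuals(
            X,
            self.fits_,
            kinds,
            time_col=self.time_col,
            status_col=self.status_col,
            covariate_col=self.covariate_col,
        )
        if self.standardize:
            out = standardize(out, kinds, covariate_col=self.covariate_col)
        return out
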