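"""Gastric evacuation: exponential decay of stomach content after a meal.

After a fish stops feeding, stomach content S(t) declines approximately
exponentially, ``S(t) = S0 * exp(-R * t)``, where ``R`` (per hour) is the
instantaneous gastric evacuation rate.  ``R`` is estimated as the negated
slope of the ordinary least-squares regression of ``ln S`` on time — a
closed-form fit, no iterative optimisation.

Content is normalised to percent body weight (%BW) by default so that fish
of different sizes are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "percent_stomach_content",
    "EvacuationRateEstimator",
    "EvacuationFit",
    "fit_evacuation",
    "predict_content",
]


def percent_stomach_content(stomach_content, body_weight):
    """Stomach content as percent of body weight: ``100 * content / weight``.

    Parameters
    ----------
    stomach_content : float or array-like
        Stomach content mass (g dry weight), >= 0.
    body_weight : float or array-like
        Fish body weight (g wet weight), > 0.

    Returns
    -------
    float or ndarray
        Content in %BW.
    """
    s = np.asarray(stomach_content, dtype=float)
    w = np.asarray(body_weight, dtype=float)
    if np.any(w <= 0):
        raise ValueError("body_weight must be positive")
    if np.any(s < 0):
        raise ValueError("stomach_content must be non-negative")
    out = 100.0 * s / w
    return float(out) if out.ndim == 0 else out


def _as_time_vector(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("expected a single time feature")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("time input must be 1d or a (n, 1) column")
    return X


def _loglinear_ols(t, y):
    """Closed-form OLS of ln(y) on t.

    Returns (s0, rate, r_squared, residuals); rate is the negated slope.
    """
    logy = np.log(y)
    tbar = t.mean()
    lbar = logy.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    if sxx == 0.0:
        raise ValueError("need at least two distinct time points")
    slope = float(np.sum((t - tbar) * (logy - lbar)) / sxx)
    intercept = lbar - slope * tbar
    resid = logy - (intercept + slope * t)
    sst = float(np.sum((logy - lbar) ** 2))
    ssr = float(np.sum(resid**2))
    # constant log-content is fit perfectly by a flat line
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    return float(np.exp(intercept)), -slope, r2, resid


class EvacuationRateEstimator(BaseEstimator, RegressorMixin):
    """Log-linear regression estimator of the gastric evacuation rate.

    Fits ``ln(content) = ln(S0) - R * t`` by ordinary least squares and
    reports the instantaneous evacuation rate ``R`` as a positive decay
    (the fitted slope is ``-R``).

    Parameters
    ----------
    zero_policy : {"drop", "offset"}, default "drop"
        Empty stomachs cannot enter the logarithm.  ``"drop"`` removes
        zero-content records with a warning; ``"offset"`` adds half of the
        smallest positive observed content to every record instead.

    Attributes
    ----------
    s0_ : float
        Fitted content at t=0, ``exp(intercept)``.
    rate_ : float
        Instantaneous evacuation rate R (per hour), negated slope.
    r_squared_ : float
        Coefficient of determination on the log scale.
    n_obs_ : int
        Number of observations used in the fit.
    residuals_ : ndarray
        Log-scale residuals, one per used observation.
    """

    def __init__(self, zero_policy: str = "drop"):
        self.zero_policy = zero_policy

    def fit(self, X, y):
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and content must have the same length")
        if np.any(y < 0):
            raise ValueError("stomach content must be non-negative")
        if self.zero_policy not in ("drop", "offset"):
            raise ValueError("zero_policy must be 'drop' or 'offset'")
        if not np.any(y > 0):
            raise ValueError("no evacuable content: all stomach contents are zero")
        if np.any(y == 0):
            if self.zero_policy == "drop":
                warnings.warn(
                    f"dropping {int(np.sum(y == 0))} zero-content records "
                    "(cannot take log)",
                    stacklevel=2,
                )
                keep = y > 0
                t, y = t[keep], y[keep]
            else:
                y = y + 0.5 * y[y > 0].min()
        if len(np.unique(t)) < 3:
            raise ValueError("need at least 3 usable time points to fit")
        self.s0_, self.rate_, self.r_squared_, self.residuals_ = _loglinear_ols(t, y)
        self.n_obs_ = int(t.size)
        return self

    def predict(self, X):
        """Predicted stomach content ``S0 * exp(-R * t)`` at times ``X``."""
        if not hasattr(self, "rate_"):
            raise ValueError("estimator is not fitted")
        t = _as_time_vector(X)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return self.s0_ * np.exp(-self.rate_ * t)


@dataclass
class EvacuationFit:
    """Result of an exponential gastric-evacuation fit."""

    s0: float
    rate: float
    r_squared: float
    n_obs: int
    residuals: np.ndarray = field(repr=False)
    units: str = "%BW"

    def predict(self, time_h):
        t = np.asarray(time_h, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        out = self.s0 * np.exp(-self.rate * t)
        return float(out) if out.ndim == 0 else out


def fit_evacuation(
    observations,
    time_col: str = "time_h",
    content_col: str | None = None,
    normalize: bool = True,
    by: str = "fish",
    zero_policy: str = "drop",
) -> EvacuationFit:
    """Fit the exponential evacuation model to an observation table.

    Parameters
    ----------
    observations : DataFrame
        Must carry ``time_col`` plus either ``content_col``, or the pair
        ``stomach_content_g`` / ``body_weight_g`` when ``normalize``.
    normalize : bool
        Fit %BW-normalised content (default) rather than raw mass.
    by : {"fish", "mean"}
        Fit every individual observation (default) or the per-time-point
        mean content.
    """
    df = pd.DataFrame(observations)
    if time_col not in df.columns:
        raise ValueError(f"missing column {time_col!r}")
    if content_col is None:
        if normalize:
            content = percent_stomach_content(
                df["stomach_content_g"], df["body_weight_g"]
            )
            units = "%BW"
        else:
            content = df["stomach_content_g"].to_numpy(float)
            units = "g"
    else:
        content = df[content_col].to_numpy(float)
        units = "%BW" if normalize else "g"
    t = df[time_col].to_numpy(float)
    if by == "mean":
        grouped = pd.DataFrame({"t": t, "c": content}).groupby("t")["c"].mean()
        t, content = grouped.index.to_numpy(), grouped.to_numpy()
    elif by != "fish":
        raise ValueError("by must be 'fish' or 'mean'")
    est = EvacuationRateEstimator(zero_policy=zero_policy).fit(t, content)
    return EvacuationFit(
        s0=est.s0_,
        rate=est.rate_,
        r_squared=est.r_squared_,
        n_obs=est.n_obs_,
        residuals=est.residuals_,
        units=units,
    )


def predict_content(fit: EvacuationFit, time_h):
    """Evaluate a fitted evacuation curve at ``time_h`` hours."""
    return fit.predict(time_h)
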