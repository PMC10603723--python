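"""Daily growth rate: OLS slope of body weight against experiment day."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["GrowthRateEstimator", "GrowthFit", "fit_growth"]


class GrowthRateEstimator(BaseEstimator, RegressorMixin):
    """Linear regression of body weight on day; the slope is G_d (g/day).

    Attributes
    ----------
    slope_ : float
        Daily growth rate in g/day.
    intercept_ : float
        Fitted weight at day 0 (g).
    r_squared_ : float
    n_obs_ : int
    """

    def fit(self, X, y):
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        w = np.asarray(y, dtype=float)
        if d.shape != w.shape:
            raise ValueError("day and weight must have the same length")
        if len(np.unique(d)) < 2:
            raise ValueError("need at least 2 distinct days to fit growth")
        dbar, wbar = d.mean(), w.mean()
        sxx = float(np.sum((d - dbar) ** 2))
        self.slope_ = float(np.sum((d - dbar) * (w - wbar)) / sxx)
        self.intercept_ = wbar - self.slope_ * dbar
        resid = w - (self.intercept_ + self.slope_ * d)
        sst = float(np.sum((w - wbar) ** 2))
        self.r_squared_ = 1.0 if sst == 0.0 else 1.0 - float(np.sum(resid**2)) / sst
        self.n_obs_ = int(d.size)
        self.mean_weight_ = float(wbar)
        return self

    def predict(self, X):
        if not hasattr(self, "slope_"):
            raise ValueError("estimator is not fitted")
        d = np.asarray(X, dtype=float)
        if d.ndim == 2:
            d = d[:, 0]
        return self.intercept_ + self.slope_ * d


@dataclass
class GrowthFit:
    """Fitted daily growth rate with regression diagnostics."""

    g_d: float
    intercept: float
    r_squared: float
    n_obs: int
    units: str = "g/day"


def fit_growth(
    weights,
    day_col: str = "day",
    weight_col: str = "body_weight_g",
    by: str = "mean",
    units: str = "g/day",
) -> GrowthFit:
    """Estimate G_d from repeated weight samples.

    Parameters
    ----------
    weights : DataFrame with ``day_col`` and ``weight_col``.
    by : {"mean", "fish"}
        Regress on per-sampling-day mean weights (default, matching a design
        that samples batches of fish on a handful of days) or on every
        individual record.
    units : {"g/day", "%BW/day"}
        ``"%BW/day"`` reports ``100 * slope / mean weight`` (mass-specific).
    """
    df = pd.DataFrame(weights)
    if by == "mean":
        g = df.groupby(day_col)[weight_col].mean()
        d, w = g.index.to_numpy(float), g.to_numpy(float)
    elif by == "fish":
        d = df[day_col].to_numpy(float)
        w = df[weight_col].to_numpy(float)
    else:
        raise ValueError("by must be 'mean' or 'fish'")
    est = GrowthRateEstimator().fit(d, w)
    if units == "g/day":
        gd = est.slope_
    elif units == "%BW/day":
        gd = 100.0 * est.slope_ / est.mean_weight_
    else:
        raise ValueError("units must be 'g/day' or '%BW/day'")
    return GrowthFit(
        g_d=gd,
        intercept=est.intercept_,
        r_squared=est.r_squared_,
        n_obs=est.n_obs_,
        units=units,
    )
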