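import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoconv import (
    EvacuationRateEstimator,
    fit_evacuation,
    percent_stomach_content,
    predict_content,
)
from oracles import loglinear_ols_lstsq


@pytest.mark.parametrize(
    "content,weight,expected",
    [(0.0, 50.0, 0.0), (1.0, 50.0, 2.0), (2.5, 100.0, 2.5)],
)
def test_percent_stomach_content(content, weight, expected):
    assert percent_stomach_content(content, weight) == pytest.approx(expected)


def test_percent_stomach_content_rejects_bad_weight():
    with pytest.raises(ValueError):
        percent_stomach_content(1.0, 0.0)
    with pytest.raises(ValueError):
        percent_stomach_content(-1.0, 10.0)


@pytest.mark.parametrize("s0,rate", [(7.23, 0.12), (9.09, 0.19)])
def test_noiseless_exponential_recovered_exactly(s0, rate):
    """Log-linear OLS on noiseless decay recovers (S0, R) to machine precision."""
    t = np.arange(11.0)
    est = EvacuationRateEstimator().fit(t, s0 * np.exp(-rate * t))
    assert est.s0_ == pytest.approx(s0, abs=1e-12)
    assert est.rate_ == pytest.approx(rate, abs=1e-12)
    assert est.r_squared_ == pytest.approx(1.0, abs=1e-12)


def test_constant_content_gives_zero_rate():
    t = np.arange(5.0)
    est = EvacuationRateEstimator().fit(t, np.full(5, 4.2))
    assert est.rate_ == pytest.approx(0.0, abs=1e-14)
    assert est.s0_ == pytest.approx(4.2)
    assert est.r_squared_ == 1.0


def test_fit_matches_independent_lstsq_oracle():
    """Two-phase (non-exponential) data: fit equals the design-matrix OLS."""
    rng = np.random.default_rng(7)
    t = np.concatenate([np.linspace(0, 5, 20), np.linspace(5, 10, 20)])
    y = np.concatenate(
        [8 * np.exp(-0.3 * t[:20]), 8 * np.exp(-1.5 - 0.05 * (t[20:] - 5))]
    ) * np.exp(rng.normal(0, 0.05, 40))
    est = EvacuationRateEstimator().fit(t, y)
    s0_o, rate_o, r2_o = loglinear_ols_lstsq(t, y)
    assert est.s0_ == pytest.approx(s0_o, rel=1e-12)
    assert est.rate_ == pytest.approx(rate_o, abs=1e-12)
    assert est.r_squared_ == pytest.approx(r2_o, abs=1e-12)


def test_zero_content_policies():
    t = np.arange(6.0)
    y = np.array([10.0, 6.0, 3.5, 2.1, 1.2, 0.0])
    with pytest.warns(UserWarning, match="zero-content"):
        dropped = EvacuationRateEstimator(zero_policy="drop").fit(t, y)
    assert dropped.n_obs_ == 5
    offset = EvacuationRateEstimator(zero_policy="offset").fit(t, y)
    assert offset.n_obs_ == 6
    with pytest.raises(ValueError, match="no evacuable content"):
        EvacuationRateEstimator().fit(t, np.zeros(6))


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        EvacuationRateEstimator().fit([0.0, 1.0], [5.0, 3.0])


def test_aggregation_invariance(noiseless_decay_table):
    """Per-fish vs per-hour-mean fits agree on noiseless data."""
    per_fish = fit_evacuation(noiseless_decay_table, by="fish")
    per_mean = fit_evacuation(noiseless_decay_table, by="mean")
    assert per_fish.rate == pytest.approx(per_mean.rate, abs=1e-12)
    assert per_fish.s0 == pytest.approx(per_mean.s0, rel=1e-12)


def test_normalization_uses_percent_bw(noiseless_decay_table):
    fit = fit_evacuation(noiseless_decay_table, normalize=True)
    assert fit.units == "%BW"
    assert fit.s0 == pytest.approx(9.09, abs=1e-10)
    raw = fit_evacuation(noiseless_decay_table, normalize=False)
    assert raw.units == "g"
    assert raw.s0 == pytest.approx(9.09 / 100 * 40.0, rel=1e-10)


@settings(max_examples=50, deadline=None)
@given(
    k=st.floats(0.1, 50.0),
    s0=st.floats(0.5, 20.0),
    rate=st.floats(0.01, 1.0),
)
def test_scale_equivariance(k, s0, rate):
    """Content scaled by k scales S0 by k and leaves R unchanged."""
    t = np.arange(8.0)
    y = s0 * np.exp(-rate * t)
    base = EvacuationRateEstimator().fit(t, y)
    scaled = EvacuationRateEstimator().fit(t, k * y)
    assert scaled.rate_ == pytest.approx(base.rate_, abs=1e-9)
    assert scaled.s0_ == pytest.approx(k * base.s0_, rel=1e-9)


def test_predict_content():
    t = np.arange(11.0)
    fit = fit_evacuation(
        pd.DataFrame({"time_h": t, "c": 10.0 * np.exp(-0.5 * t)}), content_col="c"
    )
    assert predict_content(fit, 0.0) == pytest.approx(10.0)
    assert predict_content(fit, 2.0) == pytest.approx(10.0 * np.exp(-1.0))
    assert predict_content(fit, 200.0) < 1e-10
    with pytest.raises(ValueError):
        predict_content(fit, -1.0)
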