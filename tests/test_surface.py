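import numpy as np
import pandas as pd
import pytest

from ecoconv import (
    EfficiencySurfaceInterpolator,
    build_matrix,
    compare_to_reference,
    extract_profile,
    interpolate_surface,
    load_reference_full,
    load_reference_knots,
)
from oracles import natural_cubic_spline_eval

TEMPS = (10.0, 14.0, 18.0, 22.0, 26.0)
WEIGHTS = (30.0, 50.0, 70.0, 90.0, 110.0, 130.0, 150.0, 170.0)


def test_reference_knots_build(reference_knots):
    surf = build_matrix(list(reference_knots.itertuples(index=False, name=None)))
    assert surf.determined_mask.sum() == 17
    assert surf.values[0, 0] == pytest.approx(33.70)
    assert not surf.is_filled


def test_empty_and_full_build():
    empty = build_matrix([])
    assert empty.determined_mask.sum() == 0
    full_df = load_reference_full()
    full = build_matrix(
        list(full_df[["temperature", "weight_class", "e_g"]].itertuples(index=False, name=None))
    )
    assert full.determined_mask.all()
    assert full.is_filled


def test_build_rejects_duplicates_and_off_grid():
    with pytest.raises(ValueError, match="duplicate"):
        build_matrix([(10.0, 30.0, 1.0), (10.0, 30.0, 2.0)])
    with pytest.raises(ValueError, match="not on the grid"):
        build_matrix([(11.0, 30.0, 1.0)])


def test_knots_unchanged_by_fill(reference_knots, filled_reference_surface):
    surf = filled_reference_surface
    for t, w, e in reference_knots.itertuples(index=False, name=None):
        i = list(TEMPS).index(t)
        j = list(WEIGHTS).index(w)
        assert surf.values[i, j] == e
    assert surf.is_filled


def test_linear_column_filled_linearly():
    """A surface linear in temperature is reproduced exactly by the spline."""
    records = []
    for t in (10.0, 18.0, 26.0):
        for w in WEIGHTS:
            records.append((t, w, 2.0 * t + 0.01 * w))
    filled = interpolate_surface(build_matrix(records))
    for i, t in enumerate(TEMPS):
        expect = 2.0 * t + 0.01 * np.asarray(WEIGHTS)
        assert np.allclose(filled.values[i], expect, atol=1e-10)


def test_fill_matches_tridiagonal_oracle():
    """Both passes agree with the textbook natural-spline solver."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        det_rows = sorted(rng.choice(5, size=3, replace=False))
        records, truth_rows = [], {}
        for i in det_rows:
            k = rng.choice([4, 5, 6, 7, 8])
            cols = sorted(rng.choice(8, size=k, replace=False))
            vals = rng.uniform(5, 35, size=k)
            truth_rows[i] = (cols, vals)
            records += [(TEMPS[i], WEIGHTS[j], v) for j, v in zip(cols, vals)]
        filled = interpolate_surface(build_matrix(records))
        # oracle pass 1
        grid = np.full((5, 8), np.nan)
        for i, (cols, vals) in truth_rows.items():
            grid[i] = natural_cubic_spline_eval(
                np.asarray(WEIGHTS)[cols], vals, WEIGHTS
            )
            grid[i, cols] = vals
        # oracle pass 2
        tt = np.asarray(TEMPS)[det_rows]
        for j in range(8):
            missing = [i for i in range(5) if i not in det_rows]
            grid[missing, j] = natural_cubic_spline_eval(
                tt, grid[det_rows, j], np.asarray(TEMPS)[missing]
            )
        assert np.allclose(filled.values, grid, atol=1e-10)


def test_fill_order_option_runs(reference_knots):
    surf = build_matrix(list(reference_knots.itertuples(index=False, name=None)))
    alt = interpolate_surface(surf, order="cols-then-rows")
    assert alt.is_filled
    assert np.array_equal(
        alt.values[surf.determined_mask], surf.values[surf.determined_mask]
    )


def test_record_order_invariance(reference_knots):
    records = list(reference_knots.itertuples(index=False, name=None))
    a = interpolate_surface(build_matrix(records))
    b = interpolate_surface(build_matrix(records[::-1]))
    assert np.array_equal(a.values, b.values)


def test_extract_profile_at_knot_equals_row(filled_reference_surface):
    prof = extract_profile(filled_reference_surface, 18.0)
    assert np.allclose(prof["e_g"], filled_reference_surface.values[2], atol=1e-10)


def test_extract_profile_off_knot(filled_reference_surface):
    prof = extract_profile(filled_reference_surface, 25.0)
    surf = filled_reference_surface
    # efficiency declines with body weight from 90 g upward at 25 °C
    heavy = prof.set_index("weight_g").loc[90.0:, "e_g"].to_numpy()
    assert np.all(np.diff(heavy) < 0)
    # where the 22 and 26 °C rows bracket monotonically, 25 °C lies between
    for j in range(8):
        lo, hi = sorted((surf.values[3, j], surf.values[4, j]))
        val = prof["e_g"].iloc[j]
        if hi - lo > 2.0:  # clearly separated rows
            assert lo - 1.5 <= val <= hi + 1.5


def test_extract_profile_guards_extrapolation(filled_reference_surface):
    with pytest.raises(ValueError, match="outside"):
        extract_profile(filled_reference_surface, 30.0)
    prof = extract_profile(filled_reference_surface, 30.0, allow_extrapolation=True)
    assert np.all(np.isfinite(prof["e_g"]))


def test_unfilled_profile_rejected(reference_knots):
    surf = build_matrix(list(reference_knots.itertuples(index=False, name=None)))
    with pytest.raises(ValueError, match="unfilled"):
        extract_profile(surf, 18.0)


def test_sklearn_interpolator_round_trip(reference_knots):
    X = reference_knots[["temperature", "weight_class"]].to_numpy()
    y = reference_knots["e_g"].to_numpy()
    est = EfficiencySurfaceInterpolator().fit(X, y)
    assert np.allclose(est.predict(X), y, atol=1e-8)
    params = est.get_params()
    assert params["order"] == "rows-then-cols"


def test_soft_reference_report(filled_reference_surface, capsys):
    """Diagnostic report against the published estimated cells (soft check)."""
    rep = compare_to_reference(filled_reference_surface, tol=3.0)
    assert len(rep) == 23
    assert {"filled", "reference", "difference", "within_tol"} <= set(rep.columns)
    n_ok = int(rep["within_tol"].sum())
    print(f"interpolated cells within ±3 pp of published estimates: {n_ok}/23")
    for _, row in rep[~rep["within_tol"]].iterrows():
        print(
            f"  discrepancy at ({row.temperature:g} °C, {row.weight_class:g} g): "
            f"{row.filled:.2f} vs {row.reference:.2f}"
        )
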