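"""Temperature x body-weight conversion-efficiency surface.

A small number of determined E_g values is placed on a regular
(temperature, weight-class) grid and the remaining cells are filled by
separable natural-cubic-spline interpolation in two passes:

1. every temperature row holding >= 2 determined cells is completed by a
   spline along the weight axis;
2. the remaining temperature rows are filled per weight column by a spline
   along the temperature axis through the now-complete determined rows.

Determined cells are never altered — this is interpolation, not smoothing.
Natural boundary conditions (zero second derivative at the end knots) are
used throughout; outside the knot range the end cubic is continued.
Iso-temperature profiles (e.g. at 25 °C) are read off the filled grid by a
per-column spline through all temperature rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

__all__ = [
    "EfficiencySurface",
    "build_matrix",
    "interpolate_surface",
    "extract_profile",
    "EfficiencySurfaceInterpolator",
    "load_reference_knots",
    "load_reference_full",
    "compare_to_reference",
]

DEFAULT_TEMP_AXIS = (10.0, 14.0, 18.0, 22.0, 26.0)
DEFAULT_WEIGHT_AXIS = (30.0, 50.0, 70.0, 90.0, 110.0, 130.0, 150.0, 170.0)


@dataclass
class EfficiencySurface:
    """E_g (%) on a temperature x weight grid with a determined-cell mask."""

    temp_axis: np.ndarray
    weight_axis: np.ndarray
    values: np.ndarray = field(repr=False)
    determined_mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.temp_axis = np.asarray(self.temp_axis, dtype=float)
        self.weight_axis = np.asarray(self.weight_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.determined_mask = np.asarray(self.determined_mask, dtype=bool)
        if np.any(np.diff(self.temp_axis) <= 0) or np.any(
            np.diff(self.weight_axis) <= 0
        ):
            raise ValueError("axes must be strictly increasing")
        shape = (self.temp_axis.size, self.weight_axis.size)
        if self.values.shape != shape or self.determined_mask.shape != shape:
            raise ValueError(f"values/mask must have shape {shape}")

    @property
    def is_filled(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.temp_axis, name="temperature_C"),
            columns=[f"{w:g}" for w in self.weight_axis],
        )
        return df.reset_index()


def _grid_index(axis: np.ndarray, value: float, what: str) -> int:
    hit = np.nonzero(np.isclose(axis, value, rtol=0, atol=1e-9))[0]
    if hit.size == 0:
        raise ValueError(f"{what} {value} is not on the grid axis {axis.tolist()}")
    return int(hit[0])


def build_matrix(
    records,
    temp_axis=DEFAULT_TEMP_AXIS,
    weight_axis=DEFAULT_WEIGHT_AXIS,
) -> EfficiencySurface:
    """Place determined records on the grid; unfilled cells are NaN.

    ``records`` is an iterable of objects or mappings with attributes/keys
    ``temperature``, ``weight_class`` and ``e_g`` (EfficiencyRecord works),
    or of plain ``(temperature, weight, e_g)`` triples.
    """
    temp_axis = np.asarray(temp_axis, dtype=float)
    weight_axis = np.asarray(weight_axis, dtype=float)
    values = np.full((temp_axis.size, weight_axis.size), np.nan)
    mask = np.zeros(values.shape, dtype=bool)
    for rec in records:
        if isinstance(rec, (tuple, list)):
            t, w, e = rec
        elif isinstance(rec, dict):
            t, w, e = rec["temperature"], rec["weight_class"], rec["e_g"]
        else:
            t, w, e = rec.temperature, rec.weight_class, rec.e_g
        i = _grid_index(temp_axis, float(t), "temperature")
        j = _grid_index(weight_axis, float(w), "weight class")
        if mask[i, j]:
            raise ValueError(f"duplicate record for cell ({t} °C, {w} g)")
        values[i, j] = float(e)
        mask[i, j] = True
    return EfficiencySurface(temp_axis, weight_axis, values, mask)


def _natural_spline(x, y):
    return CubicSpline(x, y, bc_type="natural", extrapolate=True)


def interpolate_surface(
    surface: EfficiencySurface, order: str = "rows-then-cols"
) -> EfficiencySurface:
    """Fill the empty cells by the two-pass separable spline scheme.

    ``order="rows-then-cols"`` (default) completes determined-temperature
    rows along weight first; ``"cols-then-rows"`` runs the passes the other
    way round, for sensitivity analysis.  Determined cells are untouched.
    """
    if order == "cols-then-rows":
        transposed = EfficiencySurface(
            surface.weight_axis,
            surface.temp_axis,
            surface.values.T.copy(),
            surface.determined_mask.T.copy(),
        )
        filled = interpolate_surface(transposed, order="rows-then-cols")
        return replace(surface, values=filled.values.T)
    if order != "rows-then-cols":
        raise ValueError("order must be 'rows-then-cols' or 'cols-then-rows'")

    vals = surface.values.copy()
    mask = surface.determined_mask
    # pass 1: complete every temperature row holding >= 2 determined cells
    complete = np.zeros(surface.temp_axis.size, dtype=bool)
    for i in range(surface.temp_axis.size):
        k = mask[i]
        if k.sum() >= 2:
            cs = _natural_spline(surface.weight_axis[k], vals[i, k])
            miss = ~np.isfinite(vals[i])
            vals[i, miss] = cs(surface.weight_axis[miss])
            complete[i] = True
    # pass 2: fill the remaining rows per weight column, knots = completed rows
    for j in range(surface.weight_axis.size):
        have = complete & np.isfinite(vals[:, j])
        if have.sum() < 2:
            raise ValueError(
                f"weight column {surface.weight_axis[j]:g} g: fewer than 2 "
                "knots available after the first pass"
            )
        miss = ~np.isfinite(vals[:, j])
        if miss.any():
            cs = _natural_spline(surface.temp_axis[have], vals[have, j])
            vals[miss, j] = cs(surface.temp_axis[miss])
    # interpolation, not smoothing: knots pass through unchanged
    assert np.array_equal(vals[mask], surface.values[mask])
    return replace(surface, values=vals)


def extract_profile(
    surface: EfficiencySurface, temperature: float, allow_extrapolation: bool = False
) -> pd.DataFrame:
    """Iso-temperature profile (weight, E_g) read off a filled surface.

    Evaluates a per-column natural cubic spline through all temperature rows
    of the filled grid; supports off-knot temperatures such as 25 °C.
    """
    if not surface.is_filled:
        raise ValueError("surface has unfilled cells; run interpolate_surface first")
    t = float(temperature)
    lo, hi = surface.temp_axis[0], surface.temp_axis[-1]
    if (t < lo or t > hi) and not allow_extrapolation:
        raise ValueError(
            f"temperature {t} outside [{lo}, {hi}]; pass allow_extrapolation=True"
        )
    e_g = np.array(
        [
            float(_natural_spline(surface.temp_axis, surface.values[:, j])(t))
            for j in range(surface.weight_axis.size)
        ]
    )
    return pd.DataFrame({"weight_g": surface.weight_axis, "e_g": e_g})


class EfficiencySurfaceInterpolator(BaseEstimator):
    """Grid spline interpolator with a scikit-learn fit/predict surface.

    ``fit(X, y)`` takes determined knots as ``X = [(temperature, weight)]``
    and ``y = E_g`` (%); the two-pass fill runs at fit time.  ``predict(X)``
    evaluates the filled surface at arbitrary (temperature, weight) points
    via a weight-axis spline through the iso-temperature profile.
    """

    def __init__(
        self,
        temp_axis=DEFAULT_TEMP_AXIS,
        weight_axis=DEFAULT_WEIGHT_AXIS,
        order: str = "rows-then-cols",
    ):
        self.temp_axis = temp_axis
        self.weight_axis = weight_axis
        self.order = order

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) columns (temperature, weight)")
        records = [(t, w, e) for (t, w), e in zip(X, y)]
        self.surface_ = interpolate_surface(
            build_matrix(records, self.temp_axis, self.weight_axis), order=self.order
        )
        return self

    def predict(self, X):
        if not hasattr(self, "surface_"):
            raise ValueError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) columns (temperature, weight)")
        out = np.empty(X.shape[0])
        for k, (t, w) in enumerate(X):
            prof = extract_profile(self.surface_, t, allow_extrapolation=True)
            cs = _natural_spline(prof["weight_g"].to_numpy(), prof["e_g"].to_numpy())
            out[k] = float(cs(w))
        return out


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("ecoconv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_knots() -> pd.DataFrame:
    """The 17 determined (temperature, weight, E_g) cells of the chub-mackerel
    temperature x weight experiment, as packaged reference data."""
    return _load_packaged("determined_efficiency_cells.csv")


def load_reference_full() -> pd.DataFrame:
    """The full published 5x8 grid (determined + spline-estimated cells)."""
    return _load_packaged("reference_efficiency_grid.csv")


def compare_to_reference(
    filled: EfficiencySurface, reference: pd.DataFrame | None = None, tol: float = 3.0
) -> pd.DataFrame:
    """Soft diagnostic report of the filled cells against published estimates.

    Returns one row per non-determined cell with the fill value, the
    reference value, their difference, and a ``within_tol`` flag.  The
    published estimates came from a spreadsheet spline whose boundary
    conditions are undocumented, so this is a report, not a validation gate.
    """
    if reference is None:
        reference = load_reference_full()
    ref = reference.set_index(["temperature", "weight_class"])["e_g"]
    rows = []
    for i, t in enumerate(filled.temp_axis):
        for j, w in enumerate(filled.weight_axis):
            if filled.determined_mask[i, j]:
                continue
            r = float(ref.loc[(t, w)])
            d = float(filled.values[i, j]) - r
            rows.append(
                {
                    "temperature": t,
                    "weight_class": w,
                    "filled": float(filled.values[i, j]),
                    "reference": r,
                    "difference": d,
                    "within_tol": abs(d) <= tol,
                }
            )
    return pd.DataFrame(rows)
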