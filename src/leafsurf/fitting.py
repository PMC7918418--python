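"""Global B-spline surface fitting of a PSF.

Two fitting paths are provided:

* :func:`fit_surface_grid` — the classical tensor-product algorithms for a
  full rectangular grid of points: one shared parameter vector and knot
  vector per direction (averaged over columns/rows), curve fits through
  every column, then through every row of the intermediate control points.
  Supports interpolation (control counts equal to data counts) and
  least-squares approximation.

* :func:`fit_surface_slicewise` — the slice-wise algorithm that also
  handles columns of unequal length (the unordered PSF). Every column is
  approximated by a p-degree curve using its *own* parameterization and knot
  vector; the u knot vector of the surface is the element-wise mean of the
  per-column knot vectors (well defined because all columns share the same
  control count). The rows of the resulting intermediate control net are
  then fitted the same way in v, and the v knot vector is again the
  element-wise mean. The mean of clamped, non-decreasing knot vectors of
  equal length is itself clamped and non-decreasing, so the output surface
  is always valid.

Orientation convention: u runs across a slice (left edge to right edge),
v runs from leaf base to tip, i.e. PSF columns are fitted in u, rows in v.
A column of coincident points (the collapsed leaf tip) is fitted as a
collapsed column with all control points equal — not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .psf import OrderedPSF, UnorderedPSF
from .splines import (NurbsSurface, basis_matrix, fit_curve_approximate,
                      knots_from_params, parameterize)

FIT_MODES = ("interpolate", "approximate", "slicewise")


@dataclass
class FitConfig:
    """Degrees, control counts and parameterization for a surface fit.

    ``n_ctrl_u`` applies across a slice, ``n_ctrl_v`` along the leaf. In
    ``interpolate`` mode the control counts are taken from the grid itself.
    """

    degree_u: int = 2
    degree_v: int = 2
    n_ctrl_u: int = 5
    n_ctrl_v: int = 5
    parameterization: str = "chord_length"
    mode: str = "slicewise"

    def __post_init__(self):
        if self.mode not in FIT_MODES:
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.n_ctrl_u < self.degree_u + 1 or self.n_ctrl_v < self.degree_v + 1:
            raise ValueError("need n_ctrl >= degree + 1 in both directions")


def _is_collapsed(points: np.ndarray) -> bool:
    return bool(np.allclose(points, points[0], atol=1e-12))


def _mean_params(columns: list[np.ndarray], method: str) -> np.ndarray:
    """Shared parameter vector: mean of per-column parameterizations.

    Collapsed columns (all points coincident) carry no chord information and
    are excluded from the mean; if every column is collapsed, equally spaced
    parameters are used.
    """
    rows = [parameterize(c, method) for c in columns if not _is_collapsed(c)]
    if not rows:
        return np.linspace(0.0, 1.0, len(columns[0]))
    return np.mean(rows, axis=0)


def fit_surface_grid(psf: OrderedPSF | np.ndarray, config: FitConfig,
                     params_u: np.ndarray | None = None,
                     params_v: np.ndarray | None = None,
                     knots_u: np.ndarray | None = None,
                     knots_v: np.ndarray | None = None) -> NurbsSurface:
    """Classical global surface fit of a full grid.

    Interpolation passes through every grid point; approximation performs an
    endpoint-interpolating least-squares fit with ``config.n_ctrl_u`` x
    ``config.n_ctrl_v`` control points. Explicit parameter or knot vectors
    may be supplied (e.g. to refit samples of a known surface in its own
    spline space); otherwise parameters are averaged over columns/rows and
    knots placed by averaging (interpolation) or parameter density
    (approximation).
    """
    grid = psf.grid if isinstance(psf, OrderedPSF) else np.asarray(psf, dtype=float)
    ku1, lv1, _ = grid.shape
    p, q = config.degree_u, config.degree_v
    interp = config.mode == "interpolate"
    n_u = ku1 if interp else config.n_ctrl_u
    n_v = lv1 if interp else config.n_ctrl_v
    if not (p + 1 <= n_u <= ku1 and q + 1 <= n_v <= lv1):
        raise ValueError("control counts incompatible with grid size and degrees")

    if params_u is None:
        params_u = _mean_params([grid[:, j] for j in range(lv1)], config.parameterization)
    if params_v is None:
        params_v = _mean_params([grid[i, :] for i in range(ku1)], config.parameterization)
    if knots_u is None:
        knots_u = knots_from_params(params_u, p, n_u)
    if knots_v is None:
        knots_v = knots_from_params(params_v, q, n_v)

    def fit_run(points, degree, n_ctrl, params, knots):
        if _is_collapsed(points):
            return np.tile(points[0], (n_ctrl, 1))
        if n_ctrl == len(points):
            B = basis_matrix(knots, degree, n_ctrl, params)
            try:
                return scipy.linalg.solve(B, points)
            except scipy.linalg.LinAlgError as exc:
                raise ValueError("singular collocation system in grid fit") from exc
        return fit_curve_approximate(points, degree, n_ctrl,
                                     params=params, knots=knots).control_points

    # u-direction: one curve fit per column, shared params/knots
    R = np.empty((n_u, lv1, 3))
    for j in range(lv1):
        R[:, j] = fit_run(grid[:, j], p, n_u, params_u, knots_u)
    # v-direction: one curve fit per row of the intermediate net
    net = np.empty((n_u, n_v, 3))
    for i in range(n_u):
        net[i] = fit_run(R[i], q, n_v, params_v, knots_v)
    return NurbsSurface(p, q, knots_u, knots_v, net)


def fit_surface_slicewise(psf: OrderedPSF | UnorderedPSF,
                           config: FitConfig) -> NurbsSurface:
    """Slice-wise surface fit with per-column parameters and averaged knots.

    Works on ordered and unordered PSFs alike. Every column must contain at
    least ``config.n_ctrl_u`` points unless it is collapsed (all points
    coincident), in which case it is fitted as a collapsed column. The
    number of columns must be at least ``config.n_ctrl_v``.
    """
    columns = psf.columns()
    p, q = config.degree_u, config.degree_v
    n_u, n_v = config.n_ctrl_u, config.n_ctrl_v
    l1 = len(columns)
    if l1 < n_v:
        raise ValueError(f"{l1} columns cannot support n_ctrl_v={n_v}")

    # (1) p-degree curve approximation through each column (u-direction)
    knot_stack = np.empty((l1, n_u + p + 1))
    R = np.empty((n_u, l1, 3))
    for j, col in enumerate(columns):
        col = np.asarray(col, dtype=float)
        if _is_collapsed(col):
            curve = fit_curve_approximate(col if len(col) > n_u else
                                          np.tile(col[0], (max(len(col), n_u), 1)),
                                          p, n_u)
        else:
            if len(col) < n_u:
                raise ValueError(
                    f"column {j} has {len(col)} points, fewer than n_ctrl_u={n_u}"
                )
            curve = fit_curve_approximate(col, p, n_u,
                                          method=config.parameterization)
        knot_stack[j] = curve.knots
        R[:, j] = curve.control_points
    knots_u = knot_stack.mean(axis=0)

    # (2) q-degree curve approximation through each row of R (v-direction)
    knot_stack_v = np.empty((n_u, n_v + q + 1))
    net = np.empty((n_u, n_v, 3))
    for i in range(n_u):
        row = R[i]
        if _is_collapsed(row):
            curve = fit_curve_approximate(np.tile(row[0], (max(l1, n_v), 1)), q, n_v)
        else:
            curve = fit_curve_approximate(row, q, n_v,
                                          method=config.parameterization)
        knot_stack_v[i] = curve.knots
        net[i] = curve.control_points
    knots_v = knot_stack_v.mean(axis=0)

    return NurbsSurface(p, q, knots_u, knots_v, net)


def fit_surface(psf, config: FitConfig, **overrides) -> NurbsSurface:
    """Dispatch on ``config.mode``; grid modes require an ordered PSF."""
    if config.mode == "slicewise":
        return fit_surface_slicewise(psf, config)
    if not isinstance(psf, OrderedPSF):
        raise ValueError("grid interpolation/approximation requires an ordered PSF")
    return fit_surface_grid(psf, config, **overrides)
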