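"""B-spline / NURBS primitives.

Everything downstream (leaf surface fitting, point projection, error metrics)
is built on the machinery in this module: Cox-de Boor basis functions and
their derivatives, clamped knot vectors, the three classical data
parameterizations (equally spaced, chord length, centripetal), knot placement
by averaging (interpolation) and by parameter density (approximation), and
global curve interpolation / least-squares approximation with interpolated
endpoints.

Conventions
-----------
* All parameter domains are [0, 1].
* Knot vectors are clamped: the first and last ``degree + 1`` knots equal
  0 and 1 respectively, and ``len(knots) == n_ctrl + degree + 1``.
* Basis functions follow the half-open-span convention, except at the right
  endpoint where the last span is closed so that evaluation at u = 1 is
  defined and the last basis function equals 1 there.
* Control nets are indexed u-major: ``control_net[i, j]`` is the control
  point with u-index ``i`` and v-index ``j``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


class DegenerateChordWarning(UserWarning):
    """Raised when chord-length style parameterization meets coincident points."""


# ---------------------------------------------------------------------------
# knot vectors
# ---------------------------------------------------------------------------

def validate_knots(knots: np.ndarray, degree: int, n_ctrl: int) -> np.ndarray:
    """Check that ``knots`` is a clamped knot vector on [0, 1].

    Returns the knots as a float array; raises ``ValueError`` otherwise.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1:
        raise ValueError("knot vector must be one-dimensional")
    if len(knots) != n_ctrl + degree + 1:
        raise ValueError(
            f"knot vector length {len(knots)} != n_ctrl + degree + 1 "
            f"= {n_ctrl + degree + 1}"
        )
    if np.any(np.diff(knots) < 0):
        raise ValueError("knot vector must be non-decreasing")
    if not (np.allclose(knots[: degree + 1], 0.0) and np.allclose(knots[-degree - 1:], 1.0)):
        raise ValueError("knot vector must be clamped to [0, 1]")
    return knots


def find_span(knots: np.ndarray, degree: int, n_ctrl: int, u) -> np.ndarray:
    """Knot span index of each value in ``u`` (vectorized).

    The last span is treated as closed so u = 1 maps to span ``n_ctrl - 1``.
    """
    u = np.asarray(u, dtype=float)
    spans = np.searchsorted(knots, u, side="right") - 1
    return np.clip(spans, degree, n_ctrl - 1)


def _basis_at_spans(knots: np.ndarray, degree: int, spans: np.ndarray,
                    u: np.ndarray) -> np.ndarray:
    """Nonzero basis functions N_{span-p..span, p}(u), vectorized over points.

    Returns array of shape (len(u), degree + 1). Triangular scheme with the
    0/0 := 0 convention.
    """
    p = degree
    u = np.asarray(u, dtype=float)
    npt = u.shape[0]
    N = np.zeros((npt, p + 1))
    N[:, 0] = 1.0
    left = np.zeros((npt, p + 1))
    right = np.zeros((npt, p + 1))
    for j in range(1, p + 1):
        left[:, j] = u - knots[spans + 1 - j]
        right[:, j] = knots[spans + j] - u
        saved = np.zeros(npt)
        for r in range(j):
            denom = right[:, r + 1] + left[:, j - r]
            temp = np.where(denom != 0.0, N[:, r] / np.where(denom == 0.0, 1.0, denom), 0.0)
            N[:, r] = saved + right[:, r + 1] * temp
            saved = left[:, j - r] * temp
        N[:, j] = saved
    return N


def basis_matrix(knots: np.ndarray, degree: int, n_ctrl: int, u) -> np.ndarray:
    """Full collocation matrix B with B[t, i] = N_{i,degree}(u[t])."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    spans = find_span(knots, degree, n_ctrl, u)
    vals = _basis_at_spans(knots, degree, spans, u)
    B = np.zeros((len(u), n_ctrl))
    cols = spans[:, None] - degree + np.arange(degree + 1)[None, :]
    np.put_along_axis(B, cols, vals, axis=1)
    return B


def _value_matrix(knots: np.ndarray, degree: int, u: np.ndarray) -> np.ndarray:
    """Collocation matrix of the degree-``degree`` basis living on ``knots``.

    Unlike :func:`basis_matrix` the number of functions is derived from the
    knot vector (``len(knots) - degree - 1``), which lets the same clamped
    knot vector serve the lower-degree bases needed by derivative formulas.
    """
    nf = len(knots) - degree - 1
    spans = np.clip(np.searchsorted(knots, u, side="right") - 1, degree, nf - 1)
    vals = _basis_at_spans(knots, degree, spans, u)
    B = np.zeros((len(u), nf))
    cols = spans[:, None] - degree + np.arange(degree + 1)[None, :]
    np.put_along_axis(B, cols, vals, axis=1)
    return B


def basis_ders_matrix(knots: np.ndarray, degree: int, u,
                      n_ders: int) -> list[np.ndarray]:
    """Basis values and derivatives at many parameters at once.

    Returns matrices ``D[k]`` of shape (len(u), n_ctrl) with
    ``D[k][t, i] = d^k/du^k N_{i,degree}(u[t])``, built from the classical
    reduction to lower-degree bases (derivatives above the degree vanish).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))

    def dmat(d: int, k: int) -> np.ndarray:
        if d < 0:
            return np.zeros((len(u), len(knots) - max(d, 0) - 1))
        if k == 0:
            return _value_matrix(knots, d, u)
        if d == 0:
            return np.zeros((len(u), len(knots) - 1))
        low = dmat(d - 1, k - 1)
        nf = len(knots) - d - 1
        out = np.zeros((len(u), nf))
        for i in range(nf):
            den1 = knots[i + d] - knots[i]
            den2 = knots[i + d + 1] - knots[i + 1]
            if den1 > 0:
                out[:, i] += d * low[:, i] / den1
            if den2 > 0:
                out[:, i] -= d * low[:, i + 1] / den2
        return out

    return [dmat(degree, k) for k in range(n_ders + 1)]


def basis_function(i: int, degree: int, u: float, knots: np.ndarray) -> float:
    """Single Cox-de Boor basis value N_{i,degree}(u) on a clamped knot vector."""
    knots = np.asarray(knots, dtype=float)
    n_ctrl = len(knots) - degree - 1
    if n_ctrl < degree + 1:
        raise ValueError("knot vector too short for this degree")
    if not (0 <= i < n_ctrl):
        raise ValueError(f"basis index {i} out of range [0, {n_ctrl - 1}]")
    if not (0.0 <= u <= 1.0):
        raise ValueError("parameter u must lie in [0, 1]")
    span = int(find_span(knots, degree, n_ctrl, np.array([u]))[0])
    if i < span - degree or i > span:
        return 0.0
    vals = _basis_at_spans(knots, degree, np.array([span]), np.array([u]))[0]
    return float(vals[i - (span - degree)])


def ders_basis_functions(knots: np.ndarray, degree: int, span: int, u: float,
                         n_ders: int) -> np.ndarray:
    """Nonzero basis functions and derivatives at ``u``.

    Returns ``ders`` of shape (n_ders + 1, degree + 1) with
    ``ders[k, r] = d^k/du^k N_{span-degree+r, degree}(u)``. Derivatives of
    order above ``degree`` are zero.
    """
    p = degree
    nd = min(n_ders, p)
    ndu = np.zeros((p + 1, p + 1))
    ndu[0, 0] = 1.0
    left = np.zeros(p + 1)
    right = np.zeros(p + 1)
    for j in range(1, p + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            ndu[j, r] = right[r + 1] + left[j - r]
            temp = ndu[r, j - 1] / ndu[j, r]
            ndu[r, j] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        ndu[j, j] = saved

    ders = np.zeros((n_ders + 1, p + 1))
    ders[0, :] = ndu[:, p]
    for r in range(p + 1):
        a = np.zeros((2, p + 1))
        a[0, 0] = 1.0
        s1, s2 = 0, 1
        for k in range(1, nd + 1):
            d = 0.0
            rk = r - k
            pk = p - k
            if r >= k:
                a[s2, 0] = a[s1, 0] / ndu[pk + 1, rk]
                d = a[s2, 0] * ndu[rk, pk]
            j1 = 1 if rk >= -1 else -rk
            j2 = k - 1 if r - 1 <= pk else p - r
            for j in range(j1, j2 + 1):
                a[s2, j] = (a[s1, j] - a[s1, j - 1]) / ndu[pk + 1, rk + j]
                d += a[s2, j] * ndu[rk + j, pk]
            if r <= pk:
                a[s2, k] = -a[s1, k - 1] / ndu[pk + 1, r]
                d += a[s2, k] * ndu[r, pk]
            ders[k, r] = d
            s1, s2 = s2, s1

    fac = float(p)
    for k in range(1, nd + 1):
        ders[k, :] *= fac
        fac *= p - k
    return ders


# ---------------------------------------------------------------------------
# parameterization and knot placement
# ---------------------------------------------------------------------------

PARAM_METHODS = ("equally_spaced", "chord_length", "centripetal")


def parameterize(points: np.ndarray, method: str = "chord_length") -> np.ndarray:
    """Assign strictly increasing parameters in [0, 1] to an ordered point run.

    ``chord_length`` uses cumulative chord fractions, ``centripetal`` the
    square roots of the chords. Coincident consecutive points produce zero
    chords; those segments fall back to the mean positive chord (equally
    spaced locally) with a :class:`DegenerateChordWarning`. A fully coincident
    run falls back to equally spaced parameters.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least two points to parameterize")
    if method not in PARAM_METHODS:
        raise ValueError(f"unknown parameterization {method!r}")
    if method == "equally_spaced":
        return np.linspace(0.0, 1.0, n)
    chords = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if method == "centripetal":
        chords = np.sqrt(chords)
    zero = chords <= 0.0
    if zero.any():
        warnings.warn(
            "coincident consecutive points; zero chords replaced by equal spacing",
            DegenerateChordWarning,
            stacklevel=2,
        )
        if zero.all():
            return np.linspace(0.0, 1.0, n)
        chords = np.where(zero, chords[~zero].mean(), chords)
    params = np.concatenate([[0.0], np.cumsum(chords)])
    params /= params[-1]
    params[-1] = 1.0
    return params


def knots_from_params(params: np.ndarray, degree: int, n_ctrl: int) -> np.ndarray:
    """Clamped knot vector adapted to a parameter distribution.

    For interpolation (``n_ctrl == len(params)``) interior knots are the
    running means of ``degree`` consecutive parameters (knot averaging). For
    approximation (``n_ctrl < len(params)``) interior knots are placed by the
    standard parameter-density rule so every knot span contains at least one
    parameter.
    """
    params = np.asarray(params, dtype=float)
    p = degree
    npts = len(params)
    if n_ctrl < p + 1:
        raise ValueError(f"n_ctrl={n_ctrl} must be at least degree + 1 = {p + 1}")
    if n_ctrl > npts:
        raise ValueError(f"n_ctrl={n_ctrl} exceeds number of parameters {npts}")
    n = n_ctrl - 1
    interior = np.empty(n - p)
    if n_ctrl == npts:
        for j in range(1, n - p + 1):
            interior[j - 1] = params[j:j + p].mean()
    else:
        m = npts - 1
        d = (m + 1) / (n - p + 1)
        for j in range(1, n - p + 1):
            i = int(np.floor(j * d))
            alpha = j * d - i
            interior[j - 1] = (1.0 - alpha) * params[i - 1] + alpha * params[i]
    return np.concatenate([np.zeros(p + 1), interior, np.ones(p + 1)])


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BSplineCurve:
    """A clamped B-spline (or rational, if weighted) curve on [0, 1]."""

    degree: int
    knots: np.ndarray
    control_points: np.ndarray          # (n_ctrl, 3)
    weights: np.ndarray | None = None   # (n_ctrl,), all > 0, None => B-spline

    def __post_init__(self):
        ctrl = np.asarray(self.control_points, dtype=float)
        object.__setattr__(self, "control_points", ctrl)
        object.__setattr__(
            self, "knots", validate_knots(self.knots, self.degree, len(ctrl))
        )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(ctrl),) or np.any(w <= 0):
                raise ValueError("weights must be positive, one per control point")
            object.__setattr__(self, "weights", w)

    @property
    def n_ctrl(self) -> int:
        return len(self.control_points)

    def evaluate(self, u) -> np.ndarray:
        """Curve point(s) at parameter(s) ``u``; shape (3,) or (len(u), 3)."""
        scalar = np.isscalar(u)
        B = basis_matrix(self.knots, self.degree, self.n_ctrl, u)
        if self.weights is None:
            pts = B @ self.control_points
        else:
            num = B @ (self.control_points * self.weights[:, None])
            den = B @ self.weights
            pts = num / den[:, None]
        return pts[0] if scalar else pts


def fit_curve_interpolate(points: np.ndarray, degree: int,
                          params: np.ndarray | None = None,
                          method: str = "chord_length") -> BSplineCurve:
    """Global curve interpolation: the curve passes through every point.

    Solves the square collocation system built from averaged knots; a
    singular system (e.g. repeated parameters from a pathological
    configuration) raises ``ValueError``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < degree + 1:
        raise ValueError("need at least degree + 1 points to interpolate")
    if params is None:
        params = parameterize(points, method)
    knots = knots_from_params(params, degree, n)
    B = basis_matrix(knots, degree, n, params)
    try:
        ctrl = scipy.linalg.solve(B, points)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "singular collocation system: repeated or degenerate parameters"
        ) from exc
    return BSplineCurve(degree, knots, ctrl)


def _collapsed_curve(point: np.ndarray, degree: int, n_ctrl: int) -> BSplineCurve:
    """All control points coincident: the constant 'curve' at ``point``."""
    knots = np.concatenate([
        np.zeros(degree + 1),
        np.linspace(0.0, 1.0, n_ctrl - degree + 1)[1:-1],
        np.ones(degree + 1),
    ])
    ctrl = np.tile(np.asarray(point, dtype=float), (n_ctrl, 1))
    return BSplineCurve(degree, knots, ctrl)


def fit_curve_approximate(points: np.ndarray, degree: int, n_ctrl: int,
                          params: np.ndarray | None = None,
                          method: str = "chord_length",
                          knots: np.ndarray | None = None) -> BSplineCurve:
    """Least-squares curve approximation with interpolated endpoints.

    The first/last control points equal the first/last data points; interior
    control points minimize the sum of squared residuals at the data
    parameters (global minimum of the linear least-squares problem). With
    ``n_ctrl == len(points)`` this reduces to interpolation. A run of
    coincident points collapses to a constant curve.
    """
    points = np.asarray(points, dtype=float)
    m = len(points) - 1
    if not (degree + 1 <= n_ctrl <= m + 1):
        raise ValueError(
            f"need degree + 1 <= n_ctrl <= #points ({degree + 1} <= {n_ctrl} <= {m + 1})"
        )
    if np.allclose(points, points[0], atol=1e-12):
        return _collapsed_curve(points[0], degree, n_ctrl)
    if params is None:
        params = parameterize(points, method)
    if n_ctrl == m + 1:
        return fit_curve_interpolate(points, degree, params=params)
    if knots is None:
        knots = knots_from_params(params, degree, n_ctrl)
    else:
        knots = validate_knots(knots, degree, n_ctrl)
    n = n_ctrl - 1
    B = basis_matrix(knots, degree, n_ctrl, params)
    # endpoint-constrained least squares: P_0 = Q_0, P_n = Q_m
    rhs = points[1:m] - np.outer(B[1:m, 0], points[0]) - np.outer(B[1:m, n], points[m])
    design = B[1:m, 1:n]
    sol, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < n - 1:
        raise ValueError(
            "rank-deficient approximation design: too few distinct parameters "
            "for the requested number of control points"
        )
    ctrl = np.vstack([points[0], sol, points[m]])
    return BSplineCurve(degree, knots, ctrl)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

@dataclass
class NurbsSurface:
    """A clamped tensor-product NURBS surface on [0, 1] x [0, 1].

    With all weights equal to 1 the surface is an ordinary B-spline surface;
    :meth:`is_bspline` reports that case. ``control_net`` has shape
    (n_ctrl_u, n_ctrl_v, 3) and ``weights`` (n_ctrl_u, n_ctrl_v).
    """

    degree_u: int
    degree_v: int
    knots_u: np.ndarray
    knots_v: np.ndarray
    control_net: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.control_net = np.asarray(self.control_net, dtype=float)
        if self.control_net.ndim != 3 or self.control_net.shape[2] != 3:
            raise ValueError("control_net must have shape (n_ctrl_u, n_ctrl_v, 3)")
        nu, nv, _ = self.control_net.shape
        self.knots_u = validate_knots(self.knots_u, self.degree_u, nu)
        self.knots_v = validate_knots(self.knots_v, self.degree_v, nv)
        if self.weights is None:
            self.weights = np.ones((nu, nv))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (nu, nv):
                raise ValueError("weights shape must match the control net")
            if np.any(self.weights <= 0):
                raise ValueError("all weights must be positive")

    @property
    def n_ctrl_u(self) -> int:
        return self.control_net.shape[0]

    @property
    def n_ctrl_v(self) -> int:
        return self.control_net.shape[1]

    def is_bspline(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.weights - 1.0) <= tol))

    def with_weights(self, weights: np.ndarray) -> "NurbsSurface":
        """Copy of this surface with a new weight matrix."""
        return NurbsSurface(self.degree_u, self.degree_v, self.knots_u.copy(),
                            self.knots_v.copy(), self.control_net.copy(),
                            np.asarray(weights, dtype=float).reshape(self.weights.shape).copy())

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, u: float, v: float) -> np.ndarray:
        """Surface point S(u, v); rational tensor-product blend."""
        return self.evaluate_many(np.array([u]), np.array([v]))[0]

    def evaluate_many(self, u, v) -> np.ndarray:
        """Pointwise evaluation at paired parameter arrays; shape (n, 3)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        Bu = basis_matrix(self.knots_u, self.degree_u, self.n_ctrl_u, u)
        Bv = basis_matrix(self.knots_v, self.degree_v, self.n_ctrl_v, v)
        wP = self.control_net * self.weights[:, :, None]
        num = np.einsum("ti,tj,ijc->tc", Bu, Bv, wP)
        den = np.einsum("ti,tj,ij->t", Bu, Bv, self.weights)
        return num / den[:, None]

    def evaluate_grid(self, us, vs) -> np.ndarray:
        """Evaluate on the tensor grid ``us x vs``; shape (len(us), len(vs), 3)."""
        us = np.atleast_1d(np.asarray(us, dtype=float))
        vs = np.atleast_1d(np.asarray(vs, dtype=float))
        Bu = basis_matrix(self.knots_u, self.degree_u, self.n_ctrl_u, us)
        Bv = basis_matrix(self.knots_v, self.degree_v, self.n_ctrl_v, vs)
        wP = self.control_net * self.weights[:, :, None]
        num = np.einsum("ai,bj,ijc->abc", Bu, Bv, wP)
        den = np.einsum("ai,bj,ij->ab", Bu, Bv, self.weights)
        return num / den[:, :, None]

    def derivatives(self, u: float, v: float, order: int = 2) -> dict[str, np.ndarray]:
        """Surface point and partial derivatives at (u, v).

        Returns a dict with keys ``S, Su, Sv`` and, for ``order >= 2``,
        ``Suu, Suv, Svv``. Rational derivatives follow from the quotient rule
        applied to the homogeneous numerator and the weight function.
        """
        u = float(np.clip(u, 0.0, 1.0))
        v = float(np.clip(v, 0.0, 1.0))
        p, q = self.degree_u, self.degree_v
        su = int(find_span(self.knots_u, p, self.n_ctrl_u, np.array([u]))[0])
        sv = int(find_span(self.knots_v, q, self.n_ctrl_v, np.array([v]))[0])
        du = ders_basis_functions(self.knots_u, p, su, u, order)
        dv = ders_basis_functions(self.knots_v, q, sv, v, order)
        iu = slice(su - p, su + 1)
        iv = slice(sv - q, sv + 1)
        W = self.weights[iu, iv]
        P = self.control_net[iu, iv]
        wP = W[:, :, None] * P

        def A(k, l):
            return np.einsum("i,j,ijc->c", du[k], dv[l], wP)

        def w(k, l):
            return float(np.einsum("i,j,ij->", du[k], dv[l], W))

        w00 = w(0, 0)
        S = A(0, 0) / w00
        out = {"S": S}
        Su = (A(1, 0) - w(1, 0) * S) / w00
        Sv = (A(0, 1) - w(0, 1) * S) / w00
        out["Su"], out["Sv"] = Su, Sv
        if order >= 2:
            out["Suu"] = (A(2, 0) - 2.0 * w(1, 0) * Su - w(2, 0) * S) / w00
            out["Svv"] = (A(0, 2) - 2.0 * w(0, 1) * Sv - w(0, 2) * S) / w00
            out["Suv"] = (A(1, 1) - w(1, 0) * Sv - w(0, 1) * Su - w(1, 1) * S) / w00
        return out

    def derivatives_many(self, u, v, order: int = 2) -> dict[str, np.ndarray]:
        """Batched version of :meth:`derivatives`; each value has shape (n, 3)."""
        u = np.clip(np.atleast_1d(np.asarray(u, dtype=float)), 0.0, 1.0)
        v = np.clip(np.atleast_1d(np.asarray(v, dtype=float)), 0.0, 1.0)
        Du = basis_ders_matrix(self.knots_u, self.degree_u, u, order)
        Dv = basis_ders_matrix(self.knots_v, self.degree_v, v, order)
        wP = self.control_net * self.weights[:, :, None]

        def A(k, l):
            return np.einsum("ti,tj,ijc->tc", Du[k], Dv[l], wP)

        def w(k, l):
            return np.einsum("ti,tj,ij->t", Du[k], Dv[l], self.weights)[:, None]

        w00 = w(0, 0)
        S = A(0, 0) / w00
        Su = (A(1, 0) - w(1, 0) * S) / w00
        Sv = (A(0, 1) - w(0, 1) * S) / w00
        out = {"S": S, "Su": Su, "Sv": Sv}
        if order >= 2:
            out["Suu"] = (A(2, 0) - 2.0 * w(1, 0) * Su - w(2, 0) * S) / w00
            out["Svv"] = (A(0, 2) - 2.0 * w(0, 1) * Sv - w(0, 2) * S) / w00
            out["Suv"] = (A(1, 1) - w(1, 0) * Sv - w(0, 1) * Su - w(1, 1) * S) / w00
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "degrees": [self.degree_u, self.degree_v],
            "knots_u": self.knots_u.tolist(),
            "knots_v": self.knots_v.tolist(),
            "control_net": self.control_net.tolist(),   # row-major, u-index major
            "weights": self.weights.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NurbsSurface":
        return cls(
            degree_u=int(d["degrees"][0]),
            degree_v=int(d["degrees"][1]),
            knots_u=np.asarray(d["knots_u"], dtype=float),
            knots_v=np.asarray(d["knots_v"], dtype=float),
            control_net=np.asarray(d["control_net"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "NurbsSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def sample_mesh(self, n_u: int = 50, n_v: int = 50):
        """Triangulated sample of the surface as (vertices, faces) arrays."""
        us = np.linspace(0.0, 1.0, n_u)
        vs = np.linspace(0.0, 1.0, n_v)
        verts = self.evaluate_grid(us, vs).reshape(-1, 3)
        faces = []
        for a in range(n_u - 1):
            for b in range(n_v - 1):
                i0 = a * n_v + b
                faces.append([i0, i0 + n_v, i0 + n_v + 1])
                faces.append([i0, i0 + n_v + 1, i0 + 1])
        return verts, np.asarray(faces, dtype=int)
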