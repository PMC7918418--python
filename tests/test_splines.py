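"""Spline primitives against independent oracles and textbook identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline

import leafsurf as ls
from leafsurf.splines import (DegenerateChordWarning, basis_ders_matrix,
                              basis_matrix, validate_knots)


def naive_basis(i, p, u, U):
    """Literal Cox-de Boor recursion, memoization-free, 0/0 := 0.

    The right endpoint closes the final span so N_{n,p}(1) = 1.
    """
    if p == 0:
        if U[i] <= u < U[i + 1]:
            return 1.0
        if u == U[-1] and U[i] < U[i + 1] == u:
            return 1.0
        return 0.0
    a = 0.0 if U[i + p] == U[i] else (u - U[i]) / (U[i + p] - U[i]) * naive_basis(i, p - 1, u, U)
    b = 0.0 if U[i + p + 1] == U[i + 1] else (U[i + p + 1] - u) / (U[i + p + 1] - U[i + 1]) * naive_basis(i + 1, p - 1, u, U)
    return a + b


KNOT_CASES = [
    (2, np.array([0, 0, 0, 0.5, 1, 1, 1.0])),
    (2, np.array([0, 0, 0, 0.25, 0.6, 1, 1, 1.0])),
    (3, np.array([0, 0, 0, 0, 0.3, 0.3, 0.7, 1, 1, 1, 1.0])),
    (1, np.array([0, 0, 0.2, 0.9, 1, 1.0])),
]


class TestBasisFunctions:
    @pytest.mark.parametrize("p,U", KNOT_CASES)
    def test_matches_literal_recursion(self, p, U, rng):
        n = len(U) - p - 1
        for u in np.concatenate([rng.uniform(0, 1, 30), [0.0, 0.25, 0.5, 1.0]]):
            for i in range(n):
                assert ls.basis_function(i, p, float(u), U) == pytest.approx(
                    naive_basis(i, p, float(u), U), abs=1e-12)

    def test_degree_zero_indicator(self):
        U = np.array([0, 0, 0.4, 1, 1.0])
        assert ls.basis_function(1, 0, 0.2, U) == 1.0
        assert ls.basis_function(1, 0, 0.6, U) == 0.0

    @pytest.mark.parametrize("p,U", KNOT_CASES)
    def test_partition_of_unity(self, p, U, rng):
        n = len(U) - p - 1
        u = rng.uniform(0, 1, 2000)
        B = basis_matrix(U, p, n, u)
        assert np.abs(B.sum(axis=1) - 1.0).max() < 1e-12

    def test_right_endpoint_closure(self):
        p, U = KNOT_CASES[0]
        vals = [ls.basis_function(i, p, 1.0, U) for i in range(4)]
        assert vals == [0.0, 0.0, 0.0, 1.0]

    def test_scipy_cross_check(self, rng):
        p, U = 2, np.array([0, 0, 0, 0.2, 0.5, 0.8, 1, 1, 1.0])
        n = len(U) - p - 1
        u = rng.uniform(0, 0.999, 200)
        B = basis_matrix(U, p, n, u)
        for i in range(n):
            c = np.zeros(n)
            c[i] = 1.0
            assert np.abs(BSpline(U, c, p)(u) - B[:, i]).max() < 1e-12

    def test_derivative_matrices_match_scipy(self, rng):
        p, U = 2, np.array([0, 0, 0, 0.3, 0.6, 1, 1, 1.0])
        n = len(U) - p - 1
        u = rng.uniform(0.001, 0.999, 100)
        D = basis_ders_matrix(U, p, u, 2)
        for i in range(n):
            c = np.zeros(n)
            c[i] = 1.0
            sp = BSpline(U, c, p)
            assert np.abs(sp(u) - D[0][:, i]).max() < 1e-12
            assert np.abs(sp.derivative()(u) - D[1][:, i]).max() < 1e-10
            assert np.abs(sp.derivative(2)(u) - D[2][:, i]).max() < 1e-10

    def test_index_out_of_range(self):
        p, U = KNOT_CASES[0]
        with pytest.raises(ValueError):
            ls.basis_function(4, p, 0.5, U)
        with pytest.raises(ValueError):
            ls.basis_function(-1, p, 0.5, U)


class TestParameterize:
    def test_equally_spaced(self):
        pts = np.zeros((5, 3))
        pts[:, 0] = [0, 1, 5, 6, 9]
        assert np.allclose(ls.parameterize(pts, "equally_spaced"),
                           [0, 0.25, 0.5, 0.75, 1])

    def test_chord_length_fractions(self):
        pts = np.zeros((4, 3))
        pts[:, 0] = [0, 1, 2, 4]  # chords 1, 1, 2
        assert np.allclose(ls.parameterize(pts, "chord_length"),
                           [0, 0.25, 0.5, 1.0])

    def test_centripetal_sqrt_fractions(self):
        pts = np.zeros((4, 3))
        pts[:, 0] = [0, 1, 2, 4]
        s = np.sqrt([1.0, 1.0, 2.0])
        expect = np.concatenate([[0], np.cumsum(s)]) / s.sum()
        assert np.allclose(ls.parameterize(pts, "centripetal"), expect)

    def test_zero_chord_falls_back_with_warning(self):
        pts = np.zeros((4, 3))
        pts[:, 0] = [0, 1, 1, 2]
        with pytest.warns(DegenerateChordWarning):
            params = ls.parameterize(pts, "chord_length")
        assert params[0] == 0 and params[-1] == 1
        assert np.all(np.diff(params) > 0)

    @given(st.integers(3, 20), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_unit_interval(self, npts, seed):
        pts = np.random.default_rng(seed).normal(size=(npts, 3)).cumsum(axis=0)
        for method in ("equally_spaced", "chord_length", "centripetal"):
            params = ls.parameterize(pts, method)
            assert params[0] == 0.0 and params[-1] == 1.0
            assert np.all(np.diff(params) > 0)


class TestKnotPlacement:
    def test_interpolation_averaging_hand_check(self):
        params = np.array([0, 0.25, 0.5, 0.75, 1.0])
        knots = ls.knots_from_params(params, 2, 5)
        # interior knots are means of consecutive parameter pairs
        assert np.allclose(knots, [0, 0, 0, 0.375, 0.625, 1, 1, 1])

    def test_bezier_case_no_interior(self):
        knots = ls.knots_from_params(np.linspace(0, 1, 8), 3, 4)
        assert np.allclose(knots, [0, 0, 0, 0, 1, 1, 1, 1])

    def test_uniform_params_give_uniform_interior(self):
        knots = ls.knots_from_params(np.linspace(0, 1, 9), 2, 9)
        interior = knots[3:-3]
        assert np.allclose(np.diff(interior), np.diff(interior)[0])

    def test_infeasible_counts_raise(self):
        with pytest.raises(ValueError):
            ls.knots_from_params(np.linspace(0, 1, 4), 2, 5)
        with pytest.raises(ValueError):
            ls.knots_from_params(np.linspace(0, 1, 4), 3, 3)

    @given(st.integers(5, 25), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_valid_clamped_for_any_params(self, npts, seed):
        r = np.random.default_rng(seed)
        params = np.sort(np.concatenate([[0.0], r.uniform(0.01, 0.99, npts - 2), [1.0]]))
        for n_ctrl in (3, 4, npts):
            knots = ls.knots_from_params(params, 2, n_ctrl)
            validate_knots(knots, 2, n_ctrl)


class TestCurveFitting:
    def test_interpolation_passes_through_points(self, rng):
        pts = rng.normal(size=(7, 3)).cumsum(axis=0)
        curve = ls.fit_curve_interpolate(pts, 2)
        assert curve.n_ctrl == 7
        params = ls.parameterize(pts)
        assert np.abs(curve.evaluate(params) - pts).max() < 1e-9 * max(
            1.0, np.abs(pts).max())

    def test_linear_precision(self):
        t = np.linspace(0, 1, 9)[:, None]
        pts = t * np.array([3.0, -1.0, 2.0])
        curve = ls.fit_curve_interpolate(pts, 2)
        samples = curve.evaluate(np.linspace(0, 1, 50))
        d = np.array([3.0, -1.0, 2.0])
        d /= np.linalg.norm(d)
        off = samples - samples @ d[:, None] * d
        assert np.abs(off).max() < 1e-9

    def test_approximation_equals_interpolation_at_full_count(self, rng):
        pts = rng.normal(size=(6, 3)).cumsum(axis=0)
        ci = ls.fit_curve_interpolate(pts, 2)
        ca = ls.fit_curve_approximate(pts, 2, 6)
        assert np.allclose(ci.control_points, ca.control_points, atol=1e-9)

    def test_residual_matches_normal_equations_oracle(self, rng):
        pts = rng.normal(size=(15, 3)).cumsum(axis=0)
        n_ctrl, p = 6, 2
        curve = ls.fit_curve_approximate(pts, p, n_ctrl)
        params = ls.parameterize(pts)
        B = basis_matrix(curve.knots, p, n_ctrl, params)
        # independent endpoint-constrained normal-equations solve
        m, n = len(pts) - 1, n_ctrl - 1
        N = B[1:m, 1:n]
        R = pts[1:m] - np.outer(B[1:m, 0], pts[0]) - np.outer(B[1:m, n], pts[m])
        interior = np.linalg.solve(N.T @ N, N.T @ R)
        ctrl = np.vstack([pts[0], interior, pts[m]])
        rss_oracle = np.sum((B @ ctrl - pts) ** 2)
        rss = np.sum((B @ curve.control_points - pts) ** 2)
        assert rss == pytest.approx(rss_oracle, rel=1e-8)

    def test_endpoints_interpolated_in_approximation(self, rng):
        pts = rng.normal(size=(12, 3)).cumsum(axis=0)
        curve = ls.fit_curve_approximate(pts, 2, 5)
        assert curve.n_ctrl == 5
        assert np.allclose(curve.evaluate(0.0), pts[0])
        assert np.allclose(curve.evaluate(1.0), pts[-1])

    def test_collapsed_points_give_constant_curve(self):
        pts = np.tile([1.0, 2.0, 3.0], (8, 1))
        curve = ls.fit_curve_approximate(pts, 2, 4)
        assert np.allclose(curve.evaluate(np.linspace(0, 1, 11)), pts[0])

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            ls.fit_curve_approximate(np.zeros((3, 3)), 2, 5)


class TestSurfaceEvaluation:
    def test_matches_naive_rational_double_sum(self, rng, random_surface_factory):
        S = random_surface_factory(rng, n_u=3, n_v=3, degree=2)

        def naive(u, v):
            num = np.zeros(3)
            den = 0.0
            for i in range(S.n_ctrl_u):
                for j in range(S.n_ctrl_v):
                    w = (naive_basis(i, S.degree_u, u, S.knots_u)
                         * naive_basis(j, S.degree_v, v, S.knots_v)
                         * S.weights[i, j])
                    num += w * S.control_net[i, j]
                    den += w
            return num / den

        for u, v in [(0.3, 0.7), (0.0, 0.0), (1.0, 1.0), (0.5, 0.123)]:
            assert np.abs(S.evaluate(u, v) - naive(u, v)).max() < 1e-12

    def test_unit_weights_reduce_to_bspline(self, rng, random_surface_factory):
        S = random_surface_factory(rng, rational=True)
        B = S.with_weights(np.ones_like(S.weights))
        uv = np.random.default_rng(3).uniform(0, 1, (200, 2))
        Bu = basis_matrix(B.knots_u, B.degree_u, B.n_ctrl_u, uv[:, 0])
        Bv = basis_matrix(B.knots_v, B.degree_v, B.n_ctrl_v, uv[:, 1])
        direct = np.einsum("ti,tj,ijc->tc", Bu, Bv, B.control_net)
        assert np.abs(B.evaluate_many(uv[:, 0], uv[:, 1]) - direct).max() < 1e-12

    def test_corner_equals_corner_control_point(self, rng, random_surface_factory):
        S = random_surface_factory(rng)
        assert np.allclose(S.evaluate(0.0, 0.0), S.control_net[0, 0])
        assert np.allclose(S.evaluate(1.0, 1.0), S.control_net[-1, -1])

    def test_grid_evaluation_matches_pointwise(self, rng, random_surface_factory):
        S = random_surface_factory(rng)
        us = np.linspace(0, 1, 7)
        vs = np.linspace(0, 1, 9)
        grid = S.evaluate_grid(us, vs)
        for a in (0, 3, 6):
            for b in (0, 4, 8):
                assert np.allclose(grid[a, b], S.evaluate(us[a], vs[b]))

    def test_scalar_derivatives_match_batched(self, rng, random_surface_factory):
        S = random_surface_factory(rng)
        for u, v in [(0.2, 0.8), (0.5, 0.5), (0.9, 0.1)]:
            d1 = S.derivatives(u, v, 2)
            d2 = S.derivatives_many([u], [v], 2)
            for key in d1:
                assert np.abs(d1[key] - d2[key][0]).max() < 1e-10

    def test_invalid_weights_rejected(self, rng, random_surface_factory):
        S = random_surface_factory(rng)
        with pytest.raises(ValueError):
            S.with_weights(np.zeros_like(S.weights))


class TestSerialization:
    def test_json_round_trip(self, rng, random_surface_factory, tmp_path):
        S = random_surface_factory(rng)
        path = tmp_path / "surface.json"
        S.to_json(path)
        T = ls.NurbsSurface.from_json(path)
        uv = np.random.default_rng(1).uniform(0, 1, (50, 2))
        assert np.allclose(S.evaluate_many(uv[:, 0], uv[:, 1]),
                           T.evaluate_many(uv[:, 0], uv[:, 1]))

    def test_sample_mesh_shapes(self, rng, random_surface_factory):
        S = random_surface_factory(rng)
        verts, faces = S.sample_mesh(10, 12)
        assert verts.shape == (120, 3)
        assert faces.shape == (2 * 9 * 11, 3)
        assert faces.max() < len(verts)
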