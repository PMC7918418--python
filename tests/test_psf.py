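"""PSF construction: ordered grids, unordered columns, evaluation subset."""

import numpy as np
import pytest

import leafsurf as ls


@pytest.fixture(scope="module")
def selected(clean_slpc):
    slices = ls.slice_cloud(clean_slpc, 50)
    return ls.select_slices(slices, 7)


class TestInteriorFeaturePoints:
    def test_triple_lies_in_center_band(self, selected):
        for slc in selected[1:-1]:
            triple = ls.interior_feature_points(slc)
            for p in (triple.left, triple.mid, triple.right):
                assert abs(p[0] - slc.plane_x) <= slc.thickness / 4 + 1e-12

    def test_mid_is_ridge_and_edges_are_extremes(self, selected):
        slc = selected[3]
        triple = ls.interior_feature_points(slc)
        band = slc.points[np.abs(slc.points[:, 0] - slc.plane_x)
                          <= slc.thickness / 4]
        assert triple.left[1] == band[:, 1].min()
        assert triple.right[1] == band[:, 1].max()
        assert triple.mid[2] == band[:, 2].max()

    def test_symmetric_slice_edges_balanced(self, selected):
        slc = selected[3]
        triple = ls.interior_feature_points(slc)
        assert abs(triple.left[1] + triple.right[1]) < 0.15 * abs(triple.right[1] - triple.left[1])

    def test_sparse_band_widens_with_warning(self, clean_slpc):
        from leafsurf.slicing import Slice
        pts = np.array([[0.0, -3, 0], [0.9, 0, 1], [0.95, 3, 0]])
        slc = Slice(index=1, x_lo=0, x_hi=1, plane_x=0.5, points=pts, thickness=1.0)
        with pytest.warns(UserWarning):
            triple = ls.interior_feature_points(slc)
        assert triple.left[1] == -3 and triple.right[1] == 3


class TestOrderedColumn:
    def test_seven_points_for_tl_tr_two(self, selected):
        slc = selected[2]
        triple = ls.interior_feature_points(slc)
        col = ls.ordered_column(slc, triple, 2, 2)
        assert col.shape == (7, 3)

    def test_interior_members_are_nearest_slice_points(self, selected):
        slc = selected[2]
        triple = ls.interior_feature_points(slc)
        col = ls.ordered_column(slc, triple, 2, 2)
        seeds = np.vstack([
            triple.left,
            np.linspace(triple.left, triple.mid, 4)[1:-1],
            triple.mid,
            np.linspace(triple.mid, triple.right, 4)[1:-1],
            triple.right,
        ])
        for i in (1, 2, 4, 5):  # filler positions
            d = np.linalg.norm(slc.points - seeds[i], axis=1)
            assert np.linalg.norm(col[i] - seeds[i]) == pytest.approx(d.min())

    def test_y_coordinates_non_decreasing_on_convex_slice(self, selected):
        for slc in selected[1:-1]:
            triple = ls.interior_feature_points(slc)
            col = ls.ordered_column(slc, triple, 2, 2)
            assert np.all(np.diff(col[:, 1]) >= -1e-6)


class TestBuildOrderedPSF:
    def test_case_study_counts_seven_by_seven(self, clean_slpc, selected):
        psf = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        assert psf.grid.shape == (7, 7, 3)
        assert psf.size == 49
        assert psf.n_cols == len(selected)

    def test_first_column_at_min_x_and_collinear(self, clean_slpc, selected):
        psf = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        x_min = clean_slpc.points[:, 0].min()
        col0 = psf.grid[:, 0]
        assert np.allclose(col0[:, 0], x_min)
        # base column is seeded on the straight left-mid-right segment
        chords = np.diff(col0[:, 1])
        assert np.all(chords > 0)

    def test_last_column_repeats_tip_point(self, clean_slpc, selected):
        psf = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        tip = ls.tip_feature_point(clean_slpc).mid
        assert np.allclose(psf.grid[:, -1], tip)

    def test_grid_points_from_interior_columns_belong_to_cloud(
            self, clean_slpc, selected):
        psf = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        cloud = clean_slpc.points
        for j in range(1, psf.n_cols - 1):
            for i in (1, 2, 4, 5):
                d = np.linalg.norm(cloud - psf.grid[i, j], axis=1).min()
                assert d < 1e-9


class TestBuildUnorderedPSF:
    def test_interior_columns_on_projection_planes(self, clean_slpc, selected):
        psf = ls.build_unordered_psf(clean_slpc, selected, 2, 2)
        for slc, col in zip(selected[1:-1], psf.columns()[1:-1]):
            assert np.allclose(col[:, 0], slc.plane_x)
            assert len(col) == len(slc.points)
            assert np.all(np.diff(col[:, 1]) >= 0)  # sorted left to right

    def test_projection_preserves_y_and_z(self, clean_slpc, selected):
        psf = ls.build_unordered_psf(clean_slpc, selected, 2, 2)
        for slc, col in zip(selected[1:-1], psf.columns()[1:-1]):
            src = slc.points[np.argsort(slc.points[:, 1], kind="stable")]
            assert np.allclose(col[:, 1:], src[:, 1:])

    def test_total_size_matches_memberships(self, clean_slpc, selected):
        psf = ls.build_unordered_psf(clean_slpc, selected, 2, 2)
        interior = sum(len(s.points) for s in selected[1:-1])
        assert psf.size == interior + 2 * 7

    def test_boundary_columns_match_ordered_construction(
            self, clean_slpc, selected):
        ordered = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        unordered = ls.build_unordered_psf(clean_slpc, selected, 2, 2)
        assert np.allclose(unordered.columns()[0], ordered.grid[:, 0])
        assert np.allclose(unordered.columns()[-1], ordered.grid[:, -1])


class TestBuildTestSubset:
    def test_ninety_points_under_reference_settings(self, clean_slpc):
        subset = ls.build_test_subset(clean_slpc, 10, 9)
        assert subset.grid.shape == (9, 10, 3)
        assert subset.size == 90

    def test_deterministic_given_slpc(self, clean_slpc):
        a = ls.build_test_subset(clean_slpc)
        b = ls.build_test_subset(clean_slpc)
        assert np.array_equal(a.grid, b.grid)

    def test_interior_points_belong_to_cloud(self, clean_slpc):
        subset = ls.build_test_subset(clean_slpc)
        cloud = clean_slpc.points
        for j in range(1, subset.n_cols - 1):
            for i in (1, 2, 3, 5, 6, 7):
                d = np.linalg.norm(cloud - subset.grid[i, j], axis=1).min()
                assert d < 1e-9

    def test_invalid_per_slice_raises(self, clean_slpc):
        with pytest.raises(ValueError):
            ls.build_test_subset(clean_slpc, 10, 8)


class TestPSFTables:
    def test_frame_round_trip_ordered(self, clean_slpc, selected):
        from leafsurf.psf import psf_from_frame, psf_to_frame
        psf = ls.build_ordered_psf(clean_slpc, selected, 2, 2)
        back = psf_from_frame(psf_to_frame(psf))
        assert isinstance(back, ls.OrderedPSF)
        assert np.allclose(back.grid, psf.grid)

    def test_frame_round_trip_unordered(self, clean_slpc, selected):
        from leafsurf.psf import psf_from_frame, psf_to_frame
        psf = ls.build_unordered_psf(clean_slpc, selected, 2, 2)
        back = psf_from_frame(psf_to_frame(psf))
        assert isinstance(back, ls.UnorderedPSF)
        for a, b in zip(back.columns(), psf.columns()):
            assert np.allclose(a, b)
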