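"""Construction of the point set to be fitted (PSF) from selected slices.

Two constructions are supported. The *ordered* PSF extracts the same number
of points, k + 1 = 3 + tl + tr, from every selected slice: the slice's
feature triple (left edge, midrib ridge, right edge) plus the nearest slice
points to tl seeds equally spaced between left and midrib and tr seeds
between midrib and right. The *unordered* PSF instead projects every point
of a selected slice onto the slice's center plane (x := plane x), so column
sizes vary with local point density.

Both constructions share the boundary columns: the base column is built
directly from the base feature triple and its in-segment seeds (all at
x = min(x)), and the tip column repeats the tip point 3 + tl + tr times.
The same machinery builds the evaluation test subset (a small ordered PSF
with its own slicing) used for error metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pose import SLPC
from .slicing import (FeatureTriple, Slice, base_feature_points, slice_cloud,
                      select_slices, tip_feature_point)


@dataclass
class OrderedPSF:
    """A full (k+1) x (l+1) grid; ``grid[i, j]`` = i-th point of column j."""

    grid: np.ndarray  # (k+1, l+1, 3)

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def size(self) -> int:
        return self.n_rows * self.n_cols

    def columns(self) -> list[np.ndarray]:
        return [self.grid[:, j] for j in range(self.n_cols)]

    def flat_points(self) -> np.ndarray:
        return self.grid.reshape(-1, 3)


@dataclass
class UnorderedPSF:
    """l + 1 columns of possibly unequal length, ordered base to tip."""

    columns_: list[np.ndarray]

    @property
    def n_cols(self) -> int:
        return len(self.columns_)

    @property
    def size(self) -> int:
        return sum(len(c) for c in self.columns_)

    def columns(self) -> list[np.ndarray]:
        return list(self.columns_)

    def flat_points(self) -> np.ndarray:
        return np.vstack(self.columns_)


def interior_feature_points(slc: Slice) -> FeatureTriple:
    """Feature triple of an interior slice.

    The leftmost (min y), highest (max z) and rightmost (max y) points are
    taken inside the center band T of the slice, of thickness Ws / 2 around
    the projection plane. If T holds fewer than 3 points the band widens to
    the whole slice with a warning.
    """
    pts = slc.points
    if len(pts) == 0:
        raise ValueError(f"slice {slc.index} is empty")
    band = pts[np.abs(pts[:, 0] - slc.plane_x) <= slc.thickness / 4.0]
    if len(band) < 3:
        warnings.warn(
            f"slice {slc.index}: fewer than 3 points in center band; using full slice"
        )
        band = pts
    left = band[np.argmin(band[:, 1])]
    mid = band[np.argmax(band[:, 2])]
    right = band[np.argmax(band[:, 1])]
    return FeatureTriple(left=left.copy(), mid=mid.copy(), right=right.copy())


def _segment_seeds(triple: FeatureTriple, tl: int, tr: int) -> np.ndarray:
    """3 + tl + tr seed points: feature points plus equally spaced fillers.

    Fillers lie on the straight 3D segments left->mid and mid->right.
    """
    if tl < 1 or tr < 1:
        raise ValueError("tl and tr must be at least 1")
    left_fill = np.linspace(triple.left, triple.mid, tl + 2)[1:-1]
    right_fill = np.linspace(triple.mid, triple.right, tr + 2)[1:-1]
    return np.vstack([triple.left, left_fill, triple.mid, right_fill, triple.right])


def ordered_column(slc: Slice, triple: FeatureTriple, tl: int, tr: int) -> np.ndarray:
    """The k + 1 = 3 + tl + tr ordered points of one interior slice.

    The three feature points enter directly; each filler seed is replaced by
    its Euclidean-nearest point in the slice. Duplicate nearest points are
    kept (the fit tolerates repeated data points).
    """
    seeds = _segment_seeds(triple, tl, tr)
    column = seeds.copy()
    fill_idx = [i for i in range(len(seeds)) if i not in (0, tl + 1, len(seeds) - 1)]
    pts = slc.points
    for i in fill_idx:
        d2 = np.einsum("ij,ij->i", pts - seeds[i], pts - seeds[i])
        column[i] = pts[np.argmin(d2)]
    return column


def _base_column(slpc: SLPC, tl: int, tr: int) -> np.ndarray:
    # base feature points and their seeds are used directly (they are derived
    # points at x = min(x), not members of the cloud)
    return _segment_seeds(base_feature_points(slpc), tl, tr)


def _tip_column(slpc: SLPC, tl: int, tr: int) -> np.ndarray:
    tip = tip_feature_point(slpc).mid
    return np.tile(tip, (3 + tl + tr, 1))


def build_ordered_psf(slpc: SLPC, selected: list[Slice], tl: int = 2,
                      tr: int = 2) -> OrderedPSF:
    """Ordered PSF over the selected slices (which include base and tip)."""
    cols = []
    for slc in selected:
        if slc.index == 0:
            cols.append(_base_column(slpc, tl, tr))
        elif slc.thickness == 0.0:
            cols.append(_tip_column(slpc, tl, tr))
        else:
            cols.append(ordered_column(slc, interior_feature_points(slc), tl, tr))
    return OrderedPSF(grid=np.stack(cols, axis=1))


def build_unordered_psf(slpc: SLPC, selected: list[Slice], tl: int = 2,
                        tr: int = 2) -> UnorderedPSF:
    """Unordered PSF: interior slices projected onto their center planes.

    Projection is along the x axis only (y and z are untouched); projected
    points are sorted by y so each column is a left-to-right traversal of the
    cross-section. Boundary columns reuse the ordered construction.
    """
    cols: list[np.ndarray] = []
    for slc in selected:
        if slc.index == 0:
            cols.append(_base_column(slpc, tl, tr))
        elif slc.thickness == 0.0:
            cols.append(_tip_column(slpc, tl, tr))
        else:
            if len(slc.points) == 0:
                raise ValueError(f"selected slice {slc.index} is empty")
            proj = slc.points.copy()
            proj[:, 0] = slc.plane_x
            cols.append(proj[np.argsort(proj[:, 1], kind="stable")])
    return UnorderedPSF(columns_=cols)


def build_test_subset(slpc: SLPC, n_slices: int = 10, per_slice: int = 9) -> OrderedPSF:
    """Ordered evaluation subset: ``n_slices`` columns of ``per_slice`` points.

    Built exactly like an ordered PSF but on its own slicing: the column
    count includes the base and tip columns, so the cloud is cut into
    ``n_slices - 2`` interior slices and every slice is used. ``per_slice``
    must equal 3 + tl + tr with tl = tr. The default 10 x 9 = 90 points.
    """
    if per_slice < 5 or (per_slice - 3) % 2 != 0:
        raise ValueError("per_slice must be 3 + tl + tr with tl = tr >= 1")
    t = (per_slice - 3) // 2
    nums = n_slices - 2
    slices = slice_cloud(slpc, nums)
    selected = select_slices(slices, n_slices)
    return build_ordered_psf(slpc, selected, tl=t, tr=t)


def psf_to_frame(psf) -> "pandas.DataFrame":  # noqa: F821  (lazy import)
    """PSF as a tidy table: slice_index, point_index, x, y, z."""
    import pandas as pd

    rows = []
    for j, col in enumerate(psf.columns()):
        for i, p in enumerate(col):
            rows.append((j, i, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["slice_index", "point_index", "x", "y", "z"])


def psf_from_frame(frame) -> UnorderedPSF | OrderedPSF:
    """Inverse of :func:`psf_to_frame`; returns an ordered PSF when columns
    have equal length, otherwise an unordered one."""
    cols = []
    for _, grp in frame.sort_values(["slice_index", "point_index"]).groupby("slice_index"):
        cols.append(grp[["x", "y", "z"]].to_numpy())
    sizes = {len(c) for c in cols}
    if len(sizes) == 1:
        return OrderedPSF(grid=np.stack(cols, axis=1))
    return UnorderedPSF(columns_=cols)
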