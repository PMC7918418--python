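"""Slicing of the standard leaf point cloud and feature-point detection.

The SLPC is cut along the first principal axis (x) into ``nums`` interior
slices of equal thickness Ws = L / nums. Each interior slice carries its
center "projection plane" at x = min(x) + (i - 0.5) Ws. Two zero-thickness
slices are appended at the leaf base (Slice 0, plane at min(x)) and leaf tip
(Slice nums+1, plane at max(x)); they contribute the base feature triple and
the tip point.

The base triple (left edge, midrib, right edge) is found by growing a slice
from the base until its transverse extent reaches 2 mm — the average tea-leaf
petiole diameter — after which the extreme-y points define the edges and
their midpoint the midrib. The tip point is the mean of the points at
x = max(x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pose import SLPC

#: transverse extent (mm) the grown base slice must reach; average petiole diameter
BASE_WIDTH_MM = 2.0
#: relative tolerance (times L) for membership in the zero-thickness end slices
END_SLICE_RTOL = 1e-6


@dataclass
class Slice:
    """One x-interval of the SLPC with its projection plane."""

    index: int
    x_lo: float
    x_hi: float
    plane_x: float
    points: np.ndarray   # (k, 3) member points
    thickness: float


@dataclass
class FeatureTriple:
    """Left-edge, midrib and right-edge points of a slice (Pl, Pm, Pr)."""

    left: np.ndarray
    mid: np.ndarray
    right: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.vstack([self.left, self.mid, self.right])


def slice_cloud(slpc: SLPC, nums: int) -> list[Slice]:
    """Partition the SLPC into ``nums`` interior slices plus the two end slices.

    Interior membership uses half-open x-intervals, with the last interval
    closed so every point belongs to exactly one interior slice. Returns
    ``nums + 2`` slices indexed 0 (base) .. nums + 1 (tip). Emits a warning
    if more than half of the interior slices are empty (``nums`` too large
    for the cloud density).
    """
    if nums < 3:
        raise ValueError("nums must be at least 3")
    pts = slpc.points
    x = pts[:, 0]
    x_min, x_max = float(x.min()), float(x.max())
    L = x_max - x_min
    ws = L / nums
    idx = np.clip(np.floor((x - x_min) / ws).astype(int), 0, nums - 1)

    tol = END_SLICE_RTOL * L
    slices = [Slice(0, x_min, x_min, x_min, pts[x <= x_min + tol], 0.0)]
    for i in range(1, nums + 1):
        lo = x_min + (i - 1) * ws
        hi = x_min + i * ws
        slices.append(Slice(i, lo, hi, x_min + (i - 0.5) * ws, pts[idx == i - 1], ws))
    slices.append(Slice(nums + 1, x_max, x_max, x_max, pts[x >= x_max - tol], 0.0))

    empty = sum(1 for s in slices[1:-1] if len(s.points) == 0)
    if empty > nums / 2:
        warnings.warn(
            f"{empty}/{nums} interior slices are empty; consider a smaller nums"
        )
    return slices


def base_feature_points(slpc: SLPC) -> FeatureTriple:
    """Base feature triple Pl0, Pm0, Pr0.

    A slice anchored at min(x) grows in steps of L/1000 until the y-range of
    its members reaches ``BASE_WIDTH_MM``. The y extremes give the left/right
    edge points; both share x = min(x) and z = mean z of the grown slice; the
    midrib point is their midpoint.
    """
    pts = slpc.points
    x = pts[:, 0]
    x_min = float(x.min())
    L = slpc.length
    step = L / 1000.0
    thickness = step
    members = None
    while thickness <= L + step:
        members = pts[x <= x_min + thickness]
        if len(members) >= 2 and np.ptp(members[:, 1]) >= BASE_WIDTH_MM:
            break
        thickness += step
    else:
        raise ValueError(
            f"degenerate leaf: base y-range never reaches {BASE_WIDTH_MM} mm"
        )
    y_lo, y_hi = float(members[:, 1].min()), float(members[:, 1].max())
    z_mean = float(members[:, 2].mean())
    left = np.array([x_min, y_lo, z_mean])
    right = np.array([x_min, y_hi, z_mean])
    return FeatureTriple(left=left, mid=0.5 * (left + right), right=right)


def tip_feature_point(slpc: SLPC) -> FeatureTriple:
    """Tip point Pend: mean of the SLPC points at x = max(x).

    All three members of the returned triple coincide.
    """
    pts = slpc.points
    x = pts[:, 0]
    x_max = float(x.max())
    tol = END_SLICE_RTOL * slpc.length
    tip = pts[x >= x_max - tol].mean(axis=0)
    tip[0] = x_max
    return FeatureTriple(left=tip.copy(), mid=tip.copy(), right=tip.copy())


def select_slices(slices: list[Slice], count: int) -> list[Slice]:
    """Pick ``count`` slices spread uniformly, always including base and tip.

    Interior picks fall on the round-half-up uniform grid over 1..nums
    (index_j = floor(j (nums+1) / (count-1) + 0.5)); for the reference
    configuration nums = 50, count = 7 this yields indices
    {0, 9, 17, 26, 34, 43, 51}. Collisions after rounding shift to the
    nearest unused interior index.
    """
    nums = len(slices) - 2
    if not (3 <= count <= nums + 2):
        raise ValueError(f"count must lie in [3, {nums + 2}]")
    chosen: list[int] = [0]
    used = {0, nums + 1}
    for j in range(1, count - 1):
        raw = int(np.floor(j * (nums + 1) / (count - 1) + 0.5))
        raw = min(max(raw, 1), nums)
        if raw in used:
            for off in range(1, nums + 1):
                for cand in (raw + off, raw - off):
                    if 1 <= cand <= nums and cand not in used:
                        raw = cand
                        break
                else:
                    continue
                break
        used.add(raw)
        chosen.append(raw)
    chosen.append(nums + 1)
    chosen = sorted(set(chosen))
    return [slices[i] for i in chosen]
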