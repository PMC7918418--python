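"""Pose standardization of leaf point clouds and voxel-grid downsampling.

A scanned leaf arrives in an arbitrary position and orientation. PCA of the
point coordinates yields three principal axes; mapping them to x (length),
y (width) and z (height) and moving the centroid to the origin produces the
standard leaf point cloud (SLPC) on which slicing and fitting operate.

PCA leaves the sign of each axis undetermined, so a deterministic convention
is applied (required for reproducibility and for the base/tip detectors
downstream):

* axis 1 (x): the end of the leaf whose transverse width within the first
  5 % of the length is smaller is the base (the petiole end narrows to about
  2 mm) and is placed at min(x);
* axis 3 (z): oriented so the median z of the aligned cloud is positive,
  which puts the convex (adaxial) side up for arched leaves;
* axis 2 (y): fixed by right-handedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SLPC:
    """Standard leaf point cloud plus the rigid map that produced it.

    ``points = (raw - centroid) @ axes`` where the columns of ``axes`` are the
    principal directions; ``rotation``/``translation`` store that map so it
    can be inverted for traceability.
    """

    points: np.ndarray        # (n, 3), centroid at origin, PCs on x/y/z
    rotation: np.ndarray      # (3, 3) orthonormal, applied as raw @ rotation
    translation: np.ndarray   # (3,), applied after rotation

    @property
    def length(self) -> float:
        """Leaf length L = max(x) - min(x) along the first principal axis."""
        x = self.points[:, 0]
        return float(x.max() - x.min())


def _as_cloud(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("point cloud must have shape (n, 3)")
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("point cloud contains non-finite coordinates")
    return points


def pca_normalize(points: np.ndarray) -> SLPC:
    """Transform a raw leaf cloud into the SLPC.

    Principal components (eigenvectors of the coordinate covariance, sorted by
    decreasing variance) become the x/y/z axes; the centroid moves to the
    origin. Raises on degenerate (collinear) clouds.
    """
    points = _as_cloud(points)
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate point cloud: points are (nearly) collinear")

    v1, v3 = evecs[:, 0], evecs[:, 2]
    x = centered @ v1
    lo, hi = x.min(), x.max()
    span = hi - lo
    y = centered @ evecs[:, 1]
    near_lo = x <= lo + 0.05 * span
    near_hi = x >= hi - 0.05 * span
    width_lo = np.ptp(y[near_lo]) if near_lo.any() else 0.0
    width_hi = np.ptp(y[near_hi]) if near_hi.any() else 0.0
    if width_lo > width_hi + 1e-12:
        v1 = -v1  # narrow (base) end goes to min(x)

    z = centered @ v3
    med = np.median(z)
    if abs(med) < 1e-12:
        med = float(np.mean(z ** 3))  # fall back to skewness sign
    if med < 0:
        v3 = -v3
    v2 = np.cross(v3, v1)  # right-handed frame

    axes = np.column_stack([v1, v2, v3])
    translation = -centroid @ axes
    return SLPC(points=points @ axes + translation, rotation=axes,
                translation=translation)


def voxel_downsample(points: np.ndarray, target_count: int,
                     origin: np.ndarray | float = 0.0) -> np.ndarray:
    """Voxel-grid filter: replace each occupied voxel by its point centroid.

    The voxel edge length is found by bisection so the output size lands
    within +/-10 % of ``target_count``. ``origin`` shifts the grid (useful
    for randomized repetitions of an otherwise deterministic filter). A
    target at or above the input size returns the input unchanged with a
    warning when strictly above.
    """
    points = _as_cloud(points)
    if target_count < 4:
        raise ValueError("target_count must be at least 4")
    n = len(points)
    if target_count > n:
        warnings.warn("target above input size; returning input unchanged")
        return points.copy()
    if target_count == n:
        return points.copy()

    origin = np.broadcast_to(np.asarray(origin, dtype=float), (3,))

    def count(edge: float) -> int:
        keys = np.floor((points - origin) / edge).astype(np.int64)
        return len(np.unique(keys, axis=0))

    lo = 1e-6 * np.ptp(points, axis=0).max()
    hi = np.linalg.norm(np.ptp(points, axis=0)) + lo
    best_edge, best_diff = hi, np.inf
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = count(mid)
        diff = abs(c - target_count)
        if diff < best_diff:
            best_edge, best_diff = mid, diff
        if c > target_count:
            lo = mid
        elif c < target_count:
            hi = mid
        else:
            break
    edge = best_edge
    keys = np.floor((points - origin) / edge).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    nvox = inverse.max() + 1
    sums = np.zeros((nvox, 3))
    np.add.at(sums, inverse, points)
    counts = np.bincount(inverse, minlength=nvox).astype(float)
    return sums / counts[:, None]


class PCAPoseNormalizer:
    """Estimator-style wrapper around :func:`pca_normalize`.

    ``fit`` learns the rigid map from a cloud; ``transform`` applies it.
    Fitted attributes: ``rotation_``, ``translation_``, ``length_``.
    """

    def fit(self, X, y=None):
        slpc = pca_normalize(X)
        self.rotation_ = slpc.rotation
        self.translation_ = slpc.translation
        self.length_ = slpc.length
        self._slpc = slpc
        return self

    def transform(self, X):
        if not hasattr(self, "rotation_"):
            raise RuntimeError("PCAPoseNormalizer is not fitted")
        return _as_cloud(X) @ self.rotation_ + self.translation_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def inverse_transform(self, X):
        return (np.asarray(X, dtype=float) - self.translation_) @ self.rotation_.T

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self
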