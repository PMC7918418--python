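"""Synthetic leaf point clouds with known ground-truth surfaces.

Real single-leaf scans (tens of thousands of points, leaf lengths of roughly
45-85 mm) are emulated by sampling a hand-shaped ground-truth NURBS surface
and adding isotropic measurement noise plus an arbitrary rigid pose. Because
the ground truth is returned alongside the cloud, every pipeline stage can be
tested for recovery without any external data.

The ground-truth surface is a degree (2, 2) patch with a 5 x 7 control net
(5 across the leaf, 7 base to tip): an elliptic outline that narrows to a
~2 mm petiole stub at the base and collapses to a single point at the tip
(the tip column's control points coincide, deliberately exercising the
degenerate-column path of the fitting code), a convex transverse arch, a
gentle longitudinal bow, an optional midrib ridge and optional low-frequency
wrinkles. Shape constants (arch fraction, bow fraction, outline profile) are
fixed here rather than exposed; :class:`LeafSpec` carries the biologically
meaningful knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splines import NurbsSurface

#: transverse arch height as a fraction of the local half-width
ARCH_FRACTION = 0.22
#: longitudinal bow height as a fraction of leaf length
BOW_FRACTION = 0.05
#: outline half-width profile at the 7 control columns (fraction of max half-width)
OUTLINE = np.array([0.0, 0.55, 0.92, 1.0, 0.85, 0.45, 0.0])
#: base half-width floor (mm) so the petiole stub spans ~2.4 mm
BASE_HALF_WIDTH_MM = 1.2


@dataclass
class LeafSpec:
    """Parameters of one synthetic leaf.

    ``midrib_height`` = 0 gives a smooth convex blade; > 0 raises a distinct
    ridge along the midrib (the "hill"-shaped leaf type).
    ``pose`` is either ``None`` (identity) or a tuple ``(R, t)`` applied as
    ``x @ R.T + t``.
    """

    length: float = 60.0             # mm, realistic range 45-85
    max_width: float | None = None   # mm; default 0.45 * length
    midrib_height: float = 0.0       # mm
    wrinkle_amplitude: float = 0.0   # mm
    n_points: int = 40_000
    noise_sd: float = 0.0            # mm, isotropic
    pose: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_points < 100:
            raise ValueError("need at least 100 points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.max_width is None:
            self.max_width = 0.45 * self.length


def ground_truth_surface(spec: LeafSpec) -> NurbsSurface:
    """The (2, 2) NURBS patch (all weights 1) encoding the leaf shape."""
    rng = np.random.default_rng(spec.seed + 1)
    n_u, n_v = 5, 7
    L, W = spec.length, spec.max_width
    t = np.linspace(0.0, 1.0, n_v)
    xs = -L / 2.0 + L * t
    half_w = np.maximum(OUTLINE * W / 2.0, BASE_HALF_WIDTH_MM)
    half_w[-1] = 0.0  # tip collapses to a point
    bow = BOW_FRACTION * L * np.sin(np.pi * t)

    cross_y = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
    cross_arch = np.array([0.0, 0.7, 1.0, 0.7, 0.0])
    ridge = np.array([0.0, 0.0, 1.0, 0.0, 0.0])

    phase = rng.uniform(0.0, 2.0 * np.pi)
    net = np.zeros((n_u, n_v, 3))
    for j in range(n_v):
        h = half_w[j]
        net[:, j, 0] = xs[j]
        net[:, j, 1] = h * cross_y
        z = (bow[j]
             + ARCH_FRACTION * h * cross_arch
             + spec.midrib_height * (h > 0.0) * ridge
             + spec.wrinkle_amplitude * np.sin(4.0 * np.pi * t[j] + phase))
        net[:, j, 2] = z
    net[:, -1, :] = net[2, -1, :]  # coincident tip control points

    interior = np.linspace(0.0, 1.0, n_v - 1)[1:-1]
    knots_v = np.concatenate([np.zeros(3), interior, np.ones(3)])
    knots_u = np.concatenate([np.zeros(3), [0.35, 0.65], np.ones(3)])
    return NurbsSurface(2, 2, knots_u, knots_v, net)


def generate_leaf(spec: LeafSpec) -> tuple[np.ndarray, NurbsSurface]:
    """Sample a leaf point cloud from its ground-truth surface.

    Returns ``(points, ground_truth)``. Points are surface samples at
    uniform (u, v) parameters, perturbed by isotropic Gaussian noise of
    ``spec.noise_sd`` and mapped through ``spec.pose``; the ground truth is
    returned in its own (un-posed) frame.
    """
    surface = ground_truth_surface(spec)
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(0.0, 1.0, spec.n_points)
    v = rng.uniform(0.0, 1.0, spec.n_points)
    pts = surface.evaluate_many(u, v)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    if spec.pose is not None:
        R, tvec = spec.pose
        R = np.asarray(R, dtype=float)
        if R.shape != (3, 3) or abs(abs(np.linalg.det(R)) - 1.0) > 1e-8:
            raise ValueError("pose rotation must be a 3x3 orthonormal matrix")
        pts = pts @ R.T + np.asarray(tvec, dtype=float)
    return pts, surface


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 100.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation and a bounded random translation."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rm))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, 3)
    return Q, t
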