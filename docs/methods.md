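# Methods

`leafsurf` converts a raw single-leaf 3D point cloud (millimetre units) into
a compact parametric surface and quantifies how faithfully that surface
represents the scan. This note documents the model, the algorithmic and
numerical choices, the defaults, and what the synthetic test bed does and
does not demonstrate.

## Model

A leaf surface is represented as a clamped tensor-product NURBS patch

    S(u, v) = Σ_i Σ_j N_{i,p}(u) N_{j,q}(v) ω_{ij} P_{ij}
              ────────────────────────────────────────────,   (u, v) ∈ [0,1]²
              Σ_i Σ_j N_{i,p}(u) N_{j,q}(v) ω_{ij}

with control net `P`, positive weights `ω`, and Cox–de Boor basis functions
`N` of degrees `(p, q)` on clamped knot vectors. With all weights equal to 1
the patch is an ordinary B-spline surface; the weight-optimization step (PSO,
below) is what moves it into genuinely rational territory. Basis evaluation
uses half-open knot spans with the final span closed, so `u = 1` is a valid
parameter and the surface interpolates its boundary control points.

The `u` direction runs across the leaf (left edge → right edge), `v` runs
from base to tip.

## Pipeline

1. **Pose standardization.** PCA of the coordinates maps the leaf into a
   standard frame: first principal axis → x (length), second → y (width),
   third → z (height); centroid at the origin. PCA leaves axis signs free,
   so a deterministic convention is imposed: the end whose transverse width
   within the first 5 % of the length is smaller (the ~2 mm petiole stub) is
   the base and sits at min(x); z is oriented so the median z is positive
   (convex side up); y follows from right-handedness. The convention is what
   makes the whole pipeline invariant under arbitrary rigid motion of the
   input (verified to < 1e-6 mm in the tests).

2. **Slicing.** The standardized cloud is cut along x into `nums` equal
   slices of thickness `Ws = L / nums`; each slice carries a center
   projection plane. Two zero-thickness slices are added at the base and
   tip. The base feature triple (left edge, midrib, right edge) comes from
   growing a slice from the base in steps of L/1000 until its y-extent
   reaches 2 mm (the average petiole diameter); the tip point is the mean of
   the points at max(x). A uniform subset of slices is selected, always
   including base and tip; the selection rounds half-up, which reproduces
   the reference selection {0, 9, 17, 26, 34, 43, 51} for 50 slices and 7
   picks.

3. **Point set to be fitted (PSF).** Ordered mode extracts `3 + tl + tr`
   points per slice: the slice's feature triple (extremes of y and the max-z
   ridge point inside a half-thickness center band) plus the nearest slice
   points to seeds spaced equally along the straight left–mid and mid–right
   segments (straight-segment spacing is a choice; arc length would also be
   defensible but adds nothing at these point counts). Unordered mode
   projects every point of a selected slice onto its center plane along x
   and sorts by y — the natural left-to-right traversal after a vertical
   projection. Both modes share the boundary columns; the tip column is
   `3 + tl + tr` copies of the tip point, deliberately degenerate.

4. **B-spline surface fitting.** Two paths:
   * *Grid algorithms* (ordered PSF only): classical global interpolation /
     least-squares approximation with one shared parameter vector and knot
     vector per direction (averaged over columns/rows), then column fits
     followed by row fits over the intermediate control points.
   * *Slice-wise algorithm* (either PSF): every column is approximated by a
     p-degree curve with its **own** chord-length parameters and knot
     vector, all sharing the control count `m + 1`; the surface's u knot
     vector is the element-wise mean of the per-column knot vectors (the
     mean of clamped non-decreasing vectors of equal length is again clamped
     and non-decreasing). Rows of the intermediate net are then fitted the
     same way in v. Forcing a common control count per direction is what
     makes element-wise averaging well defined.

   Curve approximation interpolates its endpoints (first/last control point
   = first/last data point) so the surface boundary tracks the leaf outline,
   and solves the interior least-squares problem by `lstsq` on the design
   matrix rather than explicit normal equations, for conditioning; the
   normal-equations construction exists only as a test oracle. A column of
   coincident points (the tip) is fitted as a collapsed column with all
   control points equal — never an error. Parameterization defaults to chord
   length; equally spaced and centripetal are available (the three canonical
   options for this kind of fit). Knots are placed by parameter averaging
   for interpolation and by the parameter-density rule for approximation.

5. **Accuracy metrics.** The error of a fitted surface is measured against a
   90-point evaluation subset (an ordered PSF on its own 10-column slicing,
   9 points per column) by Euclidean point-to-surface distances: RMSE, the
   maximum value MV, and F = α₁·RMSE + α₂·MV with α₁ = 0.8, α₂ = 0.2 by
   default.

6. **PSO weight optimization.** F is minimized over the weight matrix by a
   global-best particle swarm (5 particles, 10 iterations by default;
   c₁ = c₂ = 2; inertia decreasing linearly 0.9 → 0.4; fresh per-dimension
   uniform r₁, r₂ each step). Weights are clipped to [0.1, 10]: they must
   stay positive for the rational denominator, and the bounds keep the
   search sane. One particle starts exactly at all-ones — the B-spline
   solution — so the optimized F can never exceed the unoptimized F; the
   remaining particles start at 1 + U(−0.15, 0.15) with velocities
   U(−0.05, 0.05). The local initialization is deliberate: the B-spline fit
   is already a least-squares optimum, so productive weight adjustments are
   small, and with such a tiny budget a swarm scattered over the full box
   never finds them, whereas the local swarm reliably trims F by a few
   percent on noisy scans.

## Point-to-surface distance (point inversion)

The distance from a query point G to the surface is found by minimizing
`|S(u,v) − G|²` over the clamped parameter square with a damped projected
Newton method (analytic first and second surface derivatives via the
quotient rule). The first start is the chord-ratio initialization

    u₁ = |G − S(0, ½)| / (|G − S(0, ½)| + |S(1, ½) − G|)

and analogously for v₁ at fixed u₁. Because the distance field of a leaf
patch has boundary traps and the collapsed tip makes whole parameter ridges
map to one 3D point, two further safeguards are layered on: a 64×64
cell-centered parameter grid (evaluated once per surface, vectorized over
all query points) whose best cell — after a 9×9 local refinement — seeds a
second and third Newton start, and a derivative-free shrinking-grid polish
around the best iterate, followed by one final Newton pass. Steps are
capped at 0.25 in parameter space, halved until the objective decreases,
and coordinates pinned at an active bound are removed from the Newton
system. Iteration stops on step norm < 1e-10, 100 iterations, or objective
stagnation; non-convergence returns the best iterate flagged
`converged=False` rather than raising. Against a 200×200 dense-grid oracle
the returned distances are accurate to ~1e-14 mm on the synthetic test bed.

## Synthetic leaf generator

Real scans of the target kind (tens of thousands of points, leaf lengths
45–85 mm) are emulated by sampling a hand-shaped ground-truth patch: degree
(2,2), 5×7 control net, elliptic outline narrowing to a ~2.4 mm-wide petiole
stub at the base and a coincident-control-point tip, transverse arch (22 %
of the local half-width), longitudinal bow (5 % of length), optional midrib
ridge (`midrib_height`, mm — the "hill"-shaped leaf type) and optional
low-frequency wrinkles. Points are surface samples at uniform (u, v) plus
isotropic Gaussian noise (`noise_sd`, default scenarios use 0.15 mm,
a realistic hand-held-scanner figure) and an arbitrary rigid pose. Defaults:
length 60 mm, width 0.45·length, 40 000 points.

Because the ground truth is itself a NURBS patch of exactly the default
fitting configuration, recovery tests are sharp: a noiseless cloud refit
with matching degrees and control counts must reproduce the generator
surface to < 0.05 mm test-subset RMSE, and grid interpolation of samples
taken in the surface's own spline space must reproduce it to < 1e-6 mm.

What the generator does **not** emulate: scanner-specific anisotropic noise
and outliers, occlusions and holes, serrated margins, secondary venation,
and strongly folded or twisted blades. Passing tests therefore demonstrate
correctness of the algorithms and their error behaviour under realistic
density and noise, not performance on every real-world leaf pathology.

## Reference configurations

| Stage | Default | Notes |
|---|---|---|
| slices `nums` | 50 | case-study slicing |
| selected slices | 7 | indices {0, 9, 17, 26, 34, 43, 51} |
| points per ordered column | 7 (tl = tr = 2) | 7×7 = 49 point PSF |
| surface degrees | (2, 2) | |
| control net | 5×5 | case study; 3×7 for the downsample sweep |
| test subset | 10 columns × 9 points = 90 | |
| error weights | α₁ = 0.8, α₂ = 0.2 | |
| PSO | 5 particles, 10 iterations | seed required |

The point-density experiment downsamples each cloud with a voxel-grid
filter (centroid per occupied voxel; edge length found by bisection to land
within ±10 % of the target count) to 300–32 000 points and refits with 10
sections, 8 selected slices (base and tip plus 6 interior), unordered PSF
and a 3×7 control net. Downsampling repetitions randomize the voxel-grid
origin — the filter is otherwise deterministic. The acceptance checks run
this sweep on 8 synthetic leaves with 3 repetitions (the acceptance script
uses 4 leaves × 4 targets × 2 repetitions to keep its runtime modest);
every cell must stay below 1 mm mean RMSE and 2 mm mean MV.

## Known limitations

* Degrees, control counts and slice counts are user choices; nothing selects
  them automatically.
* The ordered PSF presumes a detectable midrib ridge; flat or noisy
  cross-sections fall back to whole-slice feature search with a warning, and
  the unordered PSF is the robust alternative.
* The tip is modelled as a single point; the largest fitting errors
  concentrate near base and tip edges.
* No mesh repair, multi-leaf segmentation, or handling of incomplete clouds.
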