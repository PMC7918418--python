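"""End-to-end leaf surface modelling pipeline.

``LeafSurfaceModel`` is an estimator-style front end: ``fit(X)`` takes a raw
(n, 3) leaf point cloud and runs pose normalization, slicing, PSF
generation, surface fitting and error evaluation, optionally followed by PSO
weight optimization into NURBS form. Module-level helpers run the same
pipeline functionally (:func:`run_pipeline`) and reproduce the
point-density experiment in which clouds are voxel-downsampled to a range
of sizes before fitting (:func:`run_downsample_experiment`).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_surface
from .metrics import FitReport, evaluate_fit
from .pose import SLPC, pca_normalize, voxel_downsample
from .pso import PSOConfig, optimize_weights
from .psf import build_ordered_psf, build_test_subset, build_unordered_psf
from .slicing import select_slices, slice_cloud
from .splines import NurbsSurface

logger = logging.getLogger("leafsurf")


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults mirror the case-study setup:

    50 interior slices, 7 selected, 7 points per ordered column
    (tl = tr = 2), a degree (2, 2) surface with a 5 x 5 control net fitted by
    the slice-wise algorithm, and a 10 x 9 = 90 point test subset scored with
    F = 0.8 RMSE + 0.2 MV.
    """

    nums: int = 50
    n_selected: int = 7
    tl: int = 2
    tr: int = 2
    psf_mode: str = "unordered"        # {ordered | unordered}
    fit: FitConfig = None              # default built in __post_init__
    alpha1: float = 0.8
    alpha2: float = 0.2
    test_slices: int = 10
    test_per_slice: int = 9
    run_pso: bool = False
    pso: PSOConfig = None

    def __post_init__(self):
        if self.fit is None:
            self.fit = FitConfig()
        if self.pso is None:
            self.pso = PSOConfig()
        if self.psf_mode not in ("ordered", "unordered"):
            raise ValueError("psf_mode must be 'ordered' or 'unordered'")


@dataclass
class PipelineResult:
    slpc: SLPC
    surface: NurbsSurface            # B-spline fit
    report: FitReport                # accuracy of the B-spline fit
    test_points: np.ndarray
    nurbs_surface: NurbsSurface | None = None   # after PSO, if run
    nurbs_report: FitReport | None = None
    trace: object | None = None


def run_pipeline(points: np.ndarray, config: PipelineConfig | None = None,
                 ) -> PipelineResult:
    """Raw cloud -> SLPC -> PSF -> fitted surface -> accuracy report."""
    if config is None:
        config = PipelineConfig()
    t0 = time.perf_counter()
    slpc = pca_normalize(points)
    logger.info("pose: %d points, L=%.2f mm", len(slpc.points), slpc.length)

    slices = slice_cloud(slpc, config.nums)
    selected = select_slices(slices, config.n_selected)
    logger.info("slicing: nums=%d, selected indices %s", config.nums,
                [s.index for s in selected])

    if config.psf_mode == "ordered":
        psf = build_ordered_psf(slpc, selected, config.tl, config.tr)
    else:
        psf = build_unordered_psf(slpc, selected, config.tl, config.tr)
    logger.info("psf: %s, %d points in %d columns", config.psf_mode, psf.size,
                psf.n_cols)

    surface = fit_surface(psf, config.fit)
    subset = build_test_subset(slpc, config.test_slices, config.test_per_slice)
    test_points = subset.flat_points()
    report = evaluate_fit(surface, test_points, config.alpha1, config.alpha2,
                          config=config.fit)
    logger.info("fit: %s", report.summary())

    result = PipelineResult(slpc=slpc, surface=surface, report=report,
                            test_points=test_points)
    if config.run_pso:
        result.nurbs_surface, result.trace = optimize_weights(
            surface, test_points, config.alpha1, config.alpha2, config.pso)
        result.nurbs_report = result.trace.report
        logger.info("pso: %s", result.nurbs_report.summary())
    logger.info("pipeline done in %.2f s", time.perf_counter() - t0)
    return result


#: configuration of the point-density experiment: 10 sections, 8 selected
#: slices (base and tip included), unordered PSF, degree (2, 2) surface with
#: 3 control points across the leaf and 7 along it.
DOWNSAMPLE_CONFIG = PipelineConfig(
    nums=10, n_selected=8, psf_mode="unordered",
    fit=FitConfig(degree_u=2, degree_v=2, n_ctrl_u=3, n_ctrl_v=7,
                  mode="slicewise"),
)

DOWNSAMPLE_TARGETS = (300, 500, 1000, 2000, 4000, 8000, 16000, 32000)


def run_downsample_experiment(clouds: list[np.ndarray],
                              targets=DOWNSAMPLE_TARGETS,
                              repeats: int = 10,
                              config: PipelineConfig | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Mean fitting error versus point-cloud size.

    Every cloud is voxel-downsampled to each target size ``repeats`` times
    (each repetition shifts the voxel grid by a random seeded origin), the
    fixed fitting configuration is applied, and the mean RMSE / MV over the
    repetitions is tabulated per (cloud, target) cell.
    """
    if config is None:
        config = DOWNSAMPLE_CONFIG
    rng = np.random.default_rng(seed)
    rows = []
    for ci, cloud in enumerate(clouds):
        cloud = np.asarray(cloud, dtype=float)
        scale = np.ptp(cloud, axis=0).max()
        for target in targets:
            rmses, mvs, sizes = [], [], []
            for _ in range(repeats):
                origin = rng.uniform(0.0, scale, 3)
                down = voxel_downsample(cloud, min(target, len(cloud)),
                                        origin=origin)
                res = run_pipeline(down, config)
                rmses.append(res.report.rmse)
                mvs.append(res.report.mv)
                sizes.append(len(down))
            rows.append({
                "cloud": ci,
                "target": target,
                "mean_points": float(np.mean(sizes)),
                "mean_rmse_mm": float(np.mean(rmses)),
                "mean_mv_mm": float(np.mean(mvs)),
            })
            logger.info("experiment: cloud %d target %d rmse %.3f mv %.3f",
                        ci, target, rows[-1]["mean_rmse_mm"], rows[-1]["mean_mv_mm"])
    return pd.DataFrame(rows)


class LeafSurfaceModel:
    """Estimator front end: fit a parametric surface to a leaf point cloud.

    Parameters mirror :class:`PipelineConfig`; fitted attributes carry a
    trailing underscore. ``predict`` maps (u, v) parameter pairs to 3D
    points on the fitted surface; ``score`` returns the negative RMSE so
    that larger is better, composing with sklearn model selection.
    """

    def __init__(self, nums: int = 50, n_selected: int = 7, tl: int = 2,
                 tr: int = 2, psf_mode: str = "unordered",
                 degree_u: int = 2, degree_v: int = 2,
                 n_ctrl_u: int = 5, n_ctrl_v: int = 5,
                 parameterization: str = "chord_length",
                 fit_mode: str = "slicewise",
                 alpha1: float = 0.8, alpha2: float = 0.2,
                 run_pso: bool = False, n_particles: int = 5,
                 pso_iterations: int = 10, random_state: int = 0):
        self.nums = nums
        self.n_selected = n_selected
        self.tl = tl
        self.tr = tr
        self.psf_mode = psf_mode
        self.degree_u = degree_u
        self.degree_v = degree_v
        self.n_ctrl_u = n_ctrl_u
        self.n_ctrl_v = n_ctrl_v
        self.parameterization = parameterization
        self.fit_mode = fit_mode
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.run_pso = run_pso
        self.n_particles = n_particles
        self.pso_iterations = pso_iterations
        self.random_state = random_state

    _param_names = ("nums", "n_selected", "tl", "tr", "psf_mode", "degree_u",
                    "degree_v", "n_ctrl_u", "n_ctrl_v", "parameterization",
                    "fit_mode", "alpha1", "alpha2", "run_pso", "n_particles",
                    "pso_iterations", "random_state")

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            nums=self.nums, n_selected=self.n_selected, tl=self.tl, tr=self.tr,
            psf_mode=self.psf_mode,
            fit=FitConfig(degree_u=self.degree_u, degree_v=self.degree_v,
                          n_ctrl_u=self.n_ctrl_u, n_ctrl_v=self.n_ctrl_v,
                          parameterization=self.parameterization,
                          mode=self.fit_mode),
            alpha1=self.alpha1, alpha2=self.alpha2, run_pso=self.run_pso,
            pso=PSOConfig(n_particles=self.n_particles,
                          max_iter=self.pso_iterations,
                          seed=self.random_state),
        )

    def fit(self, X, y=None):
        result = run_pipeline(np.asarray(X, dtype=float), self._config())
        self.slpc_ = result.slpc
        self.rotation_ = result.slpc.rotation
        self.translation_ = result.slpc.translation
        self.length_ = result.slpc.length
        self.surface_ = result.surface
        self.report_ = result.report
        self.test_points_ = result.test_points
        self.nurbs_surface_ = result.nurbs_surface
        self.nurbs_report_ = result.nurbs_report
        self.trace_ = result.trace
        return self

    @property
    def best_surface_(self) -> NurbsSurface:
        return self.nurbs_surface_ if self.nurbs_surface_ is not None else self.surface_

    @property
    def best_report_(self) -> FitReport:
        return self.nurbs_report_ if self.nurbs_report_ is not None else self.report_

    def predict(self, UV):
        """Evaluate the fitted surface at (u, v) rows of ``UV``."""
        self._check_fitted()
        UV = np.asarray(UV, dtype=float).reshape(-1, 2)
        return self.best_surface_.evaluate_many(UV[:, 0], UV[:, 1])

    def score(self, X=None, y=None) -> float:
        """Negative RMSE (mm) on the held test subset, or on ``X`` in the
        SLPC frame if given."""
        self._check_fitted()
        if X is None:
            return -self.best_report_.rmse
        pts = np.asarray(X, dtype=float) @ self.rotation_ + self.translation_
        return -evaluate_fit(self.best_surface_, pts, self.alpha1,
                             self.alpha2).rmse

    def _check_fitted(self):
        if not hasattr(self, "surface_"):
            raise RuntimeError("LeafSurfaceModel is not fitted")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
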