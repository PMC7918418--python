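"""Particle swarm optimization of NURBS control-point weights.

A fitted B-spline surface (all weights 1) is turned into a NURBS surface by
searching over the weight matrix to minimize the fitting error
F(X) = alpha1 * RMSE + alpha2 * MV against a fixed test subset. Each
particle is a flattened weight matrix; velocities follow the standard
global-best update

    V <- theta V + c1 r1 (Pbest - X) + c2 r2 (Gbest - X)
    X <- X + V

with fresh uniform r1, r2 drawn per dimension per step and the inertia
theta decreasing linearly from theta_max to theta_min over the run.

Weights must stay positive (they sit in the rational denominator), so
positions are clipped to ``weight_bounds``. One particle is initialized
exactly at the all-ones matrix — the B-spline solution — which guarantees
the optimized F never exceeds the unoptimized one; the rest start as small
perturbations of it, since the fitted surface is already a least-squares
optimum and the productive weight adjustments are local.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import FitReport, evaluate_fit
from .splines import NurbsSurface


@dataclass
class PSOConfig:
    """Swarm hyperparameters; defaults mirror the reference configuration."""

    n_particles: int = 5
    max_iter: int = 10
    c1: float = 2.0
    c2: float = 2.0
    theta_max: float = 0.9
    theta_min: float = 0.4
    weight_bounds: tuple[float, float] = (0.1, 10.0)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.weight_bounds
        if not (0.0 < lo < hi):
            raise ValueError("weight bounds must satisfy 0 < lo < hi")
        if self.n_particles < 1 or self.max_iter < 1:
            raise ValueError("need at least one particle and one iteration")


@dataclass
class OptimizationTrace:
    """Per-iteration best objective and the winning weights."""

    best_f: list[float]
    weights: np.ndarray
    report: FitReport


def inertia(j: int, config: PSOConfig) -> float:
    """Linearly decreasing inertia: theta_max at j = 0, theta_min at j = jmax."""
    if not (0 <= j <= config.max_iter):
        raise ValueError("iteration index out of range")
    return config.theta_max - (config.theta_max - config.theta_min) * j / config.max_iter


def optimize_weights(surface: NurbsSurface, test_points,
                     alpha1: float = 0.8, alpha2: float = 0.2,
                     config: PSOConfig | None = None,
                     ) -> tuple[NurbsSurface, OptimizationTrace]:
    """Optimize control-point weights of ``surface`` by PSO.

    Returns the surface carrying the global-best weights and the
    optimization trace. The best-F sequence is non-increasing by
    construction.
    """
    if config is None:
        config = PSOConfig()
    if hasattr(test_points, "flat_points"):
        test_points = test_points.flat_points()
    test_points = np.asarray(test_points, dtype=float)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.weight_bounds
    dim = surface.n_ctrl_u * surface.n_ctrl_v

    def objective(x: np.ndarray) -> float:
        return evaluate_fit(surface.with_weights(x), test_points,
                            alpha1, alpha2).f_value

    # swarm starts around the B-spline solution: one particle exactly at
    # all-ones, the rest scattered nearby (the fitted surface is already a
    # least-squares optimum, so the useful weight adjustments are local)
    X = np.clip(1.0 + rng.uniform(-0.15, 0.15, size=(config.n_particles, dim)),
                lo, hi)
    X[0] = 1.0
    V = rng.uniform(-0.05, 0.05, size=(config.n_particles, dim))
    v_max = (hi - lo) / 2.0

    f = np.array([objective(x) for x in X])
    pbest, pbest_f = X.copy(), f.copy()
    g = int(np.argmin(f))
    gbest, gbest_f = X[g].copy(), float(f[g])
    trace = [gbest_f]

    for j in range(config.max_iter):
        theta = inertia(j, config)
        r1 = rng.uniform(size=(config.n_particles, dim))
        r2 = rng.uniform(size=(config.n_particles, dim))
        V = (theta * V + config.c1 * r1 * (pbest - X)
             + config.c2 * r2 * (gbest[None, :] - X))
        V = np.clip(V, -v_max, v_max)
        X = np.clip(X + V, lo, hi)
        f = np.array([objective(x) for x in X])
        better = f < pbest_f
        pbest[better] = X[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)

    optimized = surface.with_weights(gbest)
    report = evaluate_fit(optimized, test_points, alpha1, alpha2)
    return optimized, OptimizationTrace(best_f=trace, weights=gbest.reshape(
        surface.n_ctrl_u, surface.n_ctrl_v), report=report)


class PSOWeightOptimizer:
    """Estimator-style wrapper around :func:`optimize_weights`.

    Hyperparameters are the PSO settings and the error weights; ``fit``
    takes the B-spline surface and the test points and exposes fitted
    attributes ``surface_``, ``trace_`` and ``report_``.
    """

    def __init__(self, n_particles: int = 5, max_iter: int = 10,
                 c1: float = 2.0, c2: float = 2.0, theta_max: float = 0.9,
                 theta_min: float = 0.4,
                 weight_bounds: tuple[float, float] = (0.1, 10.0),
                 alpha1: float = 0.8, alpha2: float = 0.2,
                 random_state: int = 0):
        self.n_particles = n_particles
        self.max_iter = max_iter
        self.c1 = c1
        self.c2 = c2
        self.theta_max = theta_max
        self.theta_min = theta_min
        self.weight_bounds = weight_bounds
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.random_state = random_state

    def _config(self) -> PSOConfig:
        return PSOConfig(n_particles=self.n_particles, max_iter=self.max_iter,
                         c1=self.c1, c2=self.c2, theta_max=self.theta_max,
                         theta_min=self.theta_min,
                         weight_bounds=tuple(self.weight_bounds),
                         seed=self.random_state)

    def fit(self, surface: NurbsSurface, test_points):
        self.surface_, self.trace_ = optimize_weights(
            surface, test_points, self.alpha1, self.alpha2, self._config())
        self.report_ = self.trace_.report
        return self

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "n_particles", "max_iter", "c1", "c2", "theta_max", "theta_min",
            "weight_bounds", "alpha1", "alpha2", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
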