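"""Point-to-surface distances and fit accuracy metrics.

The Euclidean distance from a test point G to a parametric surface S is the
distance to its foot point G' = S(u*, v*), found by Newton iteration on the
squared-distance objective f(u, v) = |S(u, v) - G|^2 over the clamped
parameter square. The first Newton start uses the chord-ratio
initialization

    u1 = |G - S(0, 0.5)| / (|G - S(0, 0.5)| + |S(1, 0.5) - G|)

and analogously for v1 with u1 held fixed. Because a single start can be
captured by a local minimum on strongly curved surfaces, further starts are
seeded from spatially diverse cells of a coarse parameter grid (refined
locally around the best cell), a shrinking-grid polish handles the flat
neighbourhoods of a collapsed tip, and the best result is kept.

Accuracy of a fitted surface against a test subset is summarized by the
root-mean-square error (RMSE) and maximum value (MV) of the point-to-surface
distances, and their convex combination F = alpha1 * RMSE + alpha2 * MV
(alpha1 + alpha2 = 1), the objective later minimized by the weight
optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .splines import NurbsSurface

NEWTON_TOL = 1e-10
NEWTON_MAX_ITER = 100
COARSE_GRID = 64
N_GRID_SEEDS = 4
SEED_SEPARATION = 4  # min Chebyshev cell distance between distinct seeds
MAX_STEP = 0.25


@dataclass
class ProjectionResult:
    """Foot point of a query point on a surface."""

    u: float
    v: float
    foot_point: np.ndarray
    distance: float
    iterations: int
    converged: bool


def _newton_batch(surface: NurbsSurface, G: np.ndarray, u0: np.ndarray,
                  v0: np.ndarray, max_iter: int, tol: float):
    """Damped, clamped Newton descent on the squared distance, batched.

    All query points iterate together; a point leaves the active set when
    its applied step falls below ``tol`` (converged) or when no halved step
    decreases its objective (stalled against a boundary or flat spot).
    Returns per-point (u, v, f, iterations, converged).
    """
    n = len(G)
    u, v = u0.copy(), v0.copy()
    S = surface.evaluate_many(u, v)
    f = np.einsum("ij,ij->i", S - G, S - G)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        d = surface.derivatives_many(u[idx], v[idx], order=2)
        r = d["S"] - G[idx]
        gu = 2.0 * np.einsum("ij,ij->i", r, d["Su"])
        gv = 2.0 * np.einsum("ij,ij->i", r, d["Sv"])
        # active bound constraints: descent (-g) would leave the unit square
        fix_u = ((u[idx] <= 0.0) & (gu > 0)) | ((u[idx] >= 1.0) & (gu < 0))
        fix_v = ((v[idx] <= 0.0) & (gv > 0)) | ((v[idx] >= 1.0) & (gv < 0))
        pgu = np.where(fix_u, 0.0, gu)
        pgv = np.where(fix_v, 0.0, gv)
        done = (f[idx] < tol**2) | (np.hypot(pgu, pgv) < tol)
        iters[idx[~done]] += 1
        converged[idx[done]] = True
        active[idx[done]] = False
        live = idx[~done]
        if len(live) == 0:
            continue
        keep = ~done
        r, Su, Sv = r[keep], d["Su"][keep], d["Sv"][keep]
        Suu, Suv, Svv = d["Suu"][keep], d["Suv"][keep], d["Svv"][keep]
        gu, gv = gu[keep], gv[keep]
        pgu, pgv = pgu[keep], pgv[keep]
        fix_u, fix_v = fix_u[keep], fix_v[keep]
        h11 = 2.0 * (np.einsum("ij,ij->i", Su, Su) + np.einsum("ij,ij->i", r, Suu))
        h12 = 2.0 * (np.einsum("ij,ij->i", Su, Sv) + np.einsum("ij,ij->i", r, Suv))
        h22 = 2.0 * (np.einsum("ij,ij->i", Sv, Sv) + np.einsum("ij,ij->i", r, Svv))
        # Newton step on the free coordinates (projected onto the active set)
        h12_eff = np.where(fix_u | fix_v, 0.0, h12)
        det = h11 * h22 - h12_eff * h12_eff
        ok = np.abs(det) > 1e-300
        su = np.where(ok, -(h22 * pgu - h12_eff * pgv) / np.where(ok, det, 1.0), -pgu)
        sv = np.where(ok, -(h11 * pgv - h12_eff * pgu) / np.where(ok, det, 1.0), -pgv)
        su = np.where(fix_u, 0.0, su)
        sv = np.where(fix_v, 0.0, sv)
        descent = su * pgu + sv * pgv < 0
        scale = np.maximum(np.hypot(pgu, pgv), 1.0)
        su = np.where(descent, su, -pgu / scale)
        sv = np.where(descent, sv, -pgv / scale)
        # trust-region style cap keeps a start inside its basin
        norm = np.maximum(np.hypot(su, sv), 1e-300)
        shrink = np.minimum(1.0, MAX_STEP / norm)
        su *= shrink
        sv *= shrink

        # damped update: try the step at halved lengths all at once and keep
        # the longest one that decreases the objective
        nl = len(live)
        factors = 0.5 ** np.arange(12)
        ut = np.clip(u[live, None] + su[:, None] * factors, 0.0, 1.0)
        vt = np.clip(v[live, None] + sv[:, None] * factors, 0.0, 1.0)
        St = surface.evaluate_many(ut.ravel(), vt.ravel()).reshape(nl, len(factors), 3)
        ft = ((St - G[live, None, :]) ** 2).sum(axis=2)
        good = ft < f[live, None]
        improved = good.any(axis=1)
        sel = np.argmax(good, axis=1)  # first (longest) improving step
        ar = np.arange(nl)
        u_new = np.where(improved, ut[ar, sel], u[live])
        v_new = np.where(improved, vt[ar, sel], v[live])
        f_new = np.where(improved, ft[ar, sel], f[live])
        moved = np.abs(u_new - u[live]) + np.abs(v_new - v[live])
        # objective stagnation: the iterate is as good as it will get
        stalled = (f[live] - f_new) <= 1e-12 * np.maximum(f_new, 1e-12)
        u[live], v[live], f[live] = u_new, v_new, f_new
        small = (moved < tol) | stalled
        converged[live[small & improved]] = True
        active[live[small | ~improved]] = False
    return u, v, f, iters, converged


def project_points(surface: NurbsSurface, points: np.ndarray,
                   max_iter: int = NEWTON_MAX_ITER,
                   tol: float = NEWTON_TOL):
    """Foot points of many query points on a surface (batched Newton).

    Each point gets several Newton starts — the chord-ratio initialization
    plus spatially diverse cells of a coarse parameter grid (evaluated once
    per surface, the best cell refined locally) — followed by a
    derivative-free shrinking-grid polish and a final Newton pass; the best
    result wins. Returns arrays ``(u, v, distance, iterations, converged)``.
    """
    G = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(G)
    a = surface.evaluate(0.0, 0.5)
    b = surface.evaluate(1.0, 0.5)
    da = np.linalg.norm(G - a, axis=1)
    db = np.linalg.norm(G - b, axis=1)
    tot = da + db
    u1 = np.where(tot > 0, da / np.where(tot > 0, tot, 1.0), 0.5)
    c = surface.evaluate_many(u1, np.zeros(n))
    d = surface.evaluate_many(u1, np.ones(n))
    dc = np.linalg.norm(G - c, axis=1)
    dd = np.linalg.norm(G - d, axis=1)
    tot = dc + dd
    v1 = np.where(tot > 0, dc / np.where(tot > 0, tot, 1.0), 0.5)

    # cell-centered seed grid: no seed sits exactly on the boundary, where
    # a narrow interior basin next to the edge would be missed
    g = (np.arange(COARSE_GRID) + 0.5) / COARSE_GRID
    grid_pts = surface.evaluate_grid(g, g).reshape(-1, 3)
    d2 = ((G[:, None, :] - grid_pts[None, :, :]) ** 2).sum(axis=2)
    ranking = np.argsort(d2, axis=1)
    # spatially diverse seeds: near-tied 3D distances often sit in distinct
    # parameter-space valleys, so skip cells adjacent to an accepted seed
    order = np.empty((n, N_GRID_SEEDS), dtype=int)
    for t in range(n):
        accepted = []
        for cell in ranking[t]:
            iu, iv = divmod(cell, COARSE_GRID)
            if all(max(abs(iu - a), abs(iv - b)) >= SEED_SEPARATION
                   for a, b in accepted):
                accepted.append((iu, iv))
                if len(accepted) == N_GRID_SEEDS:
                    break
        while len(accepted) < N_GRID_SEEDS:
            accepted.append(accepted[0])
        order[t] = [a * COARSE_GRID + b for a, b in accepted]

    # refine each point's best cell with a local sub-grid; near degenerate
    # regions (the collapsed leaf tip) Newton basins are unreliable and the
    # refined seed carries most of the work
    h = 1.0 / COARSE_GRID
    uc = g[order[:, 0] // COARSE_GRID]
    vc = g[order[:, 0] % COARSE_GRID]
    loc = np.linspace(-h, h, 9)
    uu = np.clip(uc[:, None, None] + loc[None, :, None], 0.0, 1.0)
    vv = np.clip(vc[:, None, None] + loc[None, None, :], 0.0, 1.0)
    uu, vv = np.broadcast_arrays(uu, vv)
    fine = surface.evaluate_many(uu.ravel(), vv.ravel()).reshape(n, 81, 3)
    fd2 = ((fine - G[:, None, :]) ** 2).sum(axis=2)
    fam = np.argmin(fd2, axis=1)
    u_ref = uu.reshape(n, 81)[np.arange(n), fam]
    v_ref = vv.reshape(n, 81)[np.arange(n), fam]

    starts = [(u1, v1), (u_ref, v_ref)]
    for k in range(N_GRID_SEEDS):
        starts.append((g[order[:, k] // COARSE_GRID],
                       g[order[:, k] % COARSE_GRID]))

    best = None
    for su, sv in starts:
        res = _newton_batch(surface, G, np.asarray(su, dtype=float),
                            np.asarray(sv, dtype=float), max_iter, tol)
        if best is None:
            best = list(res)
        else:
            take = res[2] < best[2]
            for k in range(5):
                best[k] = np.where(take, res[k], best[k])
    u, v, f, iters, converged = best

    # derivative-free polish: shrinking local grids handle the flat,
    # rank-deficient neighbourhoods of a collapsed tip where Newton stalls
    w = 2.0 / COARSE_GRID
    offs = np.linspace(-1.0, 1.0, 7)
    for _ in range(6):
        pu = np.clip(u[:, None, None] + w * offs[None, :, None], 0.0, 1.0)
        pv = np.clip(v[:, None, None] + w * offs[None, None, :], 0.0, 1.0)
        pu, pv = np.broadcast_arrays(pu, pv)
        P = surface.evaluate_many(pu.ravel(), pv.ravel()).reshape(n, 49, 3)
        pf = ((P - G[:, None, :]) ** 2).sum(axis=2)
        am = np.argmin(pf, axis=1)
        ar = np.arange(n)
        better = pf[ar, am] < f
        u = np.where(better, pu.reshape(n, 49)[ar, am], u)
        v = np.where(better, pv.reshape(n, 49)[ar, am], v)
        f = np.where(better, pf[ar, am], f)
        w *= 0.3

    # final Newton pass restores full precision where the surface is regular
    res = _newton_batch(surface, G, u, v, max_iter, tol)
    take = res[2] < f
    u = np.where(take, res[0], u)
    v = np.where(take, res[1], v)
    f = np.where(take, res[2], f)
    converged = np.where(take, res[4], converged)
    return u, v, np.sqrt(np.maximum(f, 0.0)), iters, converged.astype(bool)


def project_point(surface: NurbsSurface, point: np.ndarray,
                  max_iter: int = NEWTON_MAX_ITER,
                  tol: float = NEWTON_TOL) -> ProjectionResult:
    """Closest point on ``surface`` to ``point`` by damped Newton iteration.

    Non-convergence is reported through ``converged=False`` with the best
    iterate returned, never as an exception. Parameters are clamped to
    [0, 1]; the foot point may lie on the surface boundary.
    """
    u, v, dist, iters, conv = project_points(surface, np.asarray(point)[None, :],
                                             max_iter, tol)
    foot = surface.evaluate(float(u[0]), float(v[0]))
    return ProjectionResult(u=float(u[0]), v=float(v[0]), foot_point=foot,
                            distance=float(dist[0]), iterations=int(iters[0]),
                            converged=bool(conv[0]))


@dataclass
class FitReport:
    """Accuracy summary of a fitted surface against a test subset (mm)."""

    rmse: float
    mv: float
    f_value: float
    alpha1: float
    alpha2: float
    distances: np.ndarray
    config: object | None = None

    def summary(self) -> str:
        return (f"RMSE={self.rmse:.4f} mm  MV={self.mv:.4f} mm  "
                f"F={self.f_value:.4f} mm  (alpha1={self.alpha1}, "
                f"alpha2={self.alpha2}, n={len(self.distances)})")

    def to_dict(self) -> dict:
        d = {
            "rmse_mm": self.rmse,
            "mv_mm": self.mv,
            "f_mm": self.f_value,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "n_points": int(len(self.distances)),
            "distances_mm": np.asarray(self.distances).tolist(),
        }
        if self.config is not None:
            d["config"] = getattr(self.config, "__dict__", str(self.config))
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def evaluate_fit(surface: NurbsSurface, points: np.ndarray,
                 alpha1: float = 0.8, alpha2: float = 0.2,
                 config=None) -> FitReport:
    """RMSE / MV / F of a surface against a set of test points.

    ``points`` may be a flat (n, 3) array or any PSF object exposing
    ``flat_points``.
    """
    if hasattr(points, "flat_points"):
        points = points.flat_points()
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise ValueError("test subset must be a non-empty (n, 3) array")
    if alpha1 < 0 or alpha2 < 0 or abs(alpha1 + alpha2 - 1.0) > 1e-9:
        raise ValueError("alpha1 and alpha2 must be non-negative and sum to 1")
    dists = project_points(surface, points)[2]
    rmse = float(np.sqrt(np.mean(dists ** 2)))
    mv = float(dists.max())
    return FitReport(rmse=rmse, mv=mv, f_value=alpha1 * rmse + alpha2 * mv,
                     alpha1=alpha1, alpha2=alpha2, distances=dists,
                     config=config)
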