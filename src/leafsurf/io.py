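"""Point-cloud and surface file I/O.

Readers accept the formats leaf scans typically arrive in: PLY (ASCII or
binary vertex elements, via trimesh), plain whitespace/comma XYZ tables, and
OBJ vertex lists. The writer emits ASCII PLY. Surfaces serialize to a JSON
document (degrees, knot vectors, u-major control net, weights) and can be
exported as a sampled triangulated OBJ mesh for visual inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh

from .splines import NurbsSurface

POINT_SUFFIXES = (".ply", ".obj", ".xyz", ".csv", ".txt")


def read_point_cloud(path) -> np.ndarray:
    """Load a point cloud as an (n, 3) float array, dispatching on suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".ply", ".obj"):
        loaded = trimesh.load(str(path), process=False)
        verts = np.asarray(loaded.vertices, dtype=float)
    elif suffix in (".xyz", ".csv", ".txt"):
        with open(path) as fh:
            head = fh.read(4096)
        delim = "," if ("," in head.splitlines()[0] if head else False) else None
        verts = np.loadtxt(path, delimiter=delim, ndmin=2)
        verts = np.asarray(verts, dtype=float)[:, :3]
    else:
        raise ValueError(f"unsupported point-cloud format {suffix!r}")
    if verts.ndim != 2 or verts.shape[1] != 3 or len(verts) == 0:
        raise ValueError(f"no 3D vertices found in {path}")
    return verts


def write_point_cloud_ply(points: np.ndarray, path) -> None:
    """Write an ASCII PLY file holding only vertex elements."""
    points = np.asarray(points, dtype=float)
    cloud = trimesh.PointCloud(points)
    data = cloud.export(file_type="ply", encoding="ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def write_surface_json(surface: NurbsSurface, path) -> None:
    surface.to_json(path)


def read_surface_json(path) -> NurbsSurface:
    return NurbsSurface.from_json(path)


def write_surface_obj(surface: NurbsSurface, path, n_u: int = 50,
                      n_v: int = 50) -> None:
    """Export a triangulated sample of the surface as an OBJ mesh."""
    verts, faces = surface.sample_mesh(n_u=n_u, n_v=n_v)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(str(path))
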