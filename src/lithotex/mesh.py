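"""STL mesh input and rasterization onto regular height grids.

Scanned surfaces arrive as triangle meshes (binary or ASCII STL). For
texture analysis they are resampled onto a regular grid along the normal of
their least-squares reference plane, under the height-field assumption (the
mesh projects injectively onto that plane).
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .heightmap import HeightMap, SurfaceValidationError


class MeshError(ValueError):
    pass


def read_mesh(path) -> trimesh.Trimesh:
    """Load a binary or ASCII STL; degenerate faces are dropped and counted.

    Vertices are welded (exact duplicates merged). Malformed files raise
    :class:`MeshError`.
    """
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise MeshError(f"cannot parse STL {path!r}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshError(f"{path!r}: no triangles found")
    mesh.merge_vertices()
    n0 = len(mesh.faces)
    mesh.update_faces(mesh.nondegenerate_faces())
    dropped = n0 - len(mesh.faces)
    if len(mesh.faces) == 0:
        raise MeshError(f"{path!r}: all {n0} faces degenerate")
    mesh.metadata["degenerate_faces_dropped"] = int(dropped)
    return mesh


def heightmap_to_mesh(hmap: HeightMap) -> trimesh.Trimesh:
    """Triangulate a height map into a mesh (two triangles per cell)."""
    x, y = hmap.coords()
    nr, nc = hmap.shape
    verts = np.column_stack([x.ravel(), y.ravel(), hmap.heights.ravel()])
    idx = np.arange(nr * nc).reshape(nr, nc)
    a, b = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
    c, d = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, d]), np.column_stack([a, d, c])], axis=0
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def write_mesh(hmap: HeightMap, path) -> None:
    heightmap_to_mesh(hmap).export(str(path))


def _reference_plane_frame(vertices: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose third axis is the LSQ plane normal."""
    c = vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(vertices - c, full_matrices=False)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    # in-plane axes from the remaining singular vectors
    e1 = vt[0] - np.dot(vt[0], normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return np.stack([e1, e2, normal])


def rasterize_mesh(
    mesh: trimesh.Trimesh,
    spacing: float,
    max_gap_cells: int = 3,
    max_masked_fraction: float = 0.5,
    align_to_plane: bool = True,
) -> HeightMap:
    """Sample mesh heights on a regular grid along the reference-plane normal.

    Heights are linearly interpolated between vertices; grid cells not
    covered by the mesh footprint are masked, and masked gaps up to
    ``max_gap_cells`` wide are filled by nearest-valid interpolation and
    flagged in the metadata. Refuses maps with more than
    ``max_masked_fraction`` invalid cells.
    """
    if spacing <= 0:
        raise SurfaceValidationError("spacing must be > 0")
    verts = np.asarray(mesh.vertices, dtype=float)
    if align_to_plane:
        frame = _reference_plane_frame(verts)
        verts = (verts - verts.mean(axis=0)) @ frame.T
    xy, z = verts[:, :2], verts[:, 2]
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    nx = max(int(np.floor((x1 - x0) / spacing)) + 1, 2)
    ny = max(int(np.floor((y1 - y0) / spacing)) + 1, 2)
    gx = x0 + np.arange(nx) * spacing
    gy = y0 + np.arange(ny) * spacing
    gxx, gyy = np.meshgrid(gx, gy)
    interp = LinearNDInterpolator(xy, z)
    grid = interp(np.column_stack([gxx.ravel(), gyy.ravel()])).reshape(ny, nx)
    mask = np.isfinite(grid)
    frac_masked = 1.0 - mask.mean()
    if frac_masked > max_masked_fraction:
        raise MeshError(
            f"{frac_masked:.0%} of grid cells uncovered (limit {max_masked_fraction:.0%}); "
            "mesh is probably not a height field at this spacing"
        )
    filled = 0
    if (~mask).any() and max_gap_cells > 0:
        tree = cKDTree(np.column_stack([gxx[mask], gyy[mask]]))
        holes = np.column_stack([gxx[~mask], gyy[~mask]])
        dist, idx = tree.query(holes)
        ok = dist <= max_gap_cells * spacing
        vals = grid[mask][idx[ok]]
        hole_idx = np.flatnonzero(~mask.ravel())[ok]
        grid.ravel()[hole_idx] = vals
        mask.ravel()[hole_idx] = True
        filled = int(ok.sum())
    return HeightMap(
        grid,
        spacing,
        origin=(float(x0), float(y0)),
        mask=mask,
        meta={
            "source": "rasterize_mesh",
            "interpolated_cells": filled,
            "masked_fraction": float(1.0 - mask.mean()),
        },
    )
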