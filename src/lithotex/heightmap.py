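"""Regular height grids and the standard surface pre-treatment chain.

The :class:`HeightMap` is the substrate of every texture computation in this
package: a rectangular grid of surface heights ``z(x, y)`` (mm) with a fixed
lateral spacing, a per-cell validity mask and a free-form provenance record.
Pre-treatment mirrors standard surface-metrology practice: least-squares
levelling (subtract the best-fit plane), form removal (subtract a low-order
polynomial, the "F-operator") and tiling into non-overlapping square
sub-areas on which parameters are computed.

Conventions: x increases rightwards (columns), y upwards (rows), heights
along +z; angles are degrees counter-clockwise from +x, texture directions
are axial and reported on [0°, 180°).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml


class SurfaceValidationError(ValueError):
    """Raised when a height map or an operation's preconditions are invalid."""


@dataclass
class HeightMap:
    """A regular grid of surface heights in mm.

    Parameters
    ----------
    heights : (nrows, ncols) float array
        Heights in mm. Row 0 is the smallest y.
    spacing : float
        Lateral sample spacing in mm (identical along x and y).
    origin : (float, float)
        Physical (x0, y0) of the cell-centre at ``heights[0, 0]``.
    mask : bool array or None
        True where the cell is valid. NaN heights are always invalid.
    meta : dict
        Provenance record (seed, applied operators, units, ...).
    """

    heights: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise SurfaceValidationError("heights must be a non-empty 2-D grid")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise SurfaceValidationError(f"spacing must be > 0, got {self.spacing}")
        finite = np.isfinite(self.heights)
        if self.mask is None:
            self.mask = finite
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & finite
        if self.mask.shape != self.heights.shape:
            raise SurfaceValidationError("mask shape must match heights")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) in mm, counted as n * spacing."""
        nr, nc = self.heights.shape
        return nc * self.spacing, nr * self.spacing

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinate grids (x, y) in mm."""
        nr, nc = self.heights.shape
        x = self.origin[0] + np.arange(nc) * self.spacing
        y = self.origin[1] + np.arange(nr) * self.spacing
        return np.meshgrid(x, y)

    def valid_heights(self) -> np.ndarray:
        return self.heights[self.mask]

    def copy(self, **changes) -> "HeightMap":
        out = replace(
            self,
            heights=self.heights.copy(),
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        return out

    def with_provenance(self, step: str, **params) -> "HeightMap":
        out = self.copy()
        out.meta.setdefault("provenance", [])
        out.meta["provenance"] = list(out.meta["provenance"]) + [
            {"step": step, **params}
        ]
        return out


@dataclass
class SubArea:
    """A window into a parent map, physically square (default 10 x 10 mm)."""

    parent: HeightMap
    window: tuple[int, int, int, int]  # row0, col0, nrows, ncols
    worked: bool = True

    def __post_init__(self) -> None:
        r0, c0, nr, nc = self.window
        pr, pc = self.parent.shape
        if r0 < 0 or c0 < 0 or r0 + nr > pr or c0 + nc > pc:
            raise SurfaceValidationError(f"window {self.window} outside parent {self.parent.shape}")

    def extract(self) -> HeightMap:
        r0, c0, nr, nc = self.window
        p = self.parent
        return HeightMap(
            heights=p.heights[r0 : r0 + nr, c0 : c0 + nc].copy(),
            spacing=p.spacing,
            origin=(p.origin[0] + c0 * p.spacing, p.origin[1] + r0 * p.spacing),
            mask=p.mask[r0 : r0 + nr, c0 : c0 + nc].copy(),
            meta={**p.meta, "window": self.window, "worked": self.worked},
        )


# ---------------------------------------------------------------------------
# I/O: CSV grid + YAML sidecar
# ---------------------------------------------------------------------------

def write_heightmap(hmap: HeightMap, path) -> None:
    """Write a map as a CSV numeric grid plus a ``.yaml`` sidecar.

    Masked cells are stored as NaN; the sidecar records spacing, origin,
    units and provenance so the round trip is lossless.
    """
    path = str(path)
    grid = hmap.heights.copy()
    grid[~hmap.mask] = np.nan
    np.savetxt(path, grid, delimiter=",", fmt="%.9g")
    sidecar = {
        "spacing_mm": float(hmap.spacing),
        "origin_mm": [float(hmap.origin[0]), float(hmap.origin[1])],
        "units": "mm",
        "mask_encoding": "nan",
        "meta": _yaml_safe(hmap.meta),
    }
    with open(path + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_heightmap(path) -> HeightMap:
    path = str(path)
    try:
        with open(path + ".yaml") as fh:
            sidecar = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise SurfaceValidationError(f"missing sidecar {path}.yaml") from exc
    spacing = float(sidecar["spacing_mm"])
    if spacing <= 0:
        raise SurfaceValidationError(f"sidecar spacing must be > 0, got {spacing}")
    grid = np.loadtxt(path, delimiter=",", ndmin=2)
    origin = tuple(sidecar.get("origin_mm", (0.0, 0.0)))
    return HeightMap(grid, spacing, origin=origin, meta=sidecar.get("meta", {}))


def write_xyz(hmap: HeightMap, path) -> None:
    """Write unmasked cells as 3-column XYZ text (mm)."""
    x, y = hmap.coords()
    m = hmap.mask
    np.savetxt(
        str(path),
        np.column_stack([x[m], y[m], hmap.heights[m]]),
        fmt="%.9g",
        header="x_mm y_mm z_mm",
    )


def read_xyz(path, spacing: float | None = None) -> HeightMap:
    """Read 3-column XYZ text sampled on a regular grid.

    The lateral spacing is inferred from the point cloud when not given;
    grid cells without a point are masked.
    """
    pts = np.loadtxt(str(path), ndmin=2)
    if pts.shape[1] < 3 or pts.shape[0] < 4:
        raise SurfaceValidationError("XYZ file needs >= 4 rows of x y z")
    xs, ys, zs = pts[:, 0], pts[:, 1], pts[:, 2]
    if spacing is None:
        ux = np.diff(np.unique(np.round(xs, 9)))
        spacing = float(np.min(ux[ux > 0])) if ux.size else 1.0
    cols = np.round((xs - xs.min()) / spacing).astype(int)
    rows = np.round((ys - ys.min()) / spacing).astype(int)
    if np.abs(cols * spacing - (xs - xs.min())).max() > 0.25 * spacing:
        raise SurfaceValidationError("points do not lie on a regular grid")
    grid = np.full((rows.max() + 1, cols.max() + 1), np.nan)
    grid[rows, cols] = zs
    return HeightMap(grid, spacing, origin=(float(xs.min()), float(ys.min())),
                     meta={"source": "xyz"})


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Pre-treatment
# ---------------------------------------------------------------------------

def _poly_basis(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, list]:
    """Vandermonde basis of all monomials x^i y^j with total degree <= degree."""
    terms = [(i, j) for i, j in itertools.product(range(degree + 1), repeat=2) if i + j <= degree]
    terms.sort(key=lambda t: (t[0] + t[1], t[0]))
    cols = [x**i * y**j for i, j in terms]
    return np.stack(cols, axis=-1), terms


def _fit_subtract(hmap: HeightMap, degree: int, step: str) -> HeightMap:
    x, y = hmap.coords()
    m = hmap.mask
    n_terms = (degree + 1) * (degree + 2) // 2
    if m.sum() < n_terms:
        raise SurfaceValidationError(
            f"{step}: {int(m.sum())} valid cells cannot support a degree-{degree} fit"
        )
    # centre+scale coordinates for conditioning; the fitted subspace is identical
    xs = (x - x[m].mean()) / max(x[m].std(), 1e-12)
    ys = (y - y[m].mean()) / max(y[m].std(), 1e-12)
    A, _ = _poly_basis(xs[m], ys[m], degree)
    coef, _, rank, _ = np.linalg.lstsq(A, hmap.heights[m], rcond=None)
    if rank < A.shape[1]:
        raise SurfaceValidationError(f"{step}: rank-deficient design (rank {rank} < {A.shape[1]})")
    full, _ = _poly_basis(xs, ys, degree)
    out = hmap.copy()
    out.heights = hmap.heights - full @ coef
    out.heights[~out.mask] = np.nan
    return out.with_provenance(step, degree=degree)


def level_surface(hmap: HeightMap) -> HeightMap:
    """Subtract the ordinary-least-squares plane fitted on unmasked cells.

    Residuals are orthogonal to {1, x, y}; applying the operator twice is a
    no-op to numerical precision.
    """
    return _fit_subtract(hmap, 1, "level_surface")


def remove_form(hmap: HeightMap, degree: int = 3) -> HeightMap:
    """Subtract the least-squares polynomial of total degree <= ``degree``.

    ``degree=3`` (10 monomials) is the conventional F-operator used to strip
    the large-scale shape of the sample before roughness analysis;
    ``degree=0`` reduces to mean-centring.
    """
    if degree < 0:
        raise SurfaceValidationError("degree must be >= 0")
    return _fit_subtract(hmap, degree, "remove_form")


def subdivide(
    hmap: HeightMap,
    tile_mm: float = 10.0,
    n: int = 9,
    layout: str = "centred",
    worked_mask: np.ndarray | None = None,
) -> list[SubArea]:
    """Tile a map into ``n`` non-overlapping square sub-areas.

    The default layout centres a near-square r x c grid of tiles (3 x 3 for
    n=9) on the map. ``worked_mask`` (bool, parent-shaped) optionally flags
    which tiles contain worked surface: a tile is worked when more than half
    of its cells are flagged.
    """
    if tile_mm <= 0 or n < 1:
        raise SurfaceValidationError("tile size and count must be positive")
    t = int(round(tile_mm / hmap.spacing))
    nr, nc = hmap.shape
    rows = int(np.floor(np.sqrt(n)))
    while n % rows:
        rows -= 1
    cols = n // rows
    if rows * t > nr or cols * t > nc:
        feas = (nr // t) * (nc // t)
        raise SurfaceValidationError(
            f"map {hmap.extent_mm} mm too small for {rows}x{cols} tiles of {tile_mm} mm; "
            f"at most {feas} such tiles fit"
        )
    r_off = (nr - rows * t) // 2
    c_off = (nc - cols * t) // 2
    tiles = []
    for i in range(rows):
        for j in range(cols):
            win = (r_off + i * t, c_off + j * t, t, t)
            worked = True
            if worked_mask is not None:
                r0, c0, h, w = win
                worked = bool(worked_mask[r0 : r0 + h, c0 : c0 + w].mean() > 0.5)
            tiles.append(SubArea(hmap, win, worked=worked))
    return tiles


def pretreat(hmap: HeightMap, form_degree: int = 3) -> HeightMap:
    """Level then remove form: the per-sub-area standard chain."""
    return remove_form(level_surface(hmap), degree=form_degree)
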