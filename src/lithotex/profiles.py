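"""Engraving cross-section morphometrics.

A :class:`ProfileTrace` is a 2-D cross-section of an incision: x along the
section line (mm, strictly increasing), z the surface height (mm), with the
reference surface at z = 0 after levelling. From the landmark set (apex,
shoulders, depth-convergent wall points) four measurements are derived:

* ``D``   - profile depth (um), reference level minus apex height;
* ``WIS`` - width of the incision at the surface (um), between shoulders;
* ``theta`` - opening angle (deg) at the apex between the shoulder vectors;
* ``A``   - reflection asymmetry: mean horizontal distance between the
  left wall reflected about the vertical through the apex and the right
  wall, over 20 evenly spaced depth fractions (mm; an arbitrary-unit
  score in comparisons).

The wall polyline closed by the shoulder-to-shoulder segment feeds the
elliptic Fourier shape analysis in :mod:`lithotex.efa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .heightmap import HeightMap

MM_TO_UM = 1000.0


class ProfileError(ValueError):
    pass


@dataclass
class ProfileTrace:
    x: np.ndarray  # mm, strictly increasing
    z: np.ndarray  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.z = np.asarray(self.z, float)
        if self.x.size != self.z.size or self.x.size < 20:
            raise ProfileError("trace needs >= 20 aligned samples")
        if not np.all(np.diff(self.x) > 0):
            raise ProfileError("x must be strictly increasing")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.x)))


@dataclass
class ProfileLandmarks:
    apex: int
    left_shoulder: float  # interpolated x (mm)
    right_shoulder: float
    ldc: tuple[float, float]  # (x, z) left depth-convergent point
    rdc: tuple[float, float]
    reference_z: float
    shoulders_truncated: bool = False


@dataclass
class EngravingMeasurements:
    D_um: float
    WIS_um: float
    theta_deg: float
    A: float  # reflected-wall score (mm)
    set_label: str | None = None
    shallow: bool = False


def extract_profile(hmap: HeightMap, p0, p1, oversample: float = 1.0) -> ProfileTrace:
    """Bilinear sampling of map heights along the section line p0 -> p1 (mm)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(round(length / hmap.spacing * oversample)) + 1, 20)
    ts = np.linspace(0.0, 1.0, n)
    xs = p0[0] + ts * (p1[0] - p0[0])
    ys = p0[1] + ts * (p1[1] - p0[1])
    cols = (xs - hmap.origin[0]) / hmap.spacing
    rows = (ys - hmap.origin[1]) / hmap.spacing
    z = np.where(hmap.mask, hmap.heights, np.nan)
    vals = map_coordinates(z, [rows, cols], order=1, cval=np.nan)
    if not np.isfinite(vals).all():
        raise ProfileError("section line exits the unmasked region")
    return ProfileTrace(ts * length, vals, meta={"p0": tuple(p0), "p1": tuple(p1)})


def _cross_x(x0, z0, x1, z1, target):
    """x where the segment (x0,z0)-(x1,z1) crosses z = target."""
    if z1 == z0:
        return x0
    return x0 + (target - z0) / (z1 - z0) * (x1 - x0)


def detect_landmarks(
    trace: ProfileTrace,
    reference_z: float = 0.0,
    depth_fraction: float = 0.9,
    dominance_ratio: float = 2.0,
) -> ProfileLandmarks:
    """Apex, surface shoulders and depth-convergent wall points.

    The apex is the global minimum (flat-bottom ties resolve to the middle
    of the minimal plateau). Shoulders are the nearest crossings of the
    reference surface on each side (trace ends, flagged, when no crossing
    exists). A trace containing a second trough deeper than
    ``D / dominance_ratio`` separated from the main one is rejected.
    """
    z, x = trace.z, trace.x
    zmin = z.min()
    depth = reference_z - zmin
    if depth <= 0:
        raise ProfileError("no trough below the reference surface")
    # minimal plateau containing the argmin; apex = its midpoint
    tol = 1e-12 + 1e-9 * abs(depth)
    is_flat = z <= zmin + tol
    i0 = int(np.argmin(z))
    lo = i0
    while lo > 0 and is_flat[lo - 1]:
        lo -= 1
    hi = i0
    while hi < z.size - 1 and is_flat[hi + 1]:
        hi += 1
    apex = (lo + hi) // 2

    # secondary-trough dominance check: a local minimum counts as a separate
    # trough only when the ridge between it and the apex rises at least half
    # the main depth above it
    interior = z[1:-1]
    mins = np.flatnonzero((interior <= z[:-2]) & (interior <= z[2:])) + 1
    worst = 0.0
    for i in mins:
        if lo <= i <= hi:
            continue
        a, b = (i, lo) if i < lo else (hi, i)
        barrier = z[a : b + 1].max()
        if barrier - z[i] > 0.5 * depth:
            worst = max(worst, reference_z - z[i])
    if worst > depth / dominance_ratio:
        raise ProfileError(
            f"secondary trough of depth {worst:.3g} violates dominance ratio {dominance_ratio}"
        )

    truncated = False
    left = None
    for j in range(apex, 0, -1):
        if z[j - 1] >= reference_z:
            left = _cross_x(x[j], z[j], x[j - 1], z[j - 1], reference_z)
            break
    if left is None:
        left, truncated = float(x[0]), True
    right = None
    for j in range(apex, z.size - 1):
        if z[j + 1] >= reference_z:
            right = _cross_x(x[j], z[j], x[j + 1], z[j + 1], reference_z)
            break
    if right is None:
        right, truncated = float(x[-1]), True

    z_dc = reference_z - depth_fraction * depth
    ldc = _wall_point(trace, apex, z_dc, side=-1)
    rdc = _wall_point(trace, apex, z_dc, side=+1)
    return ProfileLandmarks(
        apex=int(apex),
        left_shoulder=float(left),
        right_shoulder=float(right),
        ldc=ldc,
        rdc=rdc,
        reference_z=reference_z,
        shoulders_truncated=truncated,
    )


def _wall_point(trace: ProfileTrace, apex: int, z_target: float, side: int) -> tuple[float, float]:
    """First crossing of z_target walking from the apex outward."""
    x, z = trace.x, trace.z
    rng = range(apex, 0, -1) if side < 0 else range(apex, z.size - 1)
    for j in rng:
        k = j - 1 if side < 0 else j + 1
        if (z[j] - z_target) * (z[k] - z_target) <= 0 and z[k] >= z_target:
            return (float(_cross_x(x[j], z[j], x[k], z[k], z_target)), float(z_target))
    edge = 0 if side < 0 else z.size - 1
    return (float(x[edge]), float(z[edge]))


def measure_profile(
    trace: ProfileTrace,
    lm: ProfileLandmarks,
    n_fractions: int = 20,
    set_label: str | None = None,
) -> EngravingMeasurements:
    """D, WIS, opening angle and reflection asymmetry from landmarks."""
    x, z = trace.x, trace.z
    ref = lm.reference_z
    depth = ref - z[lm.apex]
    wis = lm.right_shoulder - lm.left_shoulder
    xa = x[lm.apex]
    v_l = np.array([lm.left_shoulder - xa, ref - z[lm.apex]])
    v_r = np.array([lm.right_shoulder - xa, ref - z[lm.apex]])
    cosang = np.dot(v_l, v_r) / (np.linalg.norm(v_l) * np.linalg.norm(v_r))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    fracs = np.arange(1, n_fractions + 1) / (n_fractions + 1)
    diffs = []
    for f in fracs:
        zt = ref - f * depth
        xl, _ = _wall_point(trace, lm.apex, zt, side=-1)
        xr, _ = _wall_point(trace, lm.apex, zt, side=+1)
        diffs.append(abs((2 * xa - xl) - xr))
    return EngravingMeasurements(
        D_um=float(depth * MM_TO_UM),
        WIS_um=float(wis * MM_TO_UM),
        theta_deg=theta,
        A=float(np.mean(diffs)),
        set_label=set_label,
        shallow=depth < 3 * trace.spacing,
    )


def close_outline(trace: ProfileTrace, lm: ProfileLandmarks, n_points: int = 256) -> np.ndarray:
    """Close the incision walls into a counter-clockwise outline.

    The wall polyline left shoulder -> apex -> right shoulder is closed by
    the straight shoulder-to-shoulder segment and resampled to ``n_points``
    equally spaced points starting at the left shoulder.
    """
    x, z = trace.x, trace.z
    ref = lm.reference_z
    inside = (x > lm.left_shoulder) & (x < lm.right_shoulder)
    wall = np.column_stack([x[inside], z[inside]])
    pts = np.vstack(
        [
            [lm.left_shoulder, ref],
            wall,
            [lm.right_shoulder, ref],
        ]
    )
    poly = Polygon(pts)
    if not poly.is_valid:
        raise ProfileError("self-intersecting outline")
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    # enforce counter-clockwise orientation (positive shoelace area)
    area = 0.5 * np.sum(out[:, 0] * np.roll(out[:, 1], -1) - np.roll(out[:, 0], -1) * out[:, 1])
    if area < 0:
        out = np.vstack([out[:1], out[1:][::-1]])
    return out


def allometry_check(
    shape_variables: np.ndarray,
    centroid_sizes: np.ndarray,
    alpha: float = 0.003,
):
    """Regress each shape variable on log centroid size (isometry check).

    Returns a DataFrame of slopes and Holm-adjusted p-values plus an
    ``isometric`` verdict (True when no adjusted p falls below ``alpha``).
    Requires at least 10 profiles; constant sizes are rejected.
    """
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    X = np.asarray(shape_variables, float)
    sizes = np.asarray(centroid_sizes, float)
    if X.shape[0] != sizes.size or X.shape[0] < 10:
        raise ProfileError("allometry check requires >= 10 profiles")
    if np.ptp(sizes) <= 0:
        raise ProfileError("centroid sizes are constant; allometry undefined")
    logs = sm.add_constant(np.log(sizes))
    slopes, pvals = [], []
    for j in range(X.shape[1]):
        fit = sm.OLS(X[:, j], logs).fit()
        slopes.append(fit.params[1])
        pvals.append(fit.pvalues[1])
    adj = multipletests(pvals, alpha=alpha, method="holm")[1]
    table = pd.DataFrame(
        {"variable": np.arange(X.shape[1]), "slope": slopes, "p_value": pvals, "p_adjusted": adj}
    )
    table.attrs["isometric"] = bool((adj >= alpha).all())
    return table
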