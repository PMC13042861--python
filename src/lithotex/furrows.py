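"""Furrow-network extraction and texture-direction analysis.

Furrows are the valley-line network of the surface: cells that form a
transverse minimum of the (lightly smoothed) relief and lie deeper than a
noise floor below their local rim, thinned to a one-cell skeleton.
Reported are the maximum and length-weighted mean furrow depth (mm, depth
below the local rim) and the mean furrow density (cm/cm^2).

Texture direction integrates 2-D FFT power over radial frequency per
angular bin. Directions are axial (invariant under +180 deg) and reported
on [0, 180) using the groove-normal convention: a set of parallel grooves
running along 30 deg yields a dominant direction of 30 deg. Isotropy is
100 x mean/max bin power, so a flat spectrum scores 100% and a single
orientation scores near 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, gaussian_filter, map_coordinates, maximum_filter
from skimage.morphology import skeletonize

from .areal import segment_features
from .heightmap import HeightMap

# half-sum of distances to 8-neighbours turns a skeleton pixel count into a
# polyline length (exact for straight chains, slight overcount at junctions)
_NEIGH_KERNEL = np.array(
    [[np.sqrt(2), 1, np.sqrt(2)], [1, 0, 1], [np.sqrt(2), 1, np.sqrt(2)]]
)


@dataclass
class FurrowNetwork:
    skeleton: np.ndarray  # bool grid
    depth: np.ndarray  # mm below rim, 0 off-skeleton
    length_weight: np.ndarray  # local length contribution (mm) per pixel
    total_length_mm: float
    area_mm2: float


def detect_furrows(
    hmap: HeightMap,
    min_depth_mm: float = 0.008,
    rim_window_mm: float = 0.15,
    depth_window_mm: float = 0.5,
) -> FurrowNetwork:
    """Extract the watercourse (valley-line) network of a levelled map.

    A cell is a watercourse vertex when, across at least one of the four
    grid directions, it is a strict transverse minimum AND the surface
    rises by at least ``min_depth_mm`` on BOTH sides within
    ``rim_window_mm``. The two-sided rim makes the criterion a true
    valley test: points on an open slope (e.g. an impact-crater wall)
    have no uphill rim on one side and are rejected, while an isolated
    groove and each striation of a dense crossing field both qualify.
    The depth floor (default 8 um, a few times a structured-light
    scanner's noise amplitude) rejects undulations indistinguishable from
    measurement noise. Candidates are thinned to a one-cell skeleton
    whose vertices carry the two-sided valley depth.
    """
    z0 = np.where(hmap.mask, hmap.heights, np.nan)
    fill = np.nanmean(z0) if np.isfinite(z0).any() else 0.0
    zr = np.where(np.isfinite(z0), z0, fill)  # raw heights for depth readout
    z = gaussian_filter(zr, 1.5)
    area = float(hmap.mask.sum()) * hmap.spacing**2
    w = max(int(round(rim_window_mm / hmap.spacing)), 1)
    w2 = max(int(round(depth_window_mm / hmap.spacing)), w)
    furrow_px = np.zeros(hmap.shape, dtype=bool)
    depth_best = np.zeros(hmap.shape)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        fwd = np.full(z.shape, -np.inf)
        bwd = np.full(z.shape, -np.inf)
        fwd2 = np.full(z.shape, -np.inf)
        bwd2 = np.full(z.shape, -np.inf)
        for k in range(1, w2 + 1):
            if k <= w:
                fwd = np.maximum(fwd, np.roll(np.roll(z, k * dr, axis=0), k * dc, axis=1))
                bwd = np.maximum(bwd, np.roll(np.roll(z, -k * dr, axis=0), -k * dc, axis=1))
            fwd2 = np.maximum(fwd2, np.roll(np.roll(zr, k * dr, axis=0), k * dc, axis=1))
            bwd2 = np.maximum(bwd2, np.roll(np.roll(zr, -k * dr, axis=0), -k * dc, axis=1))
        is_min = (z < np.roll(np.roll(z, dr, axis=0), dc, axis=1)) & (
            z < np.roll(np.roll(z, -dr, axis=0), -dc, axis=1)
        )
        depth_d = np.minimum(fwd, bwd) - z  # valley depth: rim on both sides
        hit = is_min & (depth_d >= min_depth_mm)
        furrow_px |= hit
        depth_wide = np.minimum(fwd2, bwd2) - zr
        depth_best = np.where(hit & (depth_wide > depth_best), depth_wide, depth_best)
    furrow_px &= hmap.mask
    # rolls wrap at the map border; discard the outermost window ring
    furrow_px[:w, :] = furrow_px[-w:, :] = False
    furrow_px[:, :w] = furrow_px[:, -w:] = False
    if not furrow_px.any():
        empty = np.zeros(hmap.shape)
        return FurrowNetwork(furrow_px, empty, empty, 0.0, area)
    skel = skeletonize(furrow_px)
    weight = np.where(skel, convolve(skel.astype(float), _NEIGH_KERNEL, mode="constant"), 0.0)
    weight *= 0.5 * hmap.spacing
    depth_on = np.where(skel, depth_best, 0.0)
    return FurrowNetwork(skel, depth_on, weight, float(weight.sum()), area)


def furrow_params(net: FurrowNetwork) -> dict:
    """max depth (mm), length-weighted mean depth (mm), density (cm/cm^2)."""
    if net.total_length_mm == 0.0 or not net.skeleton.any():
        return {"furrow_max_depth": 0.0, "furrow_mean_depth": 0.0, "furrow_density": 0.0, "empty": True}
    d = net.depth[net.skeleton]
    w = net.length_weight[net.skeleton]
    mean_depth = float(np.average(d, weights=w)) if w.sum() > 0 else float(d.mean())
    density_mm = net.total_length_mm / net.area_mm2  # mm / mm^2
    return {
        "furrow_max_depth": float(d.max()),
        "furrow_mean_depth": mean_depth,
        "furrow_density": density_mm * 10.0,  # cm/cm^2
        "empty": False,
    }


# ---------------------------------------------------------------------------
# Texture direction
# ---------------------------------------------------------------------------

@dataclass
class DirectionSpectrum:
    angles_deg: np.ndarray  # bin centres on [0, 180)
    power: np.ndarray  # normalized, sums to 1

    def __post_init__(self):
        tot = self.power.sum()
        if tot > 0:
            self.power = self.power / tot


def direction_spectrum(hmap: HeightMap, bin_deg: float = 1.0) -> DirectionSpectrum:
    """Angular power spectrum of the surface, folded to [0, 180).

    A Hann window suppresses spectral leakage from the non-periodic
    boundary; DC is excluded. The reported angle of a frequency component
    is perpendicular to its wave vector, i.e. the direction the texture
    ridges run along.
    """
    z = hmap.heights.copy()
    mu = z[hmap.mask].mean() if hmap.mask.any() else 0.0
    z[~hmap.mask] = mu
    z = z - mu
    nr, nc = z.shape
    win = np.outer(np.hanning(nr), np.hanning(nc))
    F = np.fft.fftshift(np.abs(np.fft.fft2(z * win)) ** 2)
    cy, cx = nr // 2, nc // 2
    # resample onto a polar grid and integrate over radial frequency; the
    # interpolation spreads sparsely sampled low frequencies smoothly over
    # neighbouring angular bins instead of dumping them into single bins
    nbins = int(round(180.0 / bin_deg))
    theta = np.arange(nbins) * bin_deg  # texture direction of each bin
    phi = np.deg2rad(theta - 90.0)  # wave-vector angle (normal to ridges)
    rmax = min(nr, nc) // 2 - 1
    radii = np.arange(1.0, rmax)
    rows = cy + radii[:, None] * np.sin(phi)[None, :]
    cols = cx + radii[:, None] * np.cos(phi)[None, :]
    vals = map_coordinates(F, [rows.ravel(), cols.ravel()], order=1).reshape(rows.shape)
    power = (vals * radii[:, None]).sum(axis=0)  # annular weight ~ r
    return DirectionSpectrum(theta, power)


@dataclass
class TextureDirections:
    isotropy_pct: float
    first_direction: float
    second_direction: float
    third_direction: float
    unstable: bool = False


def texture_direction_params(
    spec: DirectionSpectrum, smooth_deg: float = 3.0, min_separation_deg: float = 10.0
) -> TextureDirections:
    """Isotropy (%) and the three strongest non-adjacent direction peaks.

    Isotropy = 100 x mean/max of the (lightly circularly smoothed) bin
    powers: flat spectrum -> 100, single line -> near 0. Fewer than three
    local maxima leave the missing directions as NaN; isotropy above 95%
    flags the directions as unstable.
    """
    p = spec.power
    n = p.size
    bin_w = 180.0 / n
    k = max(int(round(smooth_deg / bin_w)), 1)
    kernel = np.ones(2 * k + 1) / (2 * k + 1)
    ps = np.convolve(np.concatenate([p[-k:], p, p[:k]]), kernel, mode="same")[k:-k]
    iso = 100.0 * float(ps.mean() / ps.max()) if ps.max() > 0 else 100.0
    # circular local maxima
    left = np.roll(ps, 1)
    right = np.roll(ps, -1)
    is_max = (ps >= left) & (ps >= right)
    order = np.argsort(ps[is_max])[::-1]
    cand = np.flatnonzero(is_max)[order]
    sep = int(round(min_separation_deg / bin_w))
    chosen: list[int] = []
    for idx in cand:
        if all(min(abs(idx - j), n - abs(idx - j)) >= sep for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == 3:
            break
    dirs = [spec.angles_deg[j] for j in chosen] + [np.nan] * (3 - len(chosen))
    return TextureDirections(
        isotropy_pct=iso,
        first_direction=float(dirs[0]),
        second_direction=float(dirs[1]),
        third_direction=float(dirs[2]),
        unstable=iso > 95.0,
    )
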