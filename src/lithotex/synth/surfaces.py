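"""Synthetic worked-stone surfaces.

Generates height maps with the statistical structure of experimentally
carved coarse bioclastic limestone: a self-affine substrate with pore
depressions, onto which technique operators act. Every operator only
removes material (pointwise non-increasing heights); marks are subtracted
imprints or truncations by a moving tool envelope, mirroring how later
gestures obliterate earlier marks rather than adding relief.

Technique models (all length units mm):

* sawing     - parallel sinusoidal grooves (the extraction marks of
               control surfaces), strictly oriented.
* pecking    - ellipsoidal-cap craters (comet-shaped for picks, round for
               cobbles); orientation von Mises around the gesture
               direction, dispersion set by skill; per-crater size/depth
               scatter and intra-crater fracture chatter grow as skill
               drops.
* scraping   - long shallow parabolic striations with small angular
               jitter plus periodic peak truncation by a smoothed tool
               envelope, so repeated passes homogenize the relief.
* polishing  - iterated peak truncation toward a smooth envelope plus
               dense fine multi-directional striations whose depth tracks
               the polishing medium (cobble > sand > skin).
* engraving  - a V-shaped channel cut along a path; multiple strokes
               superpose laterally jittered cuts, widening the groove and
               reducing its asymmetry.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..heightmap import HeightMap, SurfaceValidationError
from .tools import SkillLevel, ToolProfile, ModalitySpec, StudyDesign, TECHNIQUE_CLASS

# event rates mapping time budgets to mark counts (per cm^2 per minute);
# calibration choices documented in the methods note
PECK_RATE = 6.0
SCRAPE_RATE = 9.0
POLISH_STRIATION_RATE = 80.0


@dataclass
class GeneratorConfig:
    """Substrate parameters emulating a coarse bioclastic limestone square."""

    size_mm: tuple[float, float] = (10.0, 10.0)
    spacing: float = 0.025
    substrate_hurst: float = 0.8
    substrate_rms: float = 0.008
    pore_density: float = 2.0  # 1/mm^2
    pore_radius: float = 0.12  # mm
    pore_depth: float = 0.02  # mm
    noise_rms: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0 or min(self.size_mm) <= 0:
            raise SurfaceValidationError("non-positive dimensions")
        if not 0 < self.substrate_hurst < 1:
            raise SurfaceValidationError("Hurst exponent must be in (0, 1)")
        if self.noise_rms < 0 or (self.substrate_rms > 0 and self.substrate_rms <= self.noise_rms):
            raise SurfaceValidationError("need substrate_rms > noise_rms >= 0")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_base_substrate(cfg: GeneratorConfig, seed: int | None = None) -> HeightMap:
    """Spectral-synthesis self-affine relief plus pore depressions.

    The fractional-surface field has isotropic power spectrum
    ``S(f) ~ f^(-2-2H)`` and is rescaled to exactly ``substrate_rms``;
    pores (spherical-cap pits) model the bioclastic porosity. With
    ``substrate_rms = 0`` the substrate is flat (no relief, no pores) and
    only the measurement noise floor remains.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    ny = int(round(cfg.size_mm[1] / cfg.spacing))
    nx = int(round(cfg.size_mm[0] / cfg.spacing))
    z = np.zeros((ny, nx))
    if cfg.substrate_rms > 0:
        noise = rng.standard_normal((ny, nx))
        fy = np.fft.fftfreq(ny)[:, None]
        fx = np.fft.fftfreq(nx)[None, :]
        f = np.hypot(fy, fx)
        f[0, 0] = np.inf  # kill DC
        amp = f ** (-(1.0 + cfg.substrate_hurst))
        z = np.real(np.fft.ifft2(np.fft.fft2(noise) * amp))
        z *= cfg.substrate_rms / max(z.std(), 1e-30)
        # pores
        area = cfg.size_mm[0] * cfg.size_mm[1]
        n_pores = rng.poisson(cfg.pore_density * area)
        for _ in range(n_pores):
            cx = rng.uniform(0, cfg.size_mm[0])
            cy = rng.uniform(0, cfg.size_mm[1])
            r = cfg.pore_radius * rng.lognormal(0.0, 0.3)
            d = cfg.pore_depth * rng.lognormal(0.0, 0.3)
            _stamp_cap(z, cfg.spacing, cx, cy, r, r, d, 0.0)
    if cfg.noise_rms > 0:
        z = z + rng.normal(0.0, cfg.noise_rms, z.shape)
    return HeightMap(
        z,
        cfg.spacing,
        meta={"provenance": [{"step": "substrate", "hurst": cfg.substrate_hurst, "rms": cfg.substrate_rms}]},
    )


def _stamp_cap(z, spacing, cx, cy, rx, ry, depth, angle_deg, chatter_rms=0.0, rng=None):
    """Subtract an ellipsoidal-cap depression in place; returns nothing."""
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    pad = max(rx, ry)
    j0 = max(int((cx - pad) / spacing) - 1, 0)
    j1 = min(int((cx + pad) / spacing) + 2, z.shape[1])
    i0 = max(int((cy - pad) / spacing) - 1, 0)
    i1 = min(int((cy + pad) / spacing) + 2, z.shape[0])
    if j1 <= j0 or i1 <= i0:
        return
    xs = np.arange(j0, j1) * spacing - cx
    ys = np.arange(i0, i1) * spacing - cy
    X, Y = np.meshgrid(xs, ys)
    u = c * X + s * Y
    v = -s * X + c * Y
    q2 = (u / rx) ** 2 + (v / ry) ** 2
    inside = q2 < 1.0
    cap = np.zeros_like(X)
    cap[inside] = depth * np.sqrt(1.0 - q2[inside])
    if chatter_rms > 0 and rng is not None and inside.any():
        rough = np.abs(rng.normal(0.0, chatter_rms, X.shape))
        rough = gaussian_filter(rough, 2.0)
        cap[inside] += rough[inside]
    z[i0:i1, j0:j1] -= cap


def apply_sawing(
    hmap: HeightMap,
    orientation_deg: float = 0.0,
    groove_amplitude: float = 0.01,
    period: float = 1.0,
) -> HeightMap:
    """Parallel sinusoidal saw grooves running along ``orientation_deg``."""
    if period <= 2 * hmap.spacing:
        raise SurfaceValidationError(
            f"period {period} mm aliases at spacing {hmap.spacing} mm"
        )
    out = hmap.copy()
    if groove_amplitude > 0:
        x, y = hmap.coords()
        th = np.deg2rad(orientation_deg)
        u = -x * np.sin(th) + y * np.cos(th)  # axis perpendicular to grooves
        out.heights = out.heights - groove_amplitude * 0.5 * (1.0 + np.sin(2 * np.pi * u / period))
    return out.with_provenance("saw", orientation=orientation_deg, amplitude=groove_amplitude, period=period)


def apply_pecking(
    hmap: HeightMap,
    tool: ToolProfile,
    skill: SkillLevel,
    budget_min: float = 5.0,
    rate: float = PECK_RATE,
    seed: int = 0,
    orientation_mean_deg: float | None = None,
    indirect: bool = False,
) -> HeightMap:
    """Subtract ellipsoidal-cap impact craters.

    Crater orientations are von Mises around the gesture direction with
    concentration 2x the skill kappa (impacts align strongly with the hand
    position); sizes and depths scatter log-normally with sigma equal to
    the skill's spacing CV, and intra-crater fracture chatter grows with
    that CV. Indirect percussion enlarges and elongates the marks.
    """
    if tool.contact_kind not in {"point", "cobble"}:
        raise SurfaceValidationError(f"{tool.name} cannot peck (contact {tool.contact_kind})")
    rng = _rng(seed)
    out = hmap.copy()
    area_cm2 = hmap.extent_mm[0] * hmap.extent_mm[1] / 100.0
    n = int(round(budget_min * rate * area_cm2))
    if n == 0:
        if rate == 0:
            warnings.warn("zero pecking rate: map unchanged", stacklevel=2)
        return out.with_provenance("peck", n_craters=0)
    if orientation_mean_deg is None:
        orientation_mean_deg = rng.uniform(0.0, 180.0)
    w, h = hmap.extent_mm
    scale = 1.4 if indirect else 1.0
    ecc = tool.imprint_eccentricity * (1.25 if indirect else 1.0)
    # impacts are organized in working sweeps: rows of blows along the
    # gesture direction; row directions drift with low skill kappa, impact
    # spacing within a row scatters with the skill CV
    sigma = skill.spacing_cv
    r_mean = tool.imprint_radius_mean * scale
    row_spacing = 2.0 * r_mean
    step_mean = 1.45 * r_mean * ecc
    diag = np.hypot(w, h)
    th0 = np.deg2rad(orientation_mean_deg)
    u_hat = np.array([np.cos(th0), np.sin(th0)])
    v_hat = np.array([-np.sin(th0), np.cos(th0)])
    centre = np.array([w / 2, h / 2])
    impacts = []  # (cx, cy, orientation_deg)
    v0 = rng.uniform(0, row_spacing)
    k = 0
    while len(impacts) < 3 * n and k * row_spacing < 1.2 * diag:
        for sgn in (1, -1) if k else (1,):
            v = sgn * (v0 + k * row_spacing) - row_spacing
            row_dir = (orientation_mean_deg
                       + np.degrees(rng.vonmises(0.0, max(3.0 * skill.gesture_concentration, 1e-6))) / 2.0)
            s = -0.6 * diag + rng.uniform(0, step_mean)
            while s < 0.6 * diag:
                p = centre + s * u_hat + v * v_hat
                if -r_mean < p[0] < w + r_mean and -r_mean < p[1] < h + r_mean:
                    impacts.append((p[0], p[1], row_dir % 180.0))
                s += step_mean * rng.lognormal(-sigma**2 / 2, sigma)
        k += 1
    rng.shuffle(impacts)
    impacts = impacts[:n]
    # low coverage uniformity: some blows land clustered instead of on-row
    n_clustered = int(round(0.5 * (1.0 - skill.coverage_uniformity) * len(impacts)))
    centres_cl = rng.uniform([0, 0], [w, h], size=(max(n_clustered // 8, 1), 2))
    orientations = []
    for i, (cx, cy, ang) in enumerate(impacts):
        if i < n_clustered:
            cx, cy = rng.normal(centres_cl[rng.integers(len(centres_cl))], 1.0)
            ang = (orientation_mean_deg
                   + np.degrees(rng.vonmises(0.0, max(skill.gesture_concentration, 1e-6))) / 2.0) % 180.0
        r = r_mean * rng.lognormal(-sigma**2 / 2, sigma)
        d = tool.imprint_depth_mean * rng.lognormal(-sigma**2 / 2, sigma)
        chatter = 0.3 * tool.imprint_depth_mean * sigma
        _stamp_cap(out.heights, hmap.spacing, cx, cy, r * ecc, r, d, ang, chatter_rms=chatter, rng=rng)
        orientations.append(float(ang))
        # unskilled blows glance off, leaving small sharp secondary nicks
        if rng.uniform() < sigma:
            nx_, ny_ = rng.normal((cx, cy), r_mean)
            _stamp_cap(out.heights, hmap.spacing, nx_, ny_, 0.3 * r_mean, 0.2 * r_mean,
                       0.4 * d, rng.uniform(0, 180.0), chatter_rms=chatter, rng=rng)
    res = out.with_provenance("peck", tool=tool.name, n_craters=n, indirect=indirect)
    res.meta["crater_orientations_deg"] = orientations
    return res


def _stamp_groove(z, spacing, point, angle_deg, depth, half_width, modulation=None, ref=None):
    """Cut a parabolic-section groove along the full line through ``point``
    at ``angle_deg``; optional along-stroke depth modulation (callable of
    arc position in mm).

    With ``ref`` (a smoothed surface the tool rides on), material is
    removed down to ``ref - profile`` — overlapping strokes re-cut the
    same groove instead of stacking, as a real tool edge does. Without
    ``ref`` the profile is subtracted outright (single indentation).
    """
    ny, nx = z.shape
    x = np.arange(nx)[None, :] * spacing
    y = np.arange(ny)[:, None] * spacing
    th = np.deg2rad(angle_deg)
    nvec = (-np.sin(th), np.cos(th))
    dist = (x - point[0]) * nvec[0] + (y - point[1]) * nvec[1]
    inside = np.abs(dist) < half_width
    if not inside.any():
        return
    prof = depth * (1.0 - (dist[inside] / half_width) ** 2)
    if modulation is not None:
        s = (x - point[0]) * np.cos(th) + (y - point[1]) * np.sin(th)
        prof = prof * modulation(s[inside])
    if ref is None:
        z[inside] -= prof
    else:
        z[inside] = np.minimum(z[inside], ref[inside] - prof)


def _truncate_peaks(z, spacing, sigma_mm, clearance=0.0):
    env = gaussian_filter(z, sigma_mm / spacing) + clearance
    np.minimum(z, env, out=z)


def apply_scraping(
    hmap: HeightMap,
    tool: ToolProfile,
    skill: SkillLevel,
    budget_min: float = 5.0,
    rate: float = SCRAPE_RATE,
    seed: int = 0,
    orientation_mean_deg: float | None = None,
    cross_fraction: float = 0.45,
) -> HeightMap:
    """Long sub-parallel striations plus peak truncation.

    Strokes follow the gesture direction with von Mises jitter; a fraction
    is crossed at ~60 deg (returning passes). Every fifth of the stroke
    budget the surface peaks are truncated against a smoothed tool
    envelope, so repeated passes homogenize the relief. Stick-slip depth
    modulation along the stroke keeps striations finite-coherence.
    """
    if tool.contact_kind != "edge":
        raise SurfaceValidationError(f"{tool.name} cannot scrape (contact {tool.contact_kind})")
    rng = _rng(seed)
    out = hmap.copy()
    area_cm2 = out.extent_mm[0] * out.extent_mm[1] / 100.0
    n = int(round(budget_min * rate * area_cm2))
    if n == 0:
        return out.with_provenance("scrape", n_strokes=0)
    if orientation_mean_deg is None:
        orientation_mean_deg = rng.uniform(0.0, 180.0)
    w, h = out.extent_mm
    batch = max(n // 5, 1)
    ref = gaussian_filter(out.heights, 0.3 / out.spacing)
    for i in range(n):
        base = orientation_mean_deg + (60.0 if rng.uniform() < cross_fraction else 0.0)
        ang = (base + np.degrees(rng.vonmises(0.0, max(skill.gesture_concentration, 1e-6))) / 2.0) % 180.0
        centre = (rng.uniform(-0.2 * w, 1.2 * w), rng.uniform(-0.2 * h, 1.2 * h))
        d = tool.striation_depth_mean * rng.lognormal(-skill.spacing_cv**2 / 2, skill.spacing_cv)
        lam = rng.uniform(1.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)

        def modulation(s, lam=lam, phase=phase):
            return 1.0 + 0.35 * np.sin(2 * np.pi * s / lam + phase)

        _stamp_groove(out.heights, out.spacing, centre, ang, d, tool.imprint_radius_mean,
                      modulation, ref=ref)
        if (i + 1) % batch == 0:
            _truncate_peaks(out.heights, out.spacing, 0.5, clearance=0.2 * tool.striation_depth_mean)
            ref = gaussian_filter(out.heights, 0.3 / out.spacing)
    # a surface leaves the scraping stage homogenized, not freshly grooved
    _truncate_peaks(out.heights, out.spacing, 0.3, clearance=0.4 * tool.striation_depth_mean)
    return out.with_provenance("scrape", tool=tool.name, n_strokes=n, orientation=orientation_mean_deg)


def apply_polishing(
    hmap: HeightMap,
    tool: ToolProfile,
    budget_min: float = 5.0,
    rate: float = POLISH_STRIATION_RATE,
    seed: int = 0,
) -> HeightMap:
    """High-frequency attenuation plus fine multi-directional striations.

    Each minute of polishing truncates the peaks toward a smoothed envelope
    (material can only be removed) and overlays shallow, wide, randomly
    oriented striations whose depth scales with the polishing medium.
    """
    if tool.contact_kind not in {"cobble", "skin", "sand"}:
        raise SurfaceValidationError(f"{tool.name} cannot polish (contact {tool.contact_kind})")
    rng = _rng(seed)
    out = hmap.copy()
    area_cm2 = out.extent_mm[0] * out.extent_mm[1] / 100.0
    n_striae = int(round(budget_min * rate * area_cm2))
    passes = max(int(round(budget_min)), 1)
    if budget_min == 0:
        return out.with_provenance("polish", n_striations=0)
    w, h = out.extent_mm
    per_pass = max(n_striae // passes, 1)
    done = 0
    for p in range(passes):
        # multi-scale peak truncation: the polishing medium rides over the
        # relief and abrades crests at every scale it can reach
        _truncate_peaks(out.heights, out.spacing, 2.5)
        _truncate_peaks(out.heights, out.spacing, 1.2)
        _truncate_peaks(out.heights, out.spacing, 0.4)
        k = per_pass if p < passes - 1 else n_striae - done
        ref = gaussian_filter(out.heights, 0.5 / out.spacing)
        for _ in range(k):
            ang = rng.uniform(0.0, 180.0)
            centre = (rng.uniform(-0.2 * w, 1.2 * w), rng.uniform(-0.2 * h, 1.2 * h))
            d = tool.striation_depth_mean * rng.lognormal(-0.045, 0.3)
            _stamp_groove(out.heights, out.spacing, centre, ang, d, 0.12, ref=ref)
        done += k
    # the medium keeps rubbing after the last tracks form: soften ridge tops
    _truncate_peaks(out.heights, out.spacing, 0.12, clearance=0.5 * tool.striation_depth_mean)
    return out.with_provenance("polish", tool=tool.name, n_striations=n_striae)


def apply_engraving_groove(
    hmap: HeightMap,
    path: np.ndarray | None = None,
    depth: float = 0.3,
    wis: float | None = None,
    asymmetry: float = 0.0,
    strokes: int = 1,
    seed: int = 0,
) -> HeightMap:
    """Cut a V-shaped channel along ``path`` (default: horizontal mid-line).

    ``wis`` is the single-stroke width at the surface (defaults to twice
    the depth, a 90-degree V); ``asymmetry`` in [0, 1) skews the two wall
    half-widths. Multiple strokes superpose laterally jittered cuts whose
    union widens the groove and evens out the asymmetry.
    """
    if depth <= 0:
        raise SurfaceValidationError("engraving depth must be > 0")
    rng = _rng(seed)
    out = hmap.copy()
    w, h = out.extent_mm
    if wis is None:
        wis = 2.0 * depth
    if path is None:
        path = np.array([[0.05 * w, h / 2], [0.95 * w, h / 2]])
    path = np.asarray(path, float)
    x, y = out.coords()
    dist = _signed_distance_to_path(x, y, path)
    ref = gaussian_filter(out.heights, 1.0 / out.spacing)
    cut = np.zeros_like(out.heights)
    jitter = 0.15 * wis if strokes > 1 else 0.0
    for _ in range(strokes):
        off = rng.normal(0.0, jitter) if jitter > 0 else 0.0
        d_k = depth * (rng.lognormal(-0.005, 0.1) if strokes > 1 else 1.0)
        wl = 0.5 * wis * (1.0 + asymmetry)
        wr = 0.5 * wis * (1.0 - asymmetry)
        u = dist - off
        vk = np.zeros_like(u)
        left = (u < 0) & (u > -wl)
        right = (u >= 0) & (u < wr)
        vk[left] = d_k * (1.0 + u[left] / wl)
        vk[right] = d_k * (1.0 - u[right] / wr)
        cut = np.maximum(cut, vk)
    np.minimum(out.heights, ref - cut, out=out.heights, where=cut > 0)
    return out.with_provenance(
        "engrave", depth=depth, wis=wis, asymmetry=asymmetry, strokes=strokes
    )


def _signed_distance_to_path(x, y, path):
    """Signed lateral distance from each grid point to a polyline."""
    best = np.full(x.shape, np.inf)
    best_signed = np.zeros(x.shape)
    for p0, p1 in zip(path[:-1], path[1:]):
        seg = p1 - p0
        L = np.hypot(*seg)
        if L == 0:
            continue
        t = ((x - p0[0]) * seg[0] + (y - p0[1]) * seg[1]) / L**2
        t = np.clip(t, 0.0, 1.0)
        px = p0[0] + t * seg[0]
        py = p0[1] + t * seg[1]
        d = np.hypot(x - px, y - py)
        sign = np.sign((x - p0[0]) * seg[1] - (y - p0[1]) * seg[0])
        closer = d < best
        best[closer] = d[closer]
        best_signed[closer] = (d * np.where(sign == 0, 1.0, sign))[closer]
    return best_signed


# ---------------------------------------------------------------------------
# Modality composition and study generation
# ---------------------------------------------------------------------------

def synthesize_modality(
    spec: ModalitySpec,
    skill: SkillLevel,
    cfg: GeneratorConfig,
    seed: int | None = None,
) -> HeightMap:
    """Apply a modality's steps, in order, to a fresh substrate."""
    root = np.random.SeedSequence([cfg.seed if seed is None else seed, 0xC0FFEE])
    sub_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(len(spec.steps) + 2)]
    hmap = make_base_substrate(cfg, seed=sub_seeds[0])
    gesture = float(_rng(sub_seeds[1]).uniform(0.0, 180.0))
    for i, step in enumerate(spec.steps):
        s = sub_seeds[i + 2]
        t = step.technique
        if t == "saw":
            hmap = apply_sawing(hmap, orientation_deg=gesture)
        elif t in ("peck_direct", "peck_indirect"):
            hmap = apply_pecking(
                hmap, step.tool, skill, step.minutes, seed=s,
                orientation_mean_deg=gesture, indirect=(t == "peck_indirect"),
            )
        elif t == "scrape":
            hmap = apply_scraping(hmap, step.tool, skill, step.minutes, seed=s, orientation_mean_deg=gesture)
        elif t == "polish":
            hmap = apply_polishing(hmap, step.tool, step.minutes, seed=s)
        elif t in ("engrave_single", "engrave_multi"):
            hmap = apply_engraving_groove(
                hmap,
                depth=step.tool.imprint_depth_mean,
                wis=2.5 * step.tool.imprint_radius_mean,
                asymmetry=0.3 * (1.0 if t == "engrave_single" else 0.3),
                strokes=1 if t == "engrave_single" else 5,
                seed=s,
            )
        else:  # pragma: no cover - ModalityStep already validates
            raise SurfaceValidationError(f"unknown technique {t!r}")
    hmap.meta["modality"] = spec.code
    hmap.meta["skill"] = skill.label
    return hmap


def generate_study(design: StudyDesign, cfg: GeneratorConfig):
    """One map per (modality x participant) plus a label table.

    Returns ``(maps, labels)`` where ``labels`` is a DataFrame with one row
    per trial (modality code, technique class, tools, skill, participant,
    seed). Byte-identical under a fixed design seed.
    """
    import pandas as pd

    maps = []
    rows = []
    i = 0
    for m in design.modalities:
        for p in design.participants:
            trial_seed = int(
                np.random.SeedSequence([design.seed, i]).generate_state(1)[0] % 2**31
            )
            maps.append(synthesize_modality(m, p.skill, cfg, seed=trial_seed))
            rows.append(
                {
                    "trial": i,
                    "modality": m.code,
                    "technique_class": m.technique_class,
                    "tools": "+".join(s.tool.name for s in m.steps),
                    "skill": p.skill.label,
                    "participant": p.pid,
                    "seed": trial_seed,
                }
            )
            i += 1
    return maps, pd.DataFrame(rows)
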