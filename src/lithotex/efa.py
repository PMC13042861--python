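"""Elliptic Fourier analysis of closed outlines.

A closed outline is decomposed into ``h`` harmonics of four coefficients
(a, b for x; c, d for y) following the classical chain/polyline
formulation. Harmonic power is (a^2+b^2+c^2+d^2)/2. Normalization uses the
first harmonic (an exact ellipse) to remove starting point, rotation and
size, leaving ``4h - 3`` shape variables: the first harmonic contributes
only its aspect term d1 once a1 is scaled to 1 and b1, c1 are rotated to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OutlineEFA:
    coefficients: np.ndarray  # (h, 4) rows [a, b, c, d]
    a0: float
    c0: float
    centroid_size: float
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def harmonics(self) -> int:
        return self.coefficients.shape[0]

    @property
    def harmonic_power(self) -> np.ndarray:
        return 0.5 * np.sum(self.coefficients**2, axis=1)

    @property
    def shape_variables(self) -> np.ndarray:
        """(4h - 3) vector [d1, a2, b2, c2, d2, ...]; normalized EFA only."""
        if not self.normalized:
            raise ValueError("shape variables require a normalized EFA")
        return np.concatenate([[self.coefficients[0, 3]], self.coefficients[1:].ravel()])


def _closed(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("outline must be an (n, 2) polyline with n >= 3")
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    return pts


def centroid_size(points: np.ndarray) -> float:
    pts = _closed(points)[:-1]
    c = pts.mean(axis=0)
    return float(np.sqrt(np.sum((pts - c) ** 2)))


def efa(points: np.ndarray, h: int = 6, parametrization: str = "arc") -> OutlineEFA:
    """Elliptic Fourier coefficients of a closed outline.

    ``points`` is an (n, 2) polyline; it is closed automatically if the
    last point differs from the first. ``parametrization='arc'`` (default)
    advances the Fourier parameter by chord length, the standard
    formulation; ``'uniform'`` advances it one unit per vertex, under
    which an ellipse sampled uniformly in its own parameter is exactly a
    single harmonic (useful as a closed-form oracle). The two coincide
    for outlines resampled to equal point spacing.
    """
    if h < 1:
        raise ValueError("need at least one harmonic")
    pts = _closed(points)
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if parametrization == "uniform":
        dt = np.ones_like(dt)
    elif parametrization != "arc":
        raise ValueError("parametrization must be 'arc' or 'uniform'")
    if dt.size < 3:
        raise ValueError("degenerate outline")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, h + 1)[:, None]
    phi = 2.0 * np.pi * t / T  # (k+1,)
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (h, k)
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * np.pi**2 * n.ravel() ** 2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const * (cos_d @ dx_dt)
    b = const * (sin_d @ dx_dt)
    c = const * (cos_d @ dy_dt)
    dd = const * (sin_d @ dy_dt)
    coeffs = np.column_stack([a, b, c, dd])
    a0 = float(pts[:-1, 0].mean())
    c0 = float(pts[:-1, 1].mean())
    return OutlineEFA(coeffs, a0, c0, centroid_size(points))


def reconstruct(model: OutlineEFA, n_points: int = 256) -> np.ndarray:
    """Evaluate the truncated Fourier series on a closed outline."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, model.harmonics + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    a, b, c, d = model.coefficients.T
    x = model.a0 + a @ cos_nt + b @ sin_nt
    y = model.c0 + c @ cos_nt + d @ sin_nt
    return np.column_stack([x, y])


def _phase_rotate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point of the parametrisation by theta."""
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        nth = (i + 1) * theta
        rot = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        out[i] = (coeffs[i].reshape(2, 2) @ rot).ravel()
    return out


def _spatial_rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        out[i] = (rot @ coeffs[i].reshape(2, 2)).ravel()
    return out


def _sign_key(coeffs: np.ndarray) -> float:
    """Sign of the first significant higher-harmonic coefficient; the two
    start-point candidates differ only by the sign of even harmonics."""
    v = coeffs[1:].ravel()
    if v.size == 0:
        return 0.0
    tol = 1e-9 * max(np.abs(v).max(), 1.0)
    sig = v[np.abs(v) > tol]
    return float(np.sign(sig[0])) if sig.size else 0.0


def normalize_efa(model: OutlineEFA) -> OutlineEFA:
    """Size/rotation/starting-point standardization via the first harmonic.

    After normalization a1 = 1 and b1 = c1 = 0, so the shape is described
    by the remaining ``4h - 3`` coefficients, invariant to outline scale,
    rotation and starting point.
    """
    a1, b1, c1, d1 = model.coefficients[0]
    if np.hypot(a1, c1) + np.hypot(b1, d1) <= 0:
        raise ValueError("degenerate first harmonic")
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    # the half-angle formula locates an axis extremum of the first-harmonic
    # ellipse only up to pi/2 (major vs minor) and the traversal start only
    # up to pi; evaluate all four candidates, keep the semi-major ones
    # (largest a1 > 0) and resolve the remaining 180-degree ambiguity with
    # a deterministic sign rule on the higher harmonics
    cands = []
    for k in range(4):
        ph = _phase_rotate(model.coefficients, theta + k * np.pi / 2.0)
        psi = np.arctan2(ph[0, 2], ph[0, 0])
        sp = _spatial_rotate(ph, psi)
        if sp[0, 0] > 0:
            cands.append(sp)
    if not cands:
        raise ValueError("degenerate first harmonic")
    a1_max = max(c[0, 0] for c in cands)
    cands = [c for c in cands if c[0, 0] > a1_max * (1.0 - 1e-9)]
    coeffs = max(cands, key=_sign_key)
    scale = coeffs[0, 0]
    coeffs = coeffs / scale
    return OutlineEFA(
        coeffs,
        a0=0.0,
        c0=0.0,
        centroid_size=model.centroid_size,
        normalized=True,
        meta={**model.meta, "scale": float(scale)},
    )


def harmonic_power_threshold(model: OutlineEFA, threshold_pct: float) -> int:
    """Smallest harmonic count whose cumulative power reaches the threshold
    (percent of the total power of this model's harmonics)."""
    power = model.harmonic_power
    cum = np.cumsum(power) / power.sum() * 100.0
    idx = np.flatnonzero(cum >= threshold_pct - 1e-12)
    return int(idx[0]) + 1 if idx.size else model.harmonics
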