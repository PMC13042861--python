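"""Variable transformations for mixed linear/circular/bounded tables.

Bounded variables (percentages, ratios) are logit-transformed after
rescaling to [0, 1], removing their hard bounds before linear modelling;
circular variables are projected to a linear axis via cos(theta) +
sin(theta) (axial variables are first doubled so that 0 and 180 degrees
coincide). Both transforms are exposed as plain functions and as
scikit-learn transformers usable in pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

LOGIT_EPS = 1e-6


def logit_transform(values, lower: float = 0.0, upper: float = 1.0, eps: float = LOGIT_EPS):
    """log(p / (1-p)) of values rescaled from [lower, upper] to [0, 1].

    Values exactly at the bounds are clipped to [eps, 1-eps] (finite
    output); values outside the native bounds raise.
    """
    v = np.asarray(values, dtype=float)
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    if np.any(v < lower - 1e-12) or np.any(v > upper + 1e-12):
        raise ValueError(f"values outside native bounds [{lower}, {upper}]")
    p = np.clip((v - lower) / (upper - lower), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if np.isscalar(values) else out


def circular_to_linear(theta_deg, axial: bool = False):
    """cos(theta) + sin(theta) with theta in radians; axial angles
    (period 180 deg) are doubled first."""
    t = np.asarray(theta_deg, dtype=float)
    if axial:
        t = 2.0 * t
    r = np.deg2rad(t)
    out = np.cos(r) + np.sin(r)
    return float(out) if np.isscalar(theta_deg) else out


class LogitTransformer(BaseEstimator, TransformerMixin):
    """Columnwise logit for bounded variables (sklearn-compatible)."""

    def __init__(self, lower: float = 0.0, upper: float = 1.0, eps: float = LOGIT_EPS):
        self.lower = lower
        self.upper = upper
        self.eps = eps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        return logit_transform(np.asarray(X, dtype=float), self.lower, self.upper, self.eps)


class CircularLinearizer(BaseEstimator, TransformerMixin):
    """Columnwise cos+sin linearization for circular variables."""

    def __init__(self, axial: bool = False):
        self.axial = axial

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        return circular_to_linear(np.asarray(X, dtype=float), axial=self.axial)
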