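"""Circular statistics: uniformity and homogeneity tests, correlations.

Angles are accepted in degrees (the package convention) and converted
internally to radians. Axial quantities (period 180 deg, e.g. texture
directions) must be doubled by the caller before testing; see
:func:`lithotex.stats.transforms.circular_to_linear` for the linearization
used in multivariate analyses.

Implemented tests
-----------------
* Rayleigh test of uniformity (with the small-sample series correction).
* Generalized Watson-Williams high-concentration F test for equal mean
  directions (correction factor 1 + 3/(8 kappa)).
* Mardia-Watson-Wheeler uniform-scores test (chi-square, with a seeded
  permutation fallback when ties are excessive).
* Fisher's nonparametric common-median-direction test.
* Jammalamadaka-Sarma circular-circular and Johnson-Wehrly-Mardia
  linear-circular squared correlations with seeded permutation p-values
  (add-one rule, so p is never 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class UnivariateResult:
    variable: str
    test_name: str
    statistic: float
    dof: float
    p_value: float
    alpha: float = 0.003
    routing: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _rad(angles_deg) -> np.ndarray:
    return np.deg2rad(np.asarray(angles_deg, float))


def circular_mean_deg(angles_deg) -> float:
    a = _rad(angles_deg)
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def resultant_length(angles_deg) -> float:
    a = _rad(angles_deg)
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def circular_median_deg(angles_deg) -> float:
    """Fisher-style circular median: the data direction minimizing the mean
    circular deviation (ties resolve to the smallest angle)."""
    a = _rad(angles_deg) % (2 * np.pi)
    dev = np.pi - np.abs(np.pi - np.abs(a[:, None] - a[None, :]))
    best = np.argmin(dev.mean(axis=1))
    return float(np.degrees(a[best]))


def _kappa_from_rbar(rbar: float) -> float:
    """Best-fitting von Mises concentration (Fisher 1993 approximation)."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def rayleigh_test(angles_deg, variable: str = "angle", alpha: float = 0.003) -> UnivariateResult:
    """Rayleigh test: H0 uniform direction vs a single preferred direction."""
    a = np.asarray(angles_deg, float)
    n = a.size
    if n < 5:
        raise ValueError("Rayleigh test needs n >= 5")
    rbar = resultant_length(a)
    big_r = n * rbar
    z = n * rbar**2
    # small-sample correction (Zar / circstat convention)
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - big_r**2)) - (1 + 2 * n))
    p = float(np.clip(p, 0.0, 1.0))
    return UnivariateResult(
        variable, "Rayleigh", float(z), np.nan, p, alpha,
        routing="circular uniformity", extra={"rbar": rbar, "mean_deg": circular_mean_deg(a)},
    )


def watson_williams(angles_deg, groups, variable: str = "angle", alpha: float = 0.003) -> UnivariateResult:
    """Generalized Watson-Williams test of equal mean directions.

    Valid for reasonably concentrated samples; a pooled concentration
    estimate below 1 is recorded as an assumption warning rather than an
    error.
    """
    a = np.asarray(angles_deg, float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    n = a.size
    rs, ns, means = [], [], []
    for lab in labels:
        sub = a[g == lab]
        ns.append(sub.size)
        rs.append(sub.size * resultant_length(sub))
        means.append(circular_mean_deg(sub))
    sum_r = float(np.sum(rs))
    big_r = n * resultant_length(a)
    k = labels.size
    rw = sum_r / n
    kappa = _kappa_from_rbar(rw)
    warn = kappa < 1.0
    denom = n - sum_r
    if denom <= 0:
        denom = 1e-12
    F = ((n - k) * (sum_r - big_r)) / ((k - 1) * denom)
    F *= 1 + 3 / (8 * kappa)
    p = float(sps.f.sf(F, k - 1, n - k))
    return UnivariateResult(
        variable, "Watson-Williams", float(F), (k - 1, n - k), p, alpha,
        routing="circular means, concentrated groups",
        extra={"group_means_deg": dict(zip(map(str, labels), means)),
               "kappa": kappa, "low_concentration_warning": bool(warn)},
    )


def mardia_watson_wheeler(
    angles_deg, groups, variable: str = "angle", alpha: float = 0.003,
    tie_fraction_for_permutation: float = 0.1, n_perm: int = 999, seed: int = 0,
) -> UnivariateResult:
    """Mardia-Watson-Wheeler uniform-scores test of homogeneity.

    Pooled angles are replaced by uniform scores ``beta = 2*pi*rank/N``;
    the statistic ``W = 2 * sum (C_g^2 + S_g^2) / n_g`` is chi-square with
    2(g-1) dof. When more than ``tie_fraction_for_permutation`` of the
    sample is tied the chi-square approximation is replaced by a seeded
    permutation p-value.
    """
    a = np.asarray(angles_deg, float) % 360.0
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2 or a.size < 10:
        raise ValueError("need >= 2 groups and n >= 10")
    n = a.size

    def w_stat(perm_groups):
        ranks = sps.rankdata(a, method="average")
        beta = 2 * np.pi * ranks / n
        w = 0.0
        for lab in labels:
            b = beta[perm_groups == lab]
            w += (np.sum(np.cos(b)) ** 2 + np.sum(np.sin(b)) ** 2) / b.size
        return 2.0 * w

    w_obs = w_stat(g)
    dof = 2 * (labels.size - 1)
    n_ties = n - np.unique(a).size
    if n_ties / n > tie_fraction_for_permutation:
        rng = np.random.default_rng(seed)
        exceed = sum(w_stat(rng.permutation(g)) >= w_obs for _ in range(n_perm))
        p = (1 + exceed) / (n_perm + 1)
        routing = f"permutation ({n_ties} ties)"
    else:
        p = float(sps.chi2.sf(w_obs, dof))
        routing = "chi-square uniform scores"
    return UnivariateResult(variable, "Mardia-Watson-Wheeler", float(w_obs), dof, float(p), alpha, routing=routing)


def fisher_circular_test(angles_deg, groups, variable: str = "angle", alpha: float = 0.003) -> UnivariateResult:
    """Fisher's nonparametric test of a common median direction.

    Counts per group how many angles fall in the half circle anticlockwise
    of the pooled circular median; the chi-square statistic follows Fisher
    (g - 1 dof).
    """
    a = np.asarray(angles_deg, float) % 360.0
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    med = circular_median_deg(a)
    rel = (a - med) % 360.0
    above = (rel > 0) & (rel <= 180.0)
    N = a.size
    M = int(above.sum())
    if M == 0 or M == N:
        return UnivariateResult(variable, "Fisher-circular", 0.0, labels.size - 1, 1.0, alpha,
                                routing="degenerate split at pooled median")
    term = 0.0
    for lab in labels:
        ni = int((g == lab).sum())
        mi = int(above[g == lab].sum())
        term += mi**2 / ni
    P = N**2 / (M * (N - M)) * term - N * M / (N - M)
    p = float(sps.chi2.sf(P, labels.size - 1))
    return UnivariateResult(variable, "Fisher-circular", float(P), labels.size - 1, p, alpha,
                            routing="common median direction")


# ---------------------------------------------------------------------------
# Circular correlations
# ---------------------------------------------------------------------------

def jammalamadaka_sarma_r(alpha_deg, beta_deg) -> float:
    a, b = _rad(alpha_deg), _rad(beta_deg)
    sa = np.sin(a - np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
    sb = np.sin(b - np.arctan2(np.sin(b).mean(), np.cos(b).mean()))
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    return float(np.sum(sa * sb) / den) if den > 0 else np.nan


def johnson_wehrly_mardia_r2(x, theta_deg) -> float:
    x = np.asarray(x, float)
    t = _rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    return float((rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2))


def circ_corr(var1, var2, kind: str = "circ-circ", n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Squared correlation and seeded permutation p-value.

    ``kind='circ-circ'`` uses Jammalamadaka-Sarma (R^2 = r^2); ``'lin-circ'``
    Johnson-Wehrly-Mardia (var1 linear, var2 circular). The second variable
    is permuted; p = (1 + #exceed) / (n_perm + 1).
    """
    v1 = np.asarray(var1, float)
    v2 = np.asarray(var2, float)
    if v1.size != v2.size or v1.size < 10:
        raise ValueError("need paired samples with n >= 10")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant variable: correlation undefined")
    if kind == "circ-circ":
        stat = lambda b: jammalamadaka_sarma_r(v1, b) ** 2  # noqa: E731
    elif kind == "lin-circ":
        stat = lambda b: johnson_wehrly_mardia_r2(v1, b)  # noqa: E731
    else:
        raise ValueError(f"unknown kind {kind!r}")
    r2_obs = stat(v2)
    rng = np.random.default_rng(seed)
    exceed = sum(stat(rng.permutation(v2)) >= r2_obs for _ in range(n_perm))
    return float(r2_obs), float((1 + exceed) / (n_perm + 1))
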