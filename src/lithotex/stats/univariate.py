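"""Normality-routed univariate testing and robust summaries."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .circular import UnivariateResult


def shapiro_route(values, groups, variable: str = "var", alpha: float = 0.003) -> UnivariateResult:
    """Shapiro-Wilk per group, then ANOVA (all Gaussian) or Kruskal-Wallis.

    The normality gate uses the same study-wide alpha as the group test;
    the chosen route and the per-group Shapiro p-values are recorded.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[g == lab] for lab in labels]
    if any(s.size < 3 for s in samples):
        raise ValueError("need >= 3 values per group")
    sw = {str(lab): float(sps.shapiro(s).pvalue) for lab, s in zip(labels, samples)}
    gaussian = all(p > alpha for p in sw.values())
    if gaussian:
        stat, p = sps.f_oneway(*samples)
        name, dof = "ANOVA", (labels.size - 1, v.size - labels.size)
        route = "all groups Gaussian (Shapiro-Wilk)"
    else:
        stat, p = sps.kruskal(*samples)
        name, dof = "Kruskal-Wallis", labels.size - 1
        route = "non-Gaussian group(s) (Shapiro-Wilk)"
    return UnivariateResult(
        variable, name, float(stat), dof, float(p), alpha,
        routing=route, extra={"shapiro_p": sw},
    )


def biweight_midvariance(values, c: float = 9.0) -> float:
    """Tukey biweight midvariance (tuning constant 9), robust to outliers."""
    x = np.asarray(values, float)
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    if mad == 0:
        return 0.0
    u = (x - m) / (c * mad)
    w = np.abs(u) < 1
    num = x.size * np.sum(((x[w] - m) ** 2) * (1 - u[w] ** 2) ** 4)
    den = np.sum((1 - u[w] ** 2) * (1 - 5 * u[w] ** 2)) ** 2
    return float(num / den) if den > 0 else 0.0


def robust_summary(values) -> dict:
    """Median and the square root of the biweight midvariance.

    With fewer than 4 values only the median is reported (flagged).
    """
    x = np.asarray(values, float)
    med = float(np.median(x))
    if x.size < 4:
        return {"median": med, "sqrt_bwmv": float("nan"), "flag": "n < 4: scale not estimated"}
    return {"median": med, "sqrt_bwmv": float(np.sqrt(biweight_midvariance(x))), "flag": None}
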