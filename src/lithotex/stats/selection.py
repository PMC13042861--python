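"""Feature tables and correlation-based variable selection.

A :class:`FeatureTable` is an observation-by-parameter matrix with a
variable class per column (linear, circular in degrees, or bounded with
native bounds) and a parallel label table. Selection proceeds in the two
documented steps: keep variables whose univariate group test is
significant at the study-wide alpha, then drop one member of every pair
correlated at R^2 >= threshold (greedily, largest R^2 first; the member
with the larger univariate p is dropped, alphabetical on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import (
    UnivariateResult,
    circ_corr,
    jammalamadaka_sarma_r,
    johnson_wehrly_mardia_r2,
    mardia_watson_wheeler,
)
from .transforms import circular_to_linear, logit_transform
from .univariate import shapiro_route


@dataclass
class FeatureTable:
    data: pd.DataFrame
    variable_classes: dict  # column -> 'linear' | 'circular' | 'bounded'
    labels: pd.DataFrame
    bounds: dict = field(default_factory=dict)  # bounded column -> (lo, hi)
    axial: set = field(default_factory=set)  # circular columns with period 180

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicated row ids")
        unknown = set(self.data.columns) - set(self.variable_classes)
        if unknown:
            raise ValueError(f"columns without a variable class: {sorted(unknown)}")

    def transformed(self) -> pd.DataFrame:
        """Linearized numeric matrix: logit for bounded, cos+sin for circular."""
        out = {}
        for col in self.data.columns:
            cls = self.variable_classes[col]
            v = self.data[col].to_numpy(float)
            if cls == "bounded":
                lo, hi = self.bounds.get(col, (0.0, 1.0))
                out[col] = logit_transform(v, lo, hi)
            elif cls == "circular":
                out[col] = circular_to_linear(v, axial=col in self.axial)
            else:
                out[col] = v
        return pd.DataFrame(out, index=self.data.index)


@dataclass
class CorrelationReport:
    pairs: pd.DataFrame  # var1, var2, method, r2, permutation_p
    dropped: pd.DataFrame  # variable, kept_partner, r2, reason
    retained: list


def univariate_screen(
    table: FeatureTable, group_col: str, alpha: float = 0.003
) -> dict[str, UnivariateResult]:
    """Route each variable to its class-appropriate group test."""
    groups = table.labels[group_col].to_numpy()
    results = {}
    for col in table.data.columns:
        cls = table.variable_classes[col]
        v = table.data[col].to_numpy(float)
        try:
            if cls == "circular":
                a = 2 * v if col in table.axial else v
                results[col] = mardia_watson_wheeler(a, groups, variable=col, alpha=alpha)
            elif cls == "bounded":
                lo, hi = table.bounds.get(col, (0.0, 1.0))
                results[col] = shapiro_route(logit_transform(v, lo, hi), groups, variable=col, alpha=alpha)
            else:
                results[col] = shapiro_route(v, groups, variable=col, alpha=alpha)
        except ValueError as exc:
            results[col] = UnivariateResult(col, "skipped", np.nan, np.nan, 1.0, alpha, routing=str(exc))
    return results


def _pair_r2(table: FeatureTable, c1: str, c2: str) -> tuple[str, float]:
    cls1, cls2 = table.variable_classes[c1], table.variable_classes[c2]
    v1 = table.data[c1].to_numpy(float)
    v2 = table.data[c2].to_numpy(float)
    a1 = 2 * v1 if c1 in table.axial else v1
    a2 = 2 * v2 if c2 in table.axial else v2
    if cls1 == "circular" and cls2 == "circular":
        return "Jammalamadaka-Sarma", jammalamadaka_sarma_r(a1, a2) ** 2
    if cls1 == "circular" or cls2 == "circular":
        lin, circ = (v2, a1) if cls1 == "circular" else (v1, a2)
        if table.variable_classes[c2 if cls1 == "circular" else c1] == "bounded":
            col = c2 if cls1 == "circular" else c1
            lo, hi = table.bounds.get(col, (0.0, 1.0))
            lin = logit_transform(lin, lo, hi)
        return "Johnson-Wehrly-Mardia", johnson_wehrly_mardia_r2(lin, circ)
    t = table.transformed()
    r = np.corrcoef(t[c1], t[c2])[0, 1]
    return "Pearson", float(r**2)


def select_variables(
    table: FeatureTable,
    group_col: str,
    alpha: float = 0.003,
    r2_threshold: float = 0.7,
    n_perm: int = 199,
    seed: int = 0,
) -> tuple[CorrelationReport, dict[str, UnivariateResult]]:
    """Significance screen then greedy de-correlation.

    Permutation p-values are computed only for the pairs at or above the
    R^2 threshold (the ones that drive a drop).
    """
    uni = univariate_screen(table, group_col, alpha)
    sig = [c for c in table.data.columns if uni[c].significant]
    if not sig:
        raise ValueError("no variable is significant at alpha; nothing to select")
    pair_rows = []
    for i, c1 in enumerate(sig):
        for c2 in sig[i + 1 :]:
            try:
                method, r2 = _pair_r2(table, c1, c2)
            except (ValueError, FloatingPointError):
                continue
            pair_rows.append({"var1": c1, "var2": c2, "method": method, "r2": r2})
    pairs = pd.DataFrame(pair_rows)
    retained = set(sig)
    drops = []
    if not pairs.empty:
        for _, row in pairs.sort_values("r2", ascending=False).iterrows():
            if row.r2 < r2_threshold:
                break
            c1, c2 = row.var1, row.var2
            if c1 not in retained or c2 not in retained:
                continue
            p1, p2 = uni[c1].p_value, uni[c2].p_value
            drop = c2 if (p2 > p1 or (p2 == p1 and c2 > c1)) else c1
            keep = c1 if drop == c2 else c2
            retained.discard(drop)
            drops.append(
                {"variable": drop, "kept_partner": keep, "r2": row.r2,
                 "reason": f"R2={row.r2:.3f} >= {r2_threshold} with {keep}"}
            )
        # permutation p for the reported high-correlation pairs
        perm_ps = []
        for _, row in pairs.iterrows():
            if row.r2 < r2_threshold:
                perm_ps.append(np.nan)
                continue
            v1 = table.data[row.var1].to_numpy(float)
            v2 = table.data[row.var2].to_numpy(float)
            kind = "circ-circ" if row.method == "Jammalamadaka-Sarma" else (
                "lin-circ" if row.method == "Johnson-Wehrly-Mardia" else None
            )
            if kind is None:
                t = table.transformed()
                r_obs = abs(np.corrcoef(t[row.var1], t[row.var2])[0, 1])
                rng = np.random.default_rng(seed)
                exceed = sum(
                    abs(np.corrcoef(t[row.var1], rng.permutation(t[row.var2]))[0, 1]) >= r_obs
                    for _ in range(n_perm)
                )
                perm_ps.append((1 + exceed) / (n_perm + 1))
            else:
                if kind == "lin-circ" and table.variable_classes[row.var1] == "circular":
                    v1, v2 = v2, v1
                _, p = circ_corr(v1, v2, kind=kind, n_perm=n_perm, seed=seed)
                perm_ps.append(p)
        pairs["permutation_p"] = perm_ps
    report = CorrelationReport(
        pairs=pairs,
        dropped=pd.DataFrame(drops, columns=["variable", "kept_partner", "r2", "reason"]),
        retained=sorted(retained),
    )
    return report, uni
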