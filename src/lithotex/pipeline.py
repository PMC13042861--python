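"""End-to-end analyses: parameter collection and the three study runners.

``collect_parameters`` assembles the full 29-parameter suite (14 ISO
25178, 8 SSFA, 3 furrow, 4 texture-direction parameters) for one levelled,
form-removed sub-area, with unit and variable-class metadata and
missing-with-reason flags.

The three runners mirror the study structure:

* technique analysis - transform, univariate screen, correlation-based
  selection, PCA, cross-validated LDA and CVA over technique classes;
* expertise analysis - the same chain per technique subset, classifying
  skill levels;
* engraving analysis - profile measurements, circular tests on opening
  angles, metric PCA with convex-hull export, EFA shape PCA, a
  Shapiro-routed test on PC1 and a permutation MANOVA on the first two
  shape PCs.

Every runner writes CSV/JSON reports plus a provenance manifest (config
hash and seed registry) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import areal, furrows, ssfa
from .efa import efa as efa_fit
from .efa import normalize_efa
from .heightmap import HeightMap, SubArea, pretreat
from .profiles import close_outline, detect_landmarks, measure_profile
from .stats import (
    FeatureTable,
    cva,
    lda_cv,
    manova_permutation,
    pca,
    rayleigh_test,
    robust_summary,
    select_variables,
    shapiro_route,
    watson_williams,
)
from .stats.transforms import circular_to_linear
from .synth import (
    GeneratorConfig,
    generate_engraving_study,
    generate_study,
    three_technique_design,
)

#: Parameter suite: name -> (unit, variable class)
PARAMETER_INFO = {
    "Sq": ("mm", "linear"),
    "Smc": ("mm", "linear"),
    "Sal": ("mm", "linear"),
    "Str": ("unitless", "bounded"),
    "Std": ("deg", "circular"),
    "Sdr": ("%", "linear"),
    "Vvv": ("mm3/mm2", "linear"),
    "Spd": ("1/mm2", "linear"),
    "Spc": ("1/mm", "linear"),
    "Svd": ("1/mm2", "linear"),
    "Shrn": ("unitless", "linear"),
    "Shrnq": ("unitless", "linear"),
    "Sdrn": ("unitless", "linear"),
    "Sdrnq": ("unitless", "linear"),
    "Ymax": ("unitless", "linear"),
    "Asfc": ("unitless", "linear"),
    "Das": ("unitless", "linear"),
    "Smfc": ("um2", "linear"),
    "HAsfc": ("unitless", "linear"),
    "MedianAsfc": ("unitless", "linear"),
    "epLsar": ("unitless", "linear"),
    "NewEplsar": ("unitless", "linear"),
    "Isotropy": ("%", "bounded"),
    "FirstDirection": ("deg", "circular"),
    "SecondDirection": ("deg", "circular"),
    "ThirdDirection": ("deg", "circular"),
    "FurrowMaxDepth": ("mm", "linear"),
    "FurrowMeanDepth": ("mm", "linear"),
    "FurrowMeanDensity": ("cm/cm2", "linear"),
}

BOUNDS = {"Str": (0.0, 1.0), "Isotropy": (0.0, 100.0)}
AXIAL = {"Std", "FirstDirection", "SecondDirection", "ThirdDirection"}


@dataclass
class AnalysisConfig:
    alpha: float = 0.003
    r2_threshold: float = 0.7
    pca_retain: float = 0.95
    lda_folds: int = 10
    test_size: float = 0.2
    n_perm: int = 999
    harmonics: int = 6
    tile_mm: float = 10.0
    n_tiles: int = 9
    n_per_class: int = 30
    n_profiles_per_set: int = 10
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def collect_parameters(
    hmap: HeightMap | SubArea,
    pretreated: bool = False,
    subset: list[str] | None = None,
) -> dict:
    """All 29 surface parameters for one sub-area.

    Any sibling-module failure is recorded as a missing-with-reason flag
    and the run continues. ``subset`` restricts computation to the listed
    parameters (siblings of a requested parameter may be computed too).
    """
    if isinstance(hmap, SubArea):
        hmap = hmap.extract()
    wanted = set(PARAMETER_INFO) if subset is None else set(subset)
    if not hmap.mask.any():
        out = {k: np.nan for k in wanted}
        out["_flags"] = {k: "all cells masked" for k in wanted}
        return out
    if not pretreated:
        hmap = pretreat(hmap)
    out: dict = {}
    flags: dict = {}

    def _try(names, fn):
        if not (wanted & set(names)):
            return
        try:
            vals = fn()
            out.update(vals)
        except Exception as exc:  # noqa: BLE001 - flagged, run continues
            for n in names:
                flags[n] = str(exc)
                out[n] = np.nan

    _try(["Sq"], lambda: {"Sq": areal.sq(hmap)})
    _try(["Smc"], lambda: {"Smc": areal.smc(hmap)})
    _try(["Sal", "Str"], lambda: dict(zip(["Sal", "Str"], areal.autocorrelation_params(hmap))))
    _try(["Sdr"], lambda: {"Sdr": areal.sdr(hmap)})
    _try(["Vvv"], lambda: {"Vvv": areal.vvv(hmap)})

    def _features():
        seg = areal.segment_features(hmap)
        return areal.feature_params(seg, hmap)

    _try(["Spd", "Spc", "Svd", "Shrn", "Shrnq", "Sdrn", "Sdrnq"], _features)

    def _ssfa_main():
        curve = ssfa.relative_area_curve(hmap)
        p = ssfa.asfc(curve)
        return {"Asfc": p.Asfc, "Smfc": p.Smfc_um2, "Das": p.Das, "Ymax": p.Ymax}

    _try(["Asfc", "Smfc", "Das", "Ymax"], _ssfa_main)
    _try(["HAsfc", "MedianAsfc"], lambda: dict(zip(["HAsfc", "MedianAsfc"], ssfa.hasfc_grid(hmap))))
    _try(["epLsar", "NewEplsar"], lambda: dict(zip(["epLsar", "NewEplsar"], ssfa.eplsar(hmap))))

    def _furrows():
        net = furrows.detect_furrows(hmap)
        fp = furrows.furrow_params(net)
        return {
            "FurrowMaxDepth": fp["furrow_max_depth"],
            "FurrowMeanDepth": fp["furrow_mean_depth"],
            "FurrowMeanDensity": fp["furrow_density"],
        }

    _try(["FurrowMaxDepth", "FurrowMeanDepth", "FurrowMeanDensity"], _furrows)

    def _directions():
        spec = furrows.direction_spectrum(hmap)
        t = furrows.texture_direction_params(spec)
        if t.unstable:
            flags["FirstDirection"] = "direction unstable (isotropy > 95%)"
        return {
            "Isotropy": t.isotropy_pct,
            "Std": t.first_direction,
            "FirstDirection": t.first_direction,
            "SecondDirection": t.second_direction,
            "ThirdDirection": t.third_direction,
        }

    _try(["Isotropy", "Std", "FirstDirection", "SecondDirection", "ThirdDirection"], _directions)
    if subset is not None:
        out = {k: v for k, v in out.items() if k in wanted}
    out["_flags"] = flags
    return out


def parameter_table(maps, labels: pd.DataFrame, subset=None) -> FeatureTable:
    """Collect parameters for a list of maps into a FeatureTable."""
    rows = []
    for hmap in maps:
        params = collect_parameters(hmap)
        params.pop("_flags", None)
        rows.append(params)
    data = pd.DataFrame(rows)
    if subset is not None:
        data = data[subset]
    # drop all-NaN columns (parameters unavailable on every observation)
    data = data.dropna(axis=1, how="all")
    classes = {c: PARAMETER_INFO[c][1] for c in data.columns}
    return FeatureTable(
        data=data,
        variable_classes=classes,
        labels=labels.reset_index(drop=True),
        bounds={c: BOUNDS[c] for c in data.columns if c in BOUNDS},
        axial={c for c in data.columns if c in AXIAL},
    )


def _write(outdir, name, obj):
    if outdir is None:
        return
    path = Path(outdir)
    path.mkdir(parents=True, exist_ok=True)
    fp = path / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(fp)
    else:
        with open(fp, "w") as fh:
            json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    return str(o)


def _manifest(config: AnalysisConfig, stage: str, extra=None) -> dict:
    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        **(extra or {}),
    }


def _classify(table: FeatureTable, group_col: str, config: AnalysisConfig):
    """Shared selection -> PCA -> LDA/CVA chain (single code path)."""
    report, uni = select_variables(
        table, group_col, alpha=config.alpha, r2_threshold=config.r2_threshold, seed=config.seed
    )
    transformed = table.transformed()[report.retained]
    # a parameter can be missing-with-reason on individual sub-areas
    # (e.g. an undefined Smfc on a near-flat block); PCA needs complete columns
    usable = [c for c in report.retained if transformed[c].notna().all()]
    if not usable:
        raise ValueError("no selected variable is complete across observations")
    report.retained = usable
    transformed = transformed[usable]
    pca_model = pca(transformed.to_numpy(), retain=config.pca_retain, columns=usable)
    scores = pca_model.scores[:, : pca_model.retained]
    labels = table.labels[group_col].to_numpy()
    classifier = lda_cv(
        scores, labels, k=config.lda_folds, test_size=config.test_size, seed=config.seed
    )
    ordination = cva(scores, labels)
    return report, uni, pca_model, classifier, ordination


def run_technique_analysis(config: AnalysisConfig, table: FeatureTable | None = None) -> dict:
    """Technique discrimination on a labelled feature table.

    Without a table, a synthetic three-technique study (pecking, scraping,
    polishing; ``n_per_class`` sub-areas each) is generated at the
    documented defaults.
    """
    if table is None:
        design = three_technique_design(config.n_per_class, seed=config.seed)
        maps, labels = generate_study(design, config.generator)
        table = parameter_table(maps, labels)
    report, uni, pca_model, classifier, ordination = _classify(table, "technique_class", config)
    out = {
        "selection": report,
        "univariate": uni,
        "pca": pca_model,
        "classifier": classifier,
        "cva": ordination,
        "table": table,
        "manifest": _manifest(config, "technique"),
    }
    _write(config.outdir, "technique_univariate.json",
           {k: dataclasses.asdict(v) for k, v in uni.items()})
    _write(config.outdir, "technique_selected.json", {"retained": report.retained})
    _write(config.outdir, "technique_confusion.csv", classifier.confusion)
    _write(config.outdir, "technique_report.json", classifier)
    _write(config.outdir, "technique_manifest.json", out["manifest"])
    return out


def run_expertise_analysis(config: AnalysisConfig, table: FeatureTable | None = None) -> dict:
    """Per-technique skill classification (one report per technique code)."""
    if table is None:
        from .synth import SKILL_PRESETS, Participant, StudyDesign, experimental_modalities

        mods = [m for m in experimental_modalities() if m.technique_class in
                ("pecking", "scraping", "polishing")][:4]
        participants = []
        for skill in ("novice", "intermediate", "expert"):
            for i in range(config.n_per_class // 3):
                participants.append(Participant(f"{skill}_{i}", SKILL_PRESETS[skill]))
        design = StudyDesign(mods, participants, seed=config.seed)
        maps, labels = generate_study(design, config.generator)
        table = parameter_table(maps, labels)
    results = {}
    rows = []
    for code, idx in table.labels.groupby("modality").groups.items():
        sub = FeatureTable(
            data=table.data.loc[idx].reset_index(drop=True),
            variable_classes=table.variable_classes,
            labels=table.labels.loc[idx].reset_index(drop=True),
            bounds=table.bounds,
            axial=table.axial,
        )
        if sub.labels["skill"].nunique() < 2 or len(sub.data) < 3 * sub.labels["skill"].nunique():
            results[code] = None
            continue
        try:
            results[code] = _classify(sub, "skill", config)
            cr = results[code][3]
            rows.append({"technique": code, "accuracy": cr.accuracy, "kappa": cr.kappa,
                         "nir": cr.nir, "p_value": cr.accuracy_p_value})
        except ValueError as exc:
            results[code] = None
            rows.append({"technique": code, "accuracy": np.nan, "kappa": np.nan,
                         "nir": np.nan, "p_value": np.nan, "skipped": str(exc)})
    summary = pd.DataFrame(rows)
    _write(config.outdir, "expertise_summary.csv", summary)
    _write(config.outdir, "expertise_manifest.json", _manifest(config, "expertise"))
    return {"per_technique": results, "summary": summary, "table": table,
            "manifest": _manifest(config, "expertise")}


def run_engraving_analysis(config: AnalysisConfig, traces=None, labels=None) -> dict:
    """Engraving-profile morphometrics and EFA shape analysis."""
    if traces is None:
        traces, labels = generate_engraving_study(
            n_per_set=config.n_profiles_per_set, seed=config.seed
        )
    meas_rows, shape_vars, sizes, kept = [], [], [], []
    for i, tr in enumerate(traces):
        set_label = labels.iloc[i]["set"] if labels is not None else tr.meta.get("set")
        try:
            lm = detect_landmarks(tr)
            m = measure_profile(tr, lm, set_label=set_label)
            outline = close_outline(tr, lm)
            model = normalize_efa(efa_fit(outline, h=config.harmonics))
        except ValueError as exc:
            meas_rows.append({"set": set_label, "error": str(exc)})
            continue
        kept.append(i)
        sizes.append(model.centroid_size)
        shape_vars.append(model.shape_variables)
        meas_rows.append(
            {"set": set_label, "D_um": m.D_um, "WIS_um": m.WIS_um,
             "theta_deg": m.theta_deg, "A": m.A}
        )
    meas = pd.DataFrame(meas_rows)
    ok = meas.dropna(subset=["D_um"]) if "D_um" in meas else meas
    # per-set robust summaries
    summaries = {
        s: {v: robust_summary(g[v].to_numpy()) for v in ("D_um", "WIS_um", "A")}
        for s, g in ok.groupby("set")
    }
    # circular analysis of opening angles
    theta = ok["theta_deg"].to_numpy()
    sets = ok["set"].to_numpy()
    rayleigh = rayleigh_test(theta, variable="theta")
    ww = watson_williams(theta, sets, variable="theta") if len(set(sets)) > 1 else None
    # metric PCA (theta linearized)
    metric = np.column_stack(
        [ok["D_um"], ok["WIS_um"], ok["A"], circular_to_linear(theta)]
    )
    metric_pca = pca(metric, retain=config.pca_retain, columns=["D_um", "WIS_um", "A", "theta_lin"])
    hulls = _convex_hulls(metric_pca.scores[:, :2], sets)
    pc1 = metric_pca.scores[:, 0]
    pc1_test = shapiro_route(pc1, sets, variable="metric_PC1", alpha=config.alpha)
    # EFA shape PCA + MANOVA
    shape_matrix = np.vstack(shape_vars)
    shape_pca = pca(shape_matrix, retain=config.pca_retain)
    shape_sets = ok["set"].to_numpy()
    manova = manova_permutation(
        shape_pca.scores, shape_sets, n_perm=config.n_perm, components=2, seed=config.seed
    )
    shape_pc1_test = shapiro_route(shape_pca.scores[:, 0], shape_sets, variable="shape_PC1",
                                   alpha=config.alpha)
    out = {
        "measurements": meas,
        "summaries": summaries,
        "rayleigh": rayleigh,
        "watson_williams": ww,
        "metric_pca": metric_pca,
        "metric_pc1_test": pc1_test,
        "convex_hulls": hulls,
        "shape_pca": shape_pca,
        "shape_pc1_test": shape_pc1_test,
        "manova": manova,
        "centroid_sizes": np.asarray(sizes),
        "shape_variables": shape_matrix,
        "manifest": _manifest(config, "engraving"),
    }
    _write(config.outdir, "engraving_measurements.csv", meas)
    _write(config.outdir, "engraving_summaries.json", summaries)
    _write(config.outdir, "engraving_circular.json",
           {"rayleigh": dataclasses.asdict(rayleigh),
            "watson_williams": dataclasses.asdict(ww) if ww else None})
    _write(config.outdir, "engraving_manova.json", dataclasses.asdict(manova))
    _write(config.outdir, "engraving_hulls.json", hulls)
    _write(config.outdir, "engraving_manifest.json", out["manifest"])
    return out


def _convex_hulls(scores2d, groups) -> dict:
    """Convex-hull vertex lists per group (data export; no plotting)."""
    from scipy.spatial import ConvexHull

    hulls = {}
    for g in np.unique(groups):
        pts = scores2d[groups == g]
        if len(pts) < 3:
            hulls[str(g)] = pts.tolist()
            continue
        hull = ConvexHull(pts)
        hulls[str(g)] = pts[hull.vertices].tolist()
    return hulls
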