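"""End-to-end orchestration: synthesize -> fit -> correct -> contextualize.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so any downstream stage can be rerun from saved intermediates
with identical results. ``run_pipeline`` executes all stages in order and
merges their summaries into a single JSON report; identical config + seed
gives byte-identical report content.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import glm, nulls, rft, similarity, surfaces, synthetic

logger = logging.getLogger("polycortex")

DEFAULT_CONFIG = {
    "seed": 0,
    "mesh": {"subdivisions": 3, "radius": 50.0, "medial_wall_fraction": 0.05},
    "cohort": {"n_subjects": 390, "age_range": [3.0, 21.0],
               "sex_ratio": 0.468, "n_scanners": 3, "n_pcs": 10},
    "effect": {"snr": 0.5, "patch_center": [0.2, 0.8, 0.4],
               "patch_radius": 0.5, "noise_sd": 0.1,
               "noise_fwhm_edges": 3.0, "mean_thickness": 2.5},
    "design": {"include_interactions": True, "contrast": "score",
               "standardize": True},
    "rft": {"primary_p": 0.001, "alpha": 0.01, "sign": "positive"},
    "nulls": {"n_perm": 10_000},
    "age_groups": [[3.0, 9.0], [10.0, 15.0], [16.0, 21.0]],
    "sweep": {"start": 3.0, "stop": 21.0, "step": 1.0},
    "atlases": {"n_types": 6, "n_networks": 7, "n_parcels": 64,
                "n_fine_parcels": 200},
    "expression": {"n_genes": 300, "n_specimens": 12,
                   "specimen_noise_sd": 0.5},
    "disorders": {"schizophrenia": -0.33, "bipolar": -0.47, "mdd": -0.54,
                  "adhd": -0.43, "ocd": 0.0, "asd": 0.0},
}


class PipelineError(RuntimeError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config, deep-merged with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def _stage_seed(seed: int, offset: int) -> int:
    return int((int(seed) * 1_000_003 + offset) % (2 ** 31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _write_json(data, path):
    Path(path).write_text(json.dumps(_jsonable(data), indent=2,
                                     sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stage: synthesize
# ---------------------------------------------------------------------------

def stage_synthesize(cfg: dict, rundir) -> dict:
    """Generate and save mesh, cohort, morphometry, atlases, expression
    panel and disorder maps with planted truth."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    mesh = synthetic.make_sphere_mesh(**cfg["mesh"])
    surfaces.write_mesh(mesh, rundir / "mesh.obj")

    cohort = synthetic.CohortSpec(**{**cfg["cohort"],
                                     "age_range": tuple(cfg["cohort"]["age_range"])})
    subjects = synthetic.simulate_cohort(cohort, seed=_stage_seed(seed, 1))
    subjects.to_csv(rundir / "subjects.tsv", sep="\t", index=False)

    ecfg = cfg["effect"]
    noise_sd = float(ecfg["noise_sd"])
    amplitude = float(ecfg["snr"]) * noise_sd / float(cohort.score_sd)
    effect_map = synthetic.focal_effect_map(
        mesh, ecfg["patch_center"], float(ecfg["patch_radius"]), amplitude)
    eff = synthetic.EffectSpec(
        effect_map=effect_map,
        covariate_betas={"intercept": float(ecfg.get("mean_thickness", 2.5))},
        noise_sd=noise_sd,
        noise_fwhm=float(ecfg["noise_fwhm_edges"]) * mesh.mean_edge_length)
    thickness = synthetic.simulate_thickness(mesh, subjects, eff,
                                             seed=_stage_seed(seed, 2))
    surfaces.write_vertex_maps(thickness, rundir / "thickness.csv",
                               subject_ids=subjects["subject_id"])
    np.savetxt(rundir / "effect_map.csv", effect_map)

    atlases = synthetic.make_atlases(mesh, seed=_stage_seed(seed, 3),
                                     **cfg["atlases"])
    for key, (labels, names) in atlases.items():
        surfaces.write_labels(labels, names, rundir / f"atlas_{key}.txt")

    area_names, area_cent = synthetic.make_area_centroids(
        mesh, seed=_stage_seed(seed, 4))
    pd.DataFrame({"area": area_names, "x": area_cent[:, 0],
                  "y": area_cent[:, 1], "z": area_cent[:, 2]}).to_csv(
        rundir / "area_centroids.tsv", sep="\t", index=False)

    espec = synthetic.ExpressionSpec(**cfg["expression"])
    sx = synthetic.simulate_expression(espec, seed=_stage_seed(seed, 5))
    sx.panel.to_csv(rundir / "expression_panel.csv", index=False)
    sx.weights.to_csv(rundir / "specificity.tsv", sep="\t", index=False)
    _write_json(sx.markers, rundir / "markers.json")
    sx.specimen_ages.to_csv(rundir / "specimens.tsv", sep="\t", index=False)
    _write_json({c: g for c, g in sx.gradients.items()},
                rundir / "truth_gradients.json")

    labels64 = atlases["parcels"][0]
    _, ref = surfaces.parcellate(np.where(mesh.medial_wall, np.nan,
                                          effect_map), labels64)
    dmaps = synthetic.simulate_disorder_maps(
        mesh, labels64, ref, cfg["disorders"], seed=_stage_seed(seed, 6))
    ids = np.unique(labels64[labels64 > 0])
    ddf = pd.DataFrame({"parcel_id": ids, **dmaps})
    ddf.to_csv(rundir / "disorder_maps.csv", index=False)

    _write_json({"effect_amplitude": amplitude,
                 "patch_n_vertices": int((effect_map != 0).sum())},
                rundir / "truth.json")
    return {"mesh": mesh, "subjects": subjects, "thickness": thickness,
            "atlases": atlases, "effect_map": effect_map,
            "expression": sx, "disorder_maps": dmaps,
            "area_centroids": (area_names, area_cent)}


# ---------------------------------------------------------------------------
# Loading saved intermediates
# ---------------------------------------------------------------------------

def load_inputs(rundir) -> dict:
    rundir = Path(rundir)
    mesh = surfaces.read_mesh(rundir / "mesh.obj")
    subjects = pd.read_csv(rundir / "subjects.tsv", sep="\t")
    thickness, _ = surfaces.read_vertex_maps(rundir / "thickness.csv")
    atlases = {}
    for key in ("types", "networks", "parcels", "fine"):
        labels, names = surfaces.read_labels(rundir / f"atlas_{key}.txt")
        atlases[key] = (labels, names)
    ac = pd.read_csv(rundir / "area_centroids.tsv", sep="\t")
    effect_map = np.loadtxt(rundir / "effect_map.csv")
    return {"mesh": mesh, "subjects": subjects, "thickness": thickness,
            "atlases": atlases, "effect_map": effect_map,
            "area_centroids": (list(ac["area"]),
                               ac[["x", "y", "z"]].to_numpy(float))}


# ---------------------------------------------------------------------------
# Stage: fit
# ---------------------------------------------------------------------------

def _design_spec(cfg) -> glm.DesignSpec:
    d = cfg["design"]
    return glm.DesignSpec(include_interactions=bool(d["include_interactions"]),
                          contrast=str(d["contrast"]),
                          standardize=bool(d["standardize"]))

def stage_fit(cfg: dict, rundir, inputs=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    res = glm.fit_model(data["thickness"], data["subjects"], _design_spec(cfg))
    np.savetxt(rundir / "tmap.csv", res.tstat)
    np.savetxt(rundir / "beta.csv", res.beta)
    surfaces.write_vertex_maps(res.resid, rundir / "residuals.csv")
    aic = glm.age_polynomial_aic(data["thickness"], data["subjects"],
                                 _design_spec(cfg))
    report = {"n": res.n, "df": res.df, "age_center": res.age_center,
              "columns": res.names, "contrast": res.contrast,
              "peak_t": float(np.nanmax(res.tstat)),
              "mean_t": float(np.nanmean(res.tstat)),
              "aic_by_age_degree": aic}
    _write_json(report, rundir / "fit_report.json")
    return {"result": res, "report": report}


# ---------------------------------------------------------------------------
# Stage: rft
# ---------------------------------------------------------------------------

def stage_rft(cfg: dict, rundir, inputs=None, fit=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    mesh = data["mesh"]
    if fit is not None:
        tmap, resid, df = fit["result"].tstat, fit["result"].resid, fit["result"].df
    else:
        tmap = np.loadtxt(rundir / "tmap.csv")
        resid, _ = surfaces.read_vertex_maps(rundir / "residuals.csv")
        df = json.loads((rundir / "fit_report.json").read_text())["df"]

    rcfg = cfg["rft"]
    sm = rft.estimate_fwhm(resid, mesh)
    thr = rft.primary_threshold_from_p(float(rcfg["primary_p"]), df)
    clusters = rft.extract_clusters(tmap, mesh, thr, sign=str(rcfg["sign"]))
    clusters = rft.cluster_pvalues(clusters, sm, df,
                                   alpha=float(rcfg["alpha"]))
    clusters.table.to_csv(rundir / "clusters.tsv", sep="\t", index=False)
    np.savetxt(rundir / "cluster_labels.csv", clusters.vertex_labels, fmt="%d")

    report = {"fwhm_mm": sm.fwhm, "resel_counts": list(sm.resel_counts),
              "primary_threshold_t": thr, "alpha": float(rcfg["alpha"]),
              "n_clusters": clusters.n_clusters,
              "n_significant": int(clusters.table["significant"].sum()),
              "clusters": clusters.table}
    effect_map = data.get("effect_map")
    if effect_map is not None and (effect_map != 0).any():
        sig = clusters.significant_mask()
        truth = effect_map != 0
        denom = sig.sum() + truth.sum()
        report["dice_vs_planted_patch"] = (
            float(2.0 * np.sum(sig & truth) / denom) if denom else 0.0)
    _write_json(report, rundir / "rft_report.json")
    return {"smoothness": sm, "clusters": clusters, "report": report}


# ---------------------------------------------------------------------------
# Stage: enrichment by class
# ---------------------------------------------------------------------------

def stage_enrich(cfg: dict, rundir, inputs=None, fit=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    mesh = data["mesh"]
    tmap = (fit["result"].tstat if fit is not None
            else np.loadtxt(rundir / "tmap.csv"))
    n_perm = int(cfg["nulls"]["n_perm"])
    report = {}
    for key in ("types", "networks"):
        labels, names = data["atlases"][key]
        table, _ = nulls.class_enrichment(
            tmap, labels, mesh, class_names=names,
            n_perm=n_perm, seed=_stage_seed(cfg["seed"], 7))
        table.to_csv(rundir / f"enrichment_{key}.tsv", sep="\t", index=False)
        report[key] = table
    _write_json(report, rundir / "enrichment_report.json")
    return {"report": report}


# ---------------------------------------------------------------------------
# Stage: expression contextualization
# ---------------------------------------------------------------------------

def stage_expression(cfg: dict, rundir, inputs=None, fit=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    mesh = data["mesh"]
    tmap = (fit["result"].tstat if fit is not None
            else np.loadtxt(rundir / "tmap.csv"))
    panel = pd.read_csv(rundir / "expression_panel.csv")
    weights = pd.read_csv(rundir / "specificity.tsv", sep="\t")
    markers = json.loads((rundir / "markers.json").read_text())

    scores = expr.score_all_components(panel, weights, markers)
    area_names, area_cent = data["area_centroids"]
    scores = scores.reindex(area_names)
    scores.to_csv(rundir / "expression_scores.csv")
    fine_labels = data["atlases"]["fine"][0]
    table, _ = expr.correlate_expression_with_effect(
        scores, tmap, fine_labels, mesh, area_centroids=area_cent,
        n_perm=int(cfg["nulls"]["n_perm"]),
        seed=_stage_seed(cfg["seed"], 8))
    table.to_csv(rundir / "expression_correlations.tsv", sep="\t",
                 index=False)
    _write_json({"correlations": table}, rundir / "expression_report.json")
    return {"scores": scores, "report": {"correlations": table}}


# ---------------------------------------------------------------------------
# Stage: disorder similarity
# ---------------------------------------------------------------------------

def stage_disorders(cfg: dict, rundir, inputs=None, fit=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    mesh = data["mesh"]
    tmap = (fit["result"].tstat if fit is not None
            else np.loadtxt(rundir / "tmap.csv"))
    labels64 = data["atlases"]["parcels"][0]
    ids, eff = surfaces.parcellate(tmap, labels64)
    _, cents, hemi = surfaces.parcel_centroids(mesh, labels64)
    ddf = pd.read_csv(rundir / "disorder_maps.csv")
    dmaps = {c: ddf[c].to_numpy(float) for c in ddf.columns
             if c != "parcel_id"}
    table = similarity.disorder_similarity(
        eff, dmaps, cents, n_perm=int(cfg["nulls"]["n_perm"]),
        seed=_stage_seed(cfg["seed"], 9))
    table.to_csv(rundir / "disorder_similarity.tsv", sep="\t", index=False)
    _write_json({"similarity": table}, rundir / "disorder_report.json")
    return {"report": {"similarity": table}}


# ---------------------------------------------------------------------------
# Stage: age groups and centering sweep
# ---------------------------------------------------------------------------

def stage_agegroups(cfg: dict, rundir, inputs=None, fit=None) -> dict:
    rundir = Path(rundir)
    data = inputs or load_inputs(rundir)
    mesh = data["mesh"]
    spec = _design_spec(cfg)
    bounds = [tuple(b) for b in cfg["age_groups"]]
    groups = glm.fit_age_groups(data["thickness"], data["subjects"], spec,
                                bounds=bounds)
    whole_t = (fit["result"].tstat if fit is not None
               else np.loadtxt(rundir / "tmap.csv"))
    labels64 = data["atlases"]["parcels"][0]
    _, whole_parcel = surfaces.parcellate(whole_t, labels64)
    group_parcel = {}
    gt = {}
    for b, res in groups.items():
        _, group_parcel[b] = surfaces.parcellate(res.tstat, labels64)
        gt[b] = res
    ddf = pd.read_csv(rundir / "disorder_maps.csv")
    scz = ddf["schizophrenia"].to_numpy(float)
    per_group, comparisons = similarity.age_group_similarity(
        group_parcel, whole_parcel, scz)
    per_group.to_csv(rundir / "agegroup_similarity.tsv", sep="\t",
                     index=False)
    comparisons.to_csv(rundir / "agegroup_comparisons.tsv", sep="\t",
                       index=False)

    scfg = cfg["sweep"]
    centers = np.arange(float(scfg["start"]), float(scfg["stop"]) + 1e-9,
                        float(scfg["step"]))
    sweep = glm.age_center_sweep(data["thickness"], data["subjects"], spec,
                                 centers=centers)
    sweep_rows = [{"center": c, "peak_t": float(np.nanmax(r.tstat)),
                   "mean_t": float(np.nanmean(r.tstat))}
                  for c, r in sweep.items()]
    sweep_table = pd.DataFrame(sweep_rows)
    sweep_table.to_csv(rundir / "sweep_summary.tsv", sep="\t", index=False)

    report = {"groups": {f"{lo}-{hi}": {"n": res.n, "df": res.df}
                         for (lo, hi), res in gt.items()},
              "similarity": per_group, "comparisons": comparisons,
              "sweep": sweep_table}
    _write_json(report, rundir / "agegroup_report.json")
    return {"report": report}


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, rundir) -> dict:
    """Execute all stages in order; returns (and writes) the merged report."""
    rundir = Path(rundir)
    report = {"config": cfg}
    try:
        inputs = stage_synthesize(cfg, rundir)
    except Exception as e:
        raise PipelineError(f"[synthesize] {e}") from e
    stages = [("fit", stage_fit), ("rft", stage_rft),
              ("enrichment", stage_enrich), ("expression", stage_expression),
              ("disorders", stage_disorders), ("age_groups", stage_agegroups)]
    fit = None
    for name, fn in stages:
        try:
            if name == "fit":
                fit = fn(cfg, rundir, inputs=inputs)
                report[name] = fit["report"]
            else:
                report[name] = fn(cfg, rundir, inputs=inputs,
                                  fit=fit)["report"]
        except Exception as e:
            raise PipelineError(f"[{name}] {e}") from e
    _write_json(report, rundir / "report.json")
    return json.loads((rundir / "report.json").read_text())
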