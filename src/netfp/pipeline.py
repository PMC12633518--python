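"""End-to-end workflow orchestration (simulate -> features -> network ->
harmonize -> reliability -> classification -> fingerprinting).

Every report is a JSON file embedding the config hash and package version;
given the same config and seed the reports are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    ClassifierConfig,
    classify_disease_binary,
    patient_fingerprint,
    regional_importance,
)
from .config import RunConfig, config_hash
from .harmonization import fit_edgewise_model, residualize
from .io import covariate_frame, write_edge_table, write_similarity_matrix
from .kinetics import KineticsConfig, feature_frame
from .network import (
    build_similarity_matrix,
    cohort_consistency,
    cohort_edge_table,
    robust_standardize,
)
from .registry import build_default_registry
from .reliability import (
    blocking_comparison,
    edgewise_icc,
    identify_subjects,
    testretest_correlation,
)
from .synthetic import example_design, simulate_cohort

__all__ = ["run_pipeline", "matrices_for_scans"]


def _write_report(path: Path, name: str, payload: dict, config: RunConfig) -> None:
    doc = {
        "report": name,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "package_version": __version__,
        **payload,
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def matrices_for_scans(scans, config: RunConfig | None = None, registry=None):
    """Features -> robust standardization -> per-scan similarity matrices."""
    registry = registry or build_default_registry()
    kin = KineticsConfig(
        suv_times_minutes=tuple(config.suv_times_minutes) if config else (1.25, 13.5, 50.0),
        k1_fit_window_minutes=tuple(config.k1_fit_window_minutes) if config else (0.0, 50.0),
    )
    features = feature_frame(scans, config=kin, registry=registry)
    tracer_map = {s.scan_id: s.tracer for s in scans}
    standardized, params = robust_standardize(features, tracer_map)
    matrices = []
    for scan in scans:
        sub = standardized.loc[scan.scan_id].reindex(registry.names)
        matrices.append(build_similarity_matrix(sub, scan_id=scan.scan_id))
    return matrices, standardized, params


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full demo workflow on a simulated cohort; return report paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = build_default_registry()
    reports: dict[str, Path] = {}

    # 1. simulate
    design = example_design(scale=config.design_scale)
    scans, truth = simulate_cohort(design, seed=config.seed, out_dir=out / "cohort")

    # 2. features + networks
    matrices, standardized, _ = matrices_for_scans(scans, config, registry)
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for m in matrices:
        write_similarity_matrix(m, mat_dir / f"{m.scan_id}.tsv")
    edge_df = cohort_edge_table(matrices)
    write_edge_table(edge_df, out / "edges.tsv")

    covariates = covariate_frame(scans)
    baseline = covariates["session"] == "baseline"
    hc_baseline = baseline & (covariates["diagnosis"] == "HC")

    # 3. consistency of HC baseline networks
    corr, summary = cohort_consistency(
        edge_df.loc[hc_baseline[hc_baseline].index],
        covariates["tracer"].to_dict(),
    )
    consistency_path = out / "consistency.json"
    _write_report(
        consistency_path,
        "cohort_consistency",
        {
            "global_median_mad": list(summary["global"]),
            "intra_tracer": {k: list(v) for k, v in summary["intra_tracer"].items()},
            "inter_tracer": {f"{a}|{b}": list(v) for (a, b), v in summary["inter_tracer"].items()},
        },
        config,
    )
    reports["consistency"] = consistency_path

    # 4. harmonization fitted on baseline HCs, one model per tracer
    #    (pooled designs are collinear: genotype NA <-> genotype-free tracer)
    corrected = edge_df.copy()
    covariate_names: list[str] = []
    for tracer in sorted(covariates["tracer"].unique()):
        in_tracer = covariates["tracer"] == tracer
        fit_ids = list(covariates.index[in_tracer & hc_baseline])
        usable = [
            c for c in config.harmonization_covariates
            if covariates.loc[fit_ids, c].nunique() > 1
        ]
        covariate_names = sorted(set(covariate_names) | set(usable))
        if not usable:
            continue
        tracer_ids = covariates.index[in_tracer]
        model = fit_edgewise_model(
            edge_df.loc[tracer_ids],
            covariates.loc[tracer_ids],
            fit_subset=fit_ids,
            covariate_names=usable,
        )
        corrected.loc[tracer_ids] = residualize(
            model, edge_df.loc[tracer_ids], covariates.loc[tracer_ids]
        )
    write_edge_table(corrected, out / "edges_corrected.tsv")

    # 5. reliability: blockade + retest
    rel: dict = {}
    block_ids = covariates.index[covariates["session"] == "block"]
    if len(block_ids) > 0:
        by_id = {m.scan_id: m for m in matrices}
        pre, post = [], []
        for bid in block_ids:
            base_id = bid.replace("_block", "_baseline")
            pre.append(by_id[base_id])
            post.append(by_id[bid])
        res = blocking_comparison(pre, post)
        rel["blocking"] = {
            "n": len(pre),
            "mean_percent_increase": res.mean_percent_increase,
            "p_value": res.p_value,
        }
    retest_ids = covariates.index[covariates["session"] == "retest"]
    if len(retest_ids) >= 3:
        subjects = [covariates.loc[i, "subject_id"] for i in retest_ids]
        test_df = edge_df.loc[[f"{s}_baseline" for s in subjects]]
        retest_df = edge_df.loc[[f"{s}_retest" for s in subjects]]
        test_df.index = retest_df.index = subjects
        rho = testretest_correlation(test_df, retest_df)
        icc, icc_med, icc_mad = edgewise_icc(test_df, retest_df)
        acc, _ = identify_subjects(test_df, retest_df)
        rel["testretest"] = {
            "n": len(subjects),
            "rho_mean": float(rho.mean()),
            "rho_sd": float(rho.std(ddof=1)),
            "icc_median": icc_med,
            "icc_mad": icc_mad,
            "identification_accuracy": acc,
        }
    rel_path = out / "reliability.json"
    _write_report(rel_path, "reliability", rel, config)
    reports["reliability"] = rel_path

    # 6. one-vs-all disease classification per tracer cohort
    clf_config = ClassifierConfig(
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
        n_bootstrap=config.n_bootstrap,
        l1_lambda_grid=tuple(np.logspace(-3, 2, config.l1_lambda_grid_size)),
    )
    clf_out: dict = {}
    base_cov = covariates.loc[baseline[baseline].index]
    for disease in sorted(set(base_cov["diagnosis"]) - {"HC"}):
        tracers = set(base_cov.loc[base_cov["diagnosis"] == disease, "tracer"])
        mask = baseline & covariates["diagnosis"].isin(["HC", disease]) & covariates[
            "tracer"
        ].isin(tracers)
        ids = covariates.index[mask]
        sub_cov = covariates.loc[ids]
        usable = [c for c in covariate_names if sub_cov[c].nunique() > 1]
        task_config = replace(clf_config, covariate_names=tuple(usable))
        try:
            report = classify_disease_binary(
                edge_df.loc[ids],
                sub_cov["diagnosis"],
                covariates=sub_cov if usable else None,
                config=task_config,
                seed=config.seed,
            )
        except ValueError as exc:
            clf_out[disease] = {"error": str(exc)}
            continue
        importance = regional_importance(report.coefficients, registry.names)
        top = importance.sort_values(ascending=False).head(5)
        clf_out[disease] = {
            "ap": report.ap,
            "ap_ci": list(report.ap_ci),
            "ap_chance": report.ap_chance,
            "roc_auc": report.roc_auc,
            "roc_auc_ci": list(report.roc_auc_ci),
            "selected_lambda": report.selected_lambda,
            "top_importance": top.to_dict(),
        }
    clf_path = out / "classification.json"
    _write_report(clf_path, "classification", clf_out, config)
    reports["classification"] = clf_path

    # 7. patient fingerprinting on corrected edges
    patient_ids = covariates.index[baseline & (covariates["diagnosis"] != "HC")]
    fp = patient_fingerprint(
        corrected.loc[patient_ids], covariates.loc[patient_ids, "diagnosis"]
    )
    fp_path = out / "fingerprint.json"
    _write_report(
        fp_path,
        "fingerprint",
        {
            "balanced_accuracy": fp.balanced_accuracy,
            "recall": fp.recall.to_dict(),
            "confusion": {str(k): v for k, v in fp.confusion.to_dict(orient="index").items()},
        },
        config,
    )
    reports["fingerprint"] = fp_path
    return reports
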