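"""End-to-end orchestration: cohort -> features -> model -> explanations -> networks.

Six stages, each logging its counts and residuals and contributing files to
a manifest with content hashes:

1. **cohort** — generate a synthetic cohort (or load a prepared one);
2. **preprocess** — smooth, variance-filter, F-test-select voxels;
3. **fit** — train/test split, boosted regression, MAE bookkeeping;
4. **explain** — Shapley values for every subject, per-voxel importance,
   peak-voxel selection, force records, MDS embedding of Shapley vectors;
5. **networks** — per-subject interaction tensors restricted to the peak
   voxels, age-ordered dynamic panel, aggregated edge importance;
6. **network-of-networks** — regularized-Laplacian SPD transform, pairwise
   geodesic distances, edge thresholding, and a lambda-sensitivity check.

The run is deterministic for a fixed config (single-threaded fitting, one
root seed fanned out to per-stage child seeds), so repeated runs produce
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import explain, io, model as model_mod, networks, preprocess, shapley
from .config import PipelineConfig
from .synthetic import CohortSpec, GroundTruth, SubjectRecord, VoxelVolume, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    out_dir: Path
    records: list[SubjectRecord]
    truth: Optional[GroundTruth]
    features: preprocess.FeatureMatrix
    split: model_mod.SplitResult
    model: model_mod.EnsembleModel
    metrics: dict
    decompositions: list[shapley.ShapDecomposition]
    importance: np.ndarray
    peak_voxels: np.ndarray
    peak_tensors: list[shapley.InteractionTensor]  # restricted to peak voxels
    embedding_table: pd.DataFrame
    panel: list[dict]
    distance_net: networks.CohortDistanceNet
    manifest_path: Path = field(default=None)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) % (2**31))]


def run_pipeline(
    config: PipelineConfig,
    cohort_spec: CohortSpec | None = None,
    cohort_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis; returns in-memory artifacts and writes files.

    Exactly one input mode: a :class:`CohortSpec` for synthetic data, or a
    cohort directory of prepared NIfTI volumes + metadata.  With neither, a
    default synthetic spec sized to the config's feature count is used.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write_json(out_dir / "config.resolved.json")
    split_seed, fit_seed = _child_seeds(config.seed, 2)
    stages: list[dict] = []

    # -- stage 1: cohort ----------------------------------------------------
    truth = None
    if cohort_dir is not None:
        if cohort_spec is not None:
            raise ValueError("give either cohort_spec or cohort_dir, not both")
        records, volumes = io.read_cohort(cohort_dir)
    else:
        if cohort_spec is None:
            cohort_spec = CohortSpec(seed=config.seed)
        records, volumes, truth = generate_cohort(cohort_spec)
    files: dict[str, Path] = {}
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "dementia_level": [r.dementia_level for r in records],
        }
    )
    meta_path = out_dir / "metadata.csv"
    meta.to_csv(meta_path, index=False)
    files["metadata"] = meta_path
    if config.write_nifti and cohort_dir is None:
        files.update(io.write_cohort(volumes, records, out_dir / "cohort"))
    stages.append({"stage": "cohort", "n_subjects": len(records), "files": files})
    logger.info("stage cohort: %d subjects", len(records))

    # -- stage 2: preprocess ------------------------------------------------
    fm = preprocess.preprocess_pipeline(volumes, records, config)
    files = io.write_feature_matrix(fm, out_dir)
    stages.append({"stage": "preprocess", "n_features": int(fm.values.shape[1]), "files": files})

    # -- stage 3: fit -------------------------------------------------------
    y = np.array([r.age for r in records])
    split = model_mod.train_test_split(len(records), config.test_fraction, seed=split_seed)
    ens = model_mod.fit(
        fm.values[split.train_idx], y[split.train_idx], config.gbt, seed=fit_seed
    )
    pred_all = model_mod.predict(ens, fm.values)
    test_mae = model_mod.mae(y[split.test_idx], pred_all[split.test_idx])
    null_mae = model_mod.mae(
        y[split.test_idx], np.full(split.test_idx.size, y[split.train_idx].mean())
    )
    metrics = {
        "train_mae": model_mod.mae(y[split.train_idx], pred_all[split.train_idx]),
        "test_mae": test_mae,
        "null_test_mae": null_mae,
        "n_train": int(split.train_idx.size),
        "n_test": int(split.test_idx.size),
        "export_fidelity": ens.meta.get("export_fidelity"),
    }
    model_path = out_dir / "model.json"
    model_mod.save_model(ens, model_path)
    metrics_path = out_dir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    pred_path = out_dir / "predictions.csv"
    pd.DataFrame(
        {
            "subject_id": fm.subject_ids,
            "age": y,
            "predicted_age": pred_all,
            "split": ["test" if i in set(split.test_idx) else "train" for i in range(len(y))],
        }
    ).to_csv(pred_path, index=False)
    files = {"model": model_path, "metrics": metrics_path, "predictions": pred_path}
    stages.append({"stage": "fit", "metrics": metrics, "files": files})
    logger.info("stage fit: test MAE %.2f (null %.2f)", test_mae, null_mae)

    # -- stage 4: explain ---------------------------------------------------
    decs, _ = shapley.cohort_shap(ens, fm.values, fm.subject_ids, interactions=False)
    max_resid = max(d.additivity_residual() for d in decs)
    importance, _pairs = explain.summary_stats(decs, fm.values)
    peaks = model_mod.select_peak_voxels(importance, min(config.n_peak_voxels, importance.size))
    forces = [explain.force_decompose(d, top_n=min(10, importance.size)) for d in decs]
    emb, emb_table = explain.shap_dynamics(decs, records)

    files = {"shap_values": io.write_shap_values(decs, out_dir / "shap_values.csv")}
    imp_path = out_dir / "importance.csv"
    pd.DataFrame(
        {"feature_id": np.arange(importance.size), "mean_abs_phi": importance}
    ).to_csv(imp_path, index=False)
    files["importance"] = imp_path
    peaks_path = out_dir / "peak_voxels.csv"
    coords = fm.feature_coords[peaks]
    pd.DataFrame(
        np.c_[peaks, importance[peaks], coords],
        columns=["feature_id", "mean_abs_phi", "i", "j", "k", "x_mm", "y_mm", "z_mm"],
    ).to_csv(peaks_path, index=False)
    files["peak_voxels"] = peaks_path
    force_path = out_dir / "force_records.csv"
    pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in forces],
            "base": [f.base for f in forces],
            "push_up_total": [f.push_up_total for f in forces],
            "pull_down_total": [f.pull_down_total for f in forces],
            "prediction": [f.prediction for f in forces],
            "top_features": [
                ";".join(f"{i}:{v:.6g}" for i, v in f.contributions) for f in forces
            ],
        }
    ).to_csv(force_path, index=False)
    files["force_records"] = force_path
    emb_path = out_dir / "embedding.csv"
    emb_table.to_csv(emb_path, index=False)
    files["embedding"] = emb_path
    stages.append(
        {
            "stage": "explain",
            "max_additivity_residual": max_resid,
            "n_peak_voxels": int(peaks.size),
            "mds_stress": emb.stress,
            "files": files,
        }
    )
    logger.info("stage explain: max additivity residual %.3e", max_resid)

    # -- stage 5: networks --------------------------------------------------
    # Interactions are computed on the full model in subject chunks, then
    # restricted to the peak voxels for the network analyses.
    peak_tensors: list[shapley.InteractionTensor] = []
    max_complete = 0.0
    chunk = 16
    for lo in range(0, len(records), chunk):
        sl = slice(lo, lo + chunk)
        cdecs, ctens = shapley.cohort_shap(
            ens, fm.values[sl], fm.subject_ids[sl], interactions=True
        )
        for d, t in zip(cdecs, ctens):
            max_complete = max(
                max_complete, abs(t.values.sum() - (d.prediction - d.phi0))
            )
            peak_tensors.append(
                shapley.InteractionTensor(t.subject_id, t.values[np.ix_(peaks, peaks)])
            )
    phi_peak = {d.subject_id: d.phi[peaks] for d in decs}
    peak_decs = [
        shapley.ShapDecomposition(d.subject_id, d.phi0, phi_peak[d.subject_id], d.prediction)
        for d in decs
    ]
    panel = networks.dynamic_network_panel(
        peak_decs, peak_tensors, records, config.edge_display_fraction
    )
    files = {}
    nodes_path = out_dir / "network_nodes.csv"
    pd.DataFrame(
        np.c_[np.arange(peaks.size), peaks, fm.feature_coords[peaks]],
        columns=["node", "feature_id", "i", "j", "k", "x_mm", "y_mm", "z_mm"],
    ).to_csv(nodes_path, index=False)
    files["network_nodes"] = nodes_path
    node_rows, edge_rows = [], []
    for order, entry in enumerate(panel):
        for node, phi in enumerate(entry["node_phi"]):
            node_rows.append((order, entry["subject_id"], entry["age"], node, phi))
        for i, j, w in entry["edges"]:
            edge_rows.append((order, entry["subject_id"], entry["age"], i, j, w))
    panel_nodes = out_dir / "panel_nodes.csv"
    pd.DataFrame(
        node_rows, columns=["age_rank", "subject_id", "age", "node", "phi"]
    ).to_csv(panel_nodes, index=False)
    panel_edges = out_dir / "panel_edges.csv"
    pd.DataFrame(
        edge_rows, columns=["age_rank", "subject_id", "age", "node_i", "node_j", "phi_ij"]
    ).to_csv(panel_edges, index=False)
    files["panel_nodes"] = panel_nodes
    files["panel_edges"] = panel_edges
    mean_abs_edge = np.abs(np.stack([t.values for t in peak_tensors])).mean(axis=0)
    iu, ju = np.triu_indices(peaks.size, k=1)
    edge_imp = out_dir / "edge_importance.csv"
    pd.DataFrame(
        {"node_i": iu, "node_j": ju, "mean_abs_phi_ij": mean_abs_edge[iu, ju]}
    ).sort_values(
        ["mean_abs_phi_ij", "node_i", "node_j"], ascending=[False, True, True]
    ).to_csv(edge_imp, index=False)
    files["edge_importance"] = edge_imp
    stages.append(
        {
            "stage": "networks",
            "n_subjects": len(peak_tensors),
            "max_completeness_residual": max_complete,
            "files": files,
        }
    )
    logger.info("stage networks: max completeness residual %.3e", max_complete)

    # -- stage 6: network of networks --------------------------------------
    def non_at(lam: float) -> networks.CohortDistanceNet:
        spd = [
            networks.regularized_laplacian(
                networks.build_network(t, config.edge_display_fraction),
                lam=lam,
                weight_mode=config.weight_mode,
                zero_diagonal=True,
            )
            for t in peak_tensors
        ]
        return networks.network_of_networks(spd, config.keep_fraction)

    net = non_at(config.laplacian_lambda)
    iu, ju = np.triu_indices(len(peak_tensors), k=1)
    lam_sensitivity = {}
    for scale, name in ((0.1, "lambda/10"), (10.0, "10*lambda")):
        alt = non_at(config.laplacian_lambda * scale)
        rho = stats.spearmanr(net.B[iu, ju], alt.B[iu, ju]).statistic
        lam_sensitivity[name] = float(rho)
    files = {}
    b_path = out_dir / "distance_matrix.csv"
    pd.DataFrame(net.B, index=net.subject_ids, columns=net.subject_ids).to_csv(b_path)
    files["distance_matrix"] = b_path
    edges_path = out_dir / "retained_edges.csv"
    pd.DataFrame(
        [
            (net.subject_ids[i], net.subject_ids[j], d)
            for i, j, d in net.retained_edges
        ],
        columns=["subject_i", "subject_j", "distance"],
    ).to_csv(edges_path, index=False)
    files["retained_edges"] = edges_path
    stages.append(
        {
            "stage": "network_of_networks",
            "n_edges": len(net.retained_edges),
            "lambda_rank_correlation": lam_sensitivity,
            "files": files,
        }
    )
    logger.info(
        "stage network_of_networks: %d edges kept, lambda sensitivity %s",
        len(net.retained_edges),
        lam_sensitivity,
    )

    manifest_path = io.write_manifest(out_dir, stages)
    return PipelineResult(
        out_dir=out_dir,
        records=records,
        truth=truth,
        features=fm,
        split=split,
        model=ens,
        metrics=metrics,
        decompositions=decs,
        importance=importance,
        peak_voxels=peaks,
        peak_tensors=peak_tensors,
        embedding_table=emb_table,
        panel=panel,
        distance_net=net,
        manifest_path=manifest_path,
    )
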