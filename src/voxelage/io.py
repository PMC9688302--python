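"""File formats: NIfTI cohorts, CSV tables, network exports, run manifests.

Layout conventions used across the pipeline and CLI:

* cohort directory — ``sub-XXX_gmv.nii.gz`` per subject, ``mask.nii.gz``
  (shared brain mask), and ``metadata.csv`` with exactly the columns
  ``subject_id, age, sex, dementia_level``;
* feature matrix — ``features.csv`` (subjects x selected voxels) plus the
  sidecar ``feature_coords.csv`` (feature_id, i, j, k, x_mm, y_mm, z_mm,
  flat_index);
* Shapley values — ``shap_values.csv`` with one row per subject: phi0,
  prediction, then per-feature phi columns;
* interaction tensors — compressed ``.npz`` with a JSON sidecar naming the
  subject and feature ids;
* networks — weighted edge lists (TSV) and GraphML via networkx;
* ``manifest.json`` — every output file with a SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix
from .shapley import InteractionTensor, ShapDecomposition
from .synthetic import SubjectRecord, VoxelVolume

METADATA_COLUMNS = ["subject_id", "age", "sex", "dementia_level"]


# -- cohort ------------------------------------------------------------------


def write_cohort(
    volumes: list[VoxelVolume],
    records: list[SubjectRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """One NIfTI per subject, a shared mask volume, and the metadata CSV."""
    if not volumes or not records:
        raise ValueError("refusing to write an empty cohort")
    if len(volumes) != len(records):
        raise ValueError(f"{len(volumes)} volumes vs {len(records)} records")
    shapes = {v.values.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volumes disagree on grid shape: {sorted(shapes)}")
    affines = {tuple(np.round(v.affine, 12).ravel()) for v in volumes}
    if len(affines) > 1:
        raise ValueError("volumes disagree on the affine")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rec, vol in zip(records, volumes):
        p = out_dir / f"{rec.subject_id}_gmv.nii.gz"
        nib.save(nib.Nifti1Image(vol.values.astype(np.float64), vol.affine), p)
        paths[rec.subject_id] = p
    mask_path = out_dir / "mask.nii.gz"
    nib.save(
        nib.Nifti1Image(volumes[0].mask.astype(np.uint8), volumes[0].affine), mask_path
    )
    paths["mask"] = mask_path
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
    paths["metadata"] = meta_path
    return paths


def read_cohort(
    nifti_dir: str | Path, metadata_csv: str | Path | None = None
) -> tuple[list[SubjectRecord], list[VoxelVolume]]:
    """Load a cohort directory written by :func:`write_cohort`.

    Also accepts externally prepared data laid out the same way (one
    spatially normalized GMV volume per subject plus the metadata table).
    """
    nifti_dir = Path(nifti_dir)
    metadata_csv = Path(metadata_csv) if metadata_csv else nifti_dir / "metadata.csv"
    if not metadata_csv.exists():
        raise FileNotFoundError(f"metadata table not found: {metadata_csv}")
    meta = pd.read_csv(metadata_csv)
    if list(meta.columns) != METADATA_COLUMNS:
        raise ValueError(
            f"metadata columns must be exactly {METADATA_COLUMNS}, got {list(meta.columns)}"
        )
    if meta.empty:
        raise ValueError(f"metadata table {metadata_csv} lists no subjects")
    mask_path = nifti_dir / "mask.nii.gz"
    mask = None
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    records: list[SubjectRecord] = []
    volumes: list[VoxelVolume] = []
    for row in meta.itertuples(index=False):
        p = nifti_dir / f"{row.subject_id}_gmv.nii.gz"
        if not p.exists():
            p_alt = nifti_dir / f"{row.subject_id}_gmv.nii"
            if not p_alt.exists():
                raise FileNotFoundError(f"no volume for subject {row.subject_id!r} in {nifti_dir}")
            p = p_alt
        img = nib.load(p)
        values = np.asarray(img.dataobj, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite voxels in volume for subject {row.subject_id!r}")
        vol_mask = mask if mask is not None else np.ones(values.shape, dtype=bool)
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                sex=str(row.sex),
                dementia_level=int(row.dementia_level),
            )
        )
        volumes.append(VoxelVolume(values=values, affine=np.asarray(img.affine), mask=vol_mask))
    return records, volumes


# -- feature matrix ----------------------------------------------------------


def write_feature_matrix(fm: FeatureMatrix, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values = pd.DataFrame(
        fm.values, index=pd.Index(fm.subject_ids, name="subject_id"),
        columns=[f"f{i}" for i in range(fm.values.shape[1])],
    )
    values_path = out_dir / "features.csv"
    values.to_csv(values_path)
    coords = pd.DataFrame(
        fm.feature_coords, columns=["i", "j", "k", "x_mm", "y_mm", "z_mm"]
    )
    coords.insert(0, "feature_id", np.arange(len(coords)))
    coords["flat_index"] = fm.flat_indices
    coords_path = out_dir / "feature_coords.csv"
    coords.to_csv(coords_path, index=False)
    return {"features": values_path, "feature_coords": coords_path}


def read_feature_matrix(out_dir: str | Path) -> FeatureMatrix:
    out_dir = Path(out_dir)
    values = pd.read_csv(out_dir / "features.csv", index_col="subject_id")
    coords = pd.read_csv(out_dir / "feature_coords.csv")
    return FeatureMatrix(
        values=values.to_numpy(dtype=float),
        feature_coords=coords[["i", "j", "k", "x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        subject_ids=[str(s) for s in values.index],
        flat_indices=coords["flat_index"].to_numpy(dtype=int),
    )


# -- Shapley outputs ---------------------------------------------------------


def write_shap_values(decs: list[ShapDecomposition], path: str | Path) -> Path:
    if not decs:
        raise ValueError("no decompositions to write")
    m = decs[0].phi.size
    frame = pd.DataFrame(
        {
            "subject_id": [d.subject_id for d in decs],
            "phi0": [d.phi0 for d in decs],
            "prediction": [d.prediction for d in decs],
        }
    )
    phis = pd.DataFrame(
        np.stack([d.phi for d in decs]), columns=[f"phi_f{i}" for i in range(m)]
    )
    path = Path(path)
    pd.concat([frame, phis], axis=1).to_csv(path, index=False)
    return path


def read_shap_values(path: str | Path) -> list[ShapDecomposition]:
    frame = pd.read_csv(path)
    phi_cols = [c for c in frame.columns if c.startswith("phi_f")]
    return [
        ShapDecomposition(
            subject_id=str(row["subject_id"]),
            phi0=float(row["phi0"]),
            phi=row[phi_cols].to_numpy(dtype=float),
            prediction=float(row["prediction"]),
        )
        for _, row in frame.iterrows()
    ]


def write_interaction_tensor(it: InteractionTensor, path: str | Path) -> Path:
    """Compressed dense matrix plus a JSON sidecar naming the subject."""
    path = Path(path)
    np.savez_compressed(path, values=it.values)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {"subject_id": it.subject_id, "n_features": int(it.values.shape[0])}, fh
        )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_interaction_tensor(path: str | Path) -> InteractionTensor:
    path = Path(path)
    with np.load(path) as npz:
        values = npz["values"]
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return InteractionTensor(subject_id=sidecar["subject_id"], values=values)


# -- network exports ---------------------------------------------------------


def write_edge_list(
    edges: list[tuple[int, int, float]], path: str | Path, header: tuple[str, str, str] = ("node_i", "node_j", "weight")
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, j, w in edges:
            fh.write(f"{i}\t{j}\t{w!r}\n")
    return path


def write_graphml(
    edges: list[tuple[int, int, float]],
    n_nodes: int,
    path: str | Path,
    node_attrs: dict[int, dict] | None = None,
) -> Path:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    if node_attrs:
        nx.set_node_attributes(g, node_attrs)
    g.add_weighted_edges_from(edges)
    path = Path(path)
    nx.write_graphml(g, path)
    return path


# -- manifest ----------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stages: list[dict]) -> Path:
    """List every produced file with its content hash, grouped by stage."""
    out_dir = Path(out_dir)
    for stage in stages:
        stage["files"] = {
            name: {"path": str(Path(p).relative_to(out_dir)), "sha256": sha256_file(p)}
            for name, p in stage.get("files", {}).items()
        }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump({"n_stages": len(stages), "stages": stages}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
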