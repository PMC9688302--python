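"""Voxel-level explanation: force decompositions, summaries, and MDS dynamics.

A subject's predicted age is the model baseline plus signed per-voxel
contributions; the *force* view splits those into the voxels pushing the
prediction up (positive Shapley values) and pulling it down (negative).
Across the cohort, per-voxel importance is the mean absolute Shapley value.
To see how explanations drift with age, each subject's Shapley vector is
treated as a point in R^M and the cohort is embedded in 2D with classical
multidimensional scaling on pairwise Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .shapley import ShapDecomposition
from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class ForceRecord:
    """One subject's prediction split into pushing and pulling voxels."""

    subject_id: str
    base: float
    contributions: list[tuple[int, float]]  # (feature_id, phi), |phi| descending
    push_up_total: float
    pull_down_total: float
    prediction: float


@dataclass
class Embedding2D:
    coords: np.ndarray  # (N, dim)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    stress: float


def force_decompose(dec: ShapDecomposition, top_n: int = 10) -> ForceRecord:
    """Split a decomposition into push-up/pull-down totals plus a top listing.

    Totals are over *all* features; only the listing is truncated to
    ``top_n``.  Ordering is deterministic: |phi| descending, feature index
    ascending on ties.
    """
    phi = dec.phi
    if top_n > phi.size:
        raise ValueError(f"top_n={top_n} exceeds feature count {phi.size}")
    order = np.lexsort((np.arange(phi.size), -np.abs(phi)))
    listed = [(int(i), float(phi[i])) for i in order[:top_n] if phi[i] != 0]
    return ForceRecord(
        subject_id=dec.subject_id,
        base=dec.phi0,
        contributions=listed,
        push_up_total=float(phi[phi > 0].sum()),
        pull_down_total=float(phi[phi < 0].sum()),
        prediction=dec.prediction,
    )


def summary_stats(
    decs: list[ShapDecomposition], X: np.ndarray | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Global importance and the per-subject (feature value, phi) pairing.

    Importance of feature i is mean_t |phi_i(x_t,i)| — the bar heights of a
    summary bar chart.  The returned long-format frame pairs each phi with
    its feature value (if X is given) for beeswarm-style export.
    """
    if not decs:
        raise ValueError("no decompositions given")
    Phi = np.stack([d.phi for d in decs])
    importance = np.abs(Phi).mean(axis=0)
    n, m = Phi.shape
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat([d.subject_id for d in decs], m),
            "feature_id": np.tile(np.arange(m), n),
            "phi": Phi.ravel(),
        }
    )
    if X is not None:
        X = np.asarray(X)
        if X.shape != Phi.shape:
            raise ValueError(f"X shape {X.shape} does not match phi shape {Phi.shape}")
        frame["feature_value"] = X.ravel()
    return importance, frame


def classical_mds(D: np.ndarray, dim: int = 2) -> Embedding2D:
    """Classical (Torgerson) MDS: eigendecomposition of -1/2 J D^2 J.

    ``D`` must be a symmetric, hollow, non-negative dissimilarity matrix.
    Coordinates are the top-``dim`` eigenvectors scaled by the square roots
    of their (negative-clamped) eigenvalues; for distances from a genuine
    Euclidean configuration the input distances are reproduced exactly.
    Sign convention: the first nonzero loading of each axis is positive.
    Stress is the relative residual of the embedded distances.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"D must be square, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("D must be symmetric")
    if np.any(D < 0):
        raise ValueError("D must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("D must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    clamped = np.clip(evals[:dim], 0.0, None)
    if np.any(evals[:dim] < -1e-10 * max(1.0, abs(evals[0]))):
        logger.warning(
            "classical_mds: negative leading eigenvalue clamped (non-Euclidean input)"
        )
    coords = evecs[:, :dim] * np.sqrt(clamped)
    for a in range(coords.shape[1]):  # deterministic sign
        nz = np.flatnonzero(np.abs(coords[:, a]) > 1e-12)
        if nz.size and coords[nz[0], a] < 0:
            coords[:, a] = -coords[:, a]
    emb = squareform(pdist(coords))
    denom = np.sqrt((D**2).sum())
    stress = float(np.sqrt(((emb - D) ** 2).sum()) / denom) if denom > 0 else 0.0
    return Embedding2D(coords=coords, eigenvalues=evals, stress=stress)


def shap_dynamics(
    decs: list[ShapDecomposition],
    records: list[SubjectRecord],
    dim: int = 2,
) -> tuple[Embedding2D, pd.DataFrame]:
    """Embed subjects' Shapley vectors in 2D, annotated with age and covariates.

    Dissimilarity is Euclidean distance between phi vectors.  Subjects of
    similar age carry similar explanations in a high-signal cohort, so the
    embedding separates young from old along its leading axis.
    """
    if len(decs) != len(records):
        raise ValueError(f"{len(decs)} decompositions vs {len(records)} records")
    by_id = {r.subject_id: r for r in records}
    missing = [d.subject_id for d in decs if d.subject_id not in by_id]
    if missing:
        raise ValueError(f"records missing for subjects: {missing[:5]}")
    Phi = np.stack([d.phi for d in decs])
    D = squareform(pdist(Phi))
    emb = classical_mds(D, dim=dim)
    rows = [by_id[d.subject_id] for d in decs]
    table = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "mds1": emb.coords[:, 0],
            "mds2": emb.coords[:, 1] if dim > 1 else 0.0,
            "age": [r.age for r in rows],
            "sex": [r.sex for r in rows],
            "dementia_level": [r.dementia_level for r in rows],
        }
    )
    return emb, table
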