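"""Per-subject interaction networks and their SPD-geodesic comparison.

Each subject's pairwise Shapley interactions form a weighted adjacency
matrix A over the analysed voxels.  To compare subjects, A is turned into a
symmetric positive-definite (SPD) matrix via the regularized graph
Laplacian

    A_bar = (D - W) + lambda I,    D = diag(row sums of W),

and pairs of subjects are compared with the affine-invariant Riemannian
distance between SPD matrices,

    d^2(P, Q) = tr log^2 (P^{-1/2} Q P^{-1/2}) = sum_k log^2 lambda_k,

where lambda_k are the generalized eigenvalues of (Q, P).  The cohort-level
"network of networks" is the N x N matrix of these distances with the
closest ``keep_fraction`` of subject pairs retained as edges.

Signed interaction weights can make D - W indefinite, so the default
``weight_mode="absolute"`` uses |phi_ij| (guaranteeing a PSD Laplacian and
min eigenvalue >= lambda); signed mode is available with an explicit
positive-definiteness check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .shapley import InteractionTensor, ShapDecomposition
from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class VoxelNetwork:
    """A subject's interaction network: adjacency = interaction matrix."""

    subject_id: str
    adjacency: np.ndarray  # (M, M), symmetric; full matrix, diagonal kept
    display_edges: list[tuple[int, int, float]]  # strongest |phi_ij| pairs, for export
    keep_fraction: float


@dataclass
class SPDNet:
    subject_id: str
    matrix: np.ndarray
    lam: float
    weight_mode: str


@dataclass
class CohortDistanceNet:
    """Network of networks: subjects as nodes, SPD geodesics as weights."""

    B: np.ndarray  # (N, N) symmetric, zero diagonal
    retained_edges: list[tuple[int, int, float]]  # closest pairs, ascending distance
    keep_fraction: float
    subject_ids: list[str]


def _top_offdiag_pairs(
    scores: np.ndarray, keep_fraction: float, largest: bool
) -> list[tuple[int, int, float]]:
    """The keep_fraction largest (or smallest) off-diagonal (i<j) entries.

    Ties are broken by ascending (i, j); the edge count is
    round(keep_fraction * n_pairs), at least 1.
    """
    m = scores.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    vals = scores[iu, ju]
    n_keep = max(1, int(round(keep_fraction * vals.size))) if vals.size else 0
    key = -vals if largest else vals
    order = np.lexsort((ju, iu, key))
    return [(int(iu[o]), int(ju[o]), float(vals[o])) for o in order[:n_keep]]


def build_network(it: InteractionTensor, edge_keep_fraction: float = 0.05) -> VoxelNetwork:
    """Wrap an interaction tensor as a network, with a sparsified edge view.

    The full matrix is always retained internally (the Laplacian uses it);
    ``display_edges`` keeps only the ``edge_keep_fraction`` largest
    |phi_ij| off-diagonal pairs, the "significant contributions" worth
    drawing.
    """
    A = np.asarray(it.values, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"interaction tensor must be square, got {A.shape}")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("interaction tensor is not symmetric")
    if not 0 < edge_keep_fraction <= 1:
        raise ValueError(f"edge_keep_fraction must be in (0, 1], got {edge_keep_fraction}")
    edges = _top_offdiag_pairs(np.abs(A), edge_keep_fraction, largest=True)
    edges = [(i, j, float(A[i, j])) for i, j, _ in edges]
    return VoxelNetwork(
        subject_id=it.subject_id,
        adjacency=A.copy(),
        display_edges=edges,
        keep_fraction=edge_keep_fraction,
    )


def regularized_laplacian(
    net: VoxelNetwork,
    lam: float = 1.0,
    weight_mode: str = "absolute",
    zero_diagonal: bool = True,
) -> SPDNet:
    """(D - W) + lambda I from a subject's interaction network.

    ``weight_mode="absolute"`` (default) uses |phi_ij| as edge weights, so
    the Laplacian is PSD and the result has min eigenvalue >= lambda for any
    lambda > 0.  Signed mode keeps the raw phi_ij and verifies positive
    definiteness numerically, raising if it fails.  The diagonal of the
    adjacency (per-voxel net main effects) is zeroed by default so that the
    comparison reflects interactions only.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    if weight_mode not in ("absolute", "signed"):
        raise ValueError(f"weight_mode must be 'absolute' or 'signed', got {weight_mode!r}")
    W = net.adjacency.copy()
    if zero_diagonal:
        np.fill_diagonal(W, 0.0)
    if weight_mode == "absolute":
        W = np.abs(W)
    Dg = np.diag(W.sum(axis=1))
    A_bar = (Dg - W) + lam * np.eye(W.shape[0])
    min_eig = float(linalg.eigvalsh(A_bar)[0])
    if weight_mode == "signed" and min_eig <= 0:
        raise ValueError(
            f"signed-weight Laplacian is not positive definite (min eigenvalue {min_eig:.3e}); "
            "use weight_mode='absolute' or increase lambda"
        )
    return SPDNet(subject_id=net.subject_id, matrix=A_bar, lam=lam, weight_mode=weight_mode)


def _check_spd(M: np.ndarray, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")


def spd_geodesic(P: SPDNet | np.ndarray, Q: SPDNet | np.ndarray) -> tuple[float, float]:
    """Affine-invariant distance between SPD matrices.

    Returns ``(d_squared, d)`` with d_squared = sum_k log^2 lambda_k over
    the generalized eigenvalues of (Q, P).  d_squared is the trace form
    tr log^2(P^{-1/2} Q P^{-1/2}); d = sqrt(d_squared) is the proper metric
    used downstream for thresholding.  Symmetric in its arguments and
    invariant under congruence P, Q -> G^T P G, G^T Q G.
    """
    Pm = P.matrix if isinstance(P, SPDNet) else np.asarray(P, dtype=float)
    Qm = Q.matrix if isinstance(Q, SPDNet) else np.asarray(Q, dtype=float)
    _check_spd(Pm, "P")
    _check_spd(Qm, "Q")
    if Pm.shape != Qm.shape:
        raise ValueError(f"size mismatch: {Pm.shape} vs {Qm.shape}")
    try:
        evals = linalg.eigh(Qm, Pm, eigvals_only=True)
    except linalg.LinAlgError as e:  # pragma: no cover - scipy raises on non-PD P
        raise ValueError(f"inputs must be positive definite: {e}") from e
    if np.any(evals <= 0):
        raise ValueError("inputs must be positive definite (non-positive relative eigenvalue)")
    d_squared = float(np.sum(np.log(evals) ** 2))
    return d_squared, float(np.sqrt(d_squared))


def spd_geodesic_matrixlog(P: np.ndarray, Q: np.ndarray) -> float:
    """d_squared via the explicit matrix-log route (independent cross-check).

    Computes tr(log^2(P^{-1/2} Q P^{-1/2})) with a dense inverse square
    root and matrix logarithm; numerically heavier than the generalized
    eigenvalue route but follows the defining formula literally.
    """
    _check_spd(np.asarray(P), "P")
    w, V = linalg.eigh(P)
    if np.any(w <= 0):
        raise ValueError("P must be positive definite")
    P_isqrt = (V / np.sqrt(w)) @ V.T
    C = P_isqrt @ Q @ P_isqrt
    L = linalg.logm((C + C.T) / 2.0)
    return float(np.trace(L @ L).real)


def network_of_networks(
    spd_list: list[SPDNet], keep_fraction: float = 0.25
) -> CohortDistanceNet:
    """Pairwise SPD geodesics between all subjects, thresholded.

    Smaller distance = stronger similarity, so the retained edges are the
    ``keep_fraction`` *smallest* off-diagonal distances (ties by ascending
    (i, j)).
    """
    if len(spd_list) < 2:
        raise ValueError(f"need >= 2 subjects, got {len(spd_list)}")
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    shapes = {s.matrix.shape for s in spd_list}
    if len(shapes) > 1:
        raise ValueError(f"SPD matrices disagree on shape: {sorted(shapes)}")
    n = len(spd_list)
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, d = spd_geodesic(spd_list[i], spd_list[j])
            B[i, j] = B[j, i] = d
    edges = _top_offdiag_pairs(B, keep_fraction, largest=False)
    return CohortDistanceNet(
        B=B,
        retained_edges=edges,
        keep_fraction=keep_fraction,
        subject_ids=[s.subject_id for s in spd_list],
    )


def dynamic_network_panel(
    decs: list[ShapDecomposition],
    tensors: list[InteractionTensor],
    records: list[SubjectRecord],
    edge_keep_fraction: float = 0.05,
) -> list[dict]:
    """Per-subject network exports ordered by increasing age.

    Each entry carries the subject's age, per-node Shapley values, and its
    strongest interaction edges under a shared node indexing, so panels are
    directly comparable across ages.  Equal ages order by subject id.
    """
    if not (len(decs) == len(tensors) == len(records)):
        raise ValueError(
            f"length mismatch: {len(decs)} decompositions, {len(tensors)} tensors, "
            f"{len(records)} records"
        )
    by_id = {r.subject_id: r for r in records}
    entries = []
    for dec, it in zip(decs, tensors):
        if dec.subject_id != it.subject_id:
            raise ValueError(f"misaligned subjects: {dec.subject_id} vs {it.subject_id}")
        rec = by_id[dec.subject_id]
        net = build_network(it, edge_keep_fraction)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "node_phi": dec.phi.copy(),
                "edges": net.display_edges,
            }
        )
    entries.sort(key=lambda e: (e["age"], e["subject_id"]))
    return entries
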