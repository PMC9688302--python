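"""Exact Shapley values and pairwise Shapley interactions for tree ensembles.

A fitted prediction ``y_t`` is decomposed additively over features,

    y_t = phi_0 + sum_i phi_i(x_t,i),

where ``phi_i`` is the Shapley value of feature *i* — its average marginal
contribution over all feature subsets S, weighted by |S|!(M-|S|-1)!/M! —
and ``phi_0 = f(emptyset)`` is the model baseline with no features known.
Pairwise synergy is measured by the Shapley interaction

    phi_ij = sum_{S ∌ i,j} |S|!(M-|S|-2)!/(2(M-1)!) * delta_ij(S),
    delta_ij(S) = f(S+ij) - f(S+i) - f(S+j) + f(S),

with the diagonal defined as the main effect net of interactions,
``phi_ii = phi_i - sum_{j != i} phi_ij``.  Three identities then hold by
construction and are enforced as contracts throughout:

* additivity:     phi_0 + sum_i phi_i = prediction
* completeness:   sum_i sum_j phi_ij = prediction - phi_0
* row consistency: phi_i = phi_ii + sum_{j != i} phi_ij

``f(S)`` for a tree ensemble is the path-dependent conditional expectation:
walking each tree, a split on a feature in S follows the sample's branch; a
split on a feature outside S averages both children weighted by their
training covers.

Two independent implementations are provided.  The *brute-force oracle*
(`shapley_values_exact`, `shapley_interactions_exact`) enumerates every
subset of all M features with explicit factorial weights — exponential in
M, usable up to M ~ 15, and deliberately free of shared code with the fast
path.  The *tree engine* (`cohort_shap` and friends) exploits that each
tree touches only its own few split features: features a tree never uses
are Shapley dummies, so the ensemble decomposition is the sum of per-tree
decompositions over each tree's small feature support, enumerated exactly.
For shallow boosted trees (depth d => at most 2^d - 1 distinct features per
tree) this is fast at any M, and it is *exact* — agreement with the oracle
is limited only by floating-point roundoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import factorial
from typing import Any, Callable, Iterable, Optional

import numpy as np

from .model import EnsembleModel, TreeNode

logger = logging.getLogger(__name__)


@dataclass
class ShapDecomposition:
    """Baseline plus per-feature contributions for one subject."""

    subject_id: str
    phi0: float
    phi: np.ndarray  # (M,)
    prediction: float

    def additivity_residual(self) -> float:
        return float(abs(self.phi0 + self.phi.sum() - self.prediction))


@dataclass
class InteractionTensor:
    """Symmetric M x M matrix of pairwise Shapley interactions.

    Entry (i, j) is ``phi_ij``; the diagonal holds the net main effects
    ``phi_ii``.  Doubles as the weighted adjacency matrix of the subject's
    voxel-interaction network.
    """

    subject_id: str
    values: np.ndarray  # (M, M)


@dataclass
class SetFunction:
    """A coalition game: subset of features -> model expectation."""

    m: int
    evaluate: Callable[[frozenset, Any], float]


# -- conditional expectation over a tree ensemble ----------------------------


def _cond_exp(node: TreeNode, S: frozenset, x32: np.ndarray) -> float:
    if node.is_leaf:
        return node.leaf_value
    cl, cr = node.left.cover, node.right.cover
    if cl + cr <= 0:
        raise ValueError("zero cover at a split node (corrupt model)")
    if node.feature in S:
        nxt = node.left if x32[node.feature] < np.float32(node.threshold) else node.right
        return _cond_exp(nxt, S, x32)
    w = cl / (cl + cr)
    return w * _cond_exp(node.left, S, x32) + (1.0 - w) * _cond_exp(node.right, S, x32)


def tree_expectation(model: EnsembleModel, S: Iterable[int], x: np.ndarray) -> float:
    """f(S): prediction with only the features in S known.

    At a split on a feature in S the sample's branch is followed; otherwise
    both children are averaged with cover weights.  ``f(all features, x)``
    equals the model prediction at x; ``f(emptyset)`` is the cover-weighted
    mean prediction, independent of x.
    """
    S = frozenset(S)
    x32 = np.asarray(x, dtype=np.float32).ravel()
    return model.base_score + sum(_cond_exp(t, S, x32) for t in model.trees)


def tree_set_function(model: EnsembleModel) -> SetFunction:
    return SetFunction(
        m=model.n_features,
        evaluate=lambda S, x: tree_expectation(model, S, x),
    )


# -- brute-force oracle ------------------------------------------------------


def _subset_table(sf: SetFunction, x: Any) -> np.ndarray:
    M = sf.m
    f = np.empty(1 << M)
    for s in range(1 << M):
        members = frozenset(i for i in range(M) if s >> i & 1)
        f[s] = sf.evaluate(members, x)
    return f


def shapley_values_exact(
    sf: SetFunction, x: Any = None, cap: int = 15, subject_id: str = ""
) -> ShapDecomposition:
    """Shapley values by full subset enumeration (2^M evaluations).

    The reference implementation: explicit factorial weights, no shortcuts.
    Refuses M beyond ``cap`` — use the tree engine for real feature counts.
    """
    M = sf.m
    if M > cap:
        raise ValueError(
            f"M={M} exceeds the brute-force cap {cap}; use the tree engine "
            "(cohort_shap / shapley_values_tree) for large feature counts"
        )
    f = _subset_table(sf, x)
    full = (1 << M) - 1
    phi = np.zeros(M)
    for i in range(M):
        bit = 1 << i
        for s in range(1 << M):
            if s & bit:
                continue
            size = bin(s).count("1")
            w = factorial(size) * factorial(M - size - 1) / factorial(M)
            phi[i] += w * (f[s | bit] - f[s])
    return ShapDecomposition(
        subject_id=subject_id, phi0=float(f[0]), phi=phi, prediction=float(f[full])
    )


def shapley_interactions_exact(
    sf: SetFunction, x: Any = None, cap: int = 15, subject_id: str = ""
) -> InteractionTensor:
    """Pairwise Shapley interactions by full subset enumeration."""
    M = sf.m
    if M > cap:
        raise ValueError(
            f"M={M} exceeds the brute-force cap {cap}; use the tree engine "
            "(shapley_interactions_tree) for large feature counts"
        )
    f = _subset_table(sf, x)
    vals = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            bi, bj = 1 << i, 1 << j
            acc = 0.0
            for s in range(1 << M):
                if s & bi or s & bj:
                    continue
                size = bin(s).count("1")
                w = factorial(size) * factorial(M - size - 2) / (2.0 * factorial(M - 1))
                acc += w * (f[s | bi | bj] - f[s | bi] - f[s | bj] + f[s])
            vals[i, j] = vals[j, i] = acc
    dec = shapley_values_exact(sf, x, cap=cap)
    np.fill_diagonal(vals, dec.phi - (vals.sum(axis=1) - np.diag(vals)))
    return InteractionTensor(subject_id=subject_id, values=vals)


# -- fast tree engine --------------------------------------------------------


def _tree_structure(root: TreeNode):
    """Flatten a tree into (used features, leaves-with-paths).

    Each leaf path step records: local feature index, global feature,
    threshold, the branch direction taken, and the cover fraction of that
    branch (the probability mass routed there when the feature is unknown).
    """
    used: set[int] = set()

    def collect(node: TreeNode):
        if not node.is_leaf:
            used.add(node.feature)
            collect(node.left)
            collect(node.right)

    collect(root)
    order = sorted(used)
    index = {f: i for i, f in enumerate(order)}
    leaves: list[tuple[float, list]] = []

    def rec(node: TreeNode, path: list):
        if node.is_leaf:
            leaves.append((node.leaf_value, list(path)))
            return
        cl, cr = node.left.cover, node.right.cover
        if cl + cr <= 0:
            raise ValueError("zero cover at a split node (corrupt model)")
        wl = cl / (cl + cr)
        path.append((index[node.feature], node.feature, node.threshold, True, wl))
        rec(node.left, path)
        path.pop()
        path.append((index[node.feature], node.feature, node.threshold, False, 1.0 - wl))
        rec(node.right, path)
        path.pop()

    rec(root, [])
    return order, leaves


@lru_cache(maxsize=None)
def _value_weight_matrix(u: int) -> np.ndarray:
    """W such that phi = W @ f_table for a game on u players."""
    W = np.zeros((u, 1 << u))
    for s in range(1 << u):
        size = bin(s).count("1")
        for i in range(u):
            if s >> i & 1:
                w = factorial(size - 1) * factorial(u - size) / factorial(u)
                W[i, s] += w  # appears as f(S u {i})
            else:
                w = factorial(size) * factorial(u - size - 1) / factorial(u)
                W[i, s] -= w  # appears as -f(S)
    return W


@lru_cache(maxsize=None)
def _pair_weight_matrix(u: int) -> tuple[tuple[tuple[int, int], ...], np.ndarray]:
    """Pairs and W such that phi_pairs = W @ f_table for a game on u players."""
    pairs = tuple((i, j) for i in range(u) for j in range(i + 1, u))
    W = np.zeros((len(pairs), 1 << u))
    for p, (i, j) in enumerate(pairs):
        bi, bj = 1 << i, 1 << j
        for s in range(1 << u):
            if s & bi or s & bj:
                continue
            size = bin(s).count("1")
            w = factorial(size) * factorial(u - size - 2) / (2.0 * factorial(u - 1))
            W[p, s | bi | bj] += w
            W[p, s | bi] -= w
            W[p, s | bj] -= w
            W[p, s] += w
    return pairs, W


def cohort_shap(
    model: EnsembleModel,
    X: np.ndarray,
    subject_ids: Optional[list[str]] = None,
    interactions: bool = True,
    max_tree_features: int = 15,
) -> tuple[list[ShapDecomposition], list[InteractionTensor]]:
    """Shapley values (and optionally interactions) for every row of X.

    Exact per-tree subset enumeration over each tree's feature support,
    batched over subjects with precomputed weight matrices.  Order
    preserving and deterministic; the maximum per-subject additivity
    residual is logged.

    Trees using more than ``max_tree_features`` distinct features are
    refused (2^u table per tree) — grow shallower trees instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, M = X.shape
    if M != model.n_features:
        raise ValueError(f"X has {M} features, model expects {model.n_features}")
    X32 = X.astype(np.float32)
    phi = np.zeros((n, M))
    phi0 = model.base_score
    preds = np.full(n, model.base_score)
    inter = np.zeros((n, M, M)) if interactions else None

    for tree in model.trees:
        used, leaves = _tree_structure(tree)
        u = len(used)
        if u == 0:
            v = leaves[0][0]
            phi0 += v
            preds += v
            continue
        if u > max_tree_features:
            raise ValueError(
                f"a tree uses {u} distinct features (> {max_tree_features}); "
                "reduce tree depth to keep exact interaction computation tractable"
            )
        nsub = 1 << u
        in_bit = [((np.arange(nsub) >> b) & 1).astype(bool) for b in range(u)]
        F = np.zeros((n, nsub))
        for value, path in leaves:
            w = np.ones((n, nsub))
            for ufi, feat, thr, went_left, frac in path:
                match = (X32[:, feat] < np.float32(thr)) == went_left
                w *= np.where(in_bit[ufi][None, :], match[:, None], frac)
            F += value * w
        phi0 += float(F[0, 0]) if n else 0.0
        preds += F[:, nsub - 1]
        phi[:, used] += F @ _value_weight_matrix(u).T
        if interactions and u >= 2:
            pairs, W = _pair_weight_matrix(u)
            P = F @ W.T
            for p, (a, b) in enumerate(pairs):
                ga, gb = used[a], used[b]
                inter[:, ga, gb] += P[:, p]
                inter[:, gb, ga] += P[:, p]

    ids = subject_ids or [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} subject ids for {n} rows")
    decs = [
        ShapDecomposition(ids[i], phi0, phi[i].copy(), float(preds[i])) for i in range(n)
    ]
    if n:
        logger.info(
            "cohort_shap: max additivity residual %.3e over %d subjects",
            max(d.additivity_residual() for d in decs),
            n,
        )
    if not interactions:
        return decs, []
    off = inter.sum(axis=2)  # diagonal still zero: sum over j != i
    idx = np.arange(M)
    inter[:, idx, idx] = phi - off
    tensors = [InteractionTensor(ids[i], inter[i].copy()) for i in range(n)]
    return decs, tensors


def shapley_values_tree(
    model: EnsembleModel, x: np.ndarray, subject_id: str = ""
) -> ShapDecomposition:
    """Single-sample Shapley values via the tree engine."""
    decs, _ = cohort_shap(model, np.atleast_2d(x), [subject_id or "0"], interactions=False)
    return decs[0]


def shapley_interactions_tree(
    model: EnsembleModel, x: np.ndarray, subject_id: str = ""
) -> InteractionTensor:
    """Single-sample Shapley interactions via the tree engine."""
    _, tensors = cohort_shap(model, np.atleast_2d(x), [subject_id or "0"], interactions=True)
    return tensors[0]
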