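"""Shared fixtures: tiny hand-built tree models and benchmark cohort runs."""

from __future__ import annotations

import numpy as np
import pytest

import voxelage as va
from voxelage.model import EnsembleModel, TreeNode


def make_stump(feature=0, threshold=0.5, left=1.0, right=3.0, cover_left=50.0, cover_right=50.0):
    """A single decision stump: x[feature] < threshold -> left value."""
    root = TreeNode(
        cover=cover_left + cover_right,
        feature=feature,
        threshold=threshold,
        left=TreeNode(cover=cover_left, leaf_value=left),
        right=TreeNode(cover=cover_right, leaf_value=right),
    )
    return EnsembleModel(trees=[root], base_score=0.0, n_features=max(feature + 1, 2))


def random_tree(rng: np.random.Generator, n_features: int, depth: int, cover: float = 64.0) -> TreeNode:
    """A random regression tree with consistent covers, splits in [0, 1]."""
    if depth == 0 or rng.random() < 0.25:
        return TreeNode(cover=cover, leaf_value=float(rng.normal()))
    frac = float(rng.uniform(0.2, 0.8))
    left = random_tree(rng, n_features, depth - 1, cover * frac)
    right = random_tree(rng, n_features, depth - 1, cover * (1 - frac))
    if left.is_leaf and right.is_leaf and left.cover + right.cover != cover:
        pass  # covers are consistent by construction
    return TreeNode(
        cover=cover,
        feature=int(rng.integers(n_features)),
        threshold=float(rng.uniform(0.1, 0.9)),
        left=left,
        right=right,
    )


def random_ensemble(seed: int, n_features: int = 8, n_trees: int = 10, depth: int = 3) -> EnsembleModel:
    rng = np.random.default_rng(seed)
    model = EnsembleModel(
        trees=[random_tree(rng, n_features, depth) for _ in range(n_trees)],
        base_score=float(rng.normal()),
        n_features=n_features,
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def benchmark_run():
    """The frozen recovery benchmark: 300 subjects, desk-scale pipeline, seed 0."""
    cfg = va.PipelineConfig.desk_scale(seed=0, output_dir="scratch_bench_out")
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        cfg.output_dir = tmp
        result = va.run_pipeline(cfg, cohort_spec=va.recovery_benchmark_spec(seed=0))
        yield result


@pytest.fixture(scope="session")
def benchmark_full_tensors(benchmark_run):
    """Full-model interaction tensors for the benchmark cohort (all 50 features)."""
    decs, tensors = va.cohort_shap(
        benchmark_run.model,
        benchmark_run.features.values,
        benchmark_run.features.subject_ids,
        interactions=True,
    )
    return decs, tensors


@pytest.fixture(scope="session")
def cohort150():
    """A 150-subject benchmark cohort with fitted model and full decomposition."""
    spec = va.recovery_benchmark_spec(seed=1, n_subjects=150)
    records, volumes, truth = va.generate_cohort(spec)
    cfg = va.PipelineConfig.desk_scale(seed=1)
    from voxelage import preprocess

    fm = preprocess.preprocess_pipeline(volumes, records, cfg)
    y = np.array([r.age for r in records])
    split = va.train_test_split(len(y), 0.15, seed=1)
    model = va.fit(fm.values[split.train_idx], y[split.train_idx], cfg.gbt, seed=1)
    decs, tensors = va.cohort_shap(model, fm.values, fm.subject_ids, interactions=True)
    return {
        "records": records,
        "truth": truth,
        "features": fm,
        "model": model,
        "decs": decs,
        "tensors": tensors,
    }
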