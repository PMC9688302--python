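"""VBM-style feature preparation: smoothing, variance filter, F-test selection.

The preprocessing chain mirrors standard voxel-based-morphometry practice on
spatially normalized GMV maps: (1) Gaussian smoothing at a given FWHM,
(2) an unsupervised variance filter that drops near-constant voxels, and
(3) supervised univariate F-test selection of the ``k`` voxels whose GMV is
most linearly dependent on age.  The surviving voxels, flattened across
subjects, form the feature matrix consumed by the regression model.

All three steps are deterministic; the selected set is invariant to subject
row order and to affine rescaling of individual voxels or of age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .synthetic import SubjectRecord, VoxelVolume, _FWHM_TO_SIGMA

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Subjects x selected-voxel GMV values with the voxel coordinate map.

    ``feature_coords`` has one row per column of ``values``: the integer
    voxel index ``(i, j, k)`` and its mm position under the shared affine.
    """

    values: np.ndarray  # (N, M)
    feature_coords: np.ndarray  # (M, 6): i, j, k, x_mm, y_mm, z_mm
    subject_ids: list[str]
    flat_indices: np.ndarray  # (M,) flat voxel index into the original grid


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm from a 4x4 affine (norm of each column)."""
    sizes = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    if np.any(sizes <= 0):
        raise ValueError(f"affine has a degenerate axis, voxel sizes {sizes}")
    return sizes


def fwhm_smooth(volume: VoxelVolume, fwhm_mm: float) -> VoxelVolume:
    """Gaussian smoothing at the given FWHM (mm), mask-renormalized.

    sigma_mm = fwhm_mm / (2 sqrt(2 ln 2)) per axis, converted to voxel units
    from the affine.  Outside-mask values are treated as missing: the volume
    is smoothed with zero padding and renormalized by the smoothed mask so
    interior values near the mask edge are not attenuated.  ``fwhm_mm = 0``
    is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VoxelVolume(volume.values.copy(), volume.affine.copy(), volume.mask.copy())
    sigma_vox = (fwhm_mm / _FWHM_TO_SIGMA) / voxel_sizes_mm(volume.affine)
    masked = np.where(volume.mask, volume.values, 0.0)
    num = ndimage.gaussian_filter(masked, sigma=sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(volume.mask.astype(float), sigma=sigma_vox, mode="constant")
    out = np.zeros_like(num)
    inside = volume.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return VoxelVolume(out, volume.affine.copy(), volume.mask.copy())


def variance_filter(X: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of columns with sample variance strictly above ``threshold``.

    Uses the unbiased (N-1) estimator; strict ``>`` means a column whose
    variance equals the threshold exactly is removed.  Column order is
    preserved.
    """
    if threshold < 0:
        raise ValueError(f"variance threshold must be >= 0, got {threshold}")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 subjects to estimate variance, got {X.shape[0]}")
    var = X.var(axis=0, ddof=1)
    return np.flatnonzero(var > threshold)


def f_test_select(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` columns by the univariate regression F statistic.

    F = r^2 (N-2) / (1 - r^2) with r the Pearson correlation of the column
    with ``y`` (the F test of a one-regressor linear fit, df (1, N-2)).
    Perfect dependence gives F = +inf; a zero-variance column gets F = 0
    with a warning (it should have been removed upstream).  Returns the
    selected column indices, ordered by F descending with ties broken by
    ascending original index, and the per-column F statistics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= 2:
        raise ValueError(f"F-test needs more than 2 subjects, got {n}")
    if not 0 < k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    dead = sx == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance column(s) reached the F-test; "
            "their F is defined as 0 (run the variance filter first)",
            stacklevel=2,
        )
    denom = np.where(dead, 1.0, sx) * (sy if sy > 0 else 1.0)
    r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.clip(r, -1.0, 1.0)
    r2 = r**2
    with np.errstate(divide="ignore"):
        F = np.where(dead, 0.0, r2 * (n - 2) / (1.0 - r2))
    order = np.lexsort((np.arange(m), -F))
    return order[:k], F


def preprocess_pipeline(
    volumes: list[VoxelVolume],
    records: list[SubjectRecord],
    config: PipelineConfig,
) -> FeatureMatrix:
    """Smooth -> mask-flatten -> variance filter -> F-test top-k, in order.

    Logs the surviving voxel count at each stage and records the selected
    voxel coordinates (integer index and mm position).
    """
    if len(volumes) < 3:
        raise ValueError(f"need >= 3 subjects, got {len(volumes)}")
    if len(volumes) != len(records):
        raise ValueError(f"{len(volumes)} volumes vs {len(records)} records")
    shapes = {v.values.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volumes disagree on grid shape: {sorted(shapes)}")

    smoothed = [fwhm_smooth(v, config.fwhm_mm) for v in volumes]
    mask = smoothed[0].mask
    flat_idx_all = np.flatnonzero(mask.ravel())
    X_full = np.stack([v.values.ravel()[flat_idx_all] for v in smoothed])
    logger.info("preprocess: %d in-mask voxels", X_full.shape[1])

    keep_var = variance_filter(X_full, config.variance_threshold)
    logger.info("preprocess: %d voxels pass variance > %g", keep_var.size, config.variance_threshold)
    if config.k_features > keep_var.size:
        raise ValueError(
            f"k_features={config.k_features} exceeds the {keep_var.size} voxels "
            "surviving the variance filter"
        )
    X_var = X_full[:, keep_var]

    y = np.array([r.age for r in records])
    sel, _F = f_test_select(X_var, y, config.k_features)
    flat_indices = flat_idx_all[keep_var[sel]]
    logger.info("preprocess: selected top %d voxels by F-test", sel.size)

    ijk = np.stack(np.unravel_index(flat_indices, mask.shape), axis=1)
    affine = smoothed[0].affine
    mm = (affine @ np.c_[ijk, np.ones(len(ijk))].T).T[:, :3]
    coords = np.c_[ijk, mm]
    return FeatureMatrix(
        values=X_var[:, sel],
        feature_coords=coords,
        subject_ids=[r.subject_id for r in records],
        flat_indices=flat_indices,
    )
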