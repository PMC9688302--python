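"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the analysis:
preprocessing (smoothing width, variance threshold, number of selected
features), the gradient-boosted model's hyperparameters, the explanation
stage (number of peak voxels), and the network stage (Laplacian regularizer,
edge-retention fractions).  Configs are plain JSON on disk; unknown keys are
rejected so typos fail loudly, and a resolved copy (defaults filled in) is
written next to pipeline outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigError(ValueError):
    """Raised when a configuration field is missing, unknown, or invalid."""


@dataclass
class GBTParams:
    """Hyperparameters of the gradient-boosted tree regressor.

    Depth is kept small on purpose: shallow trees regularize the fit on
    correlated voxel features and keep the per-tree feature support small,
    which is what makes exact Shapley interaction computation cheap.
    Per-tree feature subsampling (``colsample_bytree``) decorrelates the
    ensemble on redundant voxel features; without it, greedy splitting can
    ignore a voxel pair's joint signal entirely because some correlated
    voxel always offers more immediate gain.
    """

    max_depth: int = 4
    n_rounds: int = 200
    learning_rate: float = 0.1
    subsample: float = 1.0
    colsample_bytree: float = 0.5

    def validate(self) -> None:
        if self.max_depth < 1:
            raise ConfigError(f"max_depth must be >= 1, got {self.max_depth}")
        if not 0 < self.colsample_bytree <= 1:
            raise ConfigError(
                f"colsample_bytree must be in (0, 1], got {self.colsample_bytree}"
            )
        if self.n_rounds < 1:
            raise ConfigError(f"n_rounds must be >= 1, got {self.n_rounds}")
        if not 0 < self.learning_rate <= 1:
            raise ConfigError(f"learning_rate must be in (0, 1], got {self.learning_rate}")
        if not 0 < self.subsample <= 1:
            raise ConfigError(f"subsample must be in (0, 1], got {self.subsample}")


@dataclass
class PipelineConfig:
    # preprocessing
    fwhm_mm: float = 6.0
    variance_threshold: float = 0.01
    k_features: int = 2000
    # model
    test_fraction: float = 0.15
    gbt: GBTParams = field(default_factory=GBTParams)
    # explanation / networks
    n_peak_voxels: int = 310
    laplacian_lambda: float = 1.0
    weight_mode: str = "absolute"
    keep_fraction: float = 0.25
    edge_display_fraction: float = 0.05
    # numerics
    additivity_tol: float = 1e-8
    oracle_tol: float = 1e-6
    # bookkeeping
    seed: int = 0
    output_dir: str = "voxelage_out"
    write_nifti: bool = False

    def validate(self) -> None:
        if self.fwhm_mm < 0:
            raise ConfigError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        if self.variance_threshold < 0:
            raise ConfigError(f"variance_threshold must be >= 0, got {self.variance_threshold}")
        if self.k_features < 1:
            raise ConfigError(f"k_features must be >= 1, got {self.k_features}")
        if not 0 < self.test_fraction < 1:
            raise ConfigError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.n_peak_voxels < 1:
            raise ConfigError(f"n_peak_voxels must be >= 1, got {self.n_peak_voxels}")
        if self.laplacian_lambda <= 0:
            raise ConfigError(f"laplacian_lambda must be > 0, got {self.laplacian_lambda}")
        if self.weight_mode not in ("absolute", "signed"):
            raise ConfigError(f"weight_mode must be 'absolute' or 'signed', got {self.weight_mode!r}")
        if not 0 < self.keep_fraction <= 1:
            raise ConfigError(f"keep_fraction must be in (0, 1], got {self.keep_fraction}")
        if not 0 < self.edge_display_fraction <= 1:
            raise ConfigError(
                f"edge_display_fraction must be in (0, 1], got {self.edge_display_fraction}"
            )
        self.gbt.validate()

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "gbt" in d and isinstance(d["gbt"], dict):
            gbt_known = {f.name for f in dataclasses.fields(GBTParams)}
            gbt_unknown = set(d["gbt"]) - gbt_known
            if gbt_unknown:
                raise ConfigError(f"unknown gbt config keys: {sorted(gbt_unknown)}")
            d["gbt"] = GBTParams(**d["gbt"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    # -- presets -----------------------------------------------------------

    @classmethod
    def desk_scale(cls, seed: int = 0, output_dir: str = "voxelage_out") -> "PipelineConfig":
        """Small-cohort preset: ~50 selected features, ~20 peak voxels.

        The full-scale defaults (FWHM 6 mm, variance threshold 0.01, 2000
        features, 310 peak voxels) mirror a whole-brain VBM analysis; this
        preset keeps the identical pipeline shape at a size where the whole
        analysis runs in seconds.  The synthetic benchmark cohort is
        generated already spatially smooth with single-voxel planted
        signals, so no additional smoothing is applied here, and the
        variance threshold is matched to the synthetic GMV value scale
        (noise variance ~2.5e-3 per voxel).
        """
        return cls(
            fwhm_mm=0.0,
            variance_threshold=1e-4,
            k_features=50,
            n_peak_voxels=20,
            seed=seed,
            output_dir=output_dir,
        )
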