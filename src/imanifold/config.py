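"""Pipeline configuration: one flat record of every tunable parameter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Effective parameters of an end-to-end run.

    Defaults follow the reference analysis: ultraslow band 0.04-0.07 Hz,
    sixth-order Butterworth, RMST with gamma = 3 and k_n = 5, d = 7
    manifold dimensions, linear SVM with C = 1 under 10-fold CV, 1000
    phase-randomized surrogates, FDR at 0.05.
    """

    band_low_hz: float = 0.04
    band_high_hz: float = 0.07
    filter_order: int = 6
    gamma: float = 3.0
    k_n: int = 5
    k_local: int = 1
    dim: int = 7
    svm_C: float = 1.0
    n_folds: int = 10
    n_perm: int = 1000
    fdr_alpha: float = 0.05
    seed: int = 0
    fold_scheme: str = "random"  # "random" | "contiguous"
    laplacian_weighting: str = "binary"  # "binary" | "similarity"
    reference_subject: int = 0
    trim_trs: int = 0  # edge TRs to drop after filtering/Hilbert
    roc_dims_to_scan: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.k_n < 1 or self.k_local < 1:
            raise ValueError("k_n and k_local must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.fold_scheme not in ("random", "contiguous"):
            raise ValueError("fold_scheme must be 'random' or 'contiguous'")
        if self.laplacian_weighting not in ("binary", "similarity"):
            raise ValueError("laplacian_weighting must be 'binary' or 'similarity'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
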