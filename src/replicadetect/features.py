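"""Fixed-length feature vectors from volumes via a pluggable extractor registry.

Feature-level comparison is extractor-agnostic: any registered extractor
(or precomputed feature CSVs ingested through the dataset manifest) can feed
the retrieval pipeline. The built-in pooled descriptor is fully deterministic
so the framework is testable without pretrained model weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .volumes import Volume

__all__ = [
    "FeatureVector",
    "ExtractorConfig",
    "register_extractor",
    "extract_features",
    "builtin_pooled_descriptor",
    "available_extractors",
]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str
    source_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("feature vector must be 1D and non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"feature vector for {self.source_id!r} has non-finite elements")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ExtractorConfig:
    name: str
    params: dict = field(default_factory=dict)

    @property
    def id(self) -> str:
        parts = [f"{k}={self.params[k]}" for k in sorted(self.params)]
        return f"{self.name}({','.join(parts)})"


_REGISTRY: dict[str, Callable[..., np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register ``fn(volume, **params) -> 1D array`` under ``name``."""
    _REGISTRY[name] = fn


def available_extractors() -> list[str]:
    return sorted(_REGISTRY)


def extract_features(v: Volume, extractor: ExtractorConfig) -> FeatureVector:
    """Run a registered extractor; deterministic for fixed config and input."""
    if extractor.name not in _REGISTRY:
        raise ValueError(
            f"unknown extractor {extractor.name!r}; registered: {available_extractors()}"
        )
    try:
        values = _REGISTRY[extractor.name](v, **extractor.params)
    except Exception as exc:
        raise ValueError(f"extractor {extractor.id} failed on volume {v.id!r}: {exc}") from exc
    return FeatureVector(values=values, extractor_id=extractor.id, source_id=v.id)


def _block_edges(n: int, k: int) -> list[int]:
    # k equal blocks of n // k voxels; the last block absorbs the remainder
    size = n // k
    return [i * size for i in range(k)] + [n]


def builtin_pooled_descriptor(v: Volume, levels: int = 2) -> np.ndarray:
    """Multi-level block-pooled intensity descriptor.

    Intensities are min-max scaled to [0, 1] per volume (a constant volume
    scales to all zeros), then for each pyramid level ℓ = 1..levels the grid
    is partitioned into 2^ℓ blocks per axis (boundary blocks absorb
    remainders) and the per-block mean and standard deviation are
    concatenated. Length = Σ_ℓ 2·8^ℓ (levels=1 → 16, levels=2 → 144).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if 2 ** levels > min(v.shape):
        raise ValueError(f"levels={levels} needs 2^levels <= min axis of {v.shape}")
    data = v.data
    lo, hi = data.min(), data.max()
    scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    out: list[float] = []
    for level in range(1, levels + 1):
        k = 2 ** level
        ex, ey, ez = (_block_edges(n, k) for n in scaled.shape)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    block = scaled[ex[i]:ex[i + 1], ey[j]:ey[j + 1], ez[l]:ez[l + 1]]
                    out.append(float(block.mean()))
                    out.append(float(block.std()))
    return np.asarray(out, dtype=np.float64)


register_extractor("pooled", builtin_pooled_descriptor)
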