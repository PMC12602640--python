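"""Similarity and distance measures at the three analysis levels.

Image level compares voxel intensities directly (MAE, RMSE, 3D SSIM).
Feature level compares fixed-length embeddings (RMSE, cosine similarity).
Segmentation level compares label masks (Dice, average surface distance).

Similarity measures (SSIM, cosine, Dice) are converted onto a common
distance scale in [0, 1] by min-max mapping their theoretical range onto
[0, 1] and subtracting from 1; genuine distances pass through unchanged.
The theoretical range — not the empirical range of any batch — is used, so
thresholds transfer between runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .volumes import SegMask, Volume

__all__ = [
    "MeasureSpec",
    "FlaggedValue",
    "IMAGE_MEASURES",
    "FEATURE_MEASURES",
    "SEGMENTATION_MEASURES",
    "LEVEL_BY_MEASURE",
    "mae",
    "rmse",
    "ssim3d",
    "feature_distance",
    "dice",
    "average_surface_distance",
    "multiclass_aggregate",
    "to_distance",
]

IMAGE_MEASURES = ("mae", "rmse", "ssim")
FEATURE_MEASURES = ("feat_rmse", "feat_cosine")
SEGMENTATION_MEASURES = ("dice", "asd")

LEVEL_BY_MEASURE = {
    **{m: "image" for m in IMAGE_MEASURES},
    **{m: "feature" for m in FEATURE_MEASURES},
    **{m: "segmentation" for m in SEGMENTATION_MEASURES},
}

#: measures whose raw value is a similarity (higher = more alike) together
#: with their theoretical range, used by :func:`to_distance`.
_SIMILARITY_RANGES = {
    "ssim": (-1.0, 1.0),
    "feat_cosine": (-1.0, 1.0),
    "dice": (0.0, 1.0),
}

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class MeasureSpec:
    """A named measure with its analysis level and measure-specific settings.

    Recognized ``params``: SSIM ``window`` (odd voxel count, default 7),
    ``k1``/``k2`` stabilizers (0.01/0.03); segmentation ``labels`` (label set
    for multiclass aggregation, default: all labels present in either mask).
    """

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEVEL_BY_MEASURE:
            raise ValueError(f"unknown measure {self.name!r}; choose from {sorted(LEVEL_BY_MEASURE)}")

    @property
    def level(self) -> str:
        return LEVEL_BY_MEASURE[self.name]

    @property
    def is_similarity(self) -> bool:
        return self.name in _SIMILARITY_RANGES


@dataclass(frozen=True)
class FlaggedValue:
    """A measure value plus an optional flag for degenerate geometry.

    Flags: ``undefined-surface`` (label present in exactly one mask; the value
    carries the image physical diagonal as penalty), ``empty-both`` (label in
    neither mask; agreement-on-absence convention).
    """

    value: float
    flag: str | None = None

    def __float__(self) -> float:
        return float(self.value)


def _check_pair(a: Volume, b: Volume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"volume shape mismatch: {a.shape} vs {b.shape}")


def _check_mask_pair(a: SegMask, b: SegMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# image level
# ---------------------------------------------------------------------------

def mae(a: Volume, b: Volume) -> float:
    """Mean absolute voxel-wise error."""
    _check_pair(a, b)
    return float(np.mean(np.abs(a.data - b.data)))


def rmse(a: Volume, b: Volume) -> float:
    """Root mean squared voxel-wise error."""
    _check_pair(a, b)
    return float(np.sqrt(np.mean((a.data - b.data) ** 2)))


def ssim3d(
    a: Volume,
    b: Volume,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean structural similarity over a 3D sliding window with uniform weights.

    The data range is the joint max−min over both volumes. Local statistics
    use sample (N−1) normalization; the mean is taken over windows fully
    inside the grid. Returns a value in [−1, 1]; 1 for identical inputs.
    """
    _check_pair(a, b)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"SSIM window must be an odd count >= 3, got {window}")
    if window > min(a.shape):
        raise ValueError(f"SSIM window {window} exceeds the smallest axis of {a.shape}")
    lo = min(a.data.min(), b.data.min())
    hi = max(a.data.max(), b.data.max())
    data_range = hi - lo
    if data_range == 0:
        if k1 == 0 and k2 == 0:
            raise ValueError("zero data range with k1=k2=0: SSIM undefined")
        return 1.0  # both volumes are the same constant
    return float(
        structural_similarity(
            a.data,
            b.data,
            win_size=window,
            K1=k1,
            K2=k2,
            data_range=data_range,
            gaussian_weights=False,
        )
    )


# ---------------------------------------------------------------------------
# feature level
# ---------------------------------------------------------------------------

def feature_distance(u: Sequence[float], v: Sequence[float], kind: str) -> float:
    """Compare two feature vectors.

    ``feat_rmse`` is the root mean squared element difference; ``feat_cosine``
    returns the raw cosine similarity in [−1, 1] (conversion to a distance is
    :func:`to_distance`'s job).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.ndim != 1 or v.ndim != 1 or u.shape != v.shape or u.size < 1:
        raise ValueError(f"feature vectors must be equal-length 1D, got {u.shape} vs {v.shape}")
    if kind == "feat_rmse":
        return float(np.sqrt(np.mean((u - v) ** 2)))
    if kind == "feat_cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("cosine similarity undefined for an all-zero vector")
        return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    raise ValueError(f"unknown feature measure {kind!r}")


# ---------------------------------------------------------------------------
# segmentation level
# ---------------------------------------------------------------------------

def dice(a: SegMask, b: SegMask, label: int = 1) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) for one label; 1 if both sets empty."""
    _check_mask_pair(a, b)
    fa = a.labels == label
    fb = b.labels == label
    na, nb = int(fa.sum()), int(fb.sum())
    if na + nb == 0:
        return 1.0  # agreement on absence
    return float(2.0 * np.logical_and(fa, fb).sum() / (na + nb))


_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


def _surface(fore: np.ndarray) -> np.ndarray:
    # surface voxels: foreground with a 6-connected background neighbor;
    # the volume boundary counts as background (border_value=0)
    eroded = ndimage.binary_erosion(fore, structure=_SIX_CONNECTED, border_value=0)
    return fore & ~eroded


def _physical_diagonal(shape: Sequence[int], spacing: Sequence[float]) -> float:
    extent = np.asarray(shape, dtype=float) * np.asarray(spacing, dtype=float)
    return float(np.linalg.norm(extent))


def average_surface_distance(a: SegMask, b: SegMask, label: int = 1) -> FlaggedValue:
    """Symmetric average surface distance for one label, in millimeters.

    The symmetric ASD is the mean of the two directed mean surface distances.
    Surfaces are extracted with 6-connectivity and distances are Euclidean in
    physical units (anisotropic spacing honored). A label present in exactly
    one mask yields the image physical diagonal as a flagged penalty; a label
    absent from both yields a flagged 0.
    """
    _check_mask_pair(a, b)
    if not np.allclose(a.spacing, b.spacing, atol=1e-6):
        raise ValueError(f"mask spacing mismatch: {a.spacing} vs {b.spacing}")
    fa = a.labels == label
    fb = b.labels == label
    ea, eb = bool(fa.any()), bool(fb.any())
    if not ea and not eb:
        return FlaggedValue(0.0, "empty-both")
    if ea != eb:
        return FlaggedValue(_physical_diagonal(a.shape, a.spacing), "undefined-surface")
    sa = _surface(fa)
    sb = _surface(fb)
    # exact Euclidean distance to the nearest surface voxel of the other mask
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=a.spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=a.spacing)
    d_ab = dist_to_b[sa].mean()
    d_ba = dist_to_a[sb].mean()
    return FlaggedValue(float((d_ab + d_ba) / 2.0))


def multiclass_aggregate(
    a: SegMask,
    b: SegMask,
    labels: Iterable[int],
    base: str,
) -> FlaggedValue:
    """Macro-average of a per-label segmentation measure.

    Labels absent from both masks are skipped; a per-label undefined surface
    contributes its diagonal penalty (base=``asd``) or 0 (base=``dice``,
    which falls out naturally from empty intersection).
    """
    labels = [int(l) for l in labels]
    if not labels:
        raise ValueError("label set must be non-empty")
    if base not in ("dice", "asd"):
        raise ValueError(f"base must be 'dice' or 'asd', got {base!r}")
    values: list[float] = []
    flags: list[str] = []
    for label in labels:
        present = bool((a.labels == label).any()) or bool((b.labels == label).any())
        if not present:
            continue
        if base == "dice":
            values.append(dice(a, b, label))
        else:
            res = average_surface_distance(a, b, label)
            values.append(res.value)
            if res.flag:
                flags.append(f"{label}:{res.flag}")
    if not values:  # every requested label absent from both masks
        return FlaggedValue(1.0 if base == "dice" else 0.0, "empty-both")
    return FlaggedValue(float(np.mean(values)), ";".join(flags) or None)


# ---------------------------------------------------------------------------
# similarity -> distance conversion
# ---------------------------------------------------------------------------

def to_distance(value: float, measure: MeasureSpec | str) -> float:
    """Map a raw measure value onto the common distance scale.

    Similarities are min-max mapped from their theoretical range onto [0, 1]
    and subtracted from 1 (dice 0.7 → 0.3; ssim 1 → 0; cosine −1 → 1).
    Distances (mae, rmse, feat_rmse, asd) pass through unchanged.
    """
    name = measure.name if isinstance(measure, MeasureSpec) else measure
    if name not in LEVEL_BY_MEASURE:
        raise ValueError(f"unknown measure {name!r}")
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name}: non-finite value {value}")
    if name in _SIMILARITY_RANGES:
        lo, hi = _SIMILARITY_RANGES[name]
        if value < lo - _RANGE_TOL or value > hi + _RANGE_TOL:
            raise ValueError(f"{name}: value {value} outside theoretical range [{lo}, {hi}]")
        value = min(max(value, lo), hi)
        return 1.0 - (value - lo) / (hi - lo)
    if value < -_RANGE_TOL:
        raise ValueError(f"{name}: distance value {value} is negative")
    return max(value, 0.0)
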