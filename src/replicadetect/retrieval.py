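"""Nearest-neighbor retrieval over the training set and the distance-ratio statistic.

For each synthetic image x̂ the whole training set is ranked by a converted
distance; the distance ratio

    r(x̂) = d(x̂, x₁) / mean(d(x̂, x₁), …, d(x̂, x_n))

divides the rank-1 distance by the mean distance to the n closest training
images (rank-1 included, so r ∈ [0, 1]). Low ratios mean "abnormally close"
— the signature of a memorized training image. n defaults to 50 and is
capped (with a warning) at the training-set size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures as M
from .features import ExtractorConfig, FeatureVector, extract_features
from .measures import FlaggedValue, MeasureSpec
from .volumes import DatasetIndex, SegMask, Volume

__all__ = [
    "DEFAULT_NEIGHBORHOOD",
    "RankedNeighbors",
    "DistanceRatio",
    "pair_distance",
    "compute_distance_matrix",
    "rank_training",
    "rank_all",
    "distance_ratio",
    "preselect_pairs",
    "rank_synthetic_by_ratio",
]

DEFAULT_NEIGHBORHOOD = 50  # n closest training images entering the ratio's mean


@dataclass(frozen=True)
class RankedNeighbors:
    """Complete ascending ranking of the training set for one synthetic image."""

    synthetic_id: str
    measure: MeasureSpec
    neighbors: tuple[tuple[str, float], ...]  # (training_id, converted distance)

    def __post_init__(self) -> None:
        d = [dist for _, dist in self.neighbors]
        if any(d[i] > d[i + 1] for i in range(len(d) - 1)):
            raise ValueError("neighbor distances must be non-decreasing")


@dataclass(frozen=True)
class DistanceRatio:
    synthetic_id: str
    measure: MeasureSpec
    ratio: float
    closest_id: str
    n: int
    degenerate_flag: bool = False


def _segmentation_labels(a: SegMask, b: SegMask, spec: MeasureSpec) -> list[int]:
    labels = spec.params.get("labels")
    if labels is not None:
        return [int(l) for l in labels]
    union = sorted(set(a.present_labels()) | set(b.present_labels()))
    return union or [1]


def pair_distance(
    synthetic: Volume | FeatureVector | SegMask,
    training: Volume | FeatureVector | SegMask,
    spec: MeasureSpec,
) -> tuple[float, float, str | None]:
    """Raw measure value, converted distance, and flag for one pair."""
    name = spec.name
    if spec.level == "image":
        if not (isinstance(synthetic, Volume) and isinstance(training, Volume)):
            raise TypeError(f"{name} requires Volume inputs")
        if name == "mae":
            raw = M.mae(synthetic, training)
        elif name == "rmse":
            raw = M.rmse(synthetic, training)
        else:
            raw = M.ssim3d(
                synthetic,
                training,
                window=spec.params.get("window", 7),
                k1=spec.params.get("k1", 0.01),
                k2=spec.params.get("k2", 0.03),
            )
        return raw, M.to_distance(raw, spec), None
    if spec.level == "feature":
        if not (isinstance(synthetic, FeatureVector) and isinstance(training, FeatureVector)):
            raise TypeError(f"{name} requires FeatureVector inputs")
        raw = M.feature_distance(synthetic.values, training.values, name)
        return raw, M.to_distance(raw, spec), None
    # segmentation
    if not (isinstance(synthetic, SegMask) and isinstance(training, SegMask)):
        raise TypeError(f"{name} requires SegMask inputs")
    labels = _segmentation_labels(synthetic, training, spec)
    base = "dice" if name == "dice" else "asd"
    res: FlaggedValue = M.multiclass_aggregate(synthetic, training, labels, base)
    return res.value, M.to_distance(res.value, spec), res.flag


def _level_object(index: DatasetIndex, id: str, spec: MeasureSpec, extractor: ExtractorConfig | None):
    if spec.level == "image":
        return index.get_volume(id)
    if spec.level == "segmentation":
        return index.get_mask(id)
    feats = index.get_features(id)
    if feats is not None:
        return FeatureVector(values=feats, extractor_id="precomputed", source_id=id)
    cfg = extractor or ExtractorConfig("pooled")
    return extract_features(index.get_volume(id), cfg)


def rank_training(
    synthetic: Volume | FeatureVector | SegMask,
    training: DatasetIndex,
    measure: MeasureSpec,
    extractor: ExtractorConfig | None = None,
) -> RankedNeighbors:
    """Rank every training image by converted distance to one synthetic image.

    Ties are broken lexicographically by training id, so the ranking is
    deterministic for any input.
    """
    if len(training) == 0:
        raise ValueError("training set is empty")
    sid = getattr(synthetic, "id", None) or getattr(synthetic, "source_id", "")
    rows = []
    for tid in training.ids:
        t_obj = _level_object(training, tid, measure, extractor)
        _, dist, _ = pair_distance(synthetic, t_obj, measure)
        rows.append((tid, dist))
    rows.sort(key=lambda r: (r[1], r[0]))
    return RankedNeighbors(synthetic_id=sid, measure=measure, neighbors=tuple(rows))


def compute_distance_matrix(
    synthetic: DatasetIndex,
    training: DatasetIndex,
    measure: MeasureSpec,
    extractor: ExtractorConfig | None = None,
    cache_path: str | Path | None = None,
) -> pd.DataFrame:
    """All-pairs distances as a long table, optionally persisted to a CSV cache.

    Columns: synthetic_id, training_id, measure, level, raw_value,
    distance_value, flags. When a cache covering every pair for this measure
    exists it is reused instead of recomputing (image-level runs on large
    sets can be expensive).
    """
    if len(synthetic) == 0 or len(training) == 0:
        raise ValueError("both datasets must be non-empty")
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            cached = pd.read_csv(cache_path, keep_default_na=False)
            cached = cached[cached["measure"] == measure.name]
            want = {(s, t) for s in synthetic.ids for t in training.ids}
            have = {(str(r.synthetic_id), str(r.training_id)) for r in cached.itertuples()}
            if want <= have:
                cached = cached[
                    cached.apply(lambda r: (str(r["synthetic_id"]), str(r["training_id"])) in want, axis=1)
                ]
                return cached.reset_index(drop=True)

    rows = []
    for sid in synthetic.ids:
        s_obj = _level_object(synthetic, sid, measure, extractor)
        for tid in training.ids:
            t_obj = _level_object(training, tid, measure, extractor)
            raw, dist, flag = pair_distance(s_obj, t_obj, measure)
            rows.append(
                {
                    "synthetic_id": sid,
                    "training_id": tid,
                    "measure": measure.name,
                    "level": measure.level,
                    "raw_value": raw,
                    "distance_value": dist,
                    "flags": flag or "",
                }
            )
    df = pd.DataFrame(rows)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(cache_path, index=False)
    return df


def rank_all(
    synthetic: DatasetIndex,
    training: DatasetIndex,
    measure: MeasureSpec,
    extractor: ExtractorConfig | None = None,
    cache_path: str | Path | None = None,
) -> dict[str, RankedNeighbors]:
    """Rank the training set for every synthetic image from the distance matrix."""
    df = compute_distance_matrix(synthetic, training, measure, extractor, cache_path)
    out: dict[str, RankedNeighbors] = {}
    for sid, grp in df.groupby("synthetic_id", sort=True):
        pairs = sorted(
            ((str(t), float(d)) for t, d in zip(grp["training_id"], grp["distance_value"])),
            key=lambda r: (r[1], r[0]),
        )
        out[str(sid)] = RankedNeighbors(synthetic_id=str(sid), measure=measure, neighbors=tuple(pairs))
    return out


def distance_ratio(
    ranked: RankedNeighbors,
    n: int = DEFAULT_NEIGHBORHOOD,
    include_rank1: bool = True,
) -> DistanceRatio:
    """Rank-1 distance divided by the mean distance over the n closest images.

    By default the rank-1 image is included in the n-set, so the ratio never
    exceeds 1 and thresholds live on [0, 1]; ``include_rank1=False`` averages
    over ranks 2..n+1 instead, which can exceed 1. If the neighborhood mean
    is 0 (an exact-duplicate neighborhood) the ratio is defined as 0 with the
    degenerate flag set — maximal evidence of replication, not an error.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    if not ranked.neighbors:
        raise ValueError("ranking is empty")
    size = len(ranked.neighbors) if include_rank1 else len(ranked.neighbors) - 1
    if size < 1:
        raise ValueError("excluding rank 1 needs at least 2 training images")
    if n > size:
        warnings.warn(
            f"neighborhood n={n} exceeds available training images {size}; capping at {size}",
            stacklevel=2,
        )
        n = size
    start = 0 if include_rank1 else 1
    dists = np.array([d for _, d in ranked.neighbors[start:start + n]], dtype=np.float64)
    d1 = float(ranked.neighbors[0][1])
    mean = float(dists.mean())
    if mean == 0.0:
        return DistanceRatio(ranked.synthetic_id, ranked.measure, 0.0, ranked.neighbors[0][0], n, True)
    return DistanceRatio(
        synthetic_id=ranked.synthetic_id,
        measure=ranked.measure,
        ratio=d1 / mean,
        closest_id=ranked.neighbors[0][0],
        n=n,
        degenerate_flag=False,
    )


def preselect_pairs(
    synthetic: DatasetIndex,
    training: DatasetIndex,
) -> list[tuple[str, str, float]]:
    """Pair each synthetic image with its RMSE-closest training image.

    This is the review table handed to raters for visual scoring: comparing
    every synthetic image against every training image visually is
    infeasible, so each synthetic image gets exactly one candidate source.
    """
    spec = MeasureSpec("rmse")
    out = []
    for sid in synthetic.ids:
        ranked = rank_training(synthetic.get_volume(sid), training, spec)
        tid, d = ranked.neighbors[0]
        out.append((sid, tid, d))
    return out


def rank_synthetic_by_ratio(ratios: list[DistanceRatio]) -> list[DistanceRatio]:
    """Order synthetic images ascending by ratio (most replica-like first)."""
    if not ratios:
        return []
    names = {r.measure.name for r in ratios}
    if len(names) > 1:
        raise ValueError(f"ratios mix measures: {sorted(names)}")
    return sorted(ratios, key=lambda r: (r.ratio, r.synthetic_id))
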