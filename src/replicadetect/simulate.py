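"""Desk-scale phantom studies with planted replicas and known ground truth.

Each phantom volume is a smooth anatomy-like random background plus one or
more compact hyperintense ellipsoidal lesions, with a paired integer label
mask — the structure of a brain scan with focal pathology, at toy scale.
A generated study plants a controlled fraction of "synthetic" volumes as
exact or perturbed copies of training volumes, so every pipeline stage can
be validated against construction-time ground truth without patient data.

Reproducibility is hierarchical: a single study seed deterministically
derives per-subject seeds (study → subject → lesion), so individual
subjects are stable when the study size changes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .decision import NON_REPLICA, REPLICA, GroundTruth
from .volumes import DatasetIndex, IndexEntry, SegMask, Volume, write_mask, write_volume

__all__ = [
    "PhantomParams",
    "SyntheticStudy",
    "generate_phantom",
    "generate_study",
    "write_study",
    "PERTURBATION_KINDS",
]

PERTURBATION_KINDS = ("none", "gaussian_noise", "intensity_shift", "translation")

_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity settings for one phantom volume.

    Intensities live on a nominal [0, 1] scale: background occupies
    ``background_range`` and lesions add ``lesion_contrast`` on top, giving
    clearly hyperintense foreground (CT-hemorrhage-like contrast direction).
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_smoothness: float = 2.0  # gaussian sigma in voxels
    lesion_count: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (2.0, 4.0)  # semi-axis range, voxels
    background_range: tuple[float, float] = (0.1, 0.6)
    lesion_contrast: float = 0.4
    binary_mask: bool = True  # one shared label 1, else one label per lesion

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError(f"shape must be 3D, got {self.shape}")
        for name, (lo, hi) in (
            ("lesion_count", self.lesion_count),
            ("lesion_radius", self.lesion_radius),
            ("background_range", self.background_range),
        ):
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if self.lesion_radius[1] * 2 >= min(self.shape):
            raise ValueError(
                f"lesion radius {self.lesion_radius[1]} does not fit grid {self.shape}"
            )


@dataclass
class SyntheticStudy:
    """A training set, a synthetic set, and construction-time ground truth."""

    training: DatasetIndex
    synthetic: DatasetIndex
    truth: GroundTruth
    provenance: pd.DataFrame  # synthetic_id, source_id, perturbation, magnitude
    params: PhantomParams
    seed: int


def _subject_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(params: PhantomParams, seed: int) -> tuple[Volume, SegMask]:
    """One reproducible phantom: smooth background + ellipsoidal lesions + mask."""
    rng = _subject_rng(seed, 0)
    noise = rng.standard_normal(params.shape)
    bg = ndimage.gaussian_filter(noise, sigma=params.background_smoothness)
    lo, hi = params.background_range
    span = bg.max() - bg.min()
    bg = lo + (hi - lo) * ((bg - bg.min()) / span if span > 0 else np.zeros_like(bg))

    n_lesions = int(rng.integers(params.lesion_count[0], params.lesion_count[1] + 1))
    labels = np.zeros(params.shape, dtype=np.int64)
    volume = bg.copy()
    lesion_rng = _subject_rng(seed, 1)
    for k in range(n_lesions):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            radii = lesion_rng.uniform(*params.lesion_radius, size=3)
            center = np.array(
                [lesion_rng.uniform(r, s - 1 - r) for r, s in zip(radii, params.shape)]
            )
            blob = _ellipsoid(params.shape, center, radii)
            if not blob.any() or (labels[blob] != 0).any():
                continue  # keep lesions disjoint so labels stay distinct
            volume[blob] += params.lesion_contrast
            labels[blob] = 1 if params.binary_mask else k + 1
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {k + 1}/{n_lesions} after {_PLACEMENT_RETRIES} tries"
            )
    vol = Volume(data=volume, spacing=params.spacing, id="")
    mask = SegMask(labels=labels, spacing=params.spacing, id="")
    return vol, mask


def _perturb(
    vol: Volume,
    mask: SegMask,
    kind: str,
    magnitude: float,
    rng: np.random.Generator,
    params: PhantomParams,
) -> tuple[Volume, SegMask]:
    if kind == "none" or magnitude == 0:
        return vol, mask
    if kind == "gaussian_noise":
        data = vol.data + rng.normal(0.0, magnitude, size=vol.shape)
        return Volume(data, vol.spacing, vol.id), mask
    if kind == "intensity_shift":
        return Volume(vol.data + magnitude, vol.spacing, vol.id), mask
    if kind == "translation":
        shift = int(round(magnitude))
        if shift != magnitude:
            raise ValueError(f"translation magnitude must be integral voxels, got {magnitude}")
        axis = int(rng.integers(0, 3))
        fill = params.background_range[0]  # vacated voxels take the background floor
        data = np.full_like(vol.data, fill)
        labels = np.zeros_like(mask.labels)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[axis] = slice(0, vol.shape[axis] - shift)
        dst[axis] = slice(shift, vol.shape[axis])
        data[tuple(dst)] = vol.data[tuple(src)]
        labels[tuple(dst)] = mask.labels[tuple(src)]
        return Volume(data, vol.spacing, vol.id), SegMask(labels, mask.spacing, mask.id)
    raise ValueError(f"unknown perturbation kind {kind!r}; choose from {PERTURBATION_KINDS}")


def _index(entries: list[IndexEntry], role: str, params: PhantomParams) -> DatasetIndex:
    entries = sorted(entries, key=lambda e: e.id)
    return DatasetIndex(entries=entries, role=role, grid_shape=params.shape, spacing=params.spacing)


def generate_study(
    n_train: int,
    n_synth: int,
    replica_fraction: float,
    perturbations: list[tuple[str, float]] | None = None,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> SyntheticStudy:
    """Generate a training set plus a synthetic set with planted replicas.

    ``round(replica_fraction * n_synth)`` synthetic entries are copies of
    randomly chosen training entries, each perturbed by an entry of
    ``perturbations`` (assigned round-robin; ``("none", 0)`` plants exact
    copies). The rest are novel phantoms from fresh seeds. Masks follow
    geometric perturbations (translation) and are untouched by intensity
    perturbations. Ground truth is by construction: planted copy ⇔ replica.
    """
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    if not 0.0 <= replica_fraction <= 1.0:
        raise ValueError(f"replica_fraction must be in [0,1], got {replica_fraction}")
    params = params or PhantomParams()
    perturbations = perturbations or [("none", 0.0)]
    for kind, mag in perturbations:
        if kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {kind!r}")
        if mag < 0:
            raise ValueError(f"perturbation magnitude must be >= 0, got {mag}")

    train_entries = []
    train_items: dict[str, tuple[Volume, SegMask]] = {}
    for i in range(n_train):
        subject_seed = int(_subject_rng(seed, 10, i).integers(0, 2**31))
        vol, mask = generate_phantom(params, subject_seed)
        tid = f"train_{i:04d}"
        vol = Volume(vol.data, vol.spacing, tid)
        mask = SegMask(mask.labels, mask.spacing, tid)
        train_items[tid] = (vol, mask)
        train_entries.append(IndexEntry(id=tid, volume=vol, mask=mask))

    n_replicas = int(round(replica_fraction * n_synth))
    if n_replicas > 0 and n_train == 0:
        raise ValueError("cannot plant replicas with an empty training set")
    choice_rng = _subject_rng(seed, 20)
    source_ids = [f"train_{i:04d}" for i in choice_rng.integers(0, n_train, size=n_replicas)]

    synth_entries = []
    truth: dict[str, str] = {}
    prov_rows = []
    for j in range(n_synth):
        sid = f"synth_{j:04d}"
        if j < n_replicas:
            src = source_ids[j]
            kind, mag = perturbations[j % len(perturbations)]
            vol, mask = train_items[src]
            pert_rng = _subject_rng(seed, 30, j)
            vol, mask = _perturb(vol, mask, kind, float(mag), pert_rng, params)
            truth[sid] = REPLICA
            prov_rows.append({"synthetic_id": sid, "source_id": src, "perturbation": kind, "magnitude": float(mag)})
        else:
            subject_seed = int(_subject_rng(seed, 40, j).integers(0, 2**31))
            vol, mask = generate_phantom(params, subject_seed)
            truth[sid] = NON_REPLICA
            prov_rows.append({"synthetic_id": sid, "source_id": "novel", "perturbation": "none", "magnitude": 0.0})
        vol = Volume(vol.data, vol.spacing, sid)
        mask = SegMask(mask.labels, mask.spacing, sid)
        synth_entries.append(IndexEntry(id=sid, volume=vol, mask=mask))

    return SyntheticStudy(
        training=_index(train_entries, "training", params),
        synthetic=_index(synth_entries, "synthetic", params),
        truth=GroundTruth(labels=truth, provenance="planted by construction"),
        provenance=pd.DataFrame(prov_rows).sort_values("synthetic_id").reset_index(drop=True),
        params=params,
        seed=seed,
    )


def write_study(study: SyntheticStudy, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write a study as NIfTI volumes/masks + manifests + truth/provenance CSVs.

    The layout is exactly what :func:`replicadetect.volumes.build_index`
    consumes; returns the manifest and CSV paths.
    """
    out_dir = Path(out_dir)
    paths: dict[str, Path] = {}
    for role, index in (("training", study.training), ("synthetic", study.synthetic)):
        sub = out_dir / role
        sub.mkdir(parents=True, exist_ok=True)
        rows = []
        for e in index.entries:
            vol_path = sub / f"{e.id}.nii.gz"
            mask_path = sub / f"{e.id}_mask.nii.gz"
            write_volume(index.get_volume(e.id), vol_path)
            write_mask(index.get_mask(e.id), mask_path)
            rows.append({"id": e.id, "volume": str(vol_path), "mask": str(mask_path)})
        manifest = out_dir / f"{role}_manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        paths[f"{role}_manifest"] = manifest
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(
        [{"synthetic_id": k, "label": v} for k, v in sorted(study.truth.labels.items())]
    ).to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    prov_path = out_dir / "provenance.csv"
    study.provenance.to_csv(prov_path, index=False)
    paths["provenance"] = prov_path
    return paths
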