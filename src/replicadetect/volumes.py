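"""Volumetric image and segmentation-mask containers, NIfTI I/O, and dataset indexing.

All volumes taking part in one comparison run must live on a single shared
grid (same shape, same voxel spacing). Inputs are assumed pre-registered;
this module verifies grid equality and refuses mismatches rather than
resampling, since spatial normalization is a preprocessing concern.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "SegMask",
    "IndexEntry",
    "DatasetIndex",
    "VolumeLoadError",
    "IndexError_",
    "load_volume",
    "load_mask",
    "write_volume",
    "write_mask",
    "build_index",
    "read_feature_table",
]

SPACING_ATOL = 1e-6  # mm tolerance when comparing voxel spacings


class VolumeLoadError(ValueError):
    """Raised when a NIfTI file cannot be turned into a valid Volume/SegMask."""


class IndexError_(ValueError):
    """Raised for dataset-index construction failures (duplicates, grid mixes)."""


def _validate_grid(data: np.ndarray, spacing: tuple[float, ...], what: str) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise ValueError(f"{what}: expected a 3D grid, got shape {data.shape}")
    if len(spacing) != 3:
        raise ValueError(f"{what}: spacing must have 3 components, got {spacing}")
    sp = np.asarray(spacing, dtype=float)
    if not np.all(np.isfinite(sp)) or not np.all(sp > 0):
        raise ValueError(f"{what}: spacing must be strictly positive and finite, got {spacing}")


@dataclass(frozen=True)
class Volume:
    """A 3D scalar voxel grid with physical spacing in millimeters.

    The affine (grid-to-world transform) is carried through when present but
    never used in metric computation: all distances are computed in voxel-grid
    space scaled by ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        _validate_grid(data, self.spacing, f"Volume {self.id!r}")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"Volume {self.id!r}: voxel values must all be finite")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SegMask:
    """A 3D non-negative integer label grid; 0 means background."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""
    label_names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = np.asarray(labels, dtype=np.int64)
            if not np.allclose(labels, as_int, atol=0):
                raise ValueError(f"SegMask {self.id!r}: labels must be integers")
            labels = as_int
        labels = labels.astype(np.int64, copy=False)
        _validate_grid(labels, self.spacing, f"SegMask {self.id!r}")
        if labels.min(initial=0) < 0:
            raise ValueError(f"SegMask {self.id!r}: labels must be >= 0")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]


def _load_nifti(path: str | os.PathLike, what: str) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise VolumeLoadError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    # squeeze a singleton trailing axis (common NIfTI dialect); reject other 4D
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"{what} {path}: payload is not 3D after squeezing (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    return data, spacing, np.asarray(img.affine)


def load_volume(path: str | os.PathLike, id: str | None = None) -> Volume:
    """Read a 3D scalar NIfTI volume; ``id`` defaults to the file stem."""
    path = Path(path)
    data, spacing, affine = _load_nifti(path, "volume")
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeLoadError(f"volume {path}: contains non-finite voxel values")
    return Volume(data=data, spacing=spacing, id=id or _stem(path), affine=affine)


def load_mask(path: str | os.PathLike, id: str | None = None) -> SegMask:
    """Read a 3D integer-label NIfTI segmentation mask."""
    path = Path(path)
    data, spacing, _ = _load_nifti(path, "mask")
    rounded = np.rint(data)
    if not np.all(np.isfinite(data)) or np.abs(data - rounded).max(initial=0) > 1e-6:
        raise VolumeLoadError(f"mask {path}: labels must be finite integers")
    if rounded.min(initial=0) < 0:
        raise VolumeLoadError(f"mask {path}: labels must be >= 0")
    return SegMask(labels=rounded.astype(np.int64), spacing=spacing, id=id or _stem(path))


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _spacing_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: Volume, path: str | os.PathLike) -> Path:
    path = Path(path)
    affine = vol.affine if vol.affine is not None else _spacing_affine(vol.spacing)
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: SegMask, path: str | os.PathLike) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _spacing_affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


@dataclass
class IndexEntry:
    """One subject in a dataset: id plus volume / optional mask / optional features.

    ``volume`` and ``mask`` may be filesystem paths (loaded lazily) or already
    materialized objects (as produced by the study simulator).
    """

    id: str
    volume: Path | Volume
    mask: Path | SegMask | None = None
    features: np.ndarray | None = None


@dataclass
class DatasetIndex:
    """Ordered, grid-validated collection of subjects with role training|synthetic."""

    entries: list[IndexEntry]
    role: str
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ("training", "synthetic"):
            raise IndexError_(f"role must be 'training' or 'synthetic', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def entry(self, id: str) -> IndexEntry:
        for e in self.entries:
            if e.id == id:
                return e
        raise KeyError(id)

    def get_volume(self, id: str) -> Volume:
        key = ("vol", id)
        if key not in self._cache:
            e = self.entry(id)
            vol = e.volume if isinstance(e.volume, Volume) else load_volume(e.volume, id=id)
            self._check_grid(vol.shape, vol.spacing, f"volume {id!r}")
            self._cache[key] = vol
        return self._cache[key]

    def get_mask(self, id: str) -> SegMask:
        key = ("mask", id)
        if key not in self._cache:
            e = self.entry(id)
            if e.mask is None:
                raise IndexError_(f"{self.role} entry {id!r} has no segmentation mask")
            mask = e.mask if isinstance(e.mask, SegMask) else load_mask(e.mask, id=id)
            self._check_grid(mask.shape, mask.spacing, f"mask {id!r}")
            self._cache[key] = mask
        return self._cache[key]

    def get_features(self, id: str) -> np.ndarray | None:
        return self.entry(id).features

    def has_masks(self) -> bool:
        return all(e.mask is not None for e in self.entries)

    def has_features(self) -> bool:
        return all(e.features is not None for e in self.entries)

    def _check_grid(self, shape, spacing, what: str) -> None:
        if tuple(shape) != tuple(self.grid_shape):
            raise IndexError_(
                f"{what}: shape {tuple(shape)} differs from index grid {tuple(self.grid_shape)}"
            )
        if not np.allclose(spacing, self.spacing, atol=SPACING_ATOL):
            raise IndexError_(
                f"{what}: spacing {tuple(spacing)} differs from index spacing {tuple(self.spacing)}"
            )


def _nifti_files(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir() if p.name.endswith(".nii") or p.name.endswith(".nii.gz")
    )


def read_feature_table(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read a feature CSV (first column id, remaining columns numeric)."""
    df = pd.read_csv(path)
    id_col = df.columns[0]
    values = df.drop(columns=[id_col]).to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise VolumeLoadError(f"feature table {path}: non-finite values")
    return {str(i): values[k] for k, i in enumerate(df[id_col])}


def build_index(
    source: str | os.PathLike,
    role: str,
    features_csv: str | os.PathLike | None = None,
) -> DatasetIndex:
    """Build a DatasetIndex from a manifest CSV or a directory of NIfTI files.

    A manifest CSV has header columns ``id, volume`` and optionally ``mask``
    and ``features`` (the latter naming the dataset-level feature CSV). Entries
    are ordered lexicographically by id and cross-validated for a shared grid.
    """
    source = Path(source)
    entries: list[IndexEntry] = []
    feat_paths: set[str] = set()
    if source.is_dir():
        for p in _nifti_files(source):
            entries.append(IndexEntry(id=_stem(p), volume=p))
    else:
        df = pd.read_csv(source)
        if "id" not in df.columns or "volume" not in df.columns:
            raise IndexError_(f"manifest {source}: requires 'id' and 'volume' columns")
        base = source.parent
        for _, row in df.iterrows():
            mask = None
            if "mask" in df.columns and isinstance(row.get("mask"), str) and row["mask"]:
                mask = _resolve(base, row["mask"])
            if "features" in df.columns and isinstance(row.get("features"), str) and row["features"]:
                feat_paths.add(str(_resolve(base, row["features"])))
            entries.append(IndexEntry(id=str(row["id"]), volume=_resolve(base, row["volume"]), mask=mask))

    ids = [e.id for e in entries]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IndexError_(f"duplicate ids in {source}: {sorted(dupes)}")
    if not entries:
        raise IndexError_(f"no volumes found in {source}")
    entries.sort(key=lambda e: e.id)

    # grid consistency from headers
    shapes, spacings = [], []
    for e in entries:
        if isinstance(e.volume, Volume):
            shapes.append(e.volume.shape)
            spacings.append(e.volume.spacing)
        else:
            img = nib.load(str(e.volume))
            shp = img.shape
            if len(shp) == 4 and shp[-1] == 1:
                shp = shp[:3]
            shapes.append(tuple(shp))
            spacings.append(tuple(float(z) for z in img.header.get_zooms()[:3]))
    if len({s for s in shapes}) > 1:
        raise IndexError_(f"mixed grid shapes in {source}: {sorted(set(shapes))}")
    ref_spacing = spacings[0]
    for e, sp in zip(entries, spacings):
        if not np.allclose(sp, ref_spacing, atol=SPACING_ATOL):
            raise IndexError_(f"{e.id!r}: spacing {sp} differs from {ref_spacing}")

    index = DatasetIndex(entries=entries, role=role, grid_shape=shapes[0], spacing=ref_spacing)

    if features_csv is None and len(feat_paths) == 1:
        features_csv = feat_paths.pop()
    elif len(feat_paths) > 1:
        raise IndexError_(f"manifest {source}: multiple distinct feature CSVs referenced")
    if features_csv is not None:
        table = read_feature_table(features_csv)
        missing = [e.id for e in entries if e.id not in table]
        if missing:
            raise IndexError_(f"feature table missing ids: {missing}")
        for e in entries:
            e.features = table[e.id]
    return index


def _resolve(base: Path, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else base / path
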