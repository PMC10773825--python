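"""Volume I/O, dataset manifests, cropping, normalization and
cross-validation splits.

Conventions: all in-memory volumes are channels-first ``(C, D, H, W)``
float arrays with 0-based indexing; NIfTI affines are carried through
untouched from reading to write-back.  For the multi-modal MRI regime
the channel order is (T1, T1Gd, T2, T2-FLAIR).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple
import warnings

import nibabel as nib
import numpy as np

from .blocks import FeatureMap

MRI_CHANNEL_ORDER = ("t1", "t1gd", "t2", "flair")


@dataclass
class VolumeRecord:
    identifier: str
    image_paths: list[str]
    label_path: str | None = None
    spacing: tuple[float, float, float] | None = None


@dataclass
class DatasetManifest:
    records: list[VolumeRecord]
    label_set: frozenset[int]
    channels: int
    task: str = "segmentation"

    def __post_init__(self):
        ids = [r.identifier for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate identifiers in manifest: {dupes}")

    def save(self, path):
        payload = {
            "task": self.task,
            "channels": self.channels,
            "label_set": sorted(self.label_set),
            "training": [
                {"id": r.identifier, "image": list(r.image_paths), "label": r.label_path}
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        base = Path(path).parent
        records = []
        for entry in d["training"]:
            imgs = entry["image"]
            imgs = [imgs] if isinstance(imgs, str) else list(imgs)
            imgs = [str(base / p) if not Path(p).is_absolute() else p for p in imgs]
            lab = entry.get("label")
            if lab is not None and not Path(lab).is_absolute():
                lab = str(base / lab)
            records.append(VolumeRecord(entry["id"], imgs, lab))
        return cls(records=records, label_set=frozenset(d["label_set"]),
                   channels=int(d["channels"]), task=d.get("task", "segmentation"))


class LoadedVolume(NamedTuple):
    image: FeatureMap
    labels: np.ndarray | None
    affine: np.ndarray


def read_volume(record: VolumeRecord, label_set: frozenset[int] | None = None) -> LoadedVolume:
    """Load a record into a channels-first image and integer label volume.

    One file per channel (stacked in the given order) or a single 4D
    file.  The label extent must match the image extent; label values
    outside ``label_set`` raise an error naming the offending values.
    """
    arrays, affine = [], None
    for p in record.image_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"image file missing for {record.identifier}: {p}")
        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=np.float32)
        if affine is None:
            affine = img.affine
        if data.ndim == 4:
            arrays.extend(np.moveaxis(data, -1, 0))
        else:
            arrays.append(data)
    image = np.stack(arrays, axis=0)
    labels = None
    if record.label_path is not None:
        if not Path(record.label_path).exists():
            raise FileNotFoundError(
                f"label file missing for {record.identifier}: {record.label_path}")
        labels = np.asarray(nib.load(record.label_path).dataobj)
        labels = np.rint(labels).astype(np.int16)
        if labels.shape != image.shape[1:]:
            raise ValueError(
                f"extent mismatch for {record.identifier}: image {image.shape[1:]} "
                f"vs label {labels.shape}")
        if label_set is not None:
            bad = sorted(set(np.unique(labels).tolist()) - set(label_set))
            if bad:
                raise ValueError(
                    f"label value(s) {bad} not in declared label set "
                    f"{sorted(label_set)} for {record.identifier}")
    return LoadedVolume(FeatureMap(image), labels, affine)


def write_segmentation(labels: np.ndarray, reference: LoadedVolume | np.ndarray, path):
    """Write an integer label volume with the reference affine."""
    affine = reference.affine if isinstance(reference, LoadedVolume) else np.asarray(reference)
    if isinstance(reference, LoadedVolume) and labels.shape != reference.image.spatial_extent:
        raise ValueError(
            f"extent mismatch: labels {labels.shape} vs reference "
            f"{reference.image.spatial_extent}")
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))


def random_crop_patch(image: np.ndarray, label: np.ndarray | None,
                      size: tuple[int, int, int], rng: np.random.Generator):
    """Crop image and label with identical uniformly drawn offsets.

    Volumes smaller than ``size`` are first padded symmetrically with
    the background value (0).
    """
    image = np.asarray(image)
    extent = image.shape[1:]
    pads = [max(0, s - e) for s, e in zip(size, extent)]
    if any(pads):
        pw = [(p // 2, p - p // 2) for p in pads]
        image = np.pad(image, [(0, 0)] + pw)
        if label is not None:
            label = np.pad(label, pw)
        extent = image.shape[1:]
    offsets = tuple(int(rng.integers(0, e - s + 1)) for e, s in zip(extent, size))
    sl = tuple(slice(o, o + s) for o, s in zip(offsets, size))
    img_patch = image[(slice(None),) + sl]
    lab_patch = label[sl] if label is not None else None
    return img_patch, lab_patch


def normalize_intensity(image, scheme: str = "nonzero_zscore",
                        window: tuple[float, float] = (-175.0, 250.0)):
    """Intensity normalization.

    ``nonzero_zscore`` (MRI regime): per channel, zero-mean/unit-sd over
    the nonzero voxels; an all-zero channel is returned unchanged with a
    warning.  ``window_scale`` (CT regime): clip to ``window`` and scale
    linearly to [0, 1].
    """
    arr, wrap = (image.values, True) if isinstance(image, FeatureMap) else (np.asarray(image), False)
    arr = arr.astype(np.float32).copy()
    if scheme == "nonzero_zscore":
        for c in range(arr.shape[0]):
            mask = arr[c] != 0
            if not mask.any():
                warnings.warn(f"channel {c} is all zero; left unchanged")
                continue
            vals = arr[c][mask]
            sd = vals.std()
            arr[c][mask] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    elif scheme == "window_scale":
        lo, hi = window
        arr = np.clip(arr, lo, hi)
        arr = (arr - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    return FeatureMap(arr) if wrap else arr


@dataclass
class FoldAssignment:
    """Validation-fold index per record identifier (folds partition the set)."""

    fold_of: dict[str, int]
    k: int

    def validation_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    def training_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.fold_of.items() if f != fold)

    def save(self, path):
        Path(path).write_text(json.dumps({"k": self.k, "fold_of": self.fold_of}, indent=1))

    @classmethod
    def load(cls, path) -> "FoldAssignment":
        d = json.loads(Path(path).read_text())
        return cls(fold_of={k: int(v) for k, v in d["fold_of"].items()}, k=int(d["k"]))


def make_cv_folds(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle once with ``seed`` and partition into k near-equal
    validation folds (the 80/20 protocol at k=5)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    ids = [r.identifier for r in manifest.records]
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} records")
    order = list(np.random.default_rng(seed).permutation(ids))
    return FoldAssignment(fold_of={str(i): idx % k for idx, i in enumerate(order)}, k=k)
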