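"""Seedable synthetic phantoms emulating the two dataset regimes.

``brain4ch`` mimics multi-modal brain-tumor MRI: four channels, a
brain-like foreground ellipsoid, and a nested lesion (edema shell,
label 2 ⊃ core shell, label 1 ⊃ enhancing center, label 4) so the
WT ⊇ TC ⊇ ET region structure holds by construction.  ``abdomen1ch``
mimics single-channel abdominal CT with up to 13 pairwise-disjoint
organ-like blobs on background 0.

Geometry is ellipsoidal and intensities are constant per tissue class
plus additive Gaussian noise: the generator exists to exercise the
pipeline with controllable class volumes and contrasts, not to model
imaging physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .data import DatasetManifest, VolumeRecord

#: Per-tissue mean intensity for each of the four MRI-like channels
#: (rows: background, brain, edema, core, enhancing).
BRAIN_CONTRASTS = np.array([
    [0.00, 0.00, 0.00, 0.00],
    [0.45, 0.50, 0.40, 0.42],
    [0.55, 0.48, 0.75, 0.85],
    [0.30, 0.40, 0.60, 0.70],
    [0.75, 0.95, 0.55, 0.60],
], dtype=np.float32)


@dataclass
class PhantomSpec:
    """Seedable description of one synthetic labeled volume."""

    extent: tuple[int, int, int] = (64, 64, 64)
    regime: str = "brain4ch"
    n_lesions: int = 1
    n_organs: int = 13
    noise_sd: float = 0.05
    seed: int = 0
    contrasts: np.ndarray = field(default_factory=lambda: BRAIN_CONTRASTS.copy())
    lesion_radius_frac: tuple[float, float] = (0.14, 0.20)
    organ_radius_frac: tuple[float, float] = (0.05, 0.10)

    def __post_init__(self):
        if self.regime not in ("brain4ch", "abdomen1ch"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if min(self.extent) < 32:
            raise ValueError(f"extent must be at least 32 per axis, got {self.extent}")
        if self.regime == "abdomen1ch" and not (1 <= self.n_organs <= 13):
            raise ValueError("n_organs must be between 1 and 13")


def _ellipsoid_mask(extent, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, e) for e in extent)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_brain_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (image (4, D, H, W) float32, labels in {0, 1, 2, 4})."""
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent
    labels = np.zeros(extent, dtype=np.int16)
    center = np.array(extent) / 2.0
    brain = _ellipsoid_mask(extent, center, 0.42 * np.array(extent) * rng.uniform(0.95, 1.05, 3))
    for _ in range(spec.n_lesions):
        r_wt = rng.uniform(*spec.lesion_radius_frac) * min(extent) * rng.uniform(0.9, 1.1, 3)
        if np.any(2 * r_wt > np.array(extent)):
            raise ValueError("lesion larger than the volume")
        lc = center + rng.uniform(-0.12, 0.12, 3) * np.array(extent)
        edema = _ellipsoid_mask(extent, lc, r_wt) & brain
        core = _ellipsoid_mask(extent, lc, 0.65 * r_wt) & brain
        enh = _ellipsoid_mask(extent, lc, 0.38 * r_wt) & brain
        labels[edema] = 2
        labels[core] = 1
        labels[enh] = 4
    tissue = np.zeros(extent, dtype=np.intp)      # 0 background, 1 brain
    tissue[brain] = 1
    tissue[labels == 2] = 2
    tissue[labels == 1] = 3
    tissue[labels == 4] = 4
    image = spec.contrasts.T[:, tissue]            # (4, D, H, W)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape).astype(np.float32)
    return np.ascontiguousarray(image, dtype=np.float32), labels


def generate_abdomen_phantom(spec: PhantomSpec, max_retries: int = 200
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Return (image (1, D, H, W) float32, labels in {0..n_organs})."""
    rng = np.random.default_rng(spec.seed)
    extent = np.array(spec.extent)
    labels = np.zeros(spec.extent, dtype=np.int16)
    occupied = np.zeros(spec.extent, dtype=bool)
    for organ in range(1, spec.n_organs + 1):
        placed = False
        for _ in range(max_retries):
            radii = rng.uniform(*spec.organ_radius_frac, 3) * extent
            c = rng.uniform(0.18, 0.82, 3) * extent
            blob = _ellipsoid_mask(spec.extent, c, radii)
            if blob.any() and not (blob & occupied).any():
                labels[blob] = organ
                occupied |= blob
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place organ {organ} after {max_retries} retries")
    means = np.concatenate([[0.05], np.linspace(0.25, 0.95, spec.n_organs)]).astype(np.float32)
    image = means[labels][None]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape).astype(np.float32)
    return np.ascontiguousarray(image, dtype=np.float32), labels


def generate_manifest(n_subjects: int, spec: PhantomSpec, out_dir) -> DatasetManifest:
    """Write ``n_subjects`` phantom NIfTI pairs plus a JSON manifest.

    Per-subject seeds are spawned from the master seed, so subjects
    differ from each other but the whole dataset is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    records = []
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    brain = spec.regime == "brain4ch"
    for i, child in enumerate(child_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        sub_spec = PhantomSpec(extent=spec.extent, regime=spec.regime,
                               n_lesions=spec.n_lesions, n_organs=spec.n_organs,
                               noise_sd=spec.noise_sd, seed=sub_seed,
                               contrasts=spec.contrasts,
                               lesion_radius_frac=spec.lesion_radius_frac,
                               organ_radius_frac=spec.organ_radius_frac)
        image, labels = (generate_brain_phantom(sub_spec) if brain
                         else generate_abdomen_phantom(sub_spec))
        ident = f"subject_{i:03d}"
        paths = []
        channel_names = ("t1", "t1gd", "t2", "flair") if brain else ("ct",)
        for c, name in enumerate(channel_names):
            p = out / f"{ident}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(image[c], affine), str(p))
            paths.append(p.name)
        lab_path = out / f"{ident}_seg.nii.gz"
        nib.save(nib.Nifti1Image(labels, affine), str(lab_path))
        records.append(VolumeRecord(ident, paths, lab_path.name))
    label_set = frozenset({0, 1, 2, 4}) if brain else frozenset(range(spec.n_organs + 1))
    manifest = DatasetManifest(records=records, label_set=label_set,
                               channels=4 if brain else 1,
                               task="brain4ch" if brain else "abdomen1ch")
    manifest.save(out / "manifest.json")
    return DatasetManifest.load(out / "manifest.json")  # absolute paths resolved
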