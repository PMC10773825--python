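"""Soft Dice loss, Dice score, tumor-region construction and
cross-validation aggregation.

The loss is the voxel-wise soft Dice complement

    L = 1 - 2 * sum(p_i * g_i) / (sum(p_i^2) + sum(g_i^2)),

computed per class and averaged.  A small smoothing term (added to both
numerator and denominator) guards the empty/empty case; with
``smooth=0`` the printed formula is evaluated exactly.

Brain-tumor ground truth uses integer labels {0, 1, 2, 4} which are
evaluated as three nested overlapping regions: whole tumor
WT = {1, 2, 4}, tumor core TC = {1, 4} and enhancing tumor ET = {4}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autograd import Tensor

#: Region name -> label set, in reporting order.
BRATS_REGIONS: dict[str, frozenset[int]] = {
    "WT": frozenset({1, 2, 4}),
    "TC": frozenset({1, 4}),
    "ET": frozenset({4}),
}

BRATS_LABELS = frozenset({0, 1, 2, 4})


@dataclass
class SegmentationPair:
    """Per-class prediction (values in [0, 1]) and binary ground truth."""

    prediction: np.ndarray
    ground_truth: np.ndarray

    def __post_init__(self):
        self.prediction = np.asarray(self.prediction, dtype=np.float64)
        self.ground_truth = np.asarray(self.ground_truth, dtype=np.float64)
        if self.prediction.shape != self.ground_truth.shape:
            raise ValueError(
                f"shape mismatch: prediction {self.prediction.shape} "
                f"vs ground truth {self.ground_truth.shape}")
        if self.prediction.size < 1:
            raise ValueError("empty segmentation pair")
        if not np.isin(self.ground_truth, (0.0, 1.0)).all():
            raise ValueError("ground truth must be binary")

    @property
    def n(self) -> int:
        return self.prediction.size


def soft_dice_loss(prediction, ground_truth=None, smooth: float = 1e-5):
    """Soft Dice loss, averaged over leading (batch/class) axes.

    Two call styles: ``soft_dice_loss(pair)`` with a
    :class:`SegmentationPair` (returns a float), or
    ``soft_dice_loss(pred, target)`` where ``pred`` may be an autograd
    :class:`Tensor` of shape (N, C, ...) — the per-(sample, class) Dice
    terms are averaged and a differentiable Tensor is returned.
    """
    if isinstance(prediction, SegmentationPair):
        pair = prediction
        prediction, ground_truth = pair.prediction, pair.ground_truth
    if isinstance(prediction, Tensor):
        g = Tensor(np.asarray(ground_truth, dtype=prediction.dtype))
        if g.shape != prediction.shape:
            raise ValueError(f"shape mismatch: {prediction.shape} vs {g.shape}")
        axes = tuple(range(2, prediction.ndim)) if prediction.ndim > 2 else (1,)
        inter = (prediction * g).sum(axis=axes)
        denom = (prediction * prediction).sum(axis=axes) + (g * g).sum(axis=axes)
        dice = (inter * 2.0 + smooth) / (denom + smooth)
        return 1.0 - dice.mean()
    p = np.asarray(prediction, dtype=np.float64)
    g = np.asarray(ground_truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = float((p * g).sum())
    denom = float((p * p).sum() + (g * g).sum())
    if denom + smooth == 0.0:
        return 0.0  # both empty, smooth=0: perfect-overlap convention
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def dice_score(prediction, ground_truth=None, empty_value: float = 1.0) -> float:
    """Hard Dice overlap 2|P∩G| / (|P| + |G|) for binarized masks.

    When both masks are empty the score is ``empty_value`` (1.0 by
    convention: an absent structure correctly predicted absent).
    """
    if isinstance(prediction, SegmentationPair):
        pair = prediction
        prediction, ground_truth = pair.prediction, pair.ground_truth
    p = np.asarray(prediction).astype(bool)
    g = np.asarray(ground_truth).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return float(empty_value)
    return 2.0 * int((p & g).sum()) / denom


def brats_region_masks(labels: np.ndarray,
                       label_map: dict[str, frozenset[int]] | None = None
                       ) -> dict[str, np.ndarray]:
    """Build the nested WT / TC / ET binary masks from an integer label
    volume with values in {0, 1, 2, 4}."""
    labels = np.asarray(labels)
    regions = label_map or BRATS_REGIONS
    allowed = {0} | set().union(*regions.values())
    bad = sorted(set(np.unique(labels).tolist()) - allowed)
    if bad:
        raise ValueError(f"unexpected label value(s) {bad}; allowed: {sorted(allowed)}")
    return {name: np.isin(labels, sorted(lab)) for name, lab in regions.items()}


def aggregate_cv_results(per_fold_per_class: pd.DataFrame) -> pd.DataFrame:
    """Cross-validation aggregation: classes as rows, folds as columns.

    Appends an ``Avg.`` column (per-class mean over folds) and an
    ``Avg.`` row (per-fold mean over classes); the bottom-right cell is
    the grand average, i.e. the mean of the per-class averages.
    """
    df = pd.DataFrame(per_fold_per_class).astype(float)
    missing = [(str(r), str(c)) for r in df.index for c in df.columns
               if pd.isna(df.loc[r, c])]
    if missing:
        raise ValueError(f"missing cells (class, fold): {missing}")
    out = df.copy()
    out["Avg."] = df.mean(axis=1)
    out.loc["Avg."] = out.mean(axis=0)
    return out
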