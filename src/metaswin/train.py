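"""Training loop, sliding-window inference and evaluation harness.

Training follows the published recipe where it is stated — soft Dice
loss, batch size 1, base learning rate 1e-4 — and documented defaults
where it is not (AdamW with cosine decay).  The two head semantics are:

* ``brain4ch``: 3 sigmoid channels, one per overlapping tumor region
  (WT, TC, ET), thresholded at 0.5;
* ``abdomen1ch``: softmax over all classes including background,
  argmax-decoded.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor, no_grad
from .blocks import FeatureMap
from .data import (DatasetManifest, FoldAssignment, make_cv_folds,
                   normalize_intensity, random_crop_patch, read_volume)
from .losses import BRATS_REGIONS, aggregate_cv_results, brats_region_masks, dice_score, \
    soft_dice_loss
from .model import ModelConfig, build_network, save_checkpoint
from .nn import Adam, AdamW, SGD, cosine_lr

REGION_ORDER = tuple(BRATS_REGIONS)  # ("WT", "TC", "ET")


@dataclass
class RunConfig:
    """One training run: architecture plus optimization settings."""

    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: str = "adamw"
    learning_rate: float = 1e-4
    schedule: str = "cosine"
    weight_decay: float = 1e-2
    epochs: int = 800
    batch_size: int = 1
    patch_size: tuple[int, int, int] = (128, 128, 128)
    loss: str = "dice"            # "dice" or "dice_ce"
    smooth: float = 1e-5
    normalization: str | None = None   # None = pick by task regime
    ct_window: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    fold: int = 0
    out_dir: str = "runs/default"
    checkpoint_every: int = 1
    max_steps: int | None = None
    val_every: int = 1

    def to_json(self) -> str:
        d = asdict(self)
        d["model"] = asdict(self.model)
        return json.dumps(d, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            m = dict(d["model"])
            for k in ("depths", "heads", "roi", "pooling_depths"):
                if m.get(k) is not None:
                    m[k] = tuple(m[k])
            d["model"] = ModelConfig(**m)
        for k in ("patch_size", "ct_window"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def _make_optimizer(run: RunConfig, params):
    name = run.optimizer.lower()
    if name == "adamw":
        return AdamW(params, lr=run.learning_rate, weight_decay=run.weight_decay)
    if name == "adam":
        return Adam(params, lr=run.learning_rate)
    if name == "sgd":
        return SGD(params, lr=run.learning_rate)
    raise ValueError(f"unknown optimizer {run.optimizer!r}")


def _target_stack(labels: np.ndarray, task: str, n_classes: int) -> np.ndarray:
    if task == "brain4ch":
        masks = brats_region_masks(labels)
        return np.stack([masks[r] for r in REGION_ORDER]).astype(np.float32)
    return (np.arange(n_classes).reshape(-1, 1, 1, 1) == labels[None]).astype(np.float32)


def _probabilities(logits: Tensor, task: str) -> Tensor:
    return logits.sigmoid() if task == "brain4ch" else logits.softmax(axis=1)


def decode_labels(probs: np.ndarray, task: str) -> np.ndarray:
    """Turn per-class probabilities into an integer label volume."""
    if task == "brain4ch":
        wt, tc, et = (probs[i] >= 0.5 for i in range(3))
        out = np.zeros(probs.shape[1:], dtype=np.int16)
        out[wt] = 2
        out[wt & tc] = 1
        out[wt & tc & et] = 4
        return out
    return np.argmax(probs, axis=0).astype(np.int16)


def _loss_fn(run: RunConfig, probs: Tensor, target: np.ndarray) -> Tensor:
    loss = soft_dice_loss(probs, target, smooth=run.smooth)
    if run.loss == "dice_ce":
        eps = 1e-7
        p = probs * (1.0 - 2 * eps) + eps
        ce = -(Tensor(target) * p.log()).sum(axis=1).mean()
        loss = loss + ce
    elif run.loss != "dice":
        raise ValueError(f"unknown loss {run.loss!r}")
    return loss


def _normalize_for_task(image: np.ndarray, run: RunConfig, task: str) -> np.ndarray:
    scheme = run.normalization
    if scheme is None:
        scheme = "nonzero_zscore" if task == "brain4ch" else "window_scale"
    if scheme == "none":
        return image.astype(np.float32)
    return normalize_intensity(image, scheme=scheme, window=run.ct_window)


@dataclass
class TrainResult:
    history: list[dict]
    best_checkpoint: str
    last_checkpoint: str
    final_train_loss: float
    best_val_dice: float | None


def train(run: RunConfig, manifest: DatasetManifest,
          folds: FoldAssignment | None = None) -> TrainResult:
    """Epoch loop: random crop -> forward -> soft Dice loss -> step.

    Per-epoch mean training loss and validation Dice are appended to
    ``metrics.csv`` in ``run.out_dir``; the checkpoint with the best
    validation Dice is kept (the last checkpoint when there is no
    validation split).  All randomness flows from ``run.seed``.
    """
    out_dir = Path(run.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(run.to_json())
    task = manifest.task if manifest.task in ("brain4ch", "abdomen1ch") else "abdomen1ch"
    n_classes = run.model.out_channels
    if folds is None:
        folds = make_cv_folds(manifest, k=5, seed=run.seed) if len(manifest.records) >= 5 \
            else FoldAssignment({r.identifier: -1 for r in manifest.records}, k=1)
    train_ids = set(folds.training_ids(run.fold)) if folds.k > 1 else \
        {r.identifier for r in manifest.records}
    val_ids = set(folds.validation_ids(run.fold)) if folds.k > 1 else set()
    records = {r.identifier: r for r in manifest.records}

    rng = np.random.default_rng(run.seed)
    net = build_network(run.model, seed=run.seed)
    opt = _make_optimizer(run, net.parameters())
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def load(ident: str):
        if ident not in cache:
            vol = read_volume(records[ident], manifest.label_set)
            img = _normalize_for_task(vol.image.values, run, task)
            cache[ident] = (img, vol.labels)
        return cache[ident]

    total_steps = run.max_steps or run.epochs * max(1, len(train_ids))
    history: list[dict] = []
    best_val, best_path = None, out_dir / "best.npz"
    step = 0
    stop = False
    for epoch in range(run.epochs):
        losses = []
        order = list(train_ids)
        rng.shuffle(order)
        for ident in order:
            img, lab = load(ident)
            patch, lab_patch = random_crop_patch(img, lab, run.patch_size, rng)
            target = _target_stack(lab_patch, task, n_classes)
            if run.schedule == "cosine":
                opt.lr = cosine_lr(run.learning_rate, step, total_steps)
            opt.zero_grad()
            logits = net(Tensor(patch[None]))
            loss = _loss_fn(run, _probabilities(logits, task), target[None])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if run.max_steps is not None and step >= run.max_steps:
                stop = True
                break
        val_dice = None
        if val_ids and run.val_every and ((epoch + 1) % run.val_every == 0 or stop):
            scores = []
            for ident in sorted(val_ids):
                img, lab = load(ident)
                pred = sliding_window_predict(net, img, roi=run.patch_size, task=task)
                scores.append(np.mean(list(per_class_dice(pred, lab, task,
                                                          n_classes).values())))
            val_dice = float(np.mean(scores))
        history.append({"epoch": epoch, "step": step,
                        "train_loss": float(np.mean(losses)) if losses else float("nan"),
                        "val_dice": val_dice, "lr": opt.lr})
        if val_dice is not None and (best_val is None or val_dice > best_val):
            best_val = val_dice
            save_checkpoint(net, best_path)
        if stop:
            break
    last_path = out_dir / "last.npz"
    save_checkpoint(net, last_path)
    if best_val is None:
        save_checkpoint(net, best_path)
    with open(out_dir / "metrics.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "step", "train_loss",
                                                "val_dice", "lr"])
        writer.writeheader()
        writer.writerows(history)
    return TrainResult(history=history, best_checkpoint=str(best_path),
                       last_checkpoint=str(last_path),
                       final_train_loss=history[-1]["train_loss"] if history else float("nan"),
                       best_val_dice=best_val)


def sliding_window_predict(net, image, roi=(128, 128, 128), overlap: float = 0.5,
                           task: str = "brain4ch", return_probs: bool = False):
    """Tile the volume with ``roi``-sized windows, average overlapping
    logits, and decode labels per the task's head semantics."""
    arr = image.values if isinstance(image, FeatureMap) else np.asarray(image)
    if arr.shape[0] != net.cfg.in_channels:
        raise ValueError(f"expected {net.cfg.in_channels} channels, got {arr.shape[0]}")
    extent = arr.shape[1:]
    pads = [max(0, r - e) for r, e in zip(roi, extent)]
    padded = np.pad(arr, [(0, 0)] + [(p // 2, p - p // 2) for p in pads]) if any(pads) else arr
    pext = padded.shape[1:]
    stride = [max(1, int(r * (1.0 - overlap))) for r in roi]
    starts = []
    for e, r, s in zip(pext, roi, stride):
        pos = list(range(0, e - r + 1, s))
        if pos[-1] != e - r:
            pos.append(e - r)
        starts.append(pos)
    logits_sum = np.zeros((net.cfg.out_channels,) + pext, dtype=np.float64)
    counts = np.zeros(pext, dtype=np.float64)
    with no_grad():
        for z in starts[0]:
            for y in starts[1]:
                for x in starts[2]:
                    sl = (slice(None), slice(z, z + roi[0]),
                          slice(y, y + roi[1]), slice(x, x + roi[2]))
                    tile = net(Tensor(padded[sl][None])).data[0]
                    logits_sum[sl] += tile
                    counts[sl[1:]] += 1.0
    logits = logits_sum / counts
    if any(pads):
        lo = [p // 2 for p in pads]
        logits = logits[(slice(None),) + tuple(slice(l, l + e) for l, e in zip(lo, extent))]
    probs = _probabilities(Tensor(logits.astype(np.float32)), task).data
    labels = decode_labels(probs, task)
    return (labels, probs) if return_probs else labels


def per_class_dice(pred_labels: np.ndarray, ref_labels: np.ndarray,
                   task: str, n_classes: int) -> dict[str, float]:
    """Per-class Dice: tumor regions for the brain regime, organ labels
    (background excluded) for the abdomen regime."""
    if task == "brain4ch":
        pm = brats_region_masks(pred_labels)
        rm = brats_region_masks(ref_labels)
        return {r: dice_score(pm[r], rm[r]) for r in REGION_ORDER}
    return {str(c): dice_score(pred_labels == c, ref_labels == c)
            for c in range(1, n_classes)}


def evaluate(predictions: dict[str, np.ndarray], references: dict[str, np.ndarray],
             task: str, n_classes: int,
             fold_of: dict[str, int] | None = None) -> dict:
    """Per-subject per-class Dice plus the cross-validation aggregate table.

    ``predictions`` and ``references`` map identifiers to integer label
    volumes; the identifier sets must match exactly.
    """
    missing = sorted(set(references) ^ set(predictions))
    if missing:
        raise ValueError(f"unmatched identifiers: {missing}")
    rows = {}
    for ident in sorted(references):
        rows[ident] = per_class_dice(predictions[ident], references[ident], task, n_classes)
    per_subject = pd.DataFrame(rows).T  # subjects x classes
    if fold_of:
        folds = sorted(set(fold_of.values()))
        grid = pd.DataFrame(
            {f"Fold {f + 1}": per_subject.loc[[i for i in per_subject.index
                                               if fold_of[i] == f]].mean()
             for f in folds})
        table = aggregate_cv_results(grid)
    else:
        grid = per_subject.mean().to_frame("All")
        table = aggregate_cv_results(grid)
    return {"per_subject": per_subject, "table": table,
            "mean_dice": float(per_subject.mean().mean())}
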