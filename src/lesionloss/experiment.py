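"""Seeded multi-loss, multi-fold training and per-epoch evaluation.

The harness trains the same U-net under several loss functions while
holding everything random fixed across losses: for a given (seed, fold)
cell, initial weights and per-epoch batch shuffling are derived from the
same sub-seed for every loss, so curve differences between losses cannot be
explained by initialisation or shuffling.  After every training epoch the
model is evaluated at three scopes:

* ``patch``       — confusion counts pooled over the lesion-containing
                    training patches of that epoch;
* ``train_image`` — per-subject metrics on training images reconstructed
                    from all sliding windows by overlap averaging;
* ``test_image``  — the same on held-out subjects.

All predictions are binarised at the plan threshold (default 0.5).  Band
summaries reduce the records to min/mean/max per (loss, epoch, scope,
metric) over seeds, folds and subjects, the envelope view of training
stochasticity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .losses import make_logit_loss
from .metrics import (ConfusionCounts, MetricRecord, binarize, compute_metrics,
                      confusion, records_to_frame)
from .network import UnetSpec, build_unet
from .patchflow import (bounding_box, extract_patches, filter_lesion_patches,
                        make_batches, patch_grid, reconstruct)
from .synthetic_data import Cohort, Subject

__all__ = ["ExperimentPlan", "make_folds", "run_experiment", "band_summary",
           "derive_seed"]


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything that defines a training/evaluation campaign."""

    losses: Tuple[str, ...] = ("xent", "focal1", "focal2", "gdsc", "dsc",
                               "mixed", "new")
    seeds: Tuple[int, ...] = (0, 1, 2, 3, 4)
    n_folds: int = 5
    max_epochs: int = 25
    batch_size: int = 16
    patch_size: int = 32
    stride: int = 16
    threshold: float = 0.5
    learning_rate: float = 1e-3
    in_channels: int = 1
    widths: Tuple[int, int, int, int] = (32, 64, 128, 256)
    group_channels: int = 8
    split_seed: int = 0

    def unet_spec(self) -> UnetSpec:
        return UnetSpec(in_channels=self.in_channels, widths=self.widths,
                        group_channels=self.group_channels)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("losses", "seeds", "widths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def derive_seed(*parts: int) -> int:
    """Stable sub-seed from integer coordinates (seed, fold, epoch, ...).

    Independent of the loss, so adding losses never perturbs existing runs.
    """
    h = 0
    for p in parts:
        h = (h * 1_000_003 + int(p) + 0x9E3779B9) % (2**31)
    return h


def make_folds(subject_ids: Sequence[str], n_folds: int,
               split_seed: int = 0) -> List[Tuple[List[str], List[str]]]:
    """Disjoint, exhaustive, near-equal test splits; deterministic."""
    ids = list(subject_ids)
    if len(ids) < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects for {n_folds} folds, got {len(ids)}"
        )
    rng = np.random.default_rng(split_seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_sets = [list(part) for part in np.array_split(order, n_folds)]
    folds = []
    for test in test_sets:
        train = [i for i in order if i not in test]
        folds.append((train, test))
    return folds


# ---------------------------------------------------------------------------
# per-subject preparation
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    subject: Subject
    train_origins: List[Tuple[int, int, int]]
    eval_origins: List[Tuple[int, int, int]]
    volume: np.ndarray  # normalised (C, D, H, W) float32
    eval_patches: np.ndarray = None  # cached windows for image evaluation


def _normalise(subject: Subject) -> np.ndarray:
    """Per-volume z-score over brain voxels; air stays at zero."""
    brain = subject.brain_mask.astype(bool)
    out = np.zeros_like(subject.image, dtype=np.float32)
    for c in range(subject.image.shape[0]):
        vals = subject.image[c][brain]
        mu, sd = float(vals.mean()), float(vals.std())
        out[c][brain] = (subject.image[c][brain] - mu) / max(sd, 1e-8)
    return out


def _prepare(subject: Subject, plan: ExperimentPlan) -> _Prepared:
    box = bounding_box(subject.brain_mask)
    grid = patch_grid(box, size=plan.patch_size, stride=plan.stride)
    lesion_grid = filter_lesion_patches(grid, subject.lesion_mask)
    volume = _normalise(subject)
    return _Prepared(
        subject=subject,
        train_origins=list(lesion_grid.origins),
        eval_origins=list(grid.origins),
        volume=volume,
        eval_patches=extract_patches(volume, grid.origins, plan.patch_size),
    )


def _forward_in_batches(model, patches: np.ndarray, batch_size: int) -> np.ndarray:
    outs = []
    for i in range(0, len(patches), batch_size):
        outs.append(model.predict_proba(patches[i:i + batch_size])[:, 0])
    return np.concatenate(outs) if outs else np.empty((0,))


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def run_experiment(plan: ExperimentPlan, cohort: Cohort,
                   progress: Optional[callable] = None) -> pd.DataFrame:
    """Train every (loss, seed, fold) cell and evaluate after each epoch.

    Returns the full metric-record table (one row per record, canonical CSV
    schema).  Deterministic: identical plans and cohorts give identical
    tables.
    """
    prepared = {s.subject_id: _prepare(s, plan) for s in cohort.subjects}
    folds = make_folds(cohort.subject_ids, plan.n_folds, plan.split_seed)
    records: List[MetricRecord] = []
    init_checksums: Dict[Tuple[str, int, int], str] = {}

    for fold_idx, (train_ids, test_ids) in enumerate(folds):
        train_items = [
            (sid, origin)
            for sid in train_ids
            for origin in prepared[sid].train_origins
        ]
        if not train_items:
            raise RuntimeError(f"fold {fold_idx} has no lesion-containing patches")
        x_train, y_train = _stack_items(prepared, train_items, plan)
        for seed in plan.seeds:
            cell_seed = derive_seed(seed, fold_idx)
            for loss_name in plan.losses:
                loss = make_logit_loss(loss_name)
                model = build_unet(plan.unet_spec(), cell_seed)
                init_checksums[(loss_name, seed, fold_idx)] = hashlib.sha256(
                    model.parameter_vector().tobytes()).hexdigest()
                opt = model.make_optimizer(lr=plan.learning_rate)
                for epoch in range(1, plan.max_epochs + 1):
                    _train_one_epoch(model, opt, loss, x_train, y_train,
                                     plan, derive_seed(seed, fold_idx, epoch))
                    tags = dict(seed=seed, fold=fold_idx, loss=loss_name,
                                epoch=epoch)
                    records.append(_eval_patches(model, x_train, y_train,
                                                 plan, tags))
                    records.extend(_eval_images(model, prepared, train_ids,
                                                plan, "train_image", tags))
                    records.extend(_eval_images(model, prepared, test_ids,
                                                plan, "test_image", tags))
                    if progress is not None:
                        progress(loss=loss_name, seed=seed, fold=fold_idx,
                                 epoch=epoch)
    frame = records_to_frame(records)
    frame.attrs["init_checksums"] = init_checksums
    return frame


def _stack_items(prepared, items, plan) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for sid, origin in items:
        p = prepared[sid]
        xs.append(extract_patches(p.volume, [origin], plan.patch_size)[0])
        ys.append(extract_patches(p.subject.lesion_mask, [origin],
                                  plan.patch_size)[0])
    return (np.asarray(xs, dtype=np.float32),
            np.asarray(ys, dtype=np.uint8))


def _train_one_epoch(model, opt, loss, x_train, y_train, plan,
                     shuffle_seed) -> None:
    batches = make_batches(list(range(len(x_train))), plan.batch_size,
                           seed=shuffle_seed)
    for idx in batches:
        xb = x_train[idx]
        yb = y_train[idx]
        logits = model.forward(xb)[:, 0].astype(np.float64)
        grad = loss.grad(logits, yb)
        opt.zero_grad()
        model.backward(grad[:, None].astype(np.float32))
        opt.step()


def _eval_patches(model, x_train, y_train, plan, tags) -> MetricRecord:
    probs = _forward_in_batches(model, x_train, plan.batch_size)
    counts = confusion(binarize(probs, plan.threshold), y_train)
    return compute_metrics(counts, scope="patch", subject="pooled", **tags)


def _eval_images(model, prepared, subject_ids, plan, scope,
                 tags) -> List[MetricRecord]:
    out = []
    for sid in subject_ids:
        p = prepared[sid]
        probs = _forward_in_batches(model, p.eval_patches, plan.batch_size)
        vol = reconstruct(zip(p.eval_origins, probs),
                          p.subject.lesion_mask.shape)
        counts = confusion(binarize(vol, plan.threshold), p.subject.lesion_mask)
        out.append(compute_metrics(counts, scope=scope, subject=sid, **tags))
    return out


# ---------------------------------------------------------------------------
# band summaries
# ---------------------------------------------------------------------------

def band_summary(records: pd.DataFrame) -> pd.DataFrame:
    """min/mean/max envelope per (loss, epoch, scope, metric) over seeds,
    folds and subjects."""
    if records.empty:
        return pd.DataFrame(
            columns=["loss", "epoch", "scope", "metric", "min", "mean", "max"])
    long = records.melt(
        id_vars=["loss", "epoch", "scope"],
        value_vars=["dsc", "tpf", "precision"],
        var_name="metric", value_name="value",
    )
    grouped = (long.groupby(["loss", "epoch", "scope", "metric"])["value"]
                   .agg(["min", "mean", "max"]).reset_index())
    return grouped
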