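"""Confusion-count evaluation metrics for binary segmentation.

Predictions are binarised at a threshold (default 0.5, ties counted as
foreground), confusion counts are tallied voxelwise, and three metrics are
derived:

* DSC       = 2 TP / (2 TP + FN + FP)   (Dice similarity coefficient)
* TPf       = TP / (TP + FN)            (sensitivity / true positive fraction)
* precision = TP / (TP + FP)

Degenerate denominators follow the "reward correctly empty output"
convention: a metric whose denominator is empty is 1 when the prediction
made no compensating error and 0 otherwise (e.g. TPf on a lesion-free truth
is 1 iff there are no false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, List

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "binarize",
    "confusion",
    "compute_metrics",
    "records_to_frame",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["seed", "fold", "loss", "epoch", "scope",
               "subject", "dsc", "tpf", "precision"]

SCOPES = ("patch", "train_image", "test_image")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts of a binarised prediction against a binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricRecord:
    """One (DSC, TPf, precision) measurement tagged by its experimental cell."""

    dsc: float
    tpf: float
    precision: float
    scope: str
    seed: int = 0
    fold: int = 0
    loss: str = ""
    epoch: int = 0
    subject: str = ""

    def __post_init__(self) -> None:
        for v in (self.dsc, self.tpf, self.precision):
            if not (0.0 <= v <= 1.0):
                raise ValueError("metrics must lie in [0, 1]")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")


def binarize(pred, threshold: float = 0.5) -> np.ndarray:
    """Binarise a probability map; a value exactly at the threshold counts
    as foreground."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def confusion(pred_bin, target) -> ConfusionCounts:
    """Tally TP/FP/FN/TN of two binary masks of identical shape."""
    p = np.asarray(pred_bin)
    t = np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    if not np.isin(p, (0, 1)).all() or not np.isin(t, (0, 1)).all():
        raise ValueError("confusion requires binary masks")
    p = p.astype(bool)
    t = t.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, errors: int) -> float:
    """num/den, with the empty-denominator convention: 1 iff no errors."""
    if den == 0:
        return 1.0 if errors == 0 else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, scope: str = "patch",
                    **tags) -> MetricRecord:
    """Derive DSC, TPf and precision from confusion counts."""
    c = counts
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, c.fp + c.fn)
    tpf = _ratio(c.tp, c.tp + c.fn, c.fp)
    precision = _ratio(c.tp, c.tp + c.fp, c.fn)
    return MetricRecord(dsc=dsc, tpf=tpf, precision=precision, scope=scope, **tags)


def records_to_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Serialise metric records to the canonical CSV schema."""
    rows: List[dict] = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=[*CSV_COLUMNS])
    return frame[CSV_COLUMNS]
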