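"""Per-slice segmentation evaluation against ground truth.

Each slice of a segmentation stack is compared pixel-wise to the ground
truth, yielding confusion counts and the derived metrics sensitivity,
specificity, positive/negative predictive value and Dice coefficient. A
metric whose denominator is zero on a slice is *undefined* there and
excluded from the stack mean/SD rather than imputed; the number of valid
slices is reported per metric.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from capnet.volio import VoxelVolume

__all__ = ["ConfusionCounts", "SegMetrics", "confusion_counts", "metrics_from_counts", "evaluate_stack"]

METRIC_NAMES = ("sen", "spe", "ppv", "npv", "dsc")


@dataclass(frozen=True)
class ConfusionCounts:
    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int

    @property
    def total(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


@dataclass
class SegMetrics:
    """Per-slice metric values (NaN where undefined) plus stack summary."""

    per_slice: dict[str, np.ndarray]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n_valid_slices: dict[str, int] = field(default_factory=dict)

    def summarize(self) -> "SegMetrics":
        for name, vals in self.per_slice.items():
            valid = vals[~np.isnan(vals)]
            self.n_valid_slices[name] = int(valid.size)
            self.mean[name] = float(valid.mean()) if valid.size else math.nan
            self.sd[name] = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        return self

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["slice"] + [m.upper() for m in METRIC_NAMES])
            n = len(next(iter(self.per_slice.values())))
            for i in range(n):
                w.writerow(
                    [i] + [f"{self.per_slice[m][i]:.6f}" for m in METRIC_NAMES]
                )
            w.writerow(["mean"] + [f"{self.mean[m]:.6f}" for m in METRIC_NAMES])
            w.writerow(["sd"] + [f"{self.sd[m]:.6f}" for m in METRIC_NAMES])
            w.writerow(["n_valid"] + [self.n_valid_slices[m] for m in METRIC_NAMES])


def _check_binary_pair(gt: np.ndarray, seg: np.ndarray):
    gt = np.asarray(gt)
    seg = np.asarray(seg)
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    for name, arr in (("gt", gt), ("seg", seg)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} is not binary")
    return gt.astype(bool), seg.astype(bool)


def confusion_counts(gt_slice: np.ndarray, seg_slice: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts; 'positive' is label value 1."""
    gt, seg = _check_binary_pair(gt_slice, seg_slice)
    return ConfusionCounts(
        n_tp=int((gt & seg).sum()),
        n_tn=int((~gt & ~seg).sum()),
        n_fp=int((~gt & seg).sum()),
        n_fn=int((gt & ~seg).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """SEN, SPE, PPV, NPV, DSC from one slice's counts.

    SEN = TP/(TP+FN), SPE = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), DSC = 2 TP/(2 TP + FP + FN). A zero denominator
    yields NaN (undefined), which is a value state, not an error.
    """
    return {
        "sen": _ratio(c.n_tp, c.n_tp + c.n_fn),
        "spe": _ratio(c.n_tn, c.n_tn + c.n_fp),
        "ppv": _ratio(c.n_tp, c.n_tp + c.n_fp),
        "npv": _ratio(c.n_tn, c.n_tn + c.n_fn),
        "dsc": _ratio(2 * c.n_tp, 2 * c.n_tp + c.n_fp + c.n_fn),
    }


def evaluate_stack(gt: VoxelVolume, seg: VoxelVolume) -> SegMetrics:
    """Per-slice metrics over a stack with mean and sample SD per metric,
    averaging only slices where the metric is defined."""
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    nz = gt.shape[0]
    if nz == 0:
        raise ValueError("stack has zero slices")
    per_slice = {m: np.empty(nz) for m in METRIC_NAMES}
    for z in range(nz):
        vals = metrics_from_counts(confusion_counts(gt.data[z], seg.data[z]))
        for m in METRIC_NAMES:
            per_slice[m][z] = vals[m]
    return SegMetrics(per_slice).summarize()
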