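"""Segmentation metrics over the three clinical tumor regions.

From a multi-class label map the BraTS convention derives three nested
binary regions: whole tumor (all tumor classes), tumor core (necrotic +
enhancing) and enhancing tumor. Each region is scored with dice (DSC),
Jaccard (IoU), the 95th-percentile symmetric Hausdorff distance over
boundary pixels (HD95, in mm via the voxel spacing), plus pixelwise
accuracy/precision/recall/F1 from the 2×2 confusion table.

Conventions for degenerate masks: when ground truth and prediction are both
empty the overlap scores are 1 and HD95 is 0 (the case was segmented
perfectly); when exactly one is empty HD95 is undefined and reported as NaN,
which split-level aggregation excludes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

REGIONS = ("WT", "TC", "EnT")
#: internal class codes forming each region; file coding {1,2,4} maps 4->3
REGION_CLASSES = {"WT": (1, 2, 3), "TC": (1, 3), "EnT": (3,)}
METRIC_NAMES = ("dsc", "iou", "hd95", "precision", "recall", "f1", "accuracy")


@dataclass
class RegionMaskSet:
    WT: np.ndarray
    TC: np.ndarray
    EnT: np.ndarray

    def __post_init__(self):
        if not ((self.EnT <= self.TC).all() and (self.TC <= self.WT).all()):
            raise ValueError("region nesting EnT ⊆ TC ⊆ WT violated")

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)


def region_masks(labels: np.ndarray, coding: str = "internal") -> RegionMaskSet:
    """Binary WT/TC/EnT masks from a label map.

    ``coding='internal'`` expects classes {0,1,2,3}; ``coding='file'``
    expects the BraTS file values {0,1,2,4}.
    """
    labels = np.asarray(labels)
    if coding == "file":
        allowed, enh = {0, 1, 2, 4}, 4
    elif coding == "internal":
        allowed, enh = {0, 1, 2, 3}, 3
    else:
        raise ValueError(f"coding must be 'internal' or 'file', got {coding!r}")
    bad = set(np.unique(labels)) - allowed
    if bad:
        raise ValueError(f"unexpected label values {sorted(bad)} for {coding} coding")
    return RegionMaskSet(
        WT=np.isin(labels, [1, 2, enh]),
        TC=np.isin(labels, [1, enh]),
        EnT=labels == enh,
    )


def _check_pair(G, S):
    G = np.asarray(G, dtype=bool)
    S = np.asarray(S, dtype=bool)
    if G.shape != S.shape:
        raise ValueError(f"mask shapes differ: {G.shape} vs {S.shape}")
    return G, S


def dsc(G, S) -> float:
    """2|G∩S| / (|G|+|S|); 1 when both masks are empty."""
    G, S = _check_pair(G, S)
    total = int(G.sum()) + int(S.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((G & S).sum()) / total


def iou(G, S) -> float:
    """|G∩S| / |G∪S| (Jaccard); 1 when both masks are empty."""
    G, S = _check_pair(G, S)
    union = int((G | S).sum())
    if union == 0:
        return 1.0
    return int((G & S).sum()) / union


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of mask pixels with a 4-connected background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, mask.ndim), dtype=np.int64)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure)
    boundary = mask & ~interior
    if not boundary.any():
        boundary = mask  # single-pixel / degenerate masks
    return np.argwhere(boundary)


def hausdorff95(T, P, spacing=(1.0, 1.0), percentile: float = 95.0) -> float:
    """Symmetric percentile Hausdorff distance between mask boundaries (mm).

    The two directed distances are the ``percentile``-th percentiles of the
    nearest-neighbour Euclidean distances from each boundary to the other;
    the reported value is their maximum. Both masks empty → 0; exactly one
    empty → NaN (undefined; excluded from split averages).
    """
    T, P = _check_pair(T, P)
    t_empty, p_empty = not T.any(), not P.any()
    if t_empty and p_empty:
        return 0.0
    if t_empty or p_empty:
        return float("nan")
    spacing = np.asarray(spacing, dtype=float)
    bt = boundary_points(T) * spacing
    bp = boundary_points(P) * spacing
    d_tp = cKDTree(bp).query(bt)[0]
    d_pt = cKDTree(bt).query(bp)[0]
    return float(max(np.percentile(d_tp, percentile), np.percentile(d_pt, percentile)))


@dataclass
class PixelMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # a zero denominator was replaced by 0


def pixel_metrics(G, S) -> PixelMetrics:
    """Accuracy, precision, recall and F1 from the pixel confusion table."""
    G, S = _check_pair(G, S)
    tp = int((G & S).sum())
    fp = int((~G & S).sum())
    fn = int((G & ~S).sum())
    tn = int((~G & ~S).sum())
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    accuracy = (tp + tn) / G.size
    return PixelMetrics(accuracy, precision, recall, f1, degenerate)


def region_report(gt_labels: np.ndarray, pred_labels: np.ndarray,
                  spacing=(1.0, 1.0), coding: str = "internal") -> dict:
    """All seven metrics for each region of one case."""
    gt = region_masks(gt_labels, coding)
    pred = region_masks(pred_labels, coding)
    report = {}
    for region in REGIONS:
        G, S = gt[region], pred[region]
        pm = pixel_metrics(G, S)
        report[region] = {
            "dsc": dsc(G, S),
            "iou": iou(G, S),
            "hd95": hausdorff95(G, S, spacing),
            "precision": pm.precision,
            "recall": pm.recall,
            "f1": pm.f1,
            "accuracy": pm.accuracy,
        }
    return report


def aggregate_reports(reports: list[dict]) -> dict:
    """Mean over cases per region/metric; NaN HD95 cases are excluded there."""
    out = {}
    for region in REGIONS:
        out[region] = {}
        for metric in METRIC_NAMES:
            values = np.array([r[region][metric] for r in reports], dtype=float)
            if metric == "hd95":
                values = values[~np.isnan(values)]
            out[region][metric] = float(values.mean()) if values.size else float("nan")
    return out


def evaluate_split(model, pairs, spacing=(1.0, 1.0)) -> dict:
    """Predict every case of a split and aggregate the per-case metrics.

    ``model`` needs a ``predict_labels(batch)`` method (an identity oracle
    works too); ``pairs`` yields (MultiModalSlice, SegLabelMap).
    """
    from .preprocess import MultiModalSlice, SegLabelMap

    reports = []
    for mm, seg in pairs:
        if seg is None:
            raise ValueError("evaluate_split requires ground-truth labels")
        px = mm.pixels if isinstance(mm, MultiModalSlice) else np.asarray(mm)
        gt = seg.labels if isinstance(seg, SegLabelMap) else np.asarray(seg)
        pred = model.predict_labels(px[None].astype(np.float32))[0]
        reports.append(region_report(gt, pred, spacing))
    summary = aggregate_reports(reports)
    summary["n_cases"] = len(reports)
    return summary


def report_to_csv(summary: dict, path: str):
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region"] + list(METRIC_NAMES))
        for region in REGIONS:
            writer.writerow([region] + [summary[region][m] for m in METRIC_NAMES])
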