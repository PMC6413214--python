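"""Instance-level evaluation: cross-check matching and PR sweeps.

A ground-truth instance and a detection are matched only when each is the
other's minimum-cost partner (mutual nearest neighbour on the summed
shoulder + tail distance).  Unlike an unparameterized Hungarian
assignment, this never forces far-away pairs together just to minimise a
global cost, and it introduces no distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import DetectedInstance, FrameAnnotation, Point2D, euclidean_norm
from .decoder import AssociationMode, DecoderConfig, DetectionSet, decode
from .encoder import TargetMaps


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    precision: float = 1.0
    recall: float = 1.0
    f_measure: float = 1.0

    def __post_init__(self) -> None:
        self.precision, self.recall, self.f_measure = compute_metrics(self.tp, self.fp, self.fn)


@dataclass
class PRCurve:
    thresholds: list[float]
    reports: list[MatchReport]

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.reports):
            raise ValueError("thresholds and reports must align")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


def compute_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F-measure with empty-set conventions.

    When there are no detections, precision is 1 (nothing asserted, nothing
    wrong); likewise recall when there is nothing to find.  F is 0 when
    P + R = 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f


def instance_cost(gt: DetectedInstance, det: DetectedInstance) -> float:
    """Summed shoulder and tail distances; ears are not evaluated."""
    return euclidean_norm(gt.shoulder, det.shoulder) + euclidean_norm(gt.tail, det.tail)


def _cost_matrix(gt_set: Sequence[DetectedInstance],
                 det_set: Sequence[DetectedInstance]) -> np.ndarray:
    mat = np.zeros((len(gt_set), len(det_set)))
    for i, g in enumerate(gt_set):
        for j, d in enumerate(det_set):
            mat[i, j] = instance_cost(g, d)
    return mat


def cross_check_pairs(cost: np.ndarray) -> list[tuple[int, int]]:
    """Mutual-argmin pairs of a cost matrix; ties break to the lowest index.

    (i, j) is kept iff j minimizes row i AND i minimizes column j.  A tie
    that would make mutuality ambiguous resolves to the lowest index and
    therefore to no-match for the higher-indexed competitor.
    """
    if cost.size == 0:
        return []
    best_det = np.argmin(cost, axis=1)   # per ground truth
    best_gt = np.argmin(cost, axis=0)    # per detection
    return [(i, int(best_det[i])) for i in range(cost.shape[0])
            if best_gt[best_det[i]] == i]


def cross_check_match(gt_set: Sequence[DetectedInstance],
                      det_set: Sequence[DetectedInstance]) -> MatchReport:
    """Cross-check matching of detections against ground truth."""
    n, m = len(gt_set), len(det_set)
    if n == 0 or m == 0:
        return MatchReport(tp=0, fp=m, fn=n)
    pairs = cross_check_pairs(_cost_matrix(gt_set, det_set))
    tp = len(pairs)
    return MatchReport(tp=tp, fp=m - tp, fn=n - tp, matched_pairs=pairs)


def annotation_to_instances(frame: FrameAnnotation) -> list[DetectedInstance]:
    """Ground-truth shoulder-tail pairs as matchable instances."""
    return [
        DetectedInstance(shoulder=p.shoulder, tail=p.tail,
                         left_ear=p.left_ear, right_ear=p.right_ear)
        for p in frame.pigs
    ]


DEFAULT_THRESHOLDS = [round(0.10 + 0.05 * i, 2) for i in range(17)]  # 0.10 .. 0.90


def pr_sweep(frames: Iterable[tuple[FrameAnnotation, TargetMaps | np.ndarray]],
             thresholds: Sequence[float] | None = None,
             mode: AssociationMode = AssociationMode.VECTOR,
             config: DecoderConfig | None = None) -> PRCurve:
    """Decode every frame at each threshold and micro-average the counts.

    TP/FP/FN are summed over the whole frame set before computing the
    metrics, matching corpus-level evaluation practice.
    """
    thresholds = list(thresholds) if thresholds is not None else list(DEFAULT_THRESHOLDS)
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    base = config or DecoderConfig()
    frames = list(frames)
    gt_sets = [annotation_to_instances(f) for f, _ in frames]
    reports = []
    for thr in thresholds:
        cfg = DecoderConfig(detection_threshold=thr, peak_window=base.peak_window,
                            smooth_kernel=base.smooth_kernel, association_mode=mode)
        tp = fp = fn = 0
        for (frame, maps), gt in zip(frames, gt_sets):
            dets = decode(maps, cfg)
            rep = cross_check_match(gt, dets.instances)
            tp, fp, fn = tp + rep.tp, fp + rep.fp, fn + rep.fn
        reports.append(MatchReport(tp=tp, fp=fp, fn=fn))
    return PRCurve(thresholds=thresholds, reports=reports)


def pr_curve_frame(curve: PRCurve):
    """PR curve as a pandas DataFrame (threshold, counts, metrics)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "tp": [r.tp for r in curve.reports],
            "fp": [r.fp for r in curve.reports],
            "fn": [r.fn for r in curve.reports],
            "recall": [r.recall for r in curve.reports],
            "precision": [r.precision for r in curve.reports],
            "f_measure": [r.f_measure for r in curve.reports],
        }
    )
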