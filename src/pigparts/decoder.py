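"""Decode a 16-channel map (ground truth or network output) to instances.

Pipeline: 5x5 box smoothing -> regional-maximum part detection with a
fixed threshold -> quadratic sub-pixel refinement -> association-vector
sampling -> three pairwise distance matrices -> Hungarian assignment ->
shoulder-tail instances with ears attached.

A Euclidean baseline (``AssociationMode.EUCLIDEAN``) replaces the
association distance with plain point-to-point distance; it serves as the
ablation comparison and fails on abutting animals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .core import DetectedInstance, PartType, Point2D
from .encoder import N_ASSOC_CHANNELS, N_PART_CHANNELS, TargetMaps


class AssociationMode(Enum):
    VECTOR = "vector"
    EUCLIDEAN = "euclidean"


@dataclass
class DecoderConfig:
    """Decoding knobs; the defaults are the published operating point."""

    detection_threshold: float = 0.25
    peak_window: int = 15
    smooth_kernel: int = 5
    association_mode: AssociationMode = AssociationMode.VECTOR

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must lie in (0, 1)")
        if self.peak_window % 2 == 0 or self.smooth_kernel % 2 == 0:
            raise ValueError("window sizes must be odd")


@dataclass
class PartDetections:
    """Sub-pixel detections of one part type with their peak values."""

    points: list[Point2D] = field(default_factory=list)
    peaks: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DetectionSet:
    """Decoded instances of one frame."""

    instances: list[DetectedInstance] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instances)


# ---------------------------------------------------------------------------
# map-level operations


def smooth_maps(stacked: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Box-filter every channel (replicate border padding)."""
    if stacked.ndim != 3:
        raise ValueError("expected [channels, R, C]")
    return ndimage.uniform_filter(
        stacked.astype(float), size=(1, kernel, kernel), mode="nearest"
    )


def detect_peaks(part_map: np.ndarray, config: DecoderConfig) -> list[tuple[int, int]]:
    """Integer (x, y) regional maxima above the detection threshold.

    A pixel fires when it is >= every value in its centered
    ``peak_window`` square (clipped at borders).  Ties on a connected
    plateau are collapsed to the lexicographically smallest (y, x) pixel
    so each physical peak yields one detection.
    """
    w = config.peak_window
    local_max = ndimage.maximum_filter(part_map, size=w, mode="nearest")
    candidates = (part_map >= local_max) & (part_map >= config.detection_threshold)
    if not candidates.any():
        return []
    labels, n = ndimage.label(candidates)
    out: list[tuple[int, int]] = []
    for idx in range(1, n + 1):
        ys, xs = np.nonzero(labels == idx)
        k = np.lexsort((xs, ys))[0]
        out.append((int(xs[k]), int(ys[k])))
    out.sort(key=lambda p: (p[1], p[0]))
    return out


def subpixel_refine(part_map: np.ndarray, peak: tuple[int, int]) -> Point2D:
    """Quadratic (three-point parabola) sub-pixel refinement of a peak.

    Each axis is refined independently by fitting a parabola through the
    samples at offsets {-1, 0, +1}; the vertex offset is
    ``(v- - v+) / (2 (v- - 2 v0 + v+))``.  Border peaks, non-negative
    curvature, or vertex overshoot (|delta| > 0.5) leave the axis
    unrefined: off a genuine local maximum the vertex is meaningless.
    """
    x, y = peak
    rows, cols = part_map.shape

    def refine(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2.0 * v0 + vp
        if denom >= 0.0:
            return 0.0
        delta = (vm - vp) / (2.0 * denom)
        return delta if abs(delta) <= 0.5 else 0.0

    fx, fy = float(x), float(y)
    if 1 <= x < cols - 1:
        fx += refine(part_map[y, x - 1], part_map[y, x], part_map[y, x + 1])
    if 1 <= y < rows - 1:
        fy += refine(part_map[y - 1, x], part_map[y, x], part_map[y + 1, x])
    return Point2D(fx, fy)


def detect_parts(stacked_smoothed: np.ndarray, config: DecoderConfig) -> dict[PartType, PartDetections]:
    """Run peak detection + refinement on the four part channels."""
    out: dict[PartType, PartDetections] = {}
    for part in PartType:
        chan = stacked_smoothed[part]
        dets = PartDetections()
        for px, py in detect_peaks(chan, config):
            dets.points.append(subpixel_refine(chan, (px, py)))
            dets.peaks.append(float(chan[py, px]))
        out[part] = dets
    return out


def _bilinear(chan: np.ndarray, x: float, y: float) -> float:
    """Bilinear sample with edge clamping."""
    rows, cols = chan.shape
    x = min(max(x, 0.0), cols - 1.0)
    y = min(max(y, 0.0), rows - 1.0)
    x0, y0 = int(math.floor(x)), int(math.floor(y))
    x1, y1 = min(x0 + 1, cols - 1), min(y0 + 1, rows - 1)
    fx, fy = x - x0, y - y0
    top = chan[y0, x0] * (1 - fx) + chan[y0, x1] * fx
    bot = chan[y1, x0] * (1 - fx) + chan[y1, x1] * fx
    return float(top * (1 - fy) + bot * fy)


def sample_association(assoc_maps: np.ndarray, source: Point2D,
                       channel_pair: tuple[int, int]) -> Point2D:
    """Estimated partner location: source minus the sampled (x, y) offset."""
    cx, cy = channel_pair
    dx = _bilinear(assoc_maps[cx], source.x, source.y)
    dy = _bilinear(assoc_maps[cy], source.x, source.y)
    return Point2D(source.x - dx, source.y - dy)


def association_distance(p: Point2D, p_to_q: Point2D, q: Point2D, q_to_p: Point2D) -> float:
    """Symmetric association distance: mean of forward and backward errors."""
    from .core import euclidean_norm

    return 0.5 * (euclidean_norm(p_to_q, q) + euclidean_norm(q_to_p, p))


#: assoc channel pairs (within the 12-channel block) for each distance
#: matrix: (forward pair sampled at p, backward pair sampled at q).
_MATRIX_CHANNELS = {
    (PartType.LEFT_EAR, PartType.SHOULDER): ((0, 1), (2, 3)),
    (PartType.RIGHT_EAR, PartType.SHOULDER): ((4, 5), (6, 7)),
    (PartType.SHOULDER, PartType.TAIL): ((8, 9), (10, 11)),
}


def build_distance_matrix(parts_p: PartDetections, parts_q: PartDetections,
                          assoc_maps: Optional[np.ndarray],
                          pair: tuple[PartType, PartType],
                          mode: AssociationMode = AssociationMode.VECTOR) -> np.ndarray:
    """Pairwise distances between detections of two part types.

    VECTOR mode evaluates the association distance via the sampled offset
    fields; EUCLIDEAN mode uses the plain point distance.
    """
    from .core import euclidean_norm

    np_, nq = len(parts_p), len(parts_q)
    mat = np.zeros((np_, nq))
    if np_ == 0 or nq == 0:
        return mat
    if mode is AssociationMode.EUCLIDEAN:
        for i, p in enumerate(parts_p.points):
            for j, q in enumerate(parts_q.points):
                mat[i, j] = euclidean_norm(p, q)
        return mat
    if assoc_maps is None:
        raise ValueError("VECTOR mode requires association maps")
    fwd_ch, bwd_ch = _MATRIX_CHANNELS[pair]
    fwd = [sample_association(assoc_maps, p, fwd_ch) for p in parts_p.points]
    bwd = [sample_association(assoc_maps, q, bwd_ch) for q in parts_q.points]
    for i, p in enumerate(parts_p.points):
        for j, q in enumerate(parts_q.points):
            mat[i, j] = association_distance(p, fwd[i], q, bwd[j])
    return mat


def hungarian_assign(dist: np.ndarray) -> list[tuple[int, int]]:
    """Minimum-cost bipartite assignment (rectangular matrices allowed).

    Returns min(Np, Nq) row/col pairs; no distance gating is applied.
    """
    if dist.size == 0:
        return []
    rows, cols = linear_sum_assignment(dist)
    return list(zip(rows.tolist(), cols.tolist()))


def brute_force_assign(dist: np.ndarray) -> float:
    """Exhaustive-permutation optimum total cost (test oracle, small n)."""
    n, m = dist.shape
    if n == 0 or m == 0:
        return 0.0
    if n <= m:
        return min(
            sum(dist[i, c] for i, c in enumerate(cs))
            for cs in itertools.permutations(range(m), n)
        )
    return brute_force_assign(dist.T)


def form_instances(part_detections: dict[PartType, PartDetections],
                   st_pairs: list[tuple[int, int]],
                   ls_pairs: list[tuple[int, int]],
                   rs_pairs: list[tuple[int, int]]) -> DetectionSet:
    """Assemble instances: matched shoulder-tail pairs, then attach ears.

    Ears assigned to a shoulder that did not form an instance are dropped,
    as are unmatched lone parts.  Instance confidence is the minimum peak
    value among its constituent parts.
    """
    shoulders = part_detections[PartType.SHOULDER]
    tails = part_detections[PartType.TAIL]
    lears = part_detections[PartType.LEFT_EAR]
    rears = part_detections[PartType.RIGHT_EAR]

    by_shoulder: dict[int, DetectedInstance] = {}
    conf: dict[int, list[float]] = {}
    instances: list[DetectedInstance] = []
    for si, ti in st_pairs:
        inst = DetectedInstance(shoulder=shoulders.points[si], tail=tails.points[ti])
        by_shoulder[si] = inst
        conf[si] = [shoulders.peaks[si], tails.peaks[ti]]
        instances.append(inst)
    for li, si in ls_pairs:
        if si in by_shoulder:
            by_shoulder[si].left_ear = lears.points[li]
            conf[si].append(lears.peaks[li])
    for ri, si in rs_pairs:
        if si in by_shoulder:
            by_shoulder[si].right_ear = rears.points[ri]
            conf[si].append(rears.peaks[ri])
    for si, inst in by_shoulder.items():
        inst.confidence = min(conf[si])
    return DetectionSet(instances=instances)


def decode(maps: TargetMaps | np.ndarray, config: DecoderConfig | None = None) -> DetectionSet:
    """Full decode of a 16-channel representation into instances."""
    config = config or DecoderConfig()
    stacked = maps.stacked() if isinstance(maps, TargetMaps) else np.asarray(maps, dtype=float)
    if stacked.shape[0] != N_PART_CHANNELS + N_ASSOC_CHANNELS:
        raise ValueError("expected a 16-channel map")
    smoothed = smooth_maps(stacked, config.smooth_kernel)
    parts = detect_parts(smoothed[:N_PART_CHANNELS], config)
    assoc = smoothed[N_PART_CHANNELS:]
    assignments = {}
    for pair in _MATRIX_CHANNELS:
        p, q = pair
        mat = build_distance_matrix(parts[p], parts[q], assoc, pair, config.association_mode)
        assignments[pair] = hungarian_assign(mat)
    return form_instances(
        parts,
        st_pairs=assignments[(PartType.SHOULDER, PartType.TAIL)],
        ls_pairs=assignments[(PartType.LEFT_EAR, PartType.SHOULDER)],
        rs_pairs=assignments[(PartType.RIGHT_EAR, PartType.SHOULDER)],
    )
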