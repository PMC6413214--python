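"""Encode frame annotations into the 16-channel image-space target.

Channels 0-3 hold unit-peak isotropic Gaussian part heatmaps (left ear,
right ear, shoulder, tail).  Channels 4-15 hold six directed association
vector fields: within a disc around each *source* part the constant pixel
offset ``source - partner`` is stored in an (x, y) channel pair.  An
explicit binary mask records where association values are assigned, so a
legitimate zero offset component is never confused with "unassigned".

Directed pair order (assoc channel pairs, 0-based within the 12-channel
block)::

    0,1   left ear  -> shoulder     (disc at left ear)
    2,3   shoulder  -> left ear     (disc at shoulder)
    4,5   right ear -> shoulder     (disc at right ear)
    6,7   shoulder  -> right ear    (disc at shoulder)
    8,9   shoulder  -> tail         (disc at shoulder)
    10,11 tail      -> shoulder     (disc at tail)

Sampling the pair ``p -> q`` at a detected ``p`` and subtracting the value
from ``p`` yields the estimated partner location ``q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import FrameAnnotation, PartType, body_length

#: Gaussian kernel std-dev scale: sigma_n = SIGMA_SCALE * (mu_s->t + delta_s->t)
SIGMA_SCALE = 0.16

#: Association discs cover pixels whose part kernel magnitude exceeds 0.2,
#: i.e. radius = sigma * sqrt(-2 ln 0.2).
REGION_MAGNITUDE = 0.2
REGION_FACTOR = math.sqrt(-2.0 * math.log(REGION_MAGNITUDE))

#: Kernels are truncated at this many sigmas when rendered (< 3.4e-4,
#: below every decoder threshold).
TRUNCATE_SIGMAS = 4.0

#: Directed association pairs: (source part, target part).  The i-th pair
#: occupies assoc channels (2i, 2i+1) = file channels (5+2i, 6+2i).
ASSOC_PAIRS: tuple[tuple[PartType, PartType], ...] = (
    (PartType.LEFT_EAR, PartType.SHOULDER),
    (PartType.SHOULDER, PartType.LEFT_EAR),
    (PartType.RIGHT_EAR, PartType.SHOULDER),
    (PartType.SHOULDER, PartType.RIGHT_EAR),
    (PartType.SHOULDER, PartType.TAIL),
    (PartType.TAIL, PartType.SHOULDER),
)

N_PART_CHANNELS = 4
N_ASSOC_CHANNELS = 12
N_CHANNELS = N_PART_CHANNELS + N_ASSOC_CHANNELS


class DegenerateFrameError(ValueError):
    """Raised when an annotation cannot define Gaussian kernel sizes."""


@dataclass
class KernelParams:
    """Per-instance kernel geometry."""

    sigma: float
    region_radius: float

    @classmethod
    def from_sigma(cls, sigma: float) -> "KernelParams":
        if sigma <= 0:
            raise DegenerateFrameError(f"sigma must be positive, got {sigma}")
        return cls(sigma=sigma, region_radius=sigma * REGION_FACTOR)


@dataclass
class TargetMaps:
    """The 16-channel target: part heatmaps, association fields, mask."""

    part_maps: np.ndarray    # [4, R, C], float, in [0, 1]
    assoc_maps: np.ndarray   # [12, R, C], float, pixel offsets
    assoc_mask: np.ndarray   # [12, R, C], uint8 in {0, 1}

    @property
    def image_size(self) -> tuple[int, int]:
        return self.part_maps.shape[1], self.part_maps.shape[2]

    def stacked(self) -> np.ndarray:
        """All 16 channels as one array (parts first)."""
        return np.concatenate([self.part_maps, self.assoc_maps], axis=0)

    @classmethod
    def zeros(cls, rows: int, cols: int) -> "TargetMaps":
        return cls(
            part_maps=np.zeros((N_PART_CHANNELS, rows, cols)),
            assoc_maps=np.zeros((N_ASSOC_CHANNELS, rows, cols)),
            assoc_mask=np.zeros((N_ASSOC_CHANNELS, rows, cols), dtype=np.uint8),
        )

    @classmethod
    def from_stacked(cls, stacked: np.ndarray, assoc_mask: np.ndarray | None = None) -> "TargetMaps":
        if stacked.shape[0] != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {stacked.shape[0]}")
        if assoc_mask is None:
            assoc_mask = np.ones((N_ASSOC_CHANNELS,) + stacked.shape[1:], dtype=np.uint8)
        return cls(
            part_maps=stacked[:N_PART_CHANNELS],
            assoc_maps=stacked[N_PART_CHANNELS:],
            assoc_mask=assoc_mask,
        )


def compute_sigma(frame: FrameAnnotation) -> list[float]:
    """Per-instance Gaussian std-devs: sigma_n = 0.16 (mu + delta_n).

    ``mu`` is the mean shoulder-to-tail length over the frame, ``delta_n``
    the instance's own length; mixing the two keeps kernels from collapsing
    on unusually short (foreshortened) bodies while still adapting to size.
    """
    if not frame.pigs:
        raise DegenerateFrameError("cannot compute sigma for an empty frame")
    lengths = [body_length(p) for p in frame.pigs]
    if all(l == 0.0 for l in lengths):
        raise DegenerateFrameError("all instances have zero shoulder-tail length")
    mu = float(np.mean(lengths))
    return [SIGMA_SCALE * (mu + l) for l in lengths]


def _kernel_window(x0: float, y0: float, sigma: float, radius: float,
                   rows: int, cols: int):
    """Grid slices and squared distance for a truncated kernel window."""
    r = int(math.ceil(radius))
    ya, yb = max(0, int(math.floor(y0)) - r), min(rows, int(math.ceil(y0)) + r + 1)
    xa, xb = max(0, int(math.floor(x0)) - r), min(cols, int(math.ceil(x0)) + r + 1)
    if ya >= yb or xa >= xb:
        return None
    yy = np.arange(ya, yb, dtype=float)[:, None]
    xx = np.arange(xa, xb, dtype=float)[None, :]
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    return (slice(ya, yb), slice(xa, xb)), d2


def render_part_maps(frame: FrameAnnotation, sigmas: list[float]) -> np.ndarray:
    """Render the 4 part channels; overlapping kernels combine by maximum.

    Each annotated part contributes an isotropic Gaussian with its
    instance's sigma, scaled to peak value 1.0 at the (sub-pixel) part
    location so a single fixed threshold works for all animal sizes.
    """
    frame.validate()
    rows, cols = frame.image_size
    maps = np.zeros((N_PART_CHANNELS, rows, cols))
    for pig, sigma in zip(frame.pigs, sigmas):
        for part in PartType:
            pt = pig.part(part)
            if pt is None:
                continue
            win = _kernel_window(pt.x, pt.y, sigma, TRUNCATE_SIGMAS * sigma, rows, cols)
            if win is None:
                continue
            (sy, sx), d2 = win
            kernel = np.exp(-d2 / (2.0 * sigma * sigma))
            np.maximum(maps[part, sy, sx], kernel, out=maps[part, sy, sx])
    return maps


def render_assoc_maps(frame: FrameAnnotation, sigmas: list[float]):
    """Render the 12 association channels and their assignment mask.

    For each directed pair the constant offset ``source - target`` fills
    the disc where the source part's Gaussian magnitude exceeds 0.2.
    Where discs of different instances intersect on the same channel, the
    stored vector is the kernel-magnitude-weighted mean of the
    contributions (weights normalised to sum to one per pixel).
    """
    rows, cols = frame.image_size
    # Accumulate weights and weighted offsets, then normalise.
    wsum = np.zeros((len(ASSOC_PAIRS), rows, cols))
    vx = np.zeros((len(ASSOC_PAIRS), rows, cols))
    vy = np.zeros((len(ASSOC_PAIRS), rows, cols))
    for pig, sigma in zip(frame.pigs, sigmas):
        params = KernelParams.from_sigma(sigma)
        for gi, (src, dst) in enumerate(ASSOC_PAIRS):
            ps, pd = pig.part(src), pig.part(dst)
            if ps is None or pd is None:
                continue
            win = _kernel_window(ps.x, ps.y, sigma, params.region_radius, rows, cols)
            if win is None:
                continue
            (sy, sx), d2 = win
            weight = np.exp(-d2 / (2.0 * sigma * sigma))
            inside = weight > REGION_MAGNITUDE
            w = np.where(inside, weight, 0.0)
            wsum[gi, sy, sx] += w
            vx[gi, sy, sx] += w * (ps.x - pd.x)
            vy[gi, sy, sx] += w * (ps.y - pd.y)
    assoc = np.zeros((N_ASSOC_CHANNELS, rows, cols))
    mask = np.zeros((N_ASSOC_CHANNELS, rows, cols), dtype=np.uint8)
    assigned = wsum > 0.0
    safe = np.where(assigned, wsum, 1.0)
    for gi in range(len(ASSOC_PAIRS)):
        assoc[2 * gi] = np.where(assigned[gi], vx[gi] / safe[gi], 0.0)
        assoc[2 * gi + 1] = np.where(assigned[gi], vy[gi] / safe[gi], 0.0)
        mask[2 * gi] = assigned[gi]
        mask[2 * gi + 1] = assigned[gi]
    return assoc, mask


def encode_frame(frame: FrameAnnotation) -> TargetMaps:
    """Full 16-channel encoding of a frame annotation.

    An empty frame encodes to all-zero maps.  Frames containing an
    instance with coincident shoulder and tail are rejected: such an
    annotation defines neither an orientation nor a kernel size.
    """
    rows, cols = frame.image_size
    if not frame.pigs:
        return TargetMaps.zeros(rows, cols)
    for pig in frame.pigs:
        if pig.is_degenerate:
            raise DegenerateFrameError(
                f"instance {pig.instance_id} has zero shoulder-tail length"
            )
    sigmas = compute_sigma(frame)
    part_maps = render_part_maps(frame, sigmas)
    assoc_maps, assoc_mask = render_assoc_maps(frame, sigmas)
    return TargetMaps(part_maps=part_maps, assoc_maps=assoc_maps, assoc_mask=assoc_mask)
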