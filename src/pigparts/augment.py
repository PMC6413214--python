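"""Joint spatial augmentation of images, annotations and target maps.

Augmentations: left-right flip, rotation uniform in [0, 360), isotropic
scaling uniform in [0.5, 1.5], and XY shifts uniform in +-20 px.  The
default training path transforms the *annotations* and re-encodes (sharp
kernels, no interpolation blur); warping rendered maps is also provided
and the two must commute within interpolation tolerance
(``consistency_check``).

Rotation convention: positive theta rotates the +x axis toward the +y
axis, i.e. R = [[cos, -sin], [sin, cos]] in (x right, y down) image
coordinates (clockwise on screen).  A stored offset (30, 0) rotated by
90 degrees becomes (0, 30).

Channel bookkeeping under a horizontal flip: the left/right ear labels
swap, so part channels 0<->1 swap, association pair groups
(l<->s) <-> (r<->s) swap, and every x offset component is negated (part
of the linear map applied to offset values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .core import FrameAnnotation, PigAnnotation, Point2D
from .encoder import N_ASSOC_CHANNELS, TargetMaps, encode_frame


@dataclass
class AugmentSpec:
    flip_prob: float = 0.5
    rotation_range_deg: tuple[float, float] = (0.0, 360.0)
    scale_range: tuple[float, float] = (0.5, 1.5)
    shift_range_px: float = 20.0
    seed: int = 0


@dataclass(frozen=True)
class AugmentDraw:
    """One concrete sample from an AugmentSpec."""

    flip: bool = False
    theta_deg: float = 0.0
    scale: float = 1.0
    shift: tuple[float, float] = (0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return (not self.flip and self.theta_deg == 0.0 and self.scale == 1.0
                and self.shift == (0.0, 0.0))


def sample_draw(spec: AugmentSpec, rng: np.random.Generator) -> AugmentDraw:
    return AugmentDraw(
        flip=bool(rng.uniform() < spec.flip_prob),
        theta_deg=float(rng.uniform(*spec.rotation_range_deg)),
        scale=float(rng.uniform(*spec.scale_range)),
        shift=(float(rng.uniform(-spec.shift_range_px, spec.shift_range_px)),
               float(rng.uniform(-spec.shift_range_px, spec.shift_range_px))),
    )


def _homogeneous(draw: AugmentDraw, image_size: tuple[int, int]) -> np.ndarray:
    """Forward 3x3 transform in (x, y) coordinates.

    Flip about the vertical image axis first, then rotate+scale about the
    image center, then shift.  Pixel centers sit at integer coordinates,
    so the center is ((C-1)/2, (R-1)/2).
    """
    rows, cols = image_size
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    t = math.radians(draw.theta_deg)
    lin = draw.scale * np.array([[math.cos(t), -math.sin(t)],
                                 [math.sin(t), math.cos(t)]])
    r = np.eye(3)
    r[:2, :2] = lin
    r[:2, 2] = -lin @ center + center + np.array(draw.shift)
    if draw.flip:
        f = np.array([[-1.0, 0.0, cols - 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        return r @ f
    return r


def linear_part(draw: AugmentDraw) -> np.ndarray:
    """The 2x2 map applied to offset *values* (flip included)."""
    t = math.radians(draw.theta_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    lin = draw.scale * rot
    if draw.flip:
        lin = lin @ np.diag([-1.0, 1.0])
    return lin


def transform_point(pt: Point2D, m: np.ndarray) -> Point2D:
    v = m @ np.array([pt.x, pt.y, 1.0])
    return Point2D(float(v[0]), float(v[1]))


def augment_annotations(frame: FrameAnnotation, draw: AugmentDraw) -> FrameAnnotation:
    """Transform keypoints; drop what leaves the frame; relabel ears on flip."""
    rows, cols = frame.image_size
    m = _homogeneous(draw, frame.image_size)

    def keep(pt: Optional[Point2D]) -> Optional[Point2D]:
        if pt is None:
            return None
        out = transform_point(pt, m)
        return out if (0 <= out.x < cols and 0 <= out.y < rows) else None

    pigs = []
    for pig in frame.pigs:
        shoulder, tail = keep(pig.shoulder), keep(pig.tail)
        if shoulder is None or tail is None:
            continue  # instance leaves the frame
        left, right = keep(pig.left_ear), keep(pig.right_ear)
        if draw.flip:
            left, right = right, left
        pigs.append(PigAnnotation(shoulder=shoulder, tail=tail, left_ear=left,
                                  right_ear=right, instance_id=pig.instance_id))
    polygon = None
    if frame.mask_polygon is not None:
        polygon = [transform_point(p, m) for p in frame.mask_polygon]
    return FrameAnnotation(image_size=frame.image_size, pigs=pigs, mask_polygon=polygon)


def _warp_channels(channels: np.ndarray, m: np.ndarray, order: int) -> np.ndarray:
    """Spatially warp [C, R, C] channels by the forward (x, y) transform."""
    inv = np.linalg.inv(m)
    # scipy works in (row, col) index order: swap axes of the inverse map
    mat = np.array([[inv[1, 1], inv[1, 0]], [inv[0, 1], inv[0, 0]]])
    off = np.array([inv[1, 2], inv[0, 2]])
    out = np.empty_like(channels)
    for i in range(channels.shape[0]):
        out[i] = ndimage.affine_transform(channels[i], mat, offset=off,
                                          order=order, mode="constant", cval=0.0)
    return out


def augment_image(image: np.ndarray, draw: AugmentDraw) -> np.ndarray:
    """Warp an [R, C, 3] image (bilinear, zero fill outside)."""
    m = _homogeneous(draw, image.shape[:2])
    return _warp_channels(np.moveaxis(image, -1, 0), m, order=1).transpose(1, 2, 0)


_FLIP_PART_ORDER = [1, 0, 2, 3]
# assoc pair groups under flip: (l->s, s->l) <-> (r->s, s->r); s<->t fixed
_FLIP_ASSOC_ORDER = [4, 5, 6, 7, 0, 1, 2, 3, 8, 9, 10, 11]


def augment_maps(maps: TargetMaps, draw: AugmentDraw) -> TargetMaps:
    """Warp a rendered 16-channel target consistently with the draw."""
    rows, cols = maps.image_size
    m = _homogeneous(draw, (rows, cols))
    parts = _warp_channels(maps.part_maps, m, order=1)
    assoc = _warp_channels(maps.assoc_maps, m, order=0)
    mask = _warp_channels(maps.assoc_mask.astype(float), m, order=0)
    mask = (mask > 0.5).astype(np.uint8)
    lin = linear_part(draw)
    for gi in range(N_ASSOC_CHANNELS // 2):
        vx, vy = assoc[2 * gi].copy(), assoc[2 * gi + 1].copy()
        assoc[2 * gi] = lin[0, 0] * vx + lin[0, 1] * vy
        assoc[2 * gi + 1] = lin[1, 0] * vx + lin[1, 1] * vy
    if draw.flip:
        parts = parts[_FLIP_PART_ORDER]
        assoc = assoc[_FLIP_ASSOC_ORDER]
        mask = mask[_FLIP_ASSOC_ORDER]
    assoc = assoc * mask  # keep the zero-outside-mask invariant after warping
    return TargetMaps(part_maps=parts, assoc_maps=assoc, assoc_mask=mask)


def augment_pair(image: np.ndarray,
                 target: Union[TargetMaps, FrameAnnotation],
                 spec: AugmentSpec,
                 draw: Optional[AugmentDraw] = None,
                 rng: Optional[np.random.Generator] = None):
    """Jointly transform an image and its target (maps or annotations)."""
    if draw is None:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        draw = sample_draw(spec, rng)
    if draw.is_identity:
        return image, target
    image_out = augment_image(image, draw)
    if isinstance(target, TargetMaps):
        return image_out, augment_maps(target, draw)
    return image_out, augment_annotations(target, draw)


def consistency_check(frame: FrameAnnotation, draw: AugmentDraw,
                      tolerance: float = 0.5) -> bool:
    """Does augmenting maps commute with augmenting annotations?

    Both paths are decoded with the standard decoder and compared
    instance by instance: all part coordinates must agree within
    ``tolerance`` pixels, and the sampled shoulder->tail offsets at the
    decoded shoulders must agree within the same tolerance.
    """
    from .decoder import DecoderConfig, decode, _bilinear
    from .core import PartType

    warped = augment_maps(encode_frame(frame), draw)
    reencoded = encode_frame(augment_annotations(frame, draw))

    cfg = DecoderConfig(detection_threshold=0.25)
    da, db = decode(warped, cfg), decode(reencoded, cfg)
    if len(da) != len(db):
        return False
    used = set()
    for inst_b in db.instances:
        best, best_d = None, math.inf
        for i, inst_a in enumerate(da.instances):
            if i in used:
                continue
            d = math.hypot(inst_a.shoulder.x - inst_b.shoulder.x,
                           inst_a.shoulder.y - inst_b.shoulder.y)
            if d < best_d:
                best, best_d = i, d
        if best is None:
            return False
        used.add(best)
        inst_a = da.instances[best]
        for attr in ("shoulder", "tail", "left_ear", "right_ear"):
            pa, pb = getattr(inst_a, attr), getattr(inst_b, attr)
            if (pa is None) != (pb is None):
                return False
            if pa is not None and math.hypot(pa.x - pb.x, pa.y - pb.y) > tolerance:
                return False
        # shoulder->tail offsets sampled on both maps at the decoded shoulder
        for chan in (8, 9):
            va = _bilinear(warped.assoc_maps[chan], inst_b.shoulder.x, inst_b.shoulder.y)
            vb = _bilinear(reencoded.assoc_maps[chan], inst_b.shoulder.x, inst_b.shoulder.y)
            if abs(va - vb) > tolerance:
                return False
    return True
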