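"""Synthetic top-down pen scenes for testing and desk-scale training.

The generator emulates the geometry of downward-camera group-housing
footage: elongated, bilaterally symmetric bodies (ellipse plus a head
disc and two ear nubs) on a textured floor, optionally clipped by a pen
mask polygon, with a configurable fraction of abutting side-by-side
pairs.  Appearance is deliberately simple - correctness of encoding,
decoding and matching depends on geometry, not texture.

Keypoint conventions (fixture conventions, not claims about pigs): with
heading unit vector ``u`` (tail to head) and body length ``L``, the tail
sits at the rear major-axis end, the shoulder 70% of the way along the
major axis, and the ears flank the head point (95% along) at a
perpendicular offset of 0.25 L.  The animal's left ear lies in direction
``(u_y, -u_x)`` as seen in image coordinates (x right, y down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import FrameAnnotation, PigAnnotation, Point2D, body_length
from .encoder import SIGMA_SCALE, compute_sigma

#: body half-width as a fraction of body length (full width 0.42 L)
WIDTH_FRACTION = 0.42
SHOULDER_FRACTION = 0.70
HEAD_FRACTION = 0.95
EAR_LATERAL_FRACTION = 0.25
EAR_RADIUS_FRACTION = 0.06


class PackingError(RuntimeError):
    """Raised when a scene cannot be packed after bounded retries."""


@dataclass
class SceneConfig:
    """Study conditions for random scenes (480-column scale defaults)."""

    image_size: tuple[int, int] = (352, 480)
    n_pigs_range: tuple[int, int] = (2, 8)
    body_length_range: tuple[float, float] = (30.0, 140.0)
    abutting_fraction: float = 0.3
    background_level: float = 0.15
    noise_sigma: float = 0.02
    use_mask: bool = False
    ear_visibility: float = 0.9
    seed: int = 0
    max_attempts: int = 200


def train_scene_config(seed: int = 0) -> SceneConfig:
    """Reduced-resolution conditions for the desk-scale training suite."""
    return SceneConfig(
        image_size=(160, 224),
        n_pigs_range=(2, 4),
        body_length_range=(32.0, 60.0),
        abutting_fraction=0.25,
        noise_sigma=0.03,
        seed=seed,
    )


def generate_dataset(n_scenes: int, config: SceneConfig,
                     seed: int = 0) -> list[tuple[np.ndarray, FrameAnnotation]]:
    """Draw a deterministic batch of scenes, retrying unlucky packings.

    A scene whose rejection sampling fails is redrawn from the shared
    stream (bounded); the result is still a pure function of the seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_scenes):
        for attempt in range(20):
            try:
                out.append(generate_scene(config, rng))
                break
            except PackingError:
                if attempt == 19:
                    raise
    return out


# ---------------------------------------------------------------------------
# geometry helpers


def _left_dir(u: np.ndarray) -> np.ndarray:
    """Animal-left direction for heading u, in (x right, y down) coords."""
    return np.array([u[1], -u[0]])


def make_pig(center: np.ndarray, heading_rad: float, length: float,
             instance_id: int) -> PigAnnotation:
    """Place keypoints deterministically from a body pose."""
    u = np.array([math.cos(heading_rad), math.sin(heading_rad)])
    tail = center - 0.5 * length * u
    shoulder = tail + SHOULDER_FRACTION * length * u
    head = tail + HEAD_FRACTION * length * u
    lateral = EAR_LATERAL_FRACTION * length * _left_dir(u)
    return PigAnnotation(
        shoulder=Point2D(*shoulder),
        tail=Point2D(*tail),
        left_ear=Point2D(*(head + lateral)),
        right_ear=Point2D(*(head - lateral)),
        instance_id=instance_id,
    )


def _pig_extent(length: float) -> float:
    """Radius of the circle (about the body center) containing all parts."""
    return length * math.hypot(HEAD_FRACTION - 0.5, EAR_LATERAL_FRACTION)


def _inside(pt: Point2D, rows: int, cols: int, margin: float = 1.0) -> bool:
    return margin <= pt.x < cols - margin and margin <= pt.y < rows - margin


# ---------------------------------------------------------------------------
# rendering


def _render_ellipse(img: np.ndarray, center: np.ndarray, u: np.ndarray,
                    a: float, b: float, value: float) -> None:
    """Paint a filled rotated ellipse (in place, single channel)."""
    rows, cols = img.shape
    r = int(math.ceil(max(a, b))) + 1
    ya, yb = max(0, int(center[1]) - r), min(rows, int(center[1]) + r + 1)
    xa, xb = max(0, int(center[0]) - r), min(cols, int(center[0]) + r + 1)
    if ya >= yb or xa >= xb:
        return
    yy = np.arange(ya, yb, dtype=float)[:, None] - center[1]
    xx = np.arange(xa, xb, dtype=float)[None, :] - center[0]
    lon = xx * u[0] + yy * u[1]
    lat = -xx * u[1] + yy * u[0]
    inside = (lon / a) ** 2 + (lat / b) ** 2 <= 1.0
    region = img[ya:yb, xa:xb]
    region[inside] = value


def render_scene_image(frame: FrameAnnotation, config: SceneConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw bodies, heads and ear nubs over a textured floor."""
    rows, cols = frame.image_size
    base = rng.normal(config.background_level, 0.03, size=(rows // 8 + 1, cols // 8 + 1))
    floor = np.kron(base, np.ones((8, 8)))[:rows, :cols]
    img = np.clip(floor, 0.0, 0.45)
    for pig in frame.pigs:
        s, t = np.array(pig.shoulder.as_tuple()), np.array(pig.tail.as_tuple())
        length = body_length(pig) / SHOULDER_FRACTION
        u = (s - t) / max(np.linalg.norm(s - t), 1e-9)
        center = t + 0.5 * length * u
        tone = rng.uniform(0.6, 0.85)
        _render_ellipse(img, center, u, 0.5 * length, 0.5 * WIDTH_FRACTION * length, tone)
        # the head end must be visually discernible, as it is from a real
        # overhead camera: without it the orientation is ambiguous
        head = t + HEAD_FRACTION * length * u
        _render_ellipse(img, head, u, 0.16 * length, 0.13 * length, tone * 0.62)
        for ear in (pig.left_ear, pig.right_ear):
            if ear is not None:
                _render_ellipse(img, np.array(ear.as_tuple()), u,
                                0.08 * length, 0.08 * length, tone * 0.45)
    img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    rgb = np.stack([img, img * rng.uniform(0.92, 1.0), img * rng.uniform(0.85, 1.0)], axis=-1)
    if frame.mask_polygon is not None:
        rgb = rgb * polygon_mask(frame.mask_polygon, rows, cols)[:, :, None]
    return rgb


def polygon_mask(polygon: list[Point2D], rows: int, cols: int) -> np.ndarray:
    """Rasterize a polygon to a {0,1} float mask (pen area of interest)."""
    from PIL import Image, ImageDraw

    im = Image.new("L", (cols, rows), 0)
    ImageDraw.Draw(im).polygon([(p.x, p.y) for p in polygon], fill=1)
    return np.asarray(im, dtype=float)


def _point_in_polygon(pt: Point2D, mask: np.ndarray) -> bool:
    y, x = int(round(pt.y)), int(round(pt.x))
    if not (0 <= y < mask.shape[0] and 0 <= x < mask.shape[1]):
        return False
    return mask[y, x] > 0


# ---------------------------------------------------------------------------
# random scene generation


def _sample_length(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Triangular draw: most bodies short, a heavy-ish tail of long ones."""
    mode = lo + 0.36 * (hi - lo)
    return float(rng.triangular(lo, mode, hi))


def generate_scene(config: SceneConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[np.ndarray, FrameAnnotation]:
    """Generate one (image, annotation) pair; pure function of config+seed.

    Abutting pairs share an orientation and lie side by side with a small
    body overlap (lateral gap drawn from [-0.3, 0) body widths), the
    close-proximity regime in which Euclidean part grouping breaks down.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows, cols = config.image_size
    lo_n, hi_n = config.n_pigs_range
    n = int(rng.integers(lo_n, hi_n + 1))

    mask = None
    polygon = None
    if config.use_mask:
        inset_x, inset_y = 0.08 * cols, 0.08 * rows
        polygon = [
            Point2D(inset_x, inset_y), Point2D(cols - inset_x, 2.0),
            Point2D(cols - 4.0, rows - inset_y), Point2D(2.0, rows - 4.0),
        ]
        mask = polygon_mask(polygon, rows, cols)

    n_pairs = int(round(config.abutting_fraction * n / 2.0))
    n_singles = n - 2 * n_pairs

    placed: list[tuple[np.ndarray, float]] = []  # (center, clearance radius)
    pigs: list[PigAnnotation] = []

    def try_place(extent: float) -> Optional[np.ndarray]:
        for _ in range(config.max_attempts):
            c = np.array([rng.uniform(extent, cols - extent),
                          rng.uniform(extent, rows - extent)])
            if all(np.linalg.norm(c - pc) >= extent + pr for pc, pr in placed):
                return c
        return None

    def finalize(pig: PigAnnotation) -> PigAnnotation:
        # ears outside the frame or the pen mask are not annotated
        for attr in ("left_ear", "right_ear"):
            ear = getattr(pig, attr)
            drop = ear is not None and (
                not _inside(ear, rows, cols)
                or (mask is not None and not _point_in_polygon(ear, mask))
                or rng.uniform() > config.ear_visibility
            )
            if drop:
                setattr(pig, attr, None)
        return pig

    next_id = 0
    lo, hi = config.body_length_range
    for _ in range(n_pairs):
        length = _sample_length(rng, lo, hi)
        width = WIDTH_FRACTION * length
        theta = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])
        gap = rng.uniform(-0.3, 0.0) * width
        offset = 0.5 * (width + gap)  # center-to-center = one width + gap
        # lying pairs are rarely perfectly aligned: stagger along the body
        stagger = rng.uniform(-0.25, 0.25) * length
        extent = _pig_extent(length) + offset + abs(stagger) + 4.0
        c = try_place(extent)
        if c is None:
            raise PackingError(f"could not place abutting pair (n={n})")
        placed.append((c, extent))
        perp = _left_dir(u)
        for sgn in (+1.0, -1.0):
            pig = make_pig(c + sgn * (offset * perp + 0.5 * stagger * u),
                           theta, length, next_id)
            if not (_inside(pig.shoulder, rows, cols) and _inside(pig.tail, rows, cols)):
                raise PackingError("pair landed outside the frame")
            pigs.append(finalize(pig))
            next_id += 1
    for _ in range(n_singles):
        length = _sample_length(rng, lo, hi)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        extent = _pig_extent(length) + 4.0
        c = try_place(extent)
        if c is None:
            raise PackingError(f"could not place pig (n={n})")
        placed.append((c, extent))
        pigs.append(finalize(make_pig(c, theta, length, next_id)))
        next_id += 1

    frame = FrameAnnotation(image_size=(rows, cols), pigs=pigs, mask_polygon=polygon)
    frame.validate()
    image = render_scene_image(frame, config, rng)
    return image, frame


# ---------------------------------------------------------------------------
# deterministic suites


def round_trip_frames(n_frames: int, seed: int = 0,
                      image_size: tuple[int, int] = (384, 512),
                      n_pigs_range: tuple[int, int] = (2, 12),
                      body_length_range: tuple[float, float] = (30.0, 60.0)
                      ) -> list[FrameAnnotation]:
    """Frames whose cross-instance part separations exceed 2 * max sigma.

    Pigs are centered on a jittered 4x3 grid so the separation guarantee
    holds by construction; every frame is asserted against the actual
    kernel sizes before being returned.  These are the conditions under
    which encode -> decode must be an exact round trip.
    """
    rng = np.random.default_rng(seed)
    rows, cols = image_size
    cell_r, cell_c = rows // 3, cols // 4
    centers = [
        np.array([cc * cell_c + cell_c / 2.0, rr * cell_r + cell_r / 2.0])
        for rr in range(3) for cc in range(4)
    ]
    frames = []
    lo, hi = body_length_range
    for _ in range(n_frames):
        n = int(rng.integers(n_pigs_range[0], n_pigs_range[1] + 1))
        idx = rng.permutation(len(centers))[:n]
        pigs = []
        for k, ci in enumerate(idx):
            c = centers[ci] + rng.uniform(-12.0, 12.0, size=2)
            length = rng.uniform(lo, hi)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            pigs.append(make_pig(c, theta, length, k))
        frame = FrameAnnotation(image_size=image_size, pigs=pigs)
        frame.validate()
        sigmas = compute_sigma(frame)
        min_sep = min_cross_instance_separation(frame)
        assert min_sep > 2.0 * max(sigmas), (
            f"separation {min_sep:.1f} <= 2*max sigma {2 * max(sigmas):.1f}"
        )
        frames.append(frame)
    return frames


def min_cross_instance_separation(frame: FrameAnnotation) -> float:
    """Smallest distance between parts belonging to different instances."""
    from .core import PartType

    pts = []
    for i, pig in enumerate(frame.pigs):
        for part in PartType:
            pt = pig.part(part)
            if pt is not None:
                pts.append((i, np.array(pt.as_tuple())))
    best = math.inf
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            if pts[a][0] != pts[b][0]:
                best = min(best, float(np.linalg.norm(pts[a][1] - pts[b][1])))
    return best


def _frame(rows: int, cols: int, pigs: list[PigAnnotation],
           polygon: Optional[list[Point2D]] = None) -> FrameAnnotation:
    f = FrameAnnotation(image_size=(rows, cols), pigs=pigs, mask_polygon=polygon)
    f.validate()
    return f


def generate_fixture_suite(seed: int = 0) -> dict[str, tuple[np.ndarray, FrameAnnotation]]:
    """Six deterministic named fixtures covering the regimes of interest.

    ``abutting_pair`` uses opposed headings (each shoulder next to the
    neighbour's tail), the configuration in which nearest-neighbour
    Euclidean grouping mis-associates while vector grouping does not.
    """
    rng = np.random.default_rng(seed)
    cfg = SceneConfig(image_size=(352, 480), noise_sigma=0.02, seed=seed)
    fixtures: dict[str, tuple[np.ndarray, FrameAnnotation]] = {}

    def add(name: str, frame: FrameAnnotation) -> None:
        fixtures[name] = (render_scene_image(frame, cfg, rng), frame)

    rows, cols = 352, 480
    # 1. single pig
    add("single", _frame(rows, cols, [make_pig(np.array([240.0, 170.0]), 0.4, 90.0, 0)]))

    # 2. two abutting side-by-side pigs, opposed headings (Fig.-2 regime)
    L = 80.0
    off = 0.5 * WIDTH_FRACTION * L * 1.2
    add("abutting_pair", _frame(rows, cols, [
        make_pig(np.array([230.0, 160.0 - off]), 0.0, L, 0),
        make_pig(np.array([230.0, 160.0 + off]), math.pi, L, 1),
    ]))

    # 3. head-to-tail chain of three
    chain = []
    x = 70.0
    for k in range(3):
        chain.append(make_pig(np.array([x + 35.0, 200.0]), 0.0, 70.0, k))
        x += 70.0 + 22.0
    add("chain", _frame(rows, cols, chain))

    # 4. pig at the pen-mask border with its ears beyond it
    polygon = [Point2D(10.0, 10.0), Point2D(300.0, 10.0),
               Point2D(300.0, 340.0), Point2D(10.0, 340.0)]
    border_pig = make_pig(np.array([272.0, 170.0]), 0.0, 80.0, 0)
    mask = polygon_mask(polygon, rows, cols)
    for attr in ("left_ear", "right_ear"):
        ear = getattr(border_pig, attr)
        if ear is not None and not _point_in_polygon(ear, mask):
            setattr(border_pig, attr, None)
    lone = make_pig(np.array([120.0, 90.0]), 2.2, 70.0, 1)
    add("mask_border", _frame(rows, cols, [border_pig, lone], polygon))

    # 5. dense pen: 12 pigs on a jittered grid
    dense = []
    k = 0
    for rr in range(3):
        for cc in range(4):
            c = np.array([cc * 120 + 60.0, rr * 117 + 59.0]) + rng.uniform(-6, 6, size=2)
            dense.append(make_pig(c, rng.uniform(0, 2 * math.pi), 45.0, k))
            k += 1
    add("dense_12", _frame(rows, cols, dense))

    # 6. empty pen
    add("empty", _frame(rows, cols, []))
    return fixtures


def abutting_suite(seed: int = 0) -> list[tuple[str, FrameAnnotation]]:
    """Close-proximity configurations for the association ablation.

    Opposed-heading side-by-side pairs make Euclidean grouping swap
    shoulder-tail pairings; closed head-to-tail rings additionally make
    the swapped pairings fail cross-check matching (stub detections far
    from every ground truth), so Euclidean precision drops below 1.
    """
    rows, cols = 352, 480
    suite: list[tuple[str, FrameAnnotation]] = []

    def antiparallel(name: str, L: float, sep_factor: float, theta: float,
                     center: np.ndarray) -> None:
        off = 0.5 * WIDTH_FRACTION * L * sep_factor
        u = np.array([math.cos(theta), math.sin(theta)])
        perp = _left_dir(u)
        suite.append((name, _frame(rows, cols, [
            make_pig(center + off * perp, theta, L, 0),
            make_pig(center - off * perp, theta + math.pi, L, 1),
        ])))

    antiparallel("pair_tight", 80.0, 1.1, 0.0, np.array([240.0, 150.0]))
    antiparallel("pair_loose", 90.0, 1.25, 1.1, np.array([230.0, 180.0]))

    def ring(name: str, n_sides: int, side: float, L: float, gaps: list[float],
             center: np.ndarray) -> None:
        pigs = []
        for k in range(n_sides):
            a0 = 2 * math.pi * k / n_sides
            a1 = 2 * math.pi * (k + 1) / n_sides
            v0 = center + side * np.array([math.cos(a0), math.sin(a0)])
            v1 = center + side * np.array([math.cos(a1), math.sin(a1)])
            u = (v1 - v0) / np.linalg.norm(v1 - v0)
            tail = v0 + gaps[k] * u
            pigs.append(make_pig(tail + 0.5 * L * u, math.atan2(u[1], u[0]), L, k))
        suite.append((name, _frame(rows, cols, pigs)))

    # closed triangle: each shoulder abuts the next tail; unequal gaps
    # break argmin ties so the Euclidean stub detections fail mutuality
    ring("ring_3", 3, 64.0, 72.0, [12.0, 20.0, 16.0], np.array([240.0, 176.0]))
    ring("ring_4", 4, 62.0, 66.0, [10.0, 18.0, 14.0, 22.0], np.array([240.0, 176.0]))
    return suite
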