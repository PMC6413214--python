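"""Shared domain types and geometric helpers.

Coordinate convention (used everywhere in the package): ``x`` indexes
columns, ``y`` indexes rows, both 0-based, with pixel centers at integer
coordinates.  Arrays are indexed ``[y, x]`` (row-major).  Sub-pixel
coordinates are real numbers in the same frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional


class PartType(IntEnum):
    """The four annotated body parts, in target-channel order.

    The integer code of each part is its channel index in the 4-channel
    part heatmap block (left ear, right ear, shoulder, tail).
    """

    LEFT_EAR = 0
    RIGHT_EAR = 1
    SHOULDER = 2
    TAIL = 3


#: Parts that define an instance.  Ears are optional decorations.
REQUIRED_PARTS = (PartType.SHOULDER, PartType.TAIL)


@dataclass(frozen=True)
class Point2D:
    """A sub-pixel image location (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


def euclidean_norm(a: Point2D, b: Point2D) -> float:
    """L2 distance between two points."""
    return math.hypot(a.x - b.x, a.y - b.y)


@dataclass
class PigAnnotation:
    """One animal: shoulder and tail are always annotated, ears optionally.

    The shoulder/tail pair defines the position and orientation of the
    animal; ears, when visible, describe the head pose.
    """

    shoulder: Point2D
    tail: Point2D
    left_ear: Optional[Point2D] = None
    right_ear: Optional[Point2D] = None
    instance_id: int = 0

    def part(self, p: PartType) -> Optional[Point2D]:
        return {
            PartType.LEFT_EAR: self.left_ear,
            PartType.RIGHT_EAR: self.right_ear,
            PartType.SHOULDER: self.shoulder,
            PartType.TAIL: self.tail,
        }[p]

    @property
    def is_degenerate(self) -> bool:
        """True when shoulder and tail coincide (zero body length)."""
        return euclidean_norm(self.shoulder, self.tail) == 0.0


def body_length(pig: PigAnnotation) -> float:
    """Shoulder-to-tail distance (the per-instance length delta_s->t)."""
    return euclidean_norm(pig.shoulder, pig.tail)


@dataclass
class FrameAnnotation:
    """All annotated instances for one image.

    ``image_size`` is ``(rows, cols)``; all points must lie inside
    ``[0, cols) x [0, rows)``.  ``mask_polygon`` optionally describes the
    pen area of interest; pixels outside it are blacked out upstream.
    """

    image_size: tuple[int, int]
    pigs: list[PigAnnotation] = field(default_factory=list)
    mask_polygon: Optional[list[Point2D]] = None

    @property
    def n_pigs(self) -> int:
        return len(self.pigs)

    def validate(self) -> None:
        rows, cols = self.image_size
        seen_ids: set[int] = set()
        for pig in self.pigs:
            if pig.instance_id in seen_ids:
                raise ValueError(f"duplicate instance_id {pig.instance_id}")
            seen_ids.add(pig.instance_id)
            for p in PartType:
                pt = pig.part(p)
                if pt is None:
                    continue
                if not (0 <= pt.x < cols and 0 <= pt.y < rows):
                    raise ValueError(
                        f"part {p.name} of instance {pig.instance_id} at "
                        f"({pt.x}, {pt.y}) outside image {rows}x{cols}"
                    )


@dataclass
class DetectedInstance:
    """A decoded animal: a joined shoulder-tail pair plus optional ears.

    ``confidence`` is the minimum of the peak heatmap values of the
    constituent parts.
    """

    shoulder: Point2D
    tail: Point2D
    left_ear: Optional[Point2D] = None
    right_ear: Optional[Point2D] = None
    confidence: float = 1.0
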