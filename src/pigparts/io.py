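"""File formats and image preprocessing.

Annotations travel as a small JSON dialect::

    {"image": "frame_0001.png", "size": [rows, cols],
     "mask": [[x, y], ...] | null,
     "pigs": [{"id": 0, "shoulder": [x, y], "tail": [x, y],
               "left_ear": [x, y] | null, "right_ear": [x, y] | null}, ...]}

Coordinates are in the resized working-image space (480 columns by
default) unless an explicit ``"scale"`` field records a different
factor.  Readers validate and reject rather than coerce: a malformed
field raises ``AnnotationFormatError`` naming the offender.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from PIL import Image

from .core import FrameAnnotation, PigAnnotation, Point2D
from .decoder import DetectionSet
from .encoder import TargetMaps
from .matching import PRCurve, pr_curve_frame

PathLike = Union[str, Path]


class AnnotationFormatError(ValueError):
    pass


def _coord(obj, field: str, optional: bool = False) -> Optional[Point2D]:
    if obj is None:
        if optional:
            return None
        raise AnnotationFormatError(f"required field '{field}' is missing or null")
    if (not isinstance(obj, (list, tuple)) or len(obj) != 2
            or not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in obj)):
        raise AnnotationFormatError(f"field '{field}' must be a [x, y] number pair, got {obj!r}")
    try:
        return Point2D(float(obj[0]), float(obj[1]))
    except ValueError as exc:
        raise AnnotationFormatError(f"field '{field}': {exc}") from exc


def read_annotations(path: PathLike) -> FrameAnnotation:
    doc = json.loads(Path(path).read_text())
    if "size" not in doc:
        raise AnnotationFormatError("required field 'size' is missing")
    size = doc["size"]
    if (not isinstance(size, list) or len(size) != 2
            or not all(isinstance(v, int) and v > 0 for v in size)):
        raise AnnotationFormatError(f"field 'size' must be [rows, cols], got {size!r}")
    mask = None
    if doc.get("mask") is not None:
        mask = [_coord(p, f"mask[{i}]") for i, p in enumerate(doc["mask"])]
        if len(mask) < 3:
            raise AnnotationFormatError("field 'mask' needs at least 3 vertices")
    pigs = []
    for i, rec in enumerate(doc.get("pigs", [])):
        pigs.append(PigAnnotation(
            shoulder=_coord(rec.get("shoulder"), f"pigs[{i}].shoulder"),
            tail=_coord(rec.get("tail"), f"pigs[{i}].tail"),
            left_ear=_coord(rec.get("left_ear"), f"pigs[{i}].left_ear", optional=True),
            right_ear=_coord(rec.get("right_ear"), f"pigs[{i}].right_ear", optional=True),
            instance_id=int(rec.get("id", i)),
        ))
    frame = FrameAnnotation(image_size=(size[0], size[1]), pigs=pigs, mask_polygon=mask)
    try:
        frame.validate()
    except ValueError as exc:
        raise AnnotationFormatError(str(exc)) from exc
    return frame


def write_annotations(frame: FrameAnnotation, path: PathLike,
                      image_name: str = "") -> None:
    def pt(p: Optional[Point2D]):
        return None if p is None else [p.x, p.y]

    doc = {
        "image": image_name,
        "size": list(frame.image_size),
        "mask": None if frame.mask_polygon is None else [pt(p) for p in frame.mask_polygon],
        "pigs": [
            {"id": pig.instance_id, "shoulder": pt(pig.shoulder), "tail": pt(pig.tail),
             "left_ear": pt(pig.left_ear), "right_ear": pt(pig.right_ear)}
            for pig in frame.pigs
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_detections(dets: DetectionSet, path: PathLike) -> None:
    doc = {"instances": [
        {"shoulder": [d.shoulder.x, d.shoulder.y], "tail": [d.tail.x, d.tail.y],
         "left_ear": None if d.left_ear is None else [d.left_ear.x, d.left_ear.y],
         "right_ear": None if d.right_ear is None else [d.right_ear.x, d.right_ear.y],
         "confidence": d.confidence}
        for d in dets.instances
    ]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_detections(path: PathLike) -> DetectionSet:
    from .core import DetectedInstance

    doc = json.loads(Path(path).read_text())
    out = DetectionSet()
    for i, rec in enumerate(doc.get("instances", [])):
        out.instances.append(DetectedInstance(
            shoulder=_coord(rec.get("shoulder"), f"instances[{i}].shoulder"),
            tail=_coord(rec.get("tail"), f"instances[{i}].tail"),
            left_ear=_coord(rec.get("left_ear"), f"instances[{i}].left_ear", optional=True),
            right_ear=_coord(rec.get("right_ear"), f"instances[{i}].right_ear", optional=True),
            confidence=float(rec.get("confidence", 1.0)),
        ))
    return out


def write_pr_csv(curve: PRCurve, path: PathLike) -> None:
    pr_curve_frame(curve).to_csv(path, index=False, float_format="%.3f")


def save_maps(maps: TargetMaps, path: PathLike) -> None:
    """TargetMaps container: one .npz with the fixed channel order."""
    np.savez_compressed(path, stacked=maps.stacked().astype(np.float32),
                        assoc_mask=maps.assoc_mask)


def load_maps(path: PathLike) -> TargetMaps:
    with np.load(path) as data:
        return TargetMaps.from_stacked(data["stacked"].astype(float),
                                       data["assoc_mask"])


def load_image(path: PathLike) -> np.ndarray:
    """PNG/JPEG -> float RGB array in [0, 1]."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def save_image(image: np.ndarray, path: PathLike) -> None:
    arr = np.clip(image, 0.0, 1.0)
    Image.fromarray((arr * 255).astype(np.uint8)).save(path)


def preprocess_image(image: np.ndarray,
                     mask_polygon: Optional[list[Point2D]] = None,
                     target_cols: int = 480) -> tuple[np.ndarray, float]:
    """Mask out the pen surroundings and downsample to the working width.

    Pixels outside the polygon become pure black; the image is then
    resized (aspect-preserving, bicubic) so it has ``target_cols``
    columns.  Returns the image and the scale factor to apply to
    annotation coordinates.
    """
    rows, cols = image.shape[:2]
    if mask_polygon is not None:
        from .scenes import polygon_mask

        if len(mask_polygon) < 3:
            raise ValueError("mask polygon needs at least 3 vertices")
        image = image * polygon_mask(mask_polygon, rows, cols)[:, :, None]
    scale = target_cols / cols
    new_rows = max(1, int(round(rows * scale)))
    pil = Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8))
    pil = pil.resize((target_cols, new_rows), Image.BICUBIC)
    return np.asarray(pil, dtype=float) / 255.0, scale


def rescale_frame(frame: FrameAnnotation, scale: float,
                  new_size: tuple[int, int]) -> FrameAnnotation:
    """Apply the preprocessing scale factor to annotation coordinates."""
    def sc(p: Optional[Point2D]) -> Optional[Point2D]:
        if p is None:
            return None
        return Point2D(min(p.x * scale, new_size[1] - 1e-6),
                       min(p.y * scale, new_size[0] - 1e-6))

    return FrameAnnotation(
        image_size=new_size,
        pigs=[PigAnnotation(shoulder=sc(p.shoulder), tail=sc(p.tail),
                            left_ear=sc(p.left_ear), right_ear=sc(p.right_ear),
                            instance_id=p.instance_id) for p in frame.pigs],
        mask_polygon=None if frame.mask_polygon is None
        else [sc(p) for p in frame.mask_polygon],
    )
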