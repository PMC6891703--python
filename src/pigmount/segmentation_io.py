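"""Readers and writers for the formats that carry instance-segmentation
outputs into the pipeline.

Three file formats are supported:

* Labelme-dialect polygon JSON (one file per frame; shapes labelled ``pig``,
  optionally grouped by ``group_id`` so a multi-component mask stays one
  instance),
* 8-bit PNG label masks (0 = background, 1..n = instance ids),
* CSV bounding-box tables (``frame_id, x_min, y_min, x_max, y_max[, score]``).

Coordinate convention (fixed for the whole package): 0-based pixel indices;
a pixel ``(row i, col j)`` has its centre at ``(x = j + 0.5, y = i + 0.5)``
and is foreground iff that centre lies strictly inside the polygon; boxes are
half-open ``[x_min, x_max) x [y_min, y_max)`` when integral. Under this rule
an axis-aligned w x h rectangle rasterizes to exactly ``w * h`` pixels.

The live segmenter sits behind a structural interface: any callable mapping
an image to a list of :class:`PigInstance` can feed the pipeline; this module
ships only the file-based backends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from scipy import ndimage
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "InstanceMask",
    "PigInstance",
    "FrameRecord",
    "LabelmeParseError",
    "Segmenter",
    "polygon_to_mask",
    "read_labelme",
    "write_labelme",
    "read_mask_png",
    "write_mask_png",
    "read_bbox_table",
    "write_bbox_table",
]

#: Structural type of a pluggable segmentation backend.
Segmenter = Callable[[np.ndarray], "list[PigInstance]"]

VALID_LABELS = ("positive", "negative", "unknown")


class LabelmeParseError(ValueError):
    """Raised when an annotation file is malformed; names the offending field."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in image coordinates, half-open when integral."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def translated(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)


class InstanceMask:
    """Binary pixel grid for one instance; may have several connected components."""

    def __init__(self, pixels: np.ndarray):
        pixels = np.asarray(pixels)
        if pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {pixels.shape}")
        self.pixels = pixels.astype(bool)
        if not self.pixels.any():
            raise ValueError("mask has no foreground pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def components(self) -> list[np.ndarray]:
        """Connected components (8-connectivity) as separate boolean grids."""
        labelled, n = ndimage.label(self.pixels, structure=np.ones((3, 3), dtype=int))
        return [labelled == k for k in range(1, n + 1)]

    @property
    def n_components(self) -> int:
        _, n = ndimage.label(self.pixels, structure=np.ones((3, 3), dtype=int))
        return int(n)

    def component_areas(self) -> list[int]:
        return [int(c.sum()) for c in self.components()]

    def tight_bbox(self) -> BoundingBox:
        """Smallest half-open integral box containing every foreground pixel."""
        rows, cols = np.nonzero(self.pixels)
        return BoundingBox(
            float(cols.min()), float(rows.min()), float(cols.max() + 1), float(rows.max() + 1)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InstanceMask):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )

    def __repr__(self) -> str:
        return f"InstanceMask(shape={self.shape}, area={self.area}, components={self.n_components})"


@dataclass
class PigInstance:
    """One detected animal: its visible mask, bounding box, optional score."""

    mask: InstanceMask
    bbox: BoundingBox
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"detection score {self.score} outside [0, 1]")
        tight = self.mask.tight_bbox()
        # 1 px slack covers polygon-rasterization shrinkage at the boundary
        if (
            self.bbox.x_min > tight.x_min + 1e-9
            or self.bbox.y_min > tight.y_min + 1e-9
            or self.bbox.x_max < tight.x_max - 1e-9
            or self.bbox.y_max < tight.y_max - 1e-9
        ):
            raise ValueError(f"bbox {self.bbox} does not enclose mask extent {tight}")


@dataclass
class FrameRecord:
    """One image's worth of segmentation output plus its behaviour label."""

    frame_id: str
    image_size: tuple[int, int]  # (width, height)
    instances: list[PigInstance] = field(default_factory=list)
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label {self.label!r} not one of {VALID_LABELS}")
        w, h = self.image_size
        for inst in self.instances:
            if inst.mask.shape != (h, w):
                raise ValueError(
                    f"instance mask shape {inst.mask.shape} != frame shape {(h, w)}"
                )


# ---------------------------------------------------------------------------
# polygon rasterization


def polygon_to_mask(vertices: Sequence[tuple[float, float]], size: tuple[int, int]) -> InstanceMask:
    """Rasterize a simple polygon to a binary mask on a ``(w, h)`` canvas.

    A pixel is foreground iff its centre lies strictly inside the polygon
    (even-odd rule; for the simple polygons accepted here this coincides with
    the interior). Self-intersecting or degenerate (zero-area) polygons raise
    instead of being silently repaired.
    """
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(verts)}")
    w, h = size
    for x, y in verts:
        if not (0.0 <= x <= w and 0.0 <= y <= h):
            raise ValueError(f"vertex ({x}, {y}) outside canvas {size}")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    if poly.area <= 0.0:
        raise ValueError("polygon has zero area (collinear vertices?)")

    xs = np.array([v[0] for v in verts])
    ys = np.array([v[1] for v in verts])
    c0 = max(int(np.floor(xs.min() - 0.5)), 0)
    c1 = min(int(np.ceil(xs.max() + 0.5)), w)
    r0 = max(int(np.floor(ys.min() - 0.5)), 0)
    r1 = min(int(np.ceil(ys.max() + 0.5)), h)
    grid = np.zeros((h, w), dtype=bool)
    if c1 > c0 and r1 > r0:
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = shapely.contains_xy(poly, cols.ravel() + 0.5, rows.ravel() + 0.5)
        grid[r0:r1, c0:c1] = inside.reshape(rows.shape)
    if not grid.any():
        raise ValueError("polygon rasterized to an empty mask")
    return InstanceMask(grid)


# ---------------------------------------------------------------------------
# Labelme-dialect JSON


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise LabelmeParseError(f"missing field {key!r} in {context}")
    return mapping[key]


def read_labelme(path: str | Path, pig_label: str = "pig") -> FrameRecord:
    """Read a Labelme-dialect polygon annotation into a :class:`FrameRecord`.

    Shapes whose ``label`` equals ``pig_label`` become instances; shapes
    sharing a non-null ``group_id`` are merged into one (multi-component)
    instance. The frame's behaviour label is read from
    ``flags["behaviour"]`` when present. Zero-area polygons are skipped with
    a logged warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LabelmeParseError(f"not valid JSON: {path} ({exc})") from exc
    if not isinstance(doc, dict):
        raise LabelmeParseError(f"top-level document is not an object in {path}")
    w = int(_require(doc, "imageWidth", str(path)))
    h = int(_require(doc, "imageHeight", str(path)))
    shapes = _require(doc, "shapes", str(path))
    if not isinstance(shapes, list):
        raise LabelmeParseError(f"field 'shapes' is not a list in {path}")

    # preserve first-appearance order of groups; ungrouped shapes stand alone
    groups: dict[object, list[np.ndarray]] = {}
    order: list[object] = []
    for i, shape in enumerate(shapes):
        if not isinstance(shape, dict):
            raise LabelmeParseError(f"field 'shapes[{i}]' is not an object in {path}")
        label = _require(shape, "label", f"shapes[{i}] of {path}")
        if label != pig_label:
            continue
        points = _require(shape, "points", f"shapes[{i}] of {path}")
        try:
            mask = polygon_to_mask([(p[0], p[1]) for p in points], (w, h))
        except ValueError as exc:
            logger.warning("skipping shape %d of %s: %s", i, path, exc)
            continue
        key = shape.get("group_id")
        key = ("solo", i) if key is None else ("group", key)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(mask.pixels)

    instances = []
    for key in order:
        merged = InstanceMask(np.logical_or.reduce(groups[key]))
        instances.append(PigInstance(mask=merged, bbox=merged.tight_bbox()))
    flags = doc.get("flags") or {}
    label = flags.get("behaviour", "unknown")
    if label not in VALID_LABELS:
        raise LabelmeParseError(f"field 'flags.behaviour' has unknown value {label!r} in {path}")
    return FrameRecord(frame_id=path.stem, image_size=(w, h), instances=instances, label=label)


def write_labelme(record: FrameRecord, path: str | Path) -> None:
    """Write a FrameRecord as a Labelme-dialect JSON file.

    Each instance's connected components are written as separate polygon
    shapes sharing one ``group_id``. Outlines are sub-pixel marching-squares
    contours, so re-rasterizing them approximates (does not exactly rebuild)
    the source mask; the PNG label-mask writer is the pixel-exact channel.
    """
    from skimage import measure

    path = Path(path)
    w, h = record.image_size
    shapes = []
    for gid, inst in enumerate(record.instances, start=1):
        padded = np.pad(inst.mask.pixels.astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            pts = [
                [float(np.clip(c - 1 + 0.5, 0, w)), float(np.clip(r - 1 + 0.5, 0, h))]
                for r, c in contour[:-1]  # drop duplicated closing vertex
            ]
            if len(pts) < 3:
                continue
            shapes.append(
                {"label": "pig", "points": pts, "group_id": gid, "shape_type": "polygon"}
            )
    doc = {
        "version": "5.0.1",
        "flags": {"behaviour": record.label},
        "shapes": shapes,
        "imagePath": f"{record.frame_id}.png",
        "imageData": None,
        "imageHeight": h,
        "imageWidth": w,
    }
    path.write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# PNG label masks


def read_mask_png(path: str | Path) -> list[InstanceMask]:
    """Read an 8-bit label image (0 background, 1..n instance ids).

    Non-contiguous ids are accepted; they are remapped to dense order and the
    mapping is logged.
    """
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"label image must be single-channel, got shape {arr.shape}")
    ids = sorted(int(v) for v in np.unique(arr) if v != 0)
    if ids != list(range(1, len(ids) + 1)):
        logger.warning("non-contiguous instance ids %s in %s remapped to 1..%d", ids, path, len(ids))
    return [InstanceMask(arr == v) for v in ids]


def write_mask_png(masks: Iterable[InstanceMask], path: str | Path) -> None:
    """Write masks as a single 8-bit label image (instance i -> id i+1).

    Masks must be disjoint; overlap would silently lose pixels, so it raises.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to write")
    if len(masks) > 255:
        raise ValueError("more than 255 instances do not fit an 8-bit label image")
    shape = masks[0].shape
    out = np.zeros(shape, dtype=np.uint8)
    covered = np.zeros(shape, dtype=bool)
    for i, m in enumerate(masks, start=1):
        if m.shape != shape:
            raise ValueError(f"mask {i} shape {m.shape} != {shape}")
        if (covered & m.pixels).any():
            raise ValueError(f"mask {i} overlaps an earlier mask; label image would be ambiguous")
        covered |= m.pixels
        out[m.pixels] = i
    Image.fromarray(out, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# CSV bounding-box tables

BBOX_COLUMNS = ["frame_id", "x_min", "y_min", "x_max", "y_max"]


def read_bbox_table(path: str | Path) -> dict[str, list[BoundingBox]]:
    """Read a bounding-box CSV, grouped by frame id preserving row order.

    Rows with an inverted or degenerate box are rejected with their row
    number logged; an empty table (header only) yields an empty dict.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in BBOX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bbox table missing columns {missing}")
    out: dict[str, list[BoundingBox]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            box = BoundingBox(float(row.x_min), float(row.y_min), float(row.x_max), float(row.y_max))
        except ValueError as exc:
            logger.warning("rejecting row %d of %s: %s", row_no, path, exc)
            continue
        out.setdefault(str(row.frame_id), []).append(box)
    return out


def write_bbox_table(
    boxes: dict[str, list[BoundingBox]],
    path: str | Path,
    scores: dict[str, list[float]] | None = None,
) -> None:
    rows = []
    for frame_id, frame_boxes in boxes.items():
        for i, b in enumerate(frame_boxes):
            row = {
                "frame_id": frame_id,
                "x_min": b.x_min,
                "y_min": b.y_min,
                "x_max": b.x_max,
                "y_max": b.y_max,
            }
            if scores is not None:
                row["score"] = scores[frame_id][i]
            rows.append(row)
    cols = BBOX_COLUMNS + (["score"] if scores is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(Path(path), index=False)
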