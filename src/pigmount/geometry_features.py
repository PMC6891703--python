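"""Per-frame geometric feature extraction.

Three feature families are computed from instance-segmentation output and
assembled into a fixed-length frame descriptor ("eigenvector" in the
livestock-monitoring literature, where the term means feature vector, not a
linear-algebra eigenvector):

* the mask **perimeter** of each pig (sub-pixel marching-squares contour
  length at level 0.5, summed over connected components),
* the **half-body areas** (HBA): the mask is split by the segment joining
  the midpoints of the bounding box's two long sides, giving two pixel
  areas that always sum exactly to the mask area. When mounting fragments a
  mask into components the same geometric split applies, so the occluded
  pig's split areas remain well defined,
* the **pairwise distances** between bounding-box centres of all pigs.

For P pigs the vector has ``3 * P + C(P, 2)`` slots (18 for the default
P = 4): per pig perimeter, smaller half, larger half; then the C(P, 2)
centre distances in canonical (i < j) order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .segmentation_io import BoundingBox, FrameRecord, InstanceMask

__all__ = [
    "HalfBodyArea",
    "FeatureVector",
    "mask_perimeter",
    "half_body_areas",
    "bbox_centre",
    "pairwise_centre_distances",
    "build_eigenvector",
    "feature_layout",
    "frames_to_feature_table",
    "write_feature_csv",
    "read_feature_csv",
]


@dataclass(frozen=True)
class HalfBodyArea:
    """The two pixel areas of a mask split across its box's long axis."""

    s_small: int
    s_large: int
    split_axis: str  # "vertical" split line (box wider than tall) or "horizontal"
    n_components: int

    @property
    def total(self) -> int:
        return self.s_small + self.s_large


@dataclass
class FeatureVector:
    """Fixed-dimension frame descriptor with a named slot layout."""

    values: np.ndarray
    layout: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.layout),):
            raise ValueError(
                f"values shape {self.values.shape} != layout length {len(self.layout)}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("feature values must be finite and non-negative")


def mask_perimeter(mask: InstanceMask) -> float:
    """Total boundary length (px) of a mask over all connected components.

    Computed as the polyline length of the 0.5-level marching-squares
    iso-contour of the zero-padded mask: sub-pixel, stable across
    resolutions, and additive over disjoint components.
    """
    padded = np.pad(mask.pixels.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


def half_body_areas(mask: InstanceMask, bbox: BoundingBox) -> HalfBodyArea:
    """Split a mask across its bounding box's long axis into two areas.

    The split segment joins the midpoints of the two *long* sides, i.e. it
    crosses the box at half-length perpendicular to its long axis. Each
    foreground pixel goes to exactly one half by its centre position; a
    centre exactly on the line goes to the half nearer the box origin, so
    the two areas always sum to the mask area exactly. A square box is a
    measure-zero tie, broken by treating the x-parallel sides as long.
    """
    rows, cols = np.nonzero(mask.pixels)
    if bbox.width >= bbox.height:
        # long sides are the horizontal (x-parallel) edges -> vertical split line
        cut = (bbox.x_min + bbox.x_max) / 2.0
        near_origin = (cols + 0.5) <= cut
        axis = "vertical"
    else:
        cut = (bbox.y_min + bbox.y_max) / 2.0
        near_origin = (rows + 0.5) <= cut
        axis = "horizontal"
    a = int(near_origin.sum())
    b = int(len(rows) - a)
    return HalfBodyArea(
        s_small=min(a, b), s_large=max(a, b), split_axis=axis, n_components=mask.n_components
    )


def bbox_centre(bbox: BoundingBox) -> tuple[float, float]:
    return bbox.centre


def pairwise_centre_distances(centres: Sequence[tuple[float, float]]) -> np.ndarray:
    """Euclidean distances of all unordered point pairs in (i < j) order."""
    if len(centres) < 2:
        raise ValueError(f"need >= 2 points, got {len(centres)}")
    pts = np.asarray(centres, dtype=float)
    return np.array([float(np.hypot(*(pts[i] - pts[j]))) for i, j in combinations(range(len(pts)), 2)])


def feature_layout(expected_pigs: int = 4) -> tuple[str, ...]:
    names = []
    for k in range(1, expected_pigs + 1):
        names += [f"pig{k}_perimeter", f"pig{k}_hba_small", f"pig{k}_hba_large"]
    names += [f"dist_{i}_{j}" for i, j in combinations(range(1, expected_pigs + 1), 2)]
    return tuple(names)


def build_eigenvector(
    frame: FrameRecord, expected_pigs: int = 4, normalize: bool = False
) -> FeatureVector:
    """Assemble the per-frame feature vector.

    Instances are put in canonical raster order (centre y, then centre x) so
    the result is independent of segmentation output order. When the frame
    carries more detections than ``expected_pigs`` the lowest-scoring extras
    are dropped (missing scores count as 1.0); when it carries fewer, the
    absent pigs contribute zero perimeter/areas and image-diagonal ("far
    away") sentinel distances, keeping the dimension fixed for the
    classifier. With ``normalize`` lengths are divided by the image diagonal
    and areas by the image area.
    """
    if not frame.instances:
        raise ValueError(
            f"frame {frame.frame_id!r}: segmentation produced no instances; "
            "cannot build a feature vector"
        )
    w, h = frame.image_size
    diagonal = math.hypot(w, h)

    instances = list(frame.instances)
    if len(instances) > expected_pigs:
        # drop lowest detection scores; stable on ties
        scored = sorted(
            range(len(instances)),
            key=lambda i: (-(instances[i].score if instances[i].score is not None else 1.0), i),
        )
        keep = sorted(scored[:expected_pigs])
        instances = [instances[i] for i in keep]
    instances.sort(key=lambda inst: (inst.bbox.centre[1], inst.bbox.centre[0]))

    per_pig: list[float] = []
    centres: list[tuple[float, float] | None] = []
    for inst in instances:
        hba = half_body_areas(inst.mask, inst.bbox)
        per_pig += [mask_perimeter(inst.mask), float(hba.s_small), float(hba.s_large)]
        centres.append(inst.bbox.centre)
    for _ in range(expected_pigs - len(instances)):
        per_pig += [0.0, 0.0, 0.0]
        centres.append(None)

    dists: list[float] = []
    for i, j in combinations(range(expected_pigs), 2):
        if centres[i] is None or centres[j] is None:
            dists.append(diagonal)
        else:
            dists.append(math.dist(centres[i], centres[j]))

    values = np.array(per_pig + dists, dtype=float)
    if normalize:
        scale = np.ones_like(values)
        for k in range(expected_pigs):
            scale[3 * k] = diagonal
            scale[3 * k + 1] = scale[3 * k + 2] = float(w * h)
        scale[3 * expected_pigs :] = diagonal
        values = values / scale
    return FeatureVector(values=values, layout=feature_layout(expected_pigs))


# ---------------------------------------------------------------------------
# feature-table I/O


def frames_to_feature_table(
    frames: Sequence[FrameRecord], expected_pigs: int = 4, normalize: bool = False
) -> pd.DataFrame:
    """One row per frame: frame_id, label, then the named feature slots."""
    layout = feature_layout(expected_pigs)
    rows = []
    for frame in frames:
        fv = build_eigenvector(frame, expected_pigs=expected_pigs, normalize=normalize)
        row: dict[str, object] = {"frame_id": frame.frame_id, "label": frame.label}
        row.update(dict(zip(layout, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["frame_id", "label", *layout])


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    for col in ("frame_id", "label"):
        if col not in df.columns:
            raise ValueError(f"feature table missing column {col!r}")
    return df
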