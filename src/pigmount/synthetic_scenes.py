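"""Synthetic overhead pen scenes with ground truth.

Real mounting-behaviour footage of group-housed pigs is rarely shareable,
so this module generates the statistical situations such footage contains:
a top-down pen with a configurable number of pig-shaped instances
(an ellipse body with a small head disc) in three regimes —

* **separated**: every pig clear of every other,
* **adhering**: two pigs touching flank-to-flank without overlap (the
  designated hard-negative case),
* **mounting**: one pig standing across another's midsection, so the
  mounted pig's *visible* mask (occluder wins contested pixels) splits
  into two connected components — exactly the fragmented-mask geometry an
  instance segmenter reports when mounting occurs.

Ground-truth masks are the visible (occlusion-clipped) regions; bounding
boxes are tight boxes of the visible masks, as a detector would emit.
Rendering (grayscale, illumination gradient) exists for demos and figures
only — the downstream pipeline consumes masks, never pixels.

Reproducibility: one global seed; frame ``i`` uses the child seed
``[global_seed, i]``, so frames are independent of generation order and a
dataset can be regenerated exactly from its manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation_io import (
    FrameRecord,
    InstanceMask,
    PigInstance,
    read_mask_png,
    write_labelme,
    write_mask_png,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "SyntheticFrame",
    "PlacementError",
    "simulate_frame",
    "simulate_dataset",
    "dataset_from_manifest",
    "export_dataset",
    "import_dataset",
]

_EIGHT = np.ones((3, 3), dtype=int)


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry and regime probabilities.

    Defaults emulate four ~25 kg minipigs in a ~2 x 2.2 m pen imaged
    top-down at 640 x 480 (about 290 px/m): body semi-axes of 55-75 px by
    20-28 px give pigs of realistic pen coverage. ``overlap_range`` is the
    fraction of the mounted pig's full body hidden by the mounting pig.
    """

    image_size: tuple[int, int] = (640, 480)
    n_pigs: int = 4
    semi_major_range: tuple[float, float] = (55.0, 75.0)
    semi_minor_range: tuple[float, float] = (20.0, 28.0)
    orientation_range: tuple[float, float] = (0.0, math.pi)
    mounting_probability: float = 0.44
    adhesion_probability: float = 0.3
    overlap_range: tuple[float, float] = (0.25, 0.45)
    illumination_amplitude: float = 0.3
    min_gap_px: int = 3
    max_rejections: int = 400

    def __post_init__(self) -> None:
        for p in (self.mounting_probability, self.adhesion_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.mounting_probability + self.adhesion_probability > 1.0:
            raise ValueError("mounting and adhesion probabilities must sum to <= 1")
        if self.semi_major_range[0] <= 0 or self.semi_minor_range[0] <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0.0 <= self.overlap_range[0] < self.overlap_range[1] <= 1.0:
            raise ValueError("overlap_range must be an increasing sub-interval of [0, 1]")
        if self.n_pigs < 1:
            raise ValueError("need at least one pig")


@dataclass
class SyntheticFrame:
    record: FrameRecord
    image: np.ndarray  # uint8 grayscale rendering
    log: dict


# ---------------------------------------------------------------------------
# pig body model


def _pig_body(
    size: tuple[int, int], cx: float, cy: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Full (unoccluded) pig mask: ellipse body plus a head disc at one tip."""
    w, h = size
    head_r = 0.6 * b
    head_cx = cx + (a + 0.4 * head_r) * math.cos(theta)
    head_cy = cy + (a + 0.4 * head_r) * math.sin(theta)
    extent = a + 1.2 * head_r + 2
    c0 = max(int(cx - extent), 0)
    c1 = min(int(cx + extent) + 1, w)
    r0 = max(int(cy - extent), 0)
    r1 = min(int(cy + extent) + 1, h)
    mask = np.zeros((h, w), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    xs = np.arange(c0, c1) + 0.5
    ys = np.arange(r0, r1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    dx, dy = X - cx, Y - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    head = (X - head_cx) ** 2 + (Y - head_cy) ** 2 <= head_r**2
    mask[r0:r1, c0:c1] = body | head
    return mask


def _extent(a: float, b: float) -> float:
    return a + 1.2 * 0.6 * b + 2


def _sample_pig(rng: np.random.Generator, config: SceneConfig):
    a = rng.uniform(*config.semi_major_range)
    b = rng.uniform(*config.semi_minor_range)
    theta = rng.uniform(*config.orientation_range)
    return a, b, theta


def _sample_centre(rng: np.random.Generator, config: SceneConfig, a: float, b: float):
    w, h = config.image_size
    m = _extent(a, b)
    if 2 * m >= w or 2 * m >= h:
        raise PlacementError("pig larger than the pen; shrink semi-axes or enlarge the image")
    return rng.uniform(m, w - m), rng.uniform(m, h - m)


def _clear_of(mask: np.ndarray, occupied: np.ndarray, gap: int) -> bool:
    if not occupied.any():
        return True
    grown = ndimage.binary_dilation(mask, structure=_EIGHT, iterations=gap)
    return not (grown & occupied).any()


# ---------------------------------------------------------------------------
# frame simulation


def _place_separated(
    rng, config: SceneConfig, occupied: np.ndarray, n: int
) -> list[np.ndarray]:
    """Place n pigs pairwise clear of each other and of `occupied`."""
    masks: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(config.max_rejections):
            a, b, theta = _sample_pig(rng, config)
            cx, cy = _sample_centre(rng, config, a, b)
            mask = _pig_body(config.image_size, cx, cy, a, b, theta)
            if mask.any() and _clear_of(mask, occupied, config.min_gap_px):
                masks.append(mask)
                occupied |= mask
                break
        else:
            raise PlacementError(
                f"could not place a separated pig after {config.max_rejections} tries; "
                "use smaller pigs or a larger pen"
            )
    return masks


# below this occluded fraction the mounting pig cannot reliably cross the
# mounted body end to end, so the two-component split is not insisted upon
_SPLIT_OVERLAP_MIN = 0.15


def _place_mounting_pair(rng, config: SceneConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """Mounted pig's visible mask, mounting pig's mask, achieved overlap.

    The mounting pig is laid across the mounted pig's midsection, roughly
    perpendicular to its spine. The occluded fraction of the mounted body
    is steered to a target drawn from ``config.overlap_range`` by sliding
    the mounting pig along its own axis (the fraction falls monotonically
    with the slide distance, so bisection finds it). For substantial
    overlap (>= {:.0%} of the body) the band crosses the mounted pig end
    to end and candidates are rejected until the visible remnant has
    exactly two sizeable components — the fragmented-mask signature of
    mounting; for near-zero overlap no split is demanded.
    """.format(_SPLIT_OVERLAP_MIN)
    w, h = config.image_size
    for _try in range(config.max_rejections):
        a1, b1, theta1 = _sample_pig(rng, config)
        cx1, cy1 = _sample_centre(rng, config, a1, b1)
        mounted_full = _pig_body(config.image_size, cx1, cy1, a1, b1, theta1)
        if not mounted_full.any():
            continue
        mounted_area = mounted_full.sum()
        a2, b2, _ = _sample_pig(rng, config)
        theta2 = theta1 + math.pi / 2 + rng.uniform(-0.25, 0.25)
        # crossing point on the spine, short of the shoulders
        u = rng.uniform(-0.25, 0.25) * a1
        px = cx1 + u * math.cos(theta1)
        py = cy1 + u * math.sin(theta1)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ex, ey = sign * math.cos(theta2), sign * math.sin(theta2)

        def mounting_at(d: float) -> np.ndarray:
            return _pig_body(config.image_size, px + d * ex, py + d * ey, a2, b2, theta2)

        def frac_at(mask: np.ndarray) -> float:
            return float((mounted_full & mask).sum() / mounted_area)

        f0 = frac_at(mounting_at(0.0))
        lo, hi = config.overlap_range
        if f0 < lo:
            continue  # mounting pig too small to cover this body enough
        target = rng.uniform(lo, min(hi, f0))
        d_lo, d_hi = 0.0, _extent(a1, b1) + _extent(a2, b2)
        for _ in range(20):  # fraction decreases in d: bisect to the target
            d_mid = 0.5 * (d_lo + d_hi)
            if frac_at(mounting_at(d_mid)) > target:
                d_lo = d_mid
            else:
                d_hi = d_mid
        d = 0.5 * (d_lo + d_hi)
        cx2, cy2 = px + d * ex, py + d * ey
        m2 = _extent(a2, b2)
        if not (m2 <= cx2 <= w - m2 and m2 <= cy2 <= h - m2):
            continue
        mounting = mounting_at(d)
        frac = frac_at(mounting)
        if not (lo <= frac <= hi):
            continue
        visible = mounted_full & ~mounting
        if not visible.any():
            continue
        if lo >= _SPLIT_OVERLAP_MIN:
            labelled, n = ndimage.label(visible, structure=_EIGHT)
            if n != 2:
                continue
            if min(np.bincount(labelled.ravel())[1:]) < 25:  # both fragments visible
                continue
        return visible, mounting, frac
    raise PlacementError(
        f"could not construct a mounting pair after {config.max_rejections} tries; "
        "widen overlap_range, use smaller pigs or a larger pen"
    )


def _place_adhering_pair(rng, config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint masks in contact (gap <= 1 px): touching, not mounting."""
    for _try in range(config.max_rejections):
        a1, b1, theta1 = _sample_pig(rng, config)
        cx1, cy1 = _sample_centre(rng, config, a1, b1)
        first = _pig_body(config.image_size, cx1, cy1, a1, b1, theta1)
        if not first.any():
            continue
        a2, b2, theta2 = _sample_pig(rng, config)
        phi = rng.uniform(0, 2 * math.pi)
        e = np.array([math.cos(phi), math.sin(phi)])
        t_hi = _extent(a1, b1) + _extent(a2, b2)  # surely clear
        t_lo = 0.0  # surely overlapping

        def second_at(t: float) -> np.ndarray:
            return _pig_body(
                config.image_size, cx1 + t * e[0], cy1 + t * e[1], a2, b2, theta2
            )

        for _ in range(24):  # bisect to the contact distance
            t_mid = 0.5 * (t_lo + t_hi)
            if (second_at(t_mid) & first).any():
                t_lo = t_mid
            else:
                t_hi = t_mid
        second = second_at(t_hi)
        w, h = config.image_size
        m2 = _extent(a2, b2)
        cx2, cy2 = cx1 + t_hi * e[0], cy1 + t_hi * e[1]
        if not (m2 <= cx2 <= w - m2 and m2 <= cy2 <= h - m2):
            continue
        if not second.any() or (second & first).any():
            continue
        touching = ndimage.binary_dilation(first, structure=_EIGHT) & second
        if touching.any():
            return first, second
    raise PlacementError(
        f"could not construct an adhering pair after {config.max_rejections} tries"
    )


def _render(
    rng, config: SceneConfig, masks: Sequence[np.ndarray]
) -> np.ndarray:
    """Grayscale rendering: gradient-lit floor, pigs close to floor tone."""
    w, h = config.image_size
    xs = np.linspace(-0.5, 0.5, w)
    floor = 150.0 * (1.0 + config.illumination_amplitude * xs)[None, :] * np.ones((h, 1))
    img = floor + rng.normal(0.0, 4.0, size=(h, w))
    for mask in masks:
        img[mask] = 195.0 + rng.normal(0.0, 5.0)
    return np.clip(img, 0, 255).astype(np.uint8)


def simulate_frame(config: SceneConfig, seed, regime: str | None = None) -> SyntheticFrame:
    """Generate one frame; ``regime`` overrides the config's regime draw.

    The frame is a pure function of ``(config, seed, regime)``.
    """
    rng = np.random.default_rng(seed)
    if regime is None:
        r = rng.random()
        if r < config.mounting_probability:
            regime = "mounting"
        elif r < config.mounting_probability + config.adhesion_probability:
            regime = "adhering"
        else:
            regime = "separated"
    if regime not in ("mounting", "adhering", "separated"):
        raise ValueError(f"unknown regime {regime!r}")
    if regime in ("mounting", "adhering") and config.n_pigs < 2:
        raise ValueError(f"regime {regime!r} needs at least two pigs")

    w, h = config.image_size
    occupied = np.zeros((h, w), dtype=bool)
    log: dict = {"regime": regime}
    masks: list[np.ndarray]
    if regime == "mounting":
        visible_mounted, mounting, frac = _place_mounting_pair(rng, config)
        occupied |= visible_mounted | mounting
        masks = [visible_mounted, mounting]
        masks += _place_separated(rng, config, occupied, config.n_pigs - 2)
        log.update(mounted_index=0, mounting_index=1, overlap_achieved=frac)
        label = "positive"
    elif regime == "adhering":
        first, second = _place_adhering_pair(rng, config)
        occupied |= first | second
        masks = [first, second]
        masks += _place_separated(rng, config, occupied, config.n_pigs - 2)
        log.update(adhering_indices=(0, 1))
        label = "negative"
    else:
        masks = _place_separated(rng, config, occupied, config.n_pigs)
        label = "negative"

    instances = []
    for m in masks:
        im = InstanceMask(m)
        instances.append(PigInstance(mask=im, bbox=im.tight_bbox()))
    image = _render(rng, config, masks)
    record = FrameRecord(
        frame_id="synthetic", image_size=config.image_size, instances=instances, label=label
    )
    return SyntheticFrame(record=record, image=image, log=log)


# ---------------------------------------------------------------------------
# datasets


def simulate_dataset(
    config: SceneConfig, n_frames: int, positive_fraction: float = 0.5, seed: int = 0
) -> tuple[list[SyntheticFrame], dict]:
    """Generate a dataset with an exact positive count and a replay manifest.

    Exactly ``round(n_frames * positive_fraction)`` frames are mounting
    (positive); negatives draw adhering vs separated from the config's
    adhesion probability. The manifest records the config, every child
    seed and regime, and suffices to regenerate the dataset exactly.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction {positive_fraction} outside [0, 1]")
    n_pos = round(n_frames * positive_fraction)
    rng = np.random.default_rng([int(seed), 0])
    pos_at = np.zeros(n_frames, dtype=bool)
    pos_at[rng.permutation(n_frames)[:n_pos]] = True
    p_adhere = (
        config.adhesion_probability / (1.0 - config.mounting_probability)
        if config.mounting_probability < 1.0
        else 0.0
    )

    frames: list[SyntheticFrame] = []
    entries = []
    for i in range(n_frames):
        if pos_at[i]:
            regime = "mounting"
        else:
            regime = "adhering" if rng.random() < p_adhere else "separated"
        child_seed = [int(seed), i + 1]
        frame = simulate_frame(config, seed=child_seed, regime=regime)
        frame.record.frame_id = f"frame_{i:05d}"
        frames.append(frame)
        entries.append(
            {
                "frame_id": frame.record.frame_id,
                "seed": child_seed,
                "regime": regime,
                "label": frame.record.label,
                "overlap_achieved": frame.log.get("overlap_achieved"),
            }
        )
    manifest = {
        "config": asdict(config),
        "n_frames": n_frames,
        "positive_fraction": positive_fraction,
        "global_seed": int(seed),
        "frames": entries,
    }
    return frames, manifest


def dataset_from_manifest(manifest: dict) -> list[SyntheticFrame]:
    """Regenerate every frame of a dataset exactly from its manifest."""
    cfg = dict(manifest["config"])
    for key in ("image_size", "semi_major_range", "semi_minor_range", "orientation_range",
                "overlap_range"):
        cfg[key] = tuple(cfg[key])
    config = SceneConfig(**cfg)
    frames = []
    for entry in manifest["frames"]:
        frame = simulate_frame(config, seed=entry["seed"], regime=entry["regime"])
        frame.record.frame_id = entry["frame_id"]
        frames.append(frame)
    return frames


def export_dataset(
    frames: Sequence[SyntheticFrame],
    out_dir: str | Path,
    manifest: dict | None = None,
    overwrite: bool = False,
) -> None:
    """Write Labelme JSONs, PNG label masks and the labels CSV.

    The PNG + CSV pair round-trips exactly through :func:`import_dataset`;
    the Labelme JSONs carry sub-pixel contour outlines for interoperability
    with annotation tools (their re-rasterization is approximate).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame in frames:
        rec = frame.record
        write_labelme(rec, out_dir / f"{rec.frame_id}.json")
        write_mask_png([inst.mask for inst in rec.instances], out_dir / f"{rec.frame_id}_mask.png")
        rows.append({"frame_id": rec.frame_id, "label": rec.label})
    pd.DataFrame(rows, columns=["frame_id", "label"]).to_csv(out_dir / "labels.csv", index=False)
    if manifest is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def import_dataset(in_dir: str | Path) -> list[FrameRecord]:
    """Rebuild FrameRecords from an exported dataset (pixel-exact via PNGs)."""
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "labels.csv")
    records = []
    for row in labels.itertuples(index=False):
        masks = read_mask_png(in_dir / f"{row.frame_id}_mask.png")
        h, w = masks[0].shape
        instances = [PigInstance(mask=m, bbox=m.tight_bbox()) for m in masks]
        records.append(
            FrameRecord(
                frame_id=str(row.frame_id),
                image_size=(w, h),
                instances=instances,
                label=str(row.label),
            )
        )
    return records
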