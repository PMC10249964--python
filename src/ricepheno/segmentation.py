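"""Rule-based colour segmentation of side-view rice images.

A side-view RGB image is partitioned into background and plant by pixel
saturation (the imaging background is a low-saturation grey), and plant
pixels are classified as green or yellow by hue band. Yellowing is the
visual signature of senescence, so the green/yellow split drives the
Ypar (yellow-area-ratio) traits. Panicles are located as the topmost
yellow-leaning connected component in the upper part of the plant
bounding box: panicles sit atop the canopy and turn yellow as grain
matures.

Externally produced masks (e.g. from a neural segmenter) can be passed
through unchanged with ``source="external"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, morphology
from skimage.color import rgb2hsv


@dataclass
class PlantImage:
    """An RGB raster with acquisition metadata.

    ``rgb`` is an (H, W, 3) uint8 array. ``mm_per_px`` is the physical
    pixel pitch of the side view; ``organ_view`` is "plant" for
    whole-plant images and "culm" for post-harvest culm images.
    """

    rgb: np.ndarray
    plant_id: str = ""
    day: int = 0
    organ_view: str = "plant"
    mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.rgb)
        if a.ndim != 3 or a.shape[2] != 3:
            raise ValueError("PlantImage requires an (H, W, 3) RGB array")
        if a.size == 0:
            raise ValueError("empty image")
        self.rgb = a


@dataclass
class SegmentationConfig:
    """Thresholds for the colour rules.

    Hue bands are degrees on the usual HSV wheel: green defaults to
    [60, 180), yellow to [20, 60). Background is any pixel whose
    saturation falls below ``background_sat_max``. A single binary
    opening+closing with a square structuring element suppresses
    speckle before classification.
    """

    background_sat_max: float = 0.25
    green_hue_deg: tuple[float, float] = (60.0, 180.0)
    yellow_hue_deg: tuple[float, float] = (20.0, 60.0)
    morphology: bool = True
    selem_size: int = 3
    panicle_top_fraction: float = 0.40
    panicle_min_area_px: int = 25
    #: hue below which a plant pixel counts as "yellow-leaning" for the
    #: panicle rule; unripe panicles are straw/yellow-green, well below
    #: typical foliage hues (~95-130 deg)
    panicle_lean_hue_deg: float = 75.0

    def to_json(self, path: str | Path) -> None:
        d = {
            "background_sat_max": self.background_sat_max,
            "green_hue_deg": list(self.green_hue_deg),
            "yellow_hue_deg": list(self.yellow_hue_deg),
            "morphology": self.morphology,
            "selem_size": self.selem_size,
            "panicle_top_fraction": self.panicle_top_fraction,
            "panicle_min_area_px": self.panicle_min_area_px,
            "panicle_lean_hue_deg": self.panicle_lean_hue_deg,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentationConfig":
        d = json.loads(Path(path).read_text())
        d["green_hue_deg"] = tuple(d["green_hue_deg"])
        d["yellow_hue_deg"] = tuple(d["yellow_hue_deg"])
        return cls(**d)


@dataclass
class SegmentationResult:
    """Background/plant split with a green/yellow pixel partition.

    Invariants: ``green_mask | yellow_mask == plant_mask`` with the two
    classes disjoint (every plant pixel classified exactly once), and
    ``panicle_mask``, when present, is a subset of ``plant_mask``.
    """

    plant_mask: np.ndarray
    green_mask: np.ndarray
    yellow_mask: np.ndarray
    panicle_mask: np.ndarray | None = None
    source: str = "rule_based"

    def __post_init__(self) -> None:
        self.plant_mask = np.asarray(self.plant_mask, dtype=bool)
        self.green_mask = np.asarray(self.green_mask, dtype=bool)
        self.yellow_mask = np.asarray(self.yellow_mask, dtype=bool)
        if self.panicle_mask is not None:
            self.panicle_mask = np.asarray(self.panicle_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if not (self.plant_mask.shape == self.green_mask.shape == self.yellow_mask.shape):
            raise ValueError("mask shape mismatch")
        if np.any(self.green_mask & self.yellow_mask):
            raise ValueError("green and yellow masks overlap")
        if not np.array_equal(self.green_mask | self.yellow_mask, self.plant_mask):
            raise ValueError("green/yellow masks do not partition the plant mask")
        if self.panicle_mask is not None:
            if self.panicle_mask.shape != self.plant_mask.shape:
                raise ValueError("panicle mask shape mismatch")
            if np.any(self.panicle_mask & ~self.plant_mask):
                raise ValueError("panicle mask is not a subset of the plant mask")


@dataclass(frozen=True)
class SegMetrics:
    """The four binary-mask agreement indicators."""

    iou: float
    precision: float
    recall: float
    f_measure: float


def _hue_deg(hsv: np.ndarray) -> np.ndarray:
    return hsv[..., 0] * 360.0


def _circular_dist(h: np.ndarray, target: float) -> np.ndarray:
    d = np.abs(h - target) % 360.0
    return np.minimum(d, 360.0 - d)


def segment_plant(image: PlantImage, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Segment an RGB side-view image into background / green / yellow.

    Deterministic for a fixed image and config. Plant pixels whose hue
    falls in neither the green nor the yellow band are assigned to the
    nearer band boundary by circular hue distance, preserving the exact
    green/yellow partition of the plant mask.
    """
    cfg = config or SegmentationConfig()
    rgb = image.rgb
    if rgb.dtype != np.uint8:
        rgb = np.clip(np.asarray(rgb, dtype=float), 0, 255).astype(np.uint8)
    hsv = rgb2hsv(rgb)
    plant = hsv[..., 1] > cfg.background_sat_max

    if cfg.morphology and plant.any():
        selem = morphology.footprint_rectangle((cfg.selem_size, cfg.selem_size))
        plant = morphology.closing(morphology.opening(plant, selem), selem)

    hue = _hue_deg(hsv)
    g_lo, g_hi = cfg.green_hue_deg
    y_lo, y_hi = cfg.yellow_hue_deg
    in_green = (hue >= g_lo) & (hue < g_hi)
    in_yellow = (hue >= y_lo) & (hue < y_hi)
    green = plant & in_green
    yellow = plant & in_yellow & ~green
    # off-band plant pixels: nearest band boundary by circular hue distance
    rest = plant & ~green & ~yellow
    if rest.any():
        dg = np.minimum(_circular_dist(hue, g_lo), _circular_dist(hue, g_hi))
        dy = np.minimum(_circular_dist(hue, y_lo), _circular_dist(hue, y_hi))
        green |= rest & (dg < dy)
        yellow |= rest & ~(dg < dy)
    return SegmentationResult(plant, green, yellow, None, source="rule_based")


def segment_panicle(
    image: PlantImage,
    result: SegmentationResult,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Locate the panicle as the topmost yellow-leaning canopy component.

    Candidate pixels are plant pixels whose hue falls below
    ``panicle_lean_hue_deg`` (ripe panicles are yellow, unripe ones
    straw/yellow-green; foliage sits well above this hue) lying in the
    upper ``panicle_top_fraction`` of the plant bounding box; the
    topmost connected component of at least ``panicle_min_area_px``
    pixels is returned. An empty mask is a legal result (pre-heading
    images). The returned mask is always a subset of the plant mask.
    """
    cfg = config or SegmentationConfig()
    plant = result.plant_mask
    if plant.shape[:2] != image.rgb.shape[:2]:
        raise ValueError("mask/image shape mismatch")
    if not plant.any():
        raise ValueError("empty plant mask")
    rows = np.nonzero(plant.any(axis=1))[0]
    r0, r1 = rows[0], rows[-1]
    cutoff = r0 + cfg.panicle_top_fraction * (r1 - r0 + 1)
    upper = np.zeros_like(plant)
    upper[: int(np.ceil(cutoff)), :] = True
    rgb = image.rgb
    if rgb.dtype != np.uint8:
        rgb = np.clip(np.asarray(rgb, dtype=float), 0, 255).astype(np.uint8)
    hue = _hue_deg(rgb2hsv(rgb))
    cand = plant & upper & (hue < cfg.panicle_lean_hue_deg)
    out = np.zeros_like(plant)
    if not cand.any():
        return out
    labels = measure.label(cand, connectivity=2)
    best = None
    best_top = None
    for region in measure.regionprops(labels):
        if region.area < cfg.panicle_min_area_px:
            continue
        top = region.bbox[0]
        if best_top is None or top < best_top:
            best, best_top = region.label, top
    if best is None:
        return out
    out[labels == best] = True
    return out


def external_mask_result(
    plant_mask: np.ndarray,
    yellow_mask: np.ndarray | None = None,
    panicle_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Wrap externally supplied masks unchanged with ``source="external"``.

    When no yellow mask is supplied, all plant pixels are classed green.
    """
    plant = np.asarray(plant_mask, dtype=bool)
    yellow = (
        np.asarray(yellow_mask, dtype=bool) & plant
        if yellow_mask is not None
        else np.zeros_like(plant)
    )
    return SegmentationResult(plant, plant & ~yellow, yellow, panicle_mask, source="external")


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """IoU, precision, recall and F-measure of a predicted binary mask.

    ``iou = |pred ∩ truth| / |pred ∪ truth|``, ``precision`` and
    ``recall`` with the usual conventions; precision is defined as 0
    for an empty prediction, and ``f = 2pr/(p+r)`` (0 when p+r = 0).
    """
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if not t.any():
        raise ValueError("truth mask is empty")
    inter = float(np.count_nonzero(p & t))
    union = float(np.count_nonzero(p | t))
    np_pred = float(np.count_nonzero(p))
    nt = float(np.count_nonzero(t))
    iou = inter / union if union else 0.0
    precision = inter / np_pred if np_pred else 0.0
    recall = inter / nt
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return SegMetrics(iou=iou, precision=precision, recall=recall, f_measure=f)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    from PIL import Image

    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L")) > 127
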