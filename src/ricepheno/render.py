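"""Procedural side-view renderer with exact ground-truth masks.

The renderer draws a 2-D silhouette of a rice plant on a light grey
background: a tapering stack of centred pixel rows (culm plus canopy)
topped, after heading, by a rectangular panicle blob. It is built for
unambiguous ground truth, not photorealism: green and yellow pixels are
drawn from disjoint hue bands well inside the segmentation defaults,
and the exact plant/green/yellow/panicle masks are returned alongside
the image.

Geometric guarantees (the renderer's stated tolerances):

* plant pixel count equals ``round(TPA / scale^2)`` exactly;
* the mask's vertical extent equals ``round(height / scale)`` exactly;
* the yellow-pixel fraction is within one pixel-quantization unit
  (1/plant-pixel-count) of the requested Ypar;
* the drawn panicle area is within ``panicle_height + panicle_width``
  pixels of ``round(panicle_TPA / scale^2)``.

Yellow pixels are allocated to the panicle first (top-down) and then to
the base of the canopy bottom-up, emulating panicle maturation and
basal leaf senescence. Row widths change gradually and the base rows
are flat, so a 3x3 morphological opening leaves the silhouette nearly
unchanged.
"""

from __future__ import annotations

import numpy as np
from skimage.color import hsv2rgb

from .segmentation import PlantImage, SegmentationResult
from .synthetic import GrowthGroundTruth, PlantState

#: documented rasterization tolerances, in pixels
AREA_TOL_PX = 1
HEIGHT_TOL_PX = 1

_MIN_W = 3  # minimum row width; keeps the silhouette stable under 3x3 opening


def _row_widths(n_px: int, n_rows: int, top_w: float, taper: float) -> np.ndarray:
    """Integer centred-row widths summing exactly to ``n_px``.

    The profile tapers linearly from a wide base to ``top_w`` at the
    top; the bottom three rows share the base width. Largest-remainder
    rounding preserves the exact total.
    """
    if n_px < _MIN_W * n_rows:
        raise ValueError(
            f"plant too thin to draw: {n_px} px over {n_rows} rows "
            f"(needs >= {_MIN_W * n_rows}); increase scale or area"
        )
    # rows indexed bottom (0) to top (n_rows-1)
    pos = np.arange(n_rows, dtype=float)
    pos[:3] = 0.0  # flat base
    prof = 1.0 - taper * pos / max(n_rows - 1, 1)
    prof = np.maximum(prof, 1e-6)
    w = prof * (n_px / prof.sum())
    w = np.maximum(w, float(_MIN_W))
    # renormalize the slack above the minimum, then round preserving the sum
    for _ in range(40):
        excess = w.sum() - n_px
        free = w > _MIN_W
        if abs(excess) < 1e-9 or not free.any():
            break
        w[free] -= excess * (w[free] - _MIN_W) / (w[free] - _MIN_W).sum()
        w = np.maximum(w, float(_MIN_W))
    base = np.floor(w).astype(int)
    rem = int(round(n_px - base.sum()))
    if rem > 0:
        order = np.argsort(-(w - base), kind="stable")
        base[order[:rem]] += 1
    elif rem < 0:
        order = np.argsort(w - base, kind="stable")
        for r in order:
            if rem == 0:
                break
            if base[r] > _MIN_W:
                base[r] -= 1
                rem += 1
    if base.sum() != n_px:
        raise RuntimeError("row-width allocation failed to meet the pixel budget")
    return base


def render_plant_image(
    state: PlantState | GrowthGroundTruth,
    canvas: tuple[int, int] = (720, 460),
    scale: float = 2.0,
    seed: int | None = 0,
    day: int | None = None,
    plant_id: str = "plant",
) -> tuple[PlantImage, SegmentationResult]:
    """Render one side-view image plus its true segmentation masks.

    ``state`` may be a :class:`PlantState` or a ground truth (then
    ``day`` selects the state). A panicle blob is drawn iff the state
    is headed and its area rounds to at least one pixel.
    """
    if isinstance(state, GrowthGroundTruth):
        if day is None:
            raise ValueError("day is required when rendering from a GrowthGroundTruth")
        plant_id = state.plant_id
        state = state.state_at(day)
    if scale <= 0:
        raise ValueError("scale must be positive (mm per pixel)")
    H_px = int(round(state.height_mm / scale))
    N = int(round(state.tpa_mm2 / scale**2))
    Np = int(round(state.panicle_tpa_mm2 / scale**2)) if state.headed else 0
    ch, cw = canvas
    if H_px + 4 > ch:
        raise ValueError(f"plant height {H_px}px exceeds canvas height {ch}px at scale {scale}")
    if H_px < 6 or N < _MIN_W * H_px:
        raise ValueError("plant too small/thin at this scale; use a coarser scale")

    # ---- geometry: panicle rectangle atop a tapering canopy --------------
    if Np >= 5 * _MIN_W:
        hp = int(np.clip(round(0.18 * H_px), 3, H_px - 3))
        wp = max(Np // hp, _MIN_W)
        hp = max(Np // wp, 3)
        Np_drawn = wp * hp
    else:
        hp = wp = Np_drawn = 0
    Hv = H_px - hp
    Nv = N - Np_drawn
    widths_v = _row_widths(Nv, Hv, top_w=_MIN_W, taper=0.9)

    base_row = ch - 3  # bottom of the plant sits near the canvas bottom
    top_row = base_row - H_px + 1
    centre = cw // 2
    max_w = int(widths_v.max())
    if max(max_w, wp) + 2 > cw:
        raise ValueError("plant wider than canvas; enlarge canvas or coarsen scale")

    plant = np.zeros((ch, cw), dtype=bool)
    panicle = np.zeros((ch, cw), dtype=bool)
    # pixel orderings for yellow allocation
    veg_pixels: list[tuple[int, int]] = []  # bottom-up
    pan_pixels: list[tuple[int, int]] = []  # top-down
    for i in range(Hv):  # i = 0 at the base
        r = base_row - i
        w = int(widths_v[i])
        c0 = centre - w // 2
        plant[r, c0 : c0 + w] = True
        veg_pixels.extend((r, c) for c in range(c0, c0 + w))
    for j in range(hp):  # j = 0 at the very top
        r = top_row + j
        c0 = centre - wp // 2
        plant[r, c0 : c0 + wp] = True
        panicle[r, c0 : c0 + wp] = True
        pan_pixels.extend((r, c) for c in range(c0, c0 + wp))

    n_plant = int(plant.sum())
    assert n_plant == Nv + Np_drawn

    # ---- colour classes ---------------------------------------------------
    n_yellow = int(round(state.ypar * n_plant))
    yellow = np.zeros((ch, cw), dtype=bool)
    take_pan = min(n_yellow, len(pan_pixels))
    for r, c in pan_pixels[:take_pan]:
        yellow[r, c] = True
    for r, c in veg_pixels[: n_yellow - take_pan]:
        yellow[r, c] = True
    green = plant & ~yellow

    # ---- paint ------------------------------------------------------------
    rng = np.random.default_rng(seed)
    hsv = np.empty((ch, cw, 3), dtype=float)
    hsv[..., 0] = 0.0
    hsv[..., 1] = rng.uniform(0.00, 0.04, (ch, cw))  # grey background, near-zero saturation
    hsv[..., 2] = rng.uniform(0.80, 0.86, (ch, cw))
    foliage = green & ~panicle
    straw = green & panicle  # unripe panicle: straw/yellow-green, still green-class
    nf, ns, ny = int(foliage.sum()), int(straw.sum()), int(yellow.sum())
    hsv[..., 0][foliage] = rng.uniform(95 / 360, 125 / 360, nf)
    hsv[..., 1][foliage] = rng.uniform(0.65, 0.85, nf)
    hsv[..., 2][foliage] = rng.uniform(0.40, 0.65, nf)
    hsv[..., 0][straw] = rng.uniform(62 / 360, 72 / 360, ns)
    hsv[..., 1][straw] = rng.uniform(0.55, 0.75, ns)
    hsv[..., 2][straw] = rng.uniform(0.55, 0.75, ns)
    hsv[..., 0][yellow] = rng.uniform(38 / 360, 50 / 360, ny)
    hsv[..., 1][yellow] = rng.uniform(0.75, 0.90, ny)
    hsv[..., 2][yellow] = rng.uniform(0.70, 0.88, ny)
    rgb = (hsv2rgb(hsv) * 255).round().astype(np.uint8)

    img = PlantImage(rgb, plant_id=plant_id, day=state.day, organ_view="plant", mm_per_px=scale)
    truth = SegmentationResult(plant, green, yellow, panicle if Np_drawn else None, source="rule_based")
    return img, truth


def render_culm_image(
    gt: GrowthGroundTruth,
    canvas: tuple[int, int] = (720, 460),
    scale: float = 2.0,
    seed: int | None = 0,
) -> tuple[PlantImage, SegmentationResult]:
    """Render the post-harvest culm view: a part-yellow rectangle.

    The culm is drawn as a vertical rectangle with the planted height,
    area and yellow fraction (yellow allocated bottom-up).
    """
    H_px = int(round(gt.culm_height_mm / scale))
    N = int(round(gt.culm_tpa_mm2 / scale**2))
    ch, cw = canvas
    if H_px + 4 > ch or H_px < 3:
        raise ValueError("culm does not fit the canvas at this scale")
    w = max(N // H_px, _MIN_W)
    H_px = max(N // w, 3)
    plant = np.zeros((ch, cw), dtype=bool)
    base_row = ch - 3
    centre = cw // 2
    c0 = centre - w // 2
    plant[base_row - H_px + 1 : base_row + 1, c0 : c0 + w] = True
    n_plant = int(plant.sum())
    n_yellow = int(round(gt.culm_ypar * n_plant))
    yellow = np.zeros_like(plant)
    filled = 0
    for r in range(base_row, base_row - H_px, -1):
        if filled >= n_yellow:
            break
        take = min(w, n_yellow - filled)
        yellow[r, c0 : c0 + take] = True
        filled += take
    green = plant & ~yellow

    rng = np.random.default_rng(seed)
    hsv = np.empty((ch, cw, 3), dtype=float)
    hsv[..., 0] = 0.0
    hsv[..., 1] = rng.uniform(0.00, 0.04, (ch, cw))
    hsv[..., 2] = rng.uniform(0.80, 0.86, (ch, cw))
    ng, ny = int(green.sum()), int(yellow.sum())
    hsv[..., 0][green] = rng.uniform(95 / 360, 125 / 360, ng)
    hsv[..., 1][green] = rng.uniform(0.65, 0.85, ng)
    hsv[..., 2][green] = rng.uniform(0.40, 0.65, ng)
    hsv[..., 0][yellow] = rng.uniform(38 / 360, 50 / 360, ny)
    hsv[..., 1][yellow] = rng.uniform(0.75, 0.90, ny)
    hsv[..., 2][yellow] = rng.uniform(0.70, 0.88, ny)
    rgb = (hsv2rgb(hsv) * 255).round().astype(np.uint8)
    img = PlantImage(rgb, plant_id=gt.plant_id, day=gt.harvest_day, organ_view="culm", mm_per_px=scale)
    return img, SegmentationResult(plant, green, yellow, None)
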