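"""Per-image organ traits and grain-trait ingestion.

From a segmented side-view image the organ-dimension observables are
pixel counts and mask extents scaled to physical units: heights in mm
(rows x scale), projected areas in mm^2 (pixels x scale^2), and the
dimensionless colour ratios. Height is the full bounding-box row extent
of the mask and width the column extent.

The eight grain traits are produced by an external yield-traits scorer
and are ingested and validated only, never computed from images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult

GRAIN_COLUMNS = ["AveGL", "AveLW", "AveGW", "TFN", "Wper1000", "W", "SF", "GN"]


class EmptyPlantError(ValueError):
    """Raised when a trait is requested on an empty plant mask."""


@dataclass
class OrganTraits:
    """Per-image organ observables for one plant on one imaging day.

    Plant fields are in mm / mm^2 after scale calibration (or px / px^2
    when ``units == "px"``); panicle fields are zero when no panicle is
    visible; culm fields are populated only from culm-view images.
    """

    plant_id: str = ""
    day: int = 0
    units: str = "mm"
    PlantH: float = np.nan
    PlantTPA: float = np.nan
    PlantHWr: float = np.nan
    PlantTPAHr: float = np.nan
    PlantYpar: float = np.nan
    PlantYPA: float = np.nan
    PlantGPA: float = np.nan
    PanicleTPA: float = 0.0
    PanicleTpar: float = 0.0
    PanicleYpar: float = 0.0
    PanicleYPA: float = 0.0
    culmH: float = np.nan
    culmTPA: float = np.nan
    culmTPAHr: float = np.nan
    culmGpar: float = np.nan
    culmYpar: float = np.nan
    culmPHr: float = np.nan


def _mask_extents(mask: np.ndarray) -> tuple[int, int, int]:
    """(height_px, width_px, area_px) of a boolean mask's bounding box."""
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    h = int(rows[-1] - rows[0] + 1)
    w = int(cols[-1] - cols[0] + 1)
    return h, w, int(np.count_nonzero(mask))


def compute_plant_traits(
    seg: SegmentationResult,
    scale: float,
    plant_id: str = "",
    day: int = 0,
    units: str = "mm",
) -> OrganTraits:
    """Whole-plant traits from a segmentation result.

    PlantH and width are bounding-box extents times ``scale`` (mm/px);
    PlantTPA is the plant pixel count times ``scale**2``; the yellow and
    green projected areas partition PlantTPA exactly. Pass ``scale=1,
    units="px"`` for the uncalibrated pixel mode.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (mm per pixel)")
    if not seg.plant_mask.any():
        raise EmptyPlantError("empty plant mask: no plant pixels to measure")
    h_px, w_px, n_px = _mask_extents(seg.plant_mask)
    if w_px == 0:  # unreachable for a nonempty mask; guards ratio below
        raise ValueError("zero plant width")
    n_yellow = int(np.count_nonzero(seg.yellow_mask))
    t = OrganTraits(plant_id=plant_id, day=day, units=units)
    t.PlantH = h_px * scale
    width = w_px * scale
    t.PlantTPA = n_px * scale**2
    t.PlantHWr = t.PlantH / width
    t.PlantTPAHr = t.PlantTPA / t.PlantH
    t.PlantYPA = n_yellow * scale**2
    t.PlantGPA = t.PlantTPA - t.PlantYPA
    t.PlantYpar = t.PlantYPA / t.PlantTPA
    return t


def compute_panicle_traits(
    seg: SegmentationResult,
    scale: float,
    traits: OrganTraits | None = None,
) -> OrganTraits:
    """Panicle traits from the panicle submask; all zero when absent.

    PanicleTpar is the panicle/whole-plant projected-area ratio and
    PanicleYpar the yellow fraction within the panicle mask.
    """
    if not seg.plant_mask.any():
        raise EmptyPlantError("empty plant mask")
    t = traits if traits is not None else compute_plant_traits(seg, scale)
    pan = seg.panicle_mask
    if pan is None or not pan.any():
        t.PanicleTPA = t.PanicleTpar = t.PanicleYpar = t.PanicleYPA = 0.0
        return t
    if np.any(pan & ~seg.plant_mask):
        raise ValueError("panicle mask is not contained in the plant mask")
    n_pan = int(np.count_nonzero(pan))
    n_pan_yellow = int(np.count_nonzero(pan & seg.yellow_mask))
    t.PanicleTPA = n_pan * scale**2
    t.PanicleTpar = t.PanicleTPA / t.PlantTPA
    t.PanicleYPA = n_pan_yellow * scale**2
    t.PanicleYpar = n_pan_yellow / n_pan
    return t


def compute_culm_traits(
    seg: SegmentationResult,
    scale: float,
    plant_height: float,
    plant_id: str = "",
) -> OrganTraits:
    """Culm traits from a culm-view segmentation.

    culmPHr relates the culm height to the whole-plant height measured
    on the last pre-harvest plant image.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (mm per pixel)")
    if not seg.plant_mask.any():
        raise EmptyPlantError("empty culm mask")
    if plant_height <= 0:
        raise ValueError("plant_height must be positive")
    h_px, _, n_px = _mask_extents(seg.plant_mask)
    n_yellow = int(np.count_nonzero(seg.yellow_mask))
    t = OrganTraits(plant_id=plant_id)
    t.culmH = h_px * scale
    t.culmTPA = n_px * scale**2
    t.culmTPAHr = t.culmTPA / t.culmH
    t.culmYpar = n_yellow / n_px
    t.culmGpar = 1.0 - t.culmYpar
    t.culmPHr = t.culmH / plant_height
    return t


def load_grain_traits(path: str | Path | pd.DataFrame, sf_tol: float = 0.02) -> pd.DataFrame:
    """Read and validate the 8-column grain-trait table.

    Requires columns AveGL, AveLW, AveGW, TFN, Wper1000, W, SF, GN keyed
    by plant_id. Hard errors: missing column, non-numeric cell, SF
    outside [0, 1], GN > TFN. Soft consistency checks add entries to a
    ``flags`` column and emit warnings: |SF - GN/TFN| > ``sf_tol``,
    |W - GN*Wper1000/1000|/W > 0.1, and AveLW deviating from
    AveGL/AveGW by more than 5%.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, comment="#")
    if "plant_id" not in df.columns:
        raise ValueError("grain table must have a plant_id column")
    missing = [c for c in GRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grain table missing columns: {missing}")
    df = df.set_index("plant_id") if df.index.name != "plant_id" else df
    for c in GRAIN_COLUMNS:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any() and not df[c].isna().any():
            bad = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric value in column {c!r} at plant {bad!r}")
        df[c] = coerced
    if ((df["SF"] < 0) | (df["SF"] > 1)).any():
        bad = df.index[(df["SF"] < 0) | (df["SF"] > 1)][0]
        raise ValueError(f"SF out of [0, 1] at plant {bad!r}")
    if (df["GN"] > df["TFN"]).any():
        bad = df.index[df["GN"] > df["TFN"]][0]
        raise ValueError(f"GN exceeds TFN at plant {bad!r} (filled grains cannot outnumber spikelets)")

    flags = pd.Series([""] * len(df), index=df.index, dtype=object)
    with np.errstate(divide="ignore", invalid="ignore"):
        sf_calc = df["GN"] / df["TFN"]
        sf_bad = (df["SF"] - sf_calc).abs() > sf_tol
        w_calc = df["GN"] * df["Wper1000"] / 1000.0
        w_bad = ((df["W"] - w_calc).abs() / df["W"].abs()) > 0.1
        lw_calc = df["AveGL"] / df["AveGW"]
        lw_bad = ((df["AveLW"] - lw_calc).abs() / lw_calc.abs()) > 0.05
    for name, bad in [("SF!=GN/TFN", sf_bad), ("W!=GN*Wper1000/1000", w_bad), ("AveLW!=AveGL/AveGW", lw_bad)]:
        if bad.fillna(False).any():
            warnings.warn(
                f"grain-trait consistency: {name} for {int(bad.sum())} plant(s)",
                stacklevel=2,
            )
            flags[bad.fillna(False)] = flags[bad.fillna(False)].where(
                flags[bad.fillna(False)] == "", flags[bad.fillna(False)] + ";"
            ) + name
    df["flags"] = flags
    return df
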