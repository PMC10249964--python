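"""Temporal-dimension traits from per-plant imaging time series.

Each plant is imaged repeatedly through the season; the per-image organ
observables form a time series from which three families of traits are
derived:

* 12 phenological "days-to-event" traits (argmax days of the observed
  series, heading onset, senescence onset);
* 10 plant and 10 panicle growth traits: mean daily increase over the
  ascending phase, plus the coefficients of quadratic trajectory fits
  TPA(t) = a t^2 + b t + c and Ypar(t) = a t^2 + b t + c (the quadratic
  family describes rice growth and senescence trends best among the
  candidate models, so its coefficients are themselves traits);
* the scalarization of per-image organ observables into single
  season-level values (seasonal maxima).

Panicle phenology is reported relative to heading; panicle trajectory
fits use the post-heading subseries only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .organ_traits import GRAIN_COLUMNS, OrganTraits

#: default heading rule: panicle projected area above this value (mm^2)
#: on two consecutive imaging days marks heading
HEADING_THRESHOLD_MM2 = 100.0
HEADING_CONSECUTIVE = 2


@dataclass
class TraitTimeSeries:
    """Ordered per-day organ observables for one plant.

    Days are after sowing (sowing = day 0) and must be strictly
    increasing; quadratic trajectory fits need at least 4 observations.
    """

    plant_id: str
    observations: dict[int, OrganTraits]
    harvest_day: int
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        days = list(self.observations)
        if any(b <= a for a, b in zip(days, days[1:])):
            self.observations = dict(sorted(self.observations.items()))
            days = list(self.observations)
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("observation days must be strictly increasing")

    @property
    def days(self) -> list[int]:
        return list(self.observations)

    def values(self, trait: str) -> np.ndarray:
        return np.array([getattr(o, trait) for o in self.observations.values()], dtype=float)


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares fit of y = a t^2 + b t + c."""

    a: float
    b: float
    c: float
    r2: float
    mape: float
    n_points: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(t, float) ** 2 + self.b * np.asarray(t, float) + self.c

    @property
    def vertex_day(self) -> float:
        """Stationary point of the parabola; inf when a == 0."""
        if self.a == 0:
            return np.inf if self.b >= 0 else -np.inf
        return -self.b / (2.0 * self.a)


def fit_quadratic(days, values) -> QuadraticFit:
    """OLS on the monomial basis {t^2, t, 1}.

    Requires >= 4 points with at least two distinct days; MAPE is
    computed over the nonzero observations (NaN when all are zero).
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("days and values must be 1-D arrays of equal length")
    if len(t) < 4:
        raise ValueError(f"quadratic fit needs >= 4 points, got {len(t)}")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise ValueError("non-finite input to quadratic fit")
    if np.all(t == t[0]):
        raise ValueError("all days identical; cannot fit a trajectory")
    a, b, c = np.polyfit(t, y, 2)
    yhat = a * t**2 + b * t + c
    ssres = float(np.sum((y - yhat) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else np.nan
    nz = y != 0
    mape = float(np.mean(np.abs((y[nz] - yhat[nz]) / y[nz])) * 100.0) if nz.any() else np.nan
    return QuadraticFit(float(a), float(b), float(c), r2, mape, len(t))


def _argmax_day(days: np.ndarray, values: np.ndarray) -> float:
    """Day of the observed maximum; earliest day on ties; NaN if empty."""
    ok = np.isfinite(values)
    if not ok.any():
        return np.nan
    d, v = days[ok], values[ok]
    return float(d[int(np.argmax(v))])  # argmax returns the first maximum


def detect_heading(
    series: TraitTimeSeries,
    threshold_mm2: float = HEADING_THRESHOLD_MM2,
    consecutive: int = HEADING_CONSECUTIVE,
) -> float:
    """First imaging day whose PanicleTPA exceeds the heading threshold.

    The exceedance must hold on ``consecutive`` successive imaging days
    (a single-day spike is not heading); the last observation may
    satisfy the rule on its own. Returns NaN when no heading is found.
    """
    days = np.asarray(series.days, dtype=float)
    pan = series.values("PanicleTPA")
    above = pan > threshold_mm2
    n = len(days)
    for i in range(n):
        if not above[i]:
            continue
        run = above[i : min(i + consecutive, n)]
        if run.all():
            return float(days[i])
    return np.nan


def derive_phenological(
    series: TraitTimeSeries,
    heading_threshold_mm2: float = HEADING_THRESHOLD_MM2,
) -> dict[str, float]:
    """The 12 phenological traits of one plant.

    Argmax-day traits use the earliest day on ties; panicle argmax days
    are reported relative to heading (HS); the senescence onset PlantSD
    is the vertex day of the fitted plant-Ypar quadratic, clamped into
    the observation window.
    """
    days = np.asarray(series.days, dtype=float)
    out: dict[str, float] = {}
    out["GP"] = float(series.harvest_day)
    hs = detect_heading(series, heading_threshold_mm2)
    out["HS"] = hs
    out["PlantHD"] = _argmax_day(days, series.values("PlantH"))
    out["PlantTPAD"] = _argmax_day(days, series.values("PlantTPA"))
    out["PlantYparD"] = _argmax_day(days, series.values("PlantYpar"))
    out["PlantYPAD"] = _argmax_day(days, series.values("PlantYPA"))
    out["PlantGPAD"] = _argmax_day(days, series.values("PlantGPA"))
    if np.isnan(hs):
        warnings.warn(
            f"plant {series.plant_id!r}: no heading detected; panicle phenology set to missing",
            stacklevel=2,
        )
        for k in ("PanicleTPAD", "PanicleTparD", "PanicleYparD", "PanicleYPAD"):
            out[k] = np.nan
    else:
        for k, trait in (
            ("PanicleTPAD", "PanicleTPA"),
            ("PanicleTparD", "PanicleTpar"),
            ("PanicleYparD", "PanicleYpar"),
            ("PanicleYPAD", "PanicleYPA"),
        ):
            out[k] = _argmax_day(days, series.values(trait)) - hs
    # senescence onset: vertex of the fitted Ypar parabola, clamped
    try:
        fit = fit_quadratic(days, series.values("PlantYpar"))
        out["PlantSD"] = float(np.clip(fit.vertex_day, days[0], days[-1]))
    except ValueError:
        out["PlantSD"] = np.nan
    return out


def _daily_growth(days: np.ndarray, values: np.ndarray, label: str) -> float:
    """Mean daily increase from first observation to the observed maximum."""
    ok = np.isfinite(values)
    if ok.sum() < 2:
        return np.nan
    d, v = days[ok], values[ok]
    i = int(np.argmax(v))
    if d[i] == d[0]:
        warnings.warn(f"{label}: maximum at the first observation; daily growth set to 0", stacklevel=3)
        return 0.0
    return float((v[i] - v[0]) / (d[i] - d[0]))


def derive_growth_traits(
    series: TraitTimeSeries,
    heading_threshold_mm2: float = HEADING_THRESHOLD_MM2,
) -> dict[str, float]:
    """The 10 plant and 10 panicle growth traits, plus PaicleEndTPA.

    Daily-growth traits are the mean daily increase over the ascending
    phase (first observation to observed maximum). Coefficient traits
    come from quadratic trajectory fits; panicle fits and growth rates
    use the post-heading subseries only.
    """
    days = np.asarray(series.days, dtype=float)
    out: dict[str, float] = {}
    pid = series.plant_id

    for key, trait in (
        ("PlantHG", "PlantH"),
        ("PlantTPAG", "PlantTPA"),
        ("PlantYparG", "PlantYpar"),
        ("PlantYPAG", "PlantYPA"),
    ):
        out[key] = _daily_growth(days, series.values(trait), f"{pid}:{key}")

    for prefix, trait in (("PlantTPA", "PlantTPA"), ("PlantYpar", "PlantYpar")):
        try:
            fit = fit_quadratic(days, series.values(trait))
            out[f"{prefix}_a"], out[f"{prefix}_b"], out[f"{prefix}_c"] = fit.a, fit.b, fit.c
        except ValueError:
            out[f"{prefix}_a"] = out[f"{prefix}_b"] = out[f"{prefix}_c"] = np.nan

    hs = detect_heading(series, heading_threshold_mm2)
    pan_tpa = series.values("PanicleTPA")
    post = (days >= hs) if not np.isnan(hs) else np.zeros_like(days, dtype=bool)
    pdays = days[post]
    for key, trait in (
        ("PanicleTPAG", "PanicleTPA"),
        ("PanicleTparG", "PanicleTpar"),
        ("PanicleYparG", "PanicleYpar"),
        ("PanicleYPAG", "PanicleYPA"),
    ):
        vals = series.values(trait)[post]
        out[key] = _daily_growth(pdays, vals, f"{pid}:{key}") if post.any() else np.nan

    for prefix, trait in (("PanicleTPA", "PanicleTPA"), ("PanicleYpar", "PanicleYpar")):
        try:
            fit = fit_quadratic(pdays, series.values(trait)[post])
            out[f"{prefix}_a"], out[f"{prefix}_b"], out[f"{prefix}_c"] = fit.a, fit.b, fit.c
        except ValueError:
            out[f"{prefix}_a"] = out[f"{prefix}_b"] = out[f"{prefix}_c"] = np.nan

    # final pre-harvest panicle area
    pre = days <= series.harvest_day
    out["PaicleEndTPA"] = float(pan_tpa[pre][-1]) if pre.any() else np.nan
    return out


def scalarize_organ_traits(series: TraitTimeSeries) -> dict[str, float]:
    """Season-level organ traits from the per-image series.

    Every plant/panicle observable is summarized as its seasonal
    maximum (PaicleEndTPA, the final pre-harvest panicle area, is set
    in :func:`derive_growth_traits`).
    """
    out: dict[str, float] = {}
    for trait in (
        "PlantH",
        "PlantTPA",
        "PlantHWr",
        "PlantTPAHr",
        "PlantYpar",
        "PlantYPA",
        "PlantGPA",
        "PanicleTPA",
        "PanicleTpar",
        "PanicleYpar",
        "PanicleYPA",
    ):
        v = series.values(trait)
        ok = np.isfinite(v)
        out[trait] = float(np.max(v[ok])) if ok.any() else np.nan
    return out


def derive_plant_row(
    series: TraitTimeSeries,
    culm: OrganTraits | None = None,
    heading_threshold_mm2: float = HEADING_THRESHOLD_MM2,
) -> dict[str, float]:
    """All 50 non-grain registry traits for one plant."""
    row: dict[str, float] = {}
    row.update(scalarize_organ_traits(series))
    row.update(derive_phenological(series, heading_threshold_mm2))
    row.update(derive_growth_traits(series, heading_threshold_mm2))
    for c in ("culmH", "culmTPA", "culmTPAHr", "culmGpar", "culmYpar", "culmPHr"):
        row[c] = getattr(culm, c) if culm is not None else np.nan
    return row


def assemble_itrait_table(
    plant_rows: dict[str, dict[str, float]],
    grain_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the plants x 58-trait table in registry column order.

    ``plant_rows`` maps plant_id to the 50 image-derived traits (from
    :func:`derive_plant_row`); grain traits are joined from the
    validated grain table. Missing values stay as NaN; a plant that
    never headed keeps its row with panicle cells missing.
    """
    if len(set(plant_rows)) != len(plant_rows):
        raise ValueError("duplicate plant ids")
    df = pd.DataFrame.from_dict(plant_rows, orient="index")
    df.index.name = "plant_id"
    if grain_table is not None:
        unknown = [p for p in grain_table.index if p not in df.index]
        if unknown:
            raise ValueError(f"grain table contains unknown plant(s): {unknown[:5]}")
        if grain_table.index.has_duplicates:
            raise ValueError("duplicate plant rows in grain table")
        for c in GRAIN_COLUMNS:
            df[c] = grain_table[c].reindex(df.index)
    cols = registry.trait_names()
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]
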