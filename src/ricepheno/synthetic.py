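"""Synthetic growth trajectories and cohorts with known ground truth.

The generator emulates the study design the pipeline targets: potted
rice imaged side-on roughly weekly from day 42 to day 182 after sowing.
Whole-plant projected area (TPA, a biomass proxy) and the yellow-area
ratio (Ypar, a senescence index) follow quadratic trajectories; the
panicle appears at a heading day and its area and yellowing follow
quadratics anchored at zero at heading; plant height rises linearly to
a peak day and then plateaus. Observation noise is additive Gaussian
per observable, truncated so that areas stay nonnegative and ratios
stay in [0, 1].

Cohorts draw per-plant trajectory parameters around these defaults,
derive the 58-trait table with the same machinery used on real series,
and plant a *linear* yield signal y = beta . traits + noise so that
stepwise recovery has a known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import registry, temporal
from .organ_traits import GRAIN_COLUMNS, OrganTraits
from .temporal import TraitTimeSeries

#: default imaging schedule: every 7 days from day 42 to day 182
DEFAULT_DAYS: tuple[int, ...] = tuple(range(42, 183, 7))


def _quad(coeffs: tuple[float, float, float], t: np.ndarray) -> np.ndarray:
    a, b, c = coeffs
    return a * np.asarray(t, float) ** 2 + b * np.asarray(t, float) + c


def quad_through(peak_value: float, peak_day: float, zero_day: float, zero_value: float = 0.0):
    """Coefficients of the parabola with vertex (peak_day, peak_value)
    passing through (zero_day, zero_value)."""
    a = (zero_value - peak_value) / (zero_day - peak_day) ** 2
    b = -2.0 * a * peak_day
    c = peak_value + a * peak_day**2
    return (float(a), float(b), float(c))


@dataclass
class GrowthGroundTruth:
    """Planted trajectory parameters for one plant.

    Quadratic coefficients are (a, b, c) of y(t) = a t^2 + b t + c over
    days after sowing; panicle coefficients are valid for t >=
    heading_day (panicle observables are exactly zero before heading).
    ``noise_sd`` holds per-observable Gaussian noise scales.
    """

    plant_id: str = "plant"
    tpa_coeffs: tuple[float, float, float] = quad_through(110_000.0, 130.0, 42.0, 8_000.0)
    ypar_coeffs: tuple[float, float, float] = quad_through(0.01, 70.0, 182.0, 0.50)
    heading_day: int = 85
    harvest_day: int = 182
    height_max_mm: float = 1_100.0
    height_peak_day: int = 120
    canopy_aspect: float = 2.5  # height/width ratio of the side-view silhouette
    panicle_tpa_coeffs: tuple[float, float, float] = quad_through(12_000.0, 175.0, 85.0)
    panicle_ypar_coeffs: tuple[float, float, float] = quad_through(0.90, 180.0, 85.0)
    culm_height_mm: float = 600.0
    culm_tpa_mm2: float = 9_000.0
    culm_ypar: float = 0.35
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "height": 0.0,
            "tpa": 0.0,
            "ypar": 0.0,
            "panicle_tpa": 0.0,
            "panicle_ypar": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.heading_day >= self.harvest_day:
            raise ValueError("heading_day must precede harvest_day")
        if any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("noise_sd values must be nonnegative")

    # ---- noiseless curves -------------------------------------------------
    def height(self, t):
        t = np.asarray(t, float)
        return self.height_max_mm * np.minimum(t, self.height_peak_day) / self.height_peak_day

    def tpa(self, t):
        return _quad(self.tpa_coeffs, t)

    def ypar(self, t):
        return np.clip(_quad(self.ypar_coeffs, t), 0.0, 1.0)

    def panicle_tpa(self, t):
        t = np.asarray(t, float)
        return np.where(t >= self.heading_day, np.maximum(_quad(self.panicle_tpa_coeffs, t), 0.0), 0.0)

    def panicle_ypar(self, t):
        t = np.asarray(t, float)
        return np.where(
            t >= self.heading_day, np.clip(_quad(self.panicle_ypar_coeffs, t), 0.0, 1.0), 0.0
        )

    def state_at(self, day: int) -> "PlantState":
        return PlantState(
            day=int(day),
            height_mm=float(self.height(day)),
            tpa_mm2=float(self.tpa(day)),
            ypar=float(self.ypar(day)),
            panicle_tpa_mm2=float(self.panicle_tpa(day)),
            panicle_ypar=float(self.panicle_ypar(day)),
            headed=day >= self.heading_day,
        )


@dataclass(frozen=True)
class PlantState:
    """Noiseless single-day evaluation of a :class:`GrowthGroundTruth`."""

    day: int
    height_mm: float
    tpa_mm2: float
    ypar: float
    panicle_tpa_mm2: float
    panicle_ypar: float
    headed: bool


def simulate_growth_series(
    ground_truth: GrowthGroundTruth,
    days=DEFAULT_DAYS,
    seed: int | None = 0,
    noise_sd: dict[str, float] | float | None = None,
) -> TraitTimeSeries:
    """Simulate the per-day organ observables of one plant.

    Each observation is the noiseless planted curve plus Gaussian noise
    (scales from ``ground_truth.noise_sd`` unless overridden; a scalar
    override is applied to TPA and panicle TPA in mm^2 and to heights
    in mm, with ratio noise scaled down by 1e-4). Panicle observables
    are exactly zero before heading. The ground truth is kept on the
    returned series for recovery tests.
    """
    gt = ground_truth
    days = list(days)
    if not days:
        raise ValueError("empty day list")
    if any(b <= a for a, b in zip(days, days[1:])) or any(d < 0 for d in days):
        raise ValueError("days must be sorted ascending and nonnegative")
    if days[-1] > gt.harvest_day:
        raise ValueError(
            f"day {days[-1]} is beyond harvest_day {gt.harvest_day}: the plant is no longer standing"
        )
    sd = dict(gt.noise_sd)
    if noise_sd is not None:
        if np.isscalar(noise_sd):
            s = float(noise_sd)
            sd = {"height": s, "tpa": s, "ypar": s * 1e-4, "panicle_tpa": s, "panicle_ypar": s * 1e-4}
        else:
            sd.update(noise_sd)
    rng = np.random.default_rng(seed)
    obs: dict[int, OrganTraits] = {}
    for d in days:
        h = float(gt.height(d)) + rng.normal(0.0, sd["height"]) if sd["height"] else float(gt.height(d))
        tpa = max(float(gt.tpa(d)) + (rng.normal(0.0, sd["tpa"]) if sd["tpa"] else 0.0), 1.0)
        ypar = float(np.clip(gt.ypar(d) + (rng.normal(0.0, sd["ypar"]) if sd["ypar"] else 0.0), 0.0, 1.0))
        if d >= gt.heading_day:
            ptpa = float(gt.panicle_tpa(d)) + (rng.normal(0.0, sd["panicle_tpa"]) if sd["panicle_tpa"] else 0.0)
            ptpa = max(ptpa, 0.0)
            pypar = float(
                np.clip(
                    gt.panicle_ypar(d) + (rng.normal(0.0, sd["panicle_ypar"]) if sd["panicle_ypar"] else 0.0),
                    0.0,
                    1.0,
                )
            )
        else:
            ptpa, pypar = 0.0, 0.0
        h = max(h, 1.0)
        width = h / gt.canopy_aspect
        o = OrganTraits(plant_id=gt.plant_id, day=int(d))
        o.PlantH = h
        o.PlantTPA = tpa
        o.PlantHWr = h / width
        o.PlantTPAHr = tpa / h
        o.PlantYpar = ypar
        o.PlantYPA = ypar * tpa
        o.PlantGPA = tpa - o.PlantYPA
        o.PanicleTPA = ptpa
        o.PanicleTpar = ptpa / tpa
        o.PanicleYpar = pypar
        o.PanicleYPA = pypar * ptpa
        obs[int(d)] = o
    return TraitTimeSeries(gt.plant_id, obs, gt.harvest_day, ground_truth=gt)


def culm_organ_traits(gt: GrowthGroundTruth) -> OrganTraits:
    """Noiseless culm observables implied by the ground truth."""
    t = OrganTraits(plant_id=gt.plant_id)
    t.culmH = gt.culm_height_mm
    t.culmTPA = gt.culm_tpa_mm2
    t.culmTPAHr = gt.culm_tpa_mm2 / gt.culm_height_mm
    t.culmYpar = gt.culm_ypar
    t.culmGpar = 1.0 - gt.culm_ypar
    t.culmPHr = gt.culm_height_mm / gt.height_max_mm
    return t


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_GROUPS: dict[str, dict] = {
    # indica accessions senesce earlier and head earlier than japonica
    "indica": {"fraction": 0.34, "offsets": {"PlantYpar": 0.05, "HS": -5.0}, "latitude": (25.0, 4.0)},
    "japonica": {"fraction": 0.66, "offsets": {}, "latitude": (40.0, 5.0)},
}

DEFAULT_YIELD_BETA: dict[str, float] = {
    # most of the planted yield signal runs through panicle size and
    # panicle growth/maturation, the strongest yield correlates in rice
    "PanicleTPAG": 0.35,
    "PanicleYpar_a": 300_000.0,
    "PanicleTPA": 0.0015,
    "AveGL": 0.8,
}

#: per-observable measurement noise a segmentation-based imaging platform
#: would show (~1-2% of the typical signal)
DEFAULT_OBSERVATION_NOISE: dict[str, float] = {
    "height": 8.0,
    "tpa": 1_500.0,
    "ypar": 0.010,
    "panicle_tpa": 300.0,
    "panicle_ypar": 0.015,
}


@dataclass
class CohortSpec:
    """Population-level generator settings.

    ``groups`` maps a label to a dict with keys ``fraction`` (share of
    plants), ``offsets`` (trait-name -> additive mean shift applied to
    the derived trait columns) and ``latitude`` ((mean, sd) of the
    per-plant breeding-region latitude). ``yield_beta`` names must
    resolve to registry traits; the planted yield is
    y = intercept + sum(beta * trait) + N(0, yield_noise_sd).
    """

    n_plants: int = 93
    groups: dict[str, dict] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUPS.items()})
    yield_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YIELD_BETA))
    yield_intercept: float = 5.0
    yield_noise_sd: float = 1.2
    days: tuple[int, ...] = DEFAULT_DAYS
    observation_noise: dict[str, float] | float | None = field(
        default_factory=lambda: dict(DEFAULT_OBSERVATION_NOISE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.yield_noise_sd < 0:
            raise ValueError("yield_noise_sd must be nonnegative")
        unknown = [k for k in self.yield_beta if k not in registry.trait_names()]
        if unknown:
            raise ValueError(f"yield_beta names not in the trait registry: {unknown}")
        for g, cfg in self.groups.items():
            bad = [k for k in cfg.get("offsets", {}) if k not in registry.trait_names()]
            if bad:
                raise ValueError(f"group {g!r} offsets name unknown traits: {bad}")


def sample_ground_truth(rng: np.random.Generator, plant_id: str) -> GrowthGroundTruth:
    """Draw one plant's trajectory parameters around the cohort defaults.

    Relative jitter is ~5-8% on sizes and a few days on timings, the
    between-accession spread a modest greenhouse panel would show.
    """
    tpa_peak = rng.normal(110_000.0, 7_000.0)
    tpa_peak_day = rng.normal(130.0, 5.0)
    tpa_start = rng.normal(8_000.0, 700.0)
    ypar_onset = rng.normal(70.0, 4.0)
    ypar_end = float(np.clip(rng.normal(0.50, 0.04), 0.2, 0.8))
    heading = int(np.clip(round(rng.normal(85.0, 3.0)), 70, 110))
    pan_peak = rng.normal(12_000.0, 700.0)
    pan_peak_day = heading + rng.normal(90.0, 4.0)
    pan_ypar_end = float(np.clip(rng.normal(0.90, 0.03), 0.5, 1.0))
    height = rng.normal(1_100.0, 70.0)
    height_peak = int(np.clip(round(rng.normal(120.0, 5.0)), 90, 150))
    culm_h = float(np.clip(rng.normal(0.55, 0.04), 0.3, 0.8)) * height
    harvest = 182 + int(rng.integers(0, 9))
    return GrowthGroundTruth(
        plant_id=plant_id,
        tpa_coeffs=quad_through(tpa_peak, tpa_peak_day, 42.0, tpa_start),
        ypar_coeffs=quad_through(0.01, ypar_onset, 182.0, ypar_end),
        heading_day=heading,
        harvest_day=harvest,
        height_max_mm=height,
        height_peak_day=height_peak,
        canopy_aspect=float(np.clip(rng.normal(2.5, 0.2), 1.5, 4.0)),
        panicle_tpa_coeffs=quad_through(pan_peak, pan_peak_day, heading),
        panicle_ypar_coeffs=quad_through(pan_ypar_end, heading + 95.0, heading),
        culm_height_mm=culm_h,
        culm_tpa_mm2=rng.normal(9_000.0, 700.0),
        culm_ypar=float(np.clip(rng.normal(0.35, 0.05), 0.05, 0.9)),
    )


def _sample_grain_row(rng: np.random.Generator) -> dict[str, float]:
    gl = rng.normal(8.5, 0.5)
    gw = rng.normal(2.8, 0.2)
    tfn = max(int(round(rng.normal(1_600.0, 220.0))), 200)
    sf = float(np.clip(rng.normal(0.85, 0.05), 0.4, 0.99))
    gn = int(round(tfn * sf))
    w1000 = rng.normal(24.0, 2.0)
    return {
        "AveGL": gl,
        "AveGW": gw,
        "AveLW": gl / gw,
        "TFN": tfn,
        "SF": gn / tfn,
        "GN": gn,
        "Wper1000": w1000,
        "W": gn * w1000 / 1000.0,
    }


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Simulate a cohort: (trait table, yield, group labels, latitudes).

    Per plant, trajectory parameters are drawn, the imaging series is
    generated, and the 58 traits are derived with the production
    machinery; group offsets are then added to the designated trait
    means, and the planted yield replaces the grain-table W (GN is made
    consistent with it). Identical spec + seed reproduce the tables
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.groups)
    fracs = np.array([spec.groups[g].get("fraction", 1.0 / len(labels)) for g in labels], float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * spec.n_plants).astype(int)
    while counts.sum() < spec.n_plants:
        counts[int(np.argmax(fracs * spec.n_plants - counts))] += 1

    rows: dict[str, dict[str, float]] = {}
    grain_rows: dict[str, dict[str, float]] = {}
    group_of: dict[str, str] = {}
    lat_of: dict[str, float] = {}
    i = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # heading/daily-growth edge warnings at cohort scale
        for g, n_g in zip(labels, counts):
            lat_mu, lat_sd = spec.groups[g].get("latitude", (30.0, 8.0))
            for _ in range(n_g):
                pid = f"P{i:03d}"
                i += 1
                gt = sample_ground_truth(rng, pid)
                series = simulate_growth_series(
                    gt,
                    [d for d in spec.days if d <= gt.harvest_day],
                    seed=int(rng.integers(2**31)),
                    noise_sd=spec.observation_noise or None,
                )
                rows[pid] = temporal.derive_plant_row(series, culm=culm_organ_traits(gt))
                grain_rows[pid] = _sample_grain_row(rng)
                group_of[pid] = g
                lat_of[pid] = float(rng.normal(lat_mu, lat_sd))

    grain_df = pd.DataFrame.from_dict(grain_rows, orient="index")
    grain_df.index.name = "plant_id"
    table = temporal.assemble_itrait_table(rows, grain_df)

    # group offsets on designated trait means
    groups = pd.Series(group_of, name="group").reindex(table.index)
    for g, cfg in spec.groups.items():
        for trait, off in cfg.get("offsets", {}).items():
            table.loc[groups == g, trait] += off

    # planted linear yield
    beta = pd.Series(spec.yield_beta, dtype=float)
    X = table[beta.index].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"yield_beta traits contain missing values: {bad}")
    y = spec.yield_intercept + X.to_numpy() @ beta.to_numpy()
    if spec.yield_noise_sd > 0:
        y = y + rng.normal(0.0, spec.yield_noise_sd, size=len(y))
    y = pd.Series(y, index=table.index, name="W")
    # write the yield back into the grain columns, keeping them consistent
    table["W"] = y
    table["GN"] = np.maximum((y * 1000.0 / table["Wper1000"]).round(), 1.0)
    table["TFN"] = np.maximum(table["TFN"], table["GN"])
    table["SF"] = table["GN"] / table["TFN"]

    lats = pd.Series(lat_of, name="latitude").reindex(table.index)
    return table, y, groups, lats
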