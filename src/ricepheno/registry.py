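"""Registry of the 58 image-based traits (i-traits).

The i-trait catalogue spans two dimensions. The *organ dimension* holds
per-organ size/colour traits measured on side-view images of the whole
plant, the panicle and the culm, plus eight grain traits measured
externally by a yield-traits scorer. The *temporal dimension* holds
"days-to-event" phenological traits and growth-curve traits (daily
growth rates and quadratic trajectory coefficients) derived from the
imaging time series.

Group cardinalities: 7 plant, 5 panicle, 6 culm, 8 grain,
12 phenological, 10 panicle-growth, 10 plant-growth = 58.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

GROUPS = (
    "plant",
    "panicle",
    "culm",
    "grain",
    "phenological",
    "panicle_growth",
    "plant_growth",
)


@dataclass(frozen=True)
class TraitDef:
    """One registry entry: a trait name, its group, meaning and units."""

    name: str
    group: str
    definition: str
    units: str


_P = "plant"
_PA = "panicle"
_C = "culm"
_G = "grain"
_PH = "phenological"
_PAG = "panicle_growth"
_PLG = "plant_growth"

REGISTRY: tuple[TraitDef, ...] = (
    # ------------------------------------------------ plant (7)
    TraitDef("PlantH", _P, "Height of the whole plant", "mm"),
    TraitDef("PlantTPA", _P, "Total projected area of the whole plant", "mm^2"),
    TraitDef("PlantHWr", _P, "Ratio of the height and width of the whole plant", "-"),
    TraitDef("PlantTPAHr", _P, "Ratio of the total projected area and height of the whole plant", "mm"),
    TraitDef("PlantYpar", _P, "Ratio of the yellow projected area and total projected area of the whole plant", "-"),
    TraitDef("PlantYPA", _P, "Yellow projected area of the whole plant", "mm^2"),
    TraitDef("PlantGPA", _P, "Green projected area of the whole plant", "mm^2"),
    # ------------------------------------------------ panicle (5)
    TraitDef("PanicleTPA", _PA, "Total projected area of panicles (seasonal maximum)", "mm^2"),
    TraitDef("PaicleEndTPA", _PA, "Value of the final total projected area of panicles", "mm^2"),
    TraitDef("PanicleTpar", _PA, "Ratio of the projected panicle area and whole plant area", "-"),
    TraitDef("PanicleYpar", _PA, "Ratio of the yellow projected area and total projected area of panicles", "-"),
    TraitDef("PanicleYPA", _PA, "Yellow projected area of panicles", "mm^2"),
    # ------------------------------------------------ culm (6)
    TraitDef("culmH", _C, "Height of the plant culm", "mm"),
    TraitDef("culmTPA", _C, "Total projected area of the plant culm", "mm^2"),
    TraitDef("culmTPAHr", _C, "Ratio of the projected area and height of the plant culm", "mm"),
    TraitDef("culmGpar", _C, "Ratio of the green projected area and total projected area of the plant culm", "-"),
    TraitDef("culmYpar", _C, "Ratio of the yellow projected area and total projected area of the plant culm", "-"),
    TraitDef("culmPHr", _C, "Ratio of heights of the culm and whole plant", "-"),
    # ------------------------------------------------ grain (8)
    TraitDef("AveGL", _G, "Mean value of the grain length", "mm"),
    TraitDef("AveLW", _G, "Mean value of the grain length/width ratio", "-"),
    TraitDef("AveGW", _G, "Mean value of the grain width", "mm"),
    TraitDef("TFN", _G, "Total spikelet number", "count"),
    TraitDef("Wper1000", _G, "1,000-grain weight", "g"),
    TraitDef("W", _G, "Yield per plant (filled grain weight)", "g"),
    TraitDef("SF", _G, "Spikelet fertility", "-"),
    TraitDef("GN", _G, "Filled grain number", "count"),
    # ------------------------------------------------ phenological (12)
    TraitDef("GP", _PH, "Days to harvest from sowing", "d"),
    TraitDef("HS", _PH, "Days to the beginning of heading from sowing", "d"),
    TraitDef("PlantSD", _PH, "Days to the onset of plant senescence from sowing", "d"),
    TraitDef("PlantHD", _PH, "Days to the maximum whole-plant height from sowing", "d"),
    TraitDef("PlantTPAD", _PH, "Days to the maximum total projected whole-plant area from sowing", "d"),
    TraitDef("PlantYparD", _PH, "Days to the maximum yellow/total projected-area ratio of the whole plant from sowing", "d"),
    TraitDef("PlantYPAD", _PH, "Days to the maximum whole-plant yellow projected area from sowing", "d"),
    TraitDef("PlantGPAD", _PH, "Days to the maximum green projected area of the whole plant from sowing", "d"),
    TraitDef("PanicleTPAD", _PH, "Days to the maximum total projected panicle area from heading", "d"),
    TraitDef("PanicleTparD", _PH, "Days to the maximum panicle/whole-plant projected-area ratio from heading", "d"),
    TraitDef("PanicleYparD", _PH, "Days to the maximum yellow/total projected-area ratio of panicles from heading", "d"),
    TraitDef("PanicleYPAD", _PH, "Days to the maximum yellow projected area of panicles from heading", "d"),
    # ------------------------------------------------ panicle growth (10)
    TraitDef("PanicleTPAG", _PAG, "Value of daily growth of the total projected panicle area", "mm^2/d"),
    TraitDef("PanicleTparG", _PAG, "Value of daily growth of the panicle/whole-plant projected-area ratio", "1/d"),
    TraitDef("PanicleYparG", _PAG, "Value of daily growth of the yellow/total projected-area ratio of panicles", "1/d"),
    TraitDef("PanicleYPAG", _PAG, "Value of daily growth of the yellow projected area of panicles", "mm^2/d"),
    TraitDef("PanicleTPA_a", _PAG, "Quadratic coefficient a of the panicle TPA trajectory", "mm^2/d^2"),
    TraitDef("PanicleTPA_b", _PAG, "Quadratic coefficient b of the panicle TPA trajectory", "mm^2/d"),
    TraitDef("PanicleTPA_c", _PAG, "Quadratic coefficient c of the panicle TPA trajectory", "mm^2"),
    TraitDef("PanicleYpar_a", _PAG, "Quadratic coefficient a of the panicle Ypar trajectory", "1/d^2"),
    TraitDef("PanicleYpar_b", _PAG, "Quadratic coefficient b of the panicle Ypar trajectory", "1/d"),
    TraitDef("PanicleYpar_c", _PAG, "Quadratic coefficient c of the panicle Ypar trajectory", "-"),
    # ------------------------------------------------ plant growth (10)
    TraitDef("PlantHG", _PLG, "Daily growth value of the height of the whole plant", "mm/d"),
    TraitDef("PlantTPAG", _PLG, "Daily growth value of the total projected area of the whole plant", "mm^2/d"),
    TraitDef("PlantYparG", _PLG, "Daily growth value of the yellow/total projected-area ratio of the whole plant", "1/d"),
    TraitDef("PlantYPAG", _PLG, "Daily growth value of the yellow projected area of the plant", "mm^2/d"),
    TraitDef("PlantTPA_a", _PLG, "Quadratic coefficient a of the plant TPA trajectory", "mm^2/d^2"),
    TraitDef("PlantTPA_b", _PLG, "Quadratic coefficient b of the plant TPA trajectory", "mm^2/d"),
    TraitDef("PlantTPA_c", _PLG, "Quadratic coefficient c of the plant TPA trajectory", "mm^2"),
    TraitDef("PlantYpar_a", _PLG, "Quadratic coefficient a of the plant Ypar trajectory", "1/d^2"),
    TraitDef("PlantYpar_b", _PLG, "Quadratic coefficient b of the plant Ypar trajectory", "1/d"),
    TraitDef("PlantYpar_c", _PLG, "Quadratic coefficient c of the plant Ypar trajectory", "-"),
)

_BY_NAME = {t.name: i for i, t in enumerate(REGISTRY)}

if len(REGISTRY) != 58 or len(_BY_NAME) != 58:  # pragma: no cover
    raise AssertionError("trait registry must contain 58 unique entries")


def trait_names() -> list[str]:
    """All 58 trait names in registry order."""
    return [t.name for t in REGISTRY]


def traits_in_group(group: str) -> list[str]:
    if group not in GROUPS:
        raise KeyError(f"unknown trait group {group!r}; expected one of {GROUPS}")
    return [t.name for t in REGISTRY if t.group == group]


def group_sizes() -> dict[str, int]:
    return {g: len(traits_in_group(g)) for g in GROUPS}


def registry_index(name: str) -> int:
    """Position of a trait in registry order (the deterministic tie-break order)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown trait name {name!r}") from None


def iter_registry() -> Iterator[TraitDef]:
    return iter(REGISTRY)


# Trait subsets for the two PCA dimensions: the 26 organ-dimension traits
# (plant + panicle + culm + grain) and the 32 temporal-dimension traits
# (phenological + panicle growth + plant growth).
ORGAN_PC_TRAITS: tuple[str, ...] = tuple(
    n for g in ("plant", "panicle", "culm", "grain") for n in traits_in_group(g)
)
TIME_PC_TRAITS: tuple[str, ...] = tuple(
    n
    for g in ("phenological", "panicle_growth", "plant_growth")
    for n in traits_in_group(g)
)

# The six i-trait groups used as yield predictors (grain traits contain the
# yield itself and are excluded from the predictor side).
YIELD_PREDICTOR_GROUPS: tuple[str, ...] = (
    "plant",
    "panicle",
    "culm",
    "phenological",
    "panicle_growth",
    "plant_growth",
)
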