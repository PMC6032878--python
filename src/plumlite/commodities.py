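"""Crop and commodity taxonomies.

Seven crop types plus managed pasture make up the eight land-use types the
optimiser decides over.  Food demand is expressed for six commodity groups;
cereal demand can be met by any of the three cereal crops, livestock
commodities are produced from pasture and/or feed rather than mapped to a
single crop, and energy crops serve a global (country-less) market.
"""

from __future__ import annotations

#: Crop land-use types, in canonical order.
CROPS: tuple[str, ...] = (
    "cereals_c3",
    "cereals_c4",
    "rice",
    "oilcrops",
    "pulses",
    "starchy_roots",
    "energy_crops",
)

PASTURE = "pasture"

#: Non-agricultural land-cover classes.
NATURAL_CLASSES: tuple[str, ...] = ("forest", "other_natural")
URBAN = "urban"

#: Crop -> commodity group mapping.
CROP_COMMODITY: dict[str, str] = {
    "cereals_c3": "cereals",
    "cereals_c4": "cereals",
    "rice": "cereals",
    "oilcrops": "oilcrops",
    "pulses": "pulses",
    "starchy_roots": "starchy_roots",
    "energy_crops": "energy",
}

#: Commodity groups with country-level food demand.
FOOD_COMMODITIES: tuple[str, ...] = (
    "cereals",
    "oilcrops",
    "pulses",
    "starchy_roots",
    "ruminant",
    "monogastric",
)

LIVESTOCK_COMMODITIES: tuple[str, ...] = ("ruminant", "monogastric")

#: Dedicated energy-crop commodity (second-generation bioenergy feedstock).
ENERGY = "energy"

#: All traded commodities.
ALL_COMMODITIES: tuple[str, ...] = FOOD_COMMODITIES + (ENERGY,)

#: Fertiliser application rates (kgN/ha) of the factorial yield anchors.
FERT_LEVELS: tuple[float, float, float] = (0.0, 200.0, 1000.0)

#: Water regimes of the factorial yield anchors.
WATER_REGIMES: tuple[str, str] = ("rainfed", "irrigated")


def land_uses(crops: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """The decision land-use types: the given crops plus pasture."""
    return tuple(crops) + (PASTURE,)


def crop_commodities(crops) -> tuple[str, ...]:
    """Commodity groups producible from the given crops, in canonical order."""
    seen = []
    for c in crops:
        g = CROP_COMMODITY[c]
        if g not in seen:
            seen.append(g)
    return tuple(seen)
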