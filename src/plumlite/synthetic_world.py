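"""Synthetic miniature world generator.

Builds a self-consistent toy planet — grid cells with land cover, countries
with income/population trajectories, factorial yield anchors, runoff — whose
statistical structure mirrors the real model inputs: yields are spatially
autocorrelated and monotone in fertiliser and irrigation, and historical
consumption follows a known log-linear income relationship, so that every
downstream fitting stage can be tested for parameter recovery.

Nothing here attempts real geography or real crop physiology; spatial
fields are low-pass-filtered noise, which gives cheap, controllable
autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import lattice
from .commodities import (
    CROP_COMMODITY,
    CROPS,
    ENERGY,
    LIVESTOCK_COMMODITIES,
    crop_commodities,
    land_uses,
)


def food_groups(crops) -> tuple[str, ...]:
    """Demanded commodity groups for a world with the given crops:
    producible crop groups plus the livestock products."""
    groups = tuple(g for g in crop_commodities(crops) if g != ENERGY)
    return groups + LIVESTOCK_COMMODITIES
from .grid import CountryRecord, FPURecord, WorldGrid, YieldAnchorSet

BASE_YEAR = 2010
END_YEAR = 2100

#: Generating Engel coefficients: ln(per-capita consumption, t/yr) =
#: a + b*ln(GDP per capita, $/yr).  Signs follow observed dietary patterns:
#: animal products and oils rise with income, staples decline.
TRUE_ENGEL: dict[str, tuple[float, float]] = {
    "cereals": (np.log(0.15) - 0.10 * np.log(1e4), 0.10),
    "oilcrops": (np.log(0.035) - 0.25 * np.log(1e4), 0.25),
    "pulses": (np.log(0.012) + 0.10 * np.log(1e4), -0.10),
    "starchy_roots": (np.log(0.060) + 0.15 * np.log(1e4), -0.15),
    "ruminant": (np.log(0.020) - 0.35 * np.log(1e4), 0.35),
    "monogastric": (np.log(0.030) - 0.30 * np.log(1e4), 0.30),
}

#: Country-offset spread (log scale) and within-country observation noise.
OFFSET_SD = 0.15
HISTORY_NOISE_SD = 0.05

#: Feed-conversion ratios used when sizing the world (match the optimiser
#: defaults); ruminants are assumed fully grazed for sizing purposes.
_FCR = {"ruminant": 20.0, "monogastric": 4.0}
#: Target ratio of baseline grazing requirement to pasture capacity.
_PASTURE_CAPACITY_RATIO = 0.4

#: Pasture anchor block as multiples of the cell's pasture maximum.
_PASTURE_MULT = np.array([0.55, 0.85, 1.0])

#: Target ratio of baseline crop requirement to mid-fertiliser capacity.
_DEMAND_CAPACITY_RATIO = 0.3

#: Real-world cropland (ha) used to scale the global energy-crop trajectory
#: down to miniature-world size.
REFERENCE_CROPLAND_HA = 1.5e9


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 1.5) -> np.ndarray:
    """Low-pass-filtered standard-normal field, rescaled to unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    s = f.std()
    return (f - f.mean()) / s if s > 0 else f - f.mean()


def _unit(f: np.ndarray) -> np.ndarray:
    """Squash a roughly-normal field smoothly into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-f))


def generate_world(
    n_countries: int,
    cells_per_country: int,
    n_crops: int = len(CROPS),
    seed: int = 0,
) -> tuple[WorldGrid, YieldAnchorSet]:
    """Generate a miniature world with ``n_countries`` rectangular countries.

    Deterministic under a fixed seed.  Returns the grid plus the factorial
    yield-anchor block; both pass their full invariant validation.
    """
    if n_countries < 1 or cells_per_country < 1 or not 1 <= n_crops <= len(CROPS):
        raise ValueError(
            f"invalid sizes: n_countries={n_countries}, "
            f"cells_per_country={cells_per_country}, n_crops={n_crops}"
        )
    rng = np.random.default_rng(seed)
    crops = CROPS[:n_crops]
    lus = land_uses(crops)
    res = 0.5

    nrow = int(np.floor(np.sqrt(cells_per_country)))
    ncol = int(np.ceil(cells_per_country / nrow))

    rows, countries, fpus = [], [], []
    anchor_blocks, req_blocks, runoff_blocks = [], [], []
    cell_id = 0
    for ci in range(n_countries):
        cid = f"C{ci:02d}"
        # crop-specific climatic suitability of this country
        crop_suit = 0.6 + 0.8 * rng.random(n_crops)
        fert_field = _unit(_smooth_field(rng, (nrow, ncol)))
        arid_field = _unit(_smooth_field(rng, (nrow, ncol)))
        prot_field = 0.5 * _unit(_smooth_field(rng, (nrow, ncol)))
        # land-cover propensities -> softmax shares
        prop = {}
        for cls, scale, bias in (
            ("cropland", 1.0, -0.6),
            ("pasture", 1.0, -0.8),
            ("forest", 1.0, 0.3),
            ("other_natural", 1.0, 0.0),
            ("urban", 1.0, -3.2),
        ):
            prop[cls] = np.exp(scale * _smooth_field(rng, (nrow, ncol)) + bias)
        tot = sum(prop.values())
        shares = {k: v / tot for k, v in prop.items()}
        # split cropland across crops with fixed country-level shares
        crop_share = rng.dirichlet(np.full(n_crops, 2.0))
        if n_crops == len(CROPS):  # keep energy-crop baseline area small
            crop_share[CROPS.index("energy_crops")] *= 0.2
            crop_share = crop_share / crop_share.sum()

        country_cells = []
        lon0 = ci * (ncol + 2)  # leave a gap between countries
        n_in_country = 0
        for r in range(nrow):
            for c in range(ncol):
                if n_in_country >= cells_per_country:
                    break
                lat = lattice.centre(r + 40, res)  # mid-latitude band
                lon = lattice.centre(lon0 + c, res)
                area = float(lattice.cell_area_ha(lat, res))
                cover = {}
                for k, crop in enumerate(crops):
                    cover[crop] = shares["cropland"][r, c] * crop_share[k]
                cover["pasture"] = shares["pasture"][r, c]
                cover["forest"] = shares["forest"][r, c]
                cover["other_natural"] = shares["other_natural"][r, c]
                cover["urban"] = shares["urban"][r, c]
                s = sum(cover.values())
                cover = {k: v / s for k, v in cover.items()}
                protected = prot_field[r, c] * (cover["forest"] + cover["other_natural"])
                row = {
                    "cell_id": cell_id,
                    "lat": lat,
                    "lon": lon,
                    "area_ha": area,
                    "country_id": cid,
                    "fpu_id": f"{cid}-F{0 if r < nrow / 2 else 1}",
                    "protected_fraction": protected,
                    "aridity_index": float(arid_field[r, c]),
                }
                for cls in lus + ("forest", "other_natural", "urban"):
                    row[f"cover_{cls}"] = cover[cls]
                rows.append(row)
                country_cells.append(cell_id)

                # --- factorial yield anchors -------------------------------
                fert = fert_field[r, c]
                arid = arid_field[r, c]
                y = np.empty((n_crops + 1, 3, 2))
                req = np.empty(n_crops + 1)
                for k in range(n_crops):
                    ymax = 10.0 * crop_suit[k] * (0.3 + 0.7 * fert)
                    u0 = 0.15 + 0.25 * fert  # zero-N floor fraction
                    ratio = 0.35 + 0.55 * rng.random()  # concave response
                    y0 = ymax * u0
                    y200 = y0 + ratio * (ymax - y0)
                    boost = 1.0 + 0.05 + 0.75 * arid  # irrigation response
                    y[k, :, 0] = (y0, y200, ymax)
                    y[k, :, 1] = y[k, :, 0] * boost
                    req[k] = (2000.0 + 8000.0 * arid) * 1e-9  # m3/ha -> km3/ha
                pmax = (3.0 + 5.0 * fert) * (1.0 - 0.3 * arid)
                y[-1, :, 0] = _PASTURE_MULT * pmax
                y[-1, :, 1] = y[-1, :, 0] * (1.0 + 0.15 * arid)
                req[-1] = (1000.0 + 4000.0 * arid) * 1e-9
                anchor_blocks.append(y)
                req_blocks.append(req)
                runoff_blocks.append((1.0 + 9.0 * rng.random()) * (1.0 - 0.7 * arid))
                cell_id += 1
                n_in_country += 1

        for fid in (f"{cid}-F0", f"{cid}-F1"):
            members = [rows[i]["cell_id"] for i in range(len(rows)) if rows[i]["fpu_id"] == fid]
            if members:
                fpus.append(FPURecord(id=fid, country_id=cid, cell_ids=members))

        countries.append(_make_country(rng, cid, ci, n_countries, food_groups(crops)))

    table = pd.DataFrame(rows)
    anchors = YieldAnchorSet(
        crops=crops,
        yields=np.stack(anchor_blocks),
        irrigation_requirement=np.stack(req_blocks),
        runoff=np.asarray(runoff_blocks),
    )
    world = WorldGrid(
        resolution_deg=res, crops=crops, cells_table=table, countries=countries, fpus=fpus
    )
    _scale_demand_to_capacity(world, anchors)
    world.validate()
    anchors.validate()
    return world, anchors


def _make_country(rng: np.random.Generator, cid: str, idx: int, n_countries: int,
                  groups: tuple[str, ...]) -> CountryRecord:
    years = np.arange(BASE_YEAR, END_YEAR + 1)
    gdp0 = float(np.exp(rng.uniform(np.log(1.5e3), np.log(4e4))))
    g_growth = rng.uniform(0.015, 0.03)
    pop0 = float(np.exp(rng.uniform(np.log(1e7), np.log(1e8))))
    p_growth = rng.uniform(0.0, 0.01)
    gdp = pd.Series(gdp0 * (1 + g_growth) ** (years - BASE_YEAR), index=years)
    pop = pd.Series(pop0 * (1 + p_growth) ** (years - BASE_YEAR), index=years)

    cons, offsets = {}, {}
    for com in groups:
        a, b = TRUE_ENGEL[com]
        d0 = float(rng.normal(0.0, OFFSET_SD))
        offsets[com] = d0
        cons[com] = float(np.exp(a + b * np.log(gdp0) + d0) * pop0)
    cons[ENERGY] = 0.0

    ni = {}
    for com in groups:
        ni[com] = float(rng.uniform(-0.15, 0.15) * cons[com])
    ni[ENERGY] = 0.0

    firstgen = {g: 0.05 * cons[g] for g in ("cereals", "oilcrops") if g in cons}
    rec = CountryRecord(
        id=cid,
        gdp_pc_trajectory=gdp,
        population_trajectory=pop,
        baseline_consumption=cons,
        baseline_net_imports=ni,
        china_flag=(idx == 0 and n_countries > 1),  # one cap-flagged country
    )
    rec.offsets = offsets  # generating truth, kept for recovery tests
    rec.baseline_firstgen = firstgen
    return rec


def _scale_demand_to_capacity(world: WorldGrid, anchors: YieldAnchorSet) -> None:
    """Scale populations so baseline demand sits well inside crop capacity.

    Keeps the per-capita income-consumption structure intact while making
    the baseline land-use problem comfortably feasible, then recentres net
    imports so they sum to zero per commodity and allocates the miniature
    world's share of baseline energy-crop demand across countries.
    """
    total_cropland = 0.0
    groups = food_groups(world.crops)
    for ci, rec in enumerate(world.countries):
        rows = world.country_cells(rec.id)
        idx = rows.index.to_numpy()
        cap = 0.0
        for k, crop in enumerate(world.crops):
            area = (rows[f"cover_{crop}"] * rows.area_ha).to_numpy()
            cap += float((area * anchors.yields[idx, k, 1, 0]).sum())
        req = sum(
            rec.baseline_consumption[g]
            for g in {CROP_COMMODITY[c] for c in world.crops if c != "energy_crops"}
        )
        req += _FCR["monogastric"] * rec.baseline_consumption["monogastric"]
        scale = _DEMAND_CAPACITY_RATIO * cap / max(req, 1.0)
        rec.population_trajectory = rec.population_trajectory * scale
        rec.baseline_consumption = {k: v * scale for k, v in rec.baseline_consumption.items()}
        rec.baseline_net_imports = {k: v * scale for k, v in rec.baseline_net_imports.items()}
        rec.baseline_firstgen = {k: v * scale for k, v in rec.baseline_firstgen.items()}
        # clamp grazing demand to a comfortable share of pasture capacity,
        # folding the clamp into the country's dietary offset so the
        # generating Engel relationship stays exactly consistent
        pasture_area = (rows["cover_pasture"] * rows.area_ha).to_numpy()
        pasture_cap = float((pasture_area * anchors.yields[idx, -1, 1, 0]).sum())
        max_rum = _PASTURE_CAPACITY_RATIO * pasture_cap / _FCR["ruminant"]
        if rec.baseline_consumption["ruminant"] > max_rum > 0:
            shrink = max_rum / rec.baseline_consumption["ruminant"]
            rec.baseline_consumption["ruminant"] = max_rum
            rec.baseline_net_imports["ruminant"] *= shrink
            rec.offsets["ruminant"] += float(np.log(shrink))
        crop_cols = [f"cover_{c}" for c in world.crops]
        total_cropland += float((rows[crop_cols].sum(axis=1) * rows.area_ha).sum())

    # zero-sum net imports across countries
    for com in groups:
        mean = np.mean([c.baseline_net_imports[com] for c in world.countries])
        for c in world.countries:
            c.baseline_net_imports[com] -= mean
    # miniature-world share of global baseline energy-crop demand,
    # exported in proportion to cropland area
    energy_base = (
        34e6 * total_cropland / REFERENCE_CROPLAND_HA
        if "energy_crops" in world.crops
        else 0.0
    )
    weights = []
    for rec in world.countries:
        rows = world.country_cells(rec.id)
        crop_cols = [f"cover_{c}" for c in world.crops]
        weights.append(float((rows[crop_cols].sum(axis=1) * rows.area_ha).sum()))
    wsum = sum(weights)
    for rec, w in zip(world.countries, weights):
        rec.baseline_net_imports[ENERGY] = -energy_base * w / wsum


@dataclass
class History:
    """Synthetic consumption history with its generating truth attached."""

    table: pd.DataFrame  # country_id, year, commodity, gdp_pc, population, consumption_pc
    true_params: dict[str, tuple[float, float]]
    true_offsets: dict[str, dict[str, float]]  # country -> commodity -> d0
    noise_sd: float


def generate_history(
    world: WorldGrid, n_years: int, seed: int = 0, noise_sd: float = HISTORY_NOISE_SD,
    include_offsets: bool = True,
) -> History:
    """Per-country consumption/GDP/population history ending at the base year.

    Per-capita consumption is drawn from the generating log-linear Engel
    curves plus the country's stored offset and multiplicative log-normal
    noise; the true coefficients travel with the result so that regression
    recovery can be asserted.  The base-year observation is noise-free, so
    the history is exactly consistent with the country's stored baseline
    consumption.  ``include_offsets=False`` drops the country offsets,
    giving a pure pooled curve on which unweighted slope recovery is
    unbiased (offsets otherwise act as country-level confounders).
    """
    if n_years < 3:
        raise ValueError(f"n_years must be >= 3, got {n_years}")
    rng = np.random.default_rng(seed)
    years = np.arange(world.base_year - n_years + 1, world.base_year + 1)
    recs = []
    offsets: dict[str, dict[str, float]] = {}
    for rec in world.countries:
        gdp0 = rec.gdp_pc_trajectory[world.base_year]
        pop0 = rec.population_trajectory[world.base_year]
        growth = rng.uniform(0.015, 0.03)
        pgrowth = rng.uniform(0.0, 0.01)
        gdp = gdp0 * (1 + growth) ** (years - world.base_year)
        pop = pop0 * (1 + pgrowth) ** (years - world.base_year)
        groups = tuple(g for g in rec.baseline_consumption if g != ENERGY)
        d0s = getattr(rec, "offsets", {c: 0.0 for c in groups})
        if not include_offsets:
            d0s = {c: 0.0 for c in d0s}
        offsets[rec.id] = dict(d0s)
        for com in groups:
            a, b = TRUE_ENGEL[com]
            eps = rng.normal(0.0, noise_sd, size=len(years))
            eps[-1] = 0.0  # base year matches the stored baseline exactly
            d0 = d0s[com] if include_offsets else 0.0
            cons_pc = np.exp(a + b * np.log(gdp) + d0 + eps)
            for y, g, p, cpc in zip(years, gdp, pop, np.atleast_1d(cons_pc) * np.ones(len(years))):
                recs.append(
                    {
                        "country_id": rec.id,
                        "year": int(y),
                        "commodity": com,
                        "gdp_pc": float(g),
                        "population": float(p),
                        "consumption_pc": float(cpc),
                    }
                )
    return History(
        table=pd.DataFrame(recs),
        true_params=dict(TRUE_ENGEL),
        true_offsets=offsets,
        noise_sd=noise_sd,
    )
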