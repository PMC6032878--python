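"""Per-country least-cost land-use optimisation.

For one country and timestep the model chooses, for every cluster and each
of the eight land-use types (seven crops plus pasture), an area and three
input intensities (fertiliser rate, irrigation fraction, management), plus
country-level trade and livestock-feed decisions, minimising

    production cost + land-conversion cost + import cost - export revenue

subject to: commodity balances (production + imports - exports - feed must
cover food and first-generation bioenergy demand), the FPU irrigation-water
budget, protected areas, a minimum natural fraction, equal debiting of
expansion from forest and other natural vegetation, and an annual
deforestation cap for flagged countries.

The solver is a deterministic multi-start bounded Powell search over the
cluster variables; the country-level trade and feed variables are linear
given production and are resolved in closed form inside the objective.
During spin-up, net imports are held fixed at their baseline values and
production shortfalls carry a prohibitive penalty (with a deterministic
greedy repair pass guaranteeing the commodity balance on return).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .commodities import (
    CROP_COMMODITY,
    ENERGY,
    LIVESTOCK_COMMODITIES,
    PASTURE,
)
from .global_market import import_price
from .spatial_clustering import Cluster
from .yield_response import SurfaceArray

F_MAX = 1000.0  # kgN/ha upper bound (the high factorial anchor)


class OptimiserError(RuntimeError):
    pass


class InfeasibleError(OptimiserError):
    def __init__(self, msg: str, binding: str):
        super().__init__(f"{msg} (binding constraint: {binding})")
        self.binding = binding


@dataclass
class CostParameters:
    """Cost and constraint parameters of the country problem.

    Monetary values are 2010 US$.  Base costs are a minimum per-hectare
    cost of growing each land use (about a third of an intensive system's
    cost; the remainder sits in the management term); input costs are
    intensity x cost-rate products.  ``irrigation_cost_per_km3`` is scaled
    per cell by an aridity-driven index.
    """

    base_cost: float = 200.0  # $/ha, crops
    pasture_base_cost: float = 30.0  # $/ha, extensive grazing
    management_cost: float = 400.0  # $/ha at m=1, crops
    pasture_management_cost: float = 100.0  # $/ha at m=1
    fertiliser_price: float = 1.2  # $/kgN
    irrigation_cost_per_km3: float = 5e7  # $/km3 of water withdrawn, base
    conversion_cost_natural_to_ag: float = 2000.0  # $/ha
    conversion_cost_ag_to_natural: float = 500.0  # $/ha
    conversion_cost_cropland_pasture: float = 300.0  # $/ha
    import_tariff: float = 0.10
    import_transport: float = 0.10
    import_loss: float = 0.05
    irrigation_efficiency: float = 0.5  # requirement / withdrawal
    fcr_ruminant: float = 20.0  # t dry-matter (pasture or feed) per t product
    fcr_monogastric: float = 4.0  # t feed per t product
    min_natural_fraction: float = 0.05
    china_deforestation_cap: float = 0.011  # fraction of forest area per year
    shortfall_penalty_mult: float = 50.0  # x import price, fixed-trade mode

    def __post_init__(self):
        if not 0 < self.irrigation_efficiency <= 1:
            raise ValueError("irrigation efficiency must be in (0, 1]")
        for name in (
            "base_cost", "pasture_base_cost", "management_cost",
            "pasture_management_cost", "fertiliser_price", "irrigation_cost_per_km3",
            "conversion_cost_natural_to_ag", "conversion_cost_ag_to_natural",
            "conversion_cost_cropland_pasture", "import_tariff", "import_transport",
            "import_loss", "fcr_ruminant", "fcr_monogastric",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def import_unit_price(self, price: float) -> float:
        return import_price(price, self.import_tariff, self.import_transport, self.import_loss)

    def base_cost_vector(self, land_uses) -> np.ndarray:
        return np.array(
            [self.pasture_base_cost if lu == PASTURE else self.base_cost for lu in land_uses]
        )

    def management_cost_vector(self, land_uses) -> np.ndarray:
        return np.array(
            [
                self.pasture_management_cost if lu == PASTURE else self.management_cost
                for lu in land_uses
            ]
        )


@dataclass
class WaterBudget:
    """Irrigation water availability, pooled by FPU and split over cells."""

    fpu_available: dict[str, float]  # km3/yr after non-agricultural uses
    cell_available: pd.Series  # cell_id -> km3/yr


def build_water_budget(
    world,
    anchors,
    non_ag_use: dict[str, float] | None = None,
    reserve_fraction: float = 0.1,
) -> WaterBudget:
    """Pool cell runoff into FPUs, deduct non-agricultural consumption and
    an environmental reserve, and allocate the remainder equally across the
    FPU's cells."""
    non_ag_use = non_ag_use or {}
    if reserve_fraction < 0 or any(v < 0 for v in non_ag_use.values()):
        raise ValueError("water budget inputs must be >= 0")
    cell_ids, alloc = [], []
    fpu_avail = {}
    id_to_pos = {int(c): i for i, c in enumerate(world.cells_table.cell_id)}
    for fpu in world.fpus:
        pos = [id_to_pos[c] for c in fpu.cell_ids]
        runoff = float(anchors.runoff[pos].sum())
        avail = max(0.0, runoff * (1 - reserve_fraction) - non_ag_use.get(fpu.id, 0.0))
        fpu_avail[fpu.id] = avail
        share = avail / len(fpu.cell_ids)
        for c in fpu.cell_ids:
            cell_ids.append(int(c))
            alloc.append(share)
    return WaterBudget(fpu_available=fpu_avail, cell_available=pd.Series(alloc, index=cell_ids))


def attach_water(clusters: list[Cluster], budget: WaterBudget) -> None:
    """Set each cluster's available water to the sum over member cells."""
    for cl in clusters:
        cl.available_water = float(budget.cell_available.loc[list(cl.cell_ids)].sum())


def production_cost(
    cluster: Cluster,
    land_use: int | str,
    area: float,
    F: float,
    irr_frac: float,
    m: float,
    costs: CostParameters,
    land_uses: tuple[str, ...],
) -> float:
    """Annual production cost ($/yr) of one cluster x land use choice."""
    if isinstance(land_use, str):
        land_use = land_uses.index(land_use)
    lu_name = land_uses[land_use]
    base = costs.pasture_base_cost if lu_name == PASTURE else costs.base_cost
    mg = costs.pasture_management_cost if lu_name == PASTURE else costs.management_cost
    req = float(cluster.mean_irrigation_requirement[land_use])
    p_w = costs.irrigation_cost_per_km3 * cluster.mean_irrigation_cost_index
    water_per_ha = irr_frac * req / costs.irrigation_efficiency
    return area * (base + costs.fertiliser_price * F + p_w * water_per_ha + mg * m)


def livestock_balance(
    ruminant_demand: float,
    monogastric_demand: float,
    pasture_output: float,
    fcr_ruminant: float,
    fcr_monogastric: float,
) -> dict[str, float]:
    """Feed bookkeeping: monogastrics eat feed only; ruminants graze first
    and the residual requirement is met with feed."""
    if min(ruminant_demand, monogastric_demand, pasture_output) < 0:
        raise ValueError("livestock balance inputs must be >= 0")
    req_r = fcr_ruminant * ruminant_demand
    pasture_used = min(pasture_output, req_r)
    return {
        "monogastric_feed": fcr_monogastric * monogastric_demand,
        "ruminant_requirement": req_r,
        "pasture_used": pasture_used,
        "ruminant_feed": req_r - pasture_used,
    }


@dataclass
class CountryState:
    """Current land use and intensities of one country, at cluster level."""

    country_id: str
    clusters: list[Cluster]
    land_uses: tuple[str, ...]
    areas: np.ndarray  # (nk, nlu) ha
    fert: np.ndarray  # (nk, nlu) kgN/ha
    irr: np.ndarray  # (nk, nlu) fraction of full requirement
    mgmt: np.ndarray  # (nk, nlu) management intensity
    forest: np.ndarray  # (nk,) ha
    other_natural: np.ndarray  # (nk,) ha
    china_flag: bool = False

    @classmethod
    def from_clusters(cls, clusters: list[Cluster], land_uses, china_flag=False,
                      fert0: float = 200.0, irr0: float = 0.2, m0: float = 0.5) -> "CountryState":
        nk, nlu = len(clusters), len(land_uses)
        areas = np.array([[cl.areas[lu] for lu in land_uses] for cl in clusters])
        return cls(
            country_id=clusters[0].country_id,
            clusters=clusters,
            land_uses=tuple(land_uses),
            areas=areas,
            fert=np.full((nk, nlu), fert0),
            irr=np.full((nk, nlu), irr0),
            mgmt=np.full((nk, nlu), m0),
            forest=np.array([cl.areas["forest"] for cl in clusters]),
            other_natural=np.array([cl.areas["other_natural"] for cl in clusters]),
            china_flag=china_flag,
        )

    def copy(self) -> "CountryState":
        return replace(
            self,
            areas=self.areas.copy(),
            fert=self.fert.copy(),
            irr=self.irr.copy(),
            mgmt=self.mgmt.copy(),
            forest=self.forest.copy(),
            other_natural=self.other_natural.copy(),
        )


@dataclass
class CountrySolution:
    """Optimised cluster areas/intensities and country trade/feed choices."""

    country_id: str
    land_uses: tuple[str, ...]
    areas: np.ndarray
    fert: np.ndarray
    irr: np.ndarray
    mgmt: np.ndarray
    forest: np.ndarray
    other_natural: np.ndarray
    production: dict[str, float]  # tonnes per commodity (incl. livestock)
    pasture_output: float
    imports: dict[str, float]
    exports: dict[str, float]
    feed: dict[str, float]  # livestock type -> feed tonnes
    water_use: np.ndarray  # (nk,) km3/yr
    objective: float
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.areas.shape[0]):
            for j, lu in enumerate(self.land_uses):
                rows.append(
                    {
                        "country_id": self.country_id,
                        "cluster": k,
                        "land_use": lu,
                        "area_ha": self.areas[k, j],
                        "fertiliser_kgN_ha": self.fert[k, j],
                        "irrigation_fraction": self.irr[k, j],
                        "management": self.mgmt[k, j],
                    }
                )
        return pd.DataFrame(rows)


class _Problem:
    """Precomputed arrays and the objective for one country solve."""

    def __init__(self, state, demand, firstgen, prices, surfaces, costs, year,
                 net_imports=None, secondgen_price=None):
        self.state = state
        self.costs = costs
        self.year = year
        self.prices = dict(prices)
        self.demand = dict(demand)
        self.firstgen = dict(firstgen or {})
        self.net_imports = None if net_imports is None else dict(net_imports)
        self.surfaces = surfaces
        lus = state.land_uses
        self.lus = lus
        self.nk, self.nlu = state.areas.shape
        self.crop_idx = [j for j, lu in enumerate(lus) if lu != PASTURE]
        self.pasture_j = lus.index(PASTURE)
        self.commodities = sorted({CROP_COMMODITY[lu] for lu in lus if lu != PASTURE})
        self.com_of = np.array(
            [self.commodities.index(CROP_COMMODITY[lu]) if lu != PASTURE else -1 for lu in lus]
        )
        cls = state.clusters
        self.cluster_area = np.array([cl.area_ha for cl in cls])
        self.urban = np.array([cl.areas["urban"] for cl in cls])
        self.protected = np.array([cl.protected_ha for cl in cls])
        self.reserved = np.array(
            [cl.reserved_ha(costs.min_natural_fraction) for cl in cls]
        )
        self.avail = np.maximum(self.cluster_area - self.urban - self.reserved, 0.0)
        self.water = np.array([cl.available_water for cl in cls])
        self.p_w = costs.irrigation_cost_per_km3 * np.array(
            [cl.mean_irrigation_cost_index for cl in cls]
        )
        self.req = surfaces.irrigation_requirement  # (nk, nlu)
        self.base_c = costs.base_cost_vector(lus)
        self.mgmt_c = costs.management_cost_vector(lus)
        self.areas0 = state.areas.copy()
        self.forest0 = state.forest.copy()
        self.othernat0 = state.other_natural.copy()
        self.unprot_forest = np.maximum(
            self.forest0 - np.minimum(self.reserved, self.forest0), 0.0
        )
        self.unprot_other = np.maximum(
            self.forest0 + self.othernat0 - self.reserved - self.unprot_forest, 0.0
        )
        # penalty scale: well above any plausible objective magnitude
        self.pen_scale = 100.0 * float(
            (self.avail * (self.base_c.max() + self.mgmt_c.max()
                           + costs.fertiliser_price * F_MAX)).sum() + 1e6
        )

    # -- decoding ----------------------------------------------------------
    def decode(self, x: np.ndarray):
        n = self.nk * self.nlu
        a, f, i, m = (x[:n], x[n:2 * n], x[2 * n:3 * n], x[3 * n:])
        shp = (self.nk, self.nlu)
        areas = a.reshape(shp) * self.avail[:, None]
        return areas, f.reshape(shp) * F_MAX, i.reshape(shp).copy(), m.reshape(shp).copy()

    def encode(self, areas, fert, irr, mgmt) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(self.avail[:, None] > 0, areas / self.avail[:, None], 0.0)
        return np.concatenate(
            [np.clip(a, 0, 1).ravel(), np.clip(fert / F_MAX, 0, 1).ravel(),
             np.clip(irr, 0, 1).ravel(), np.clip(mgmt, 0, 1).ravel()]
        )

    # -- physical bookkeeping ---------------------------------------------
    def water_use(self, areas, irr):
        return (irr * self.req * areas).sum(axis=1) / self.costs.irrigation_efficiency

    def forest_loss(self, areas):
        """Forest debit of net agricultural expansion per cluster (equal
        split with forest/other-natural availability fallback)."""
        net = (areas - self.areas0).sum(axis=1)
        gain = np.maximum(net, 0.0)
        take_f = np.minimum(gain / 2.0, self.unprot_forest)
        take_o = np.minimum(gain - take_f, self.unprot_other)
        return gain - take_o  # remainder falls back on forest

    def conversion_cost(self, areas):
        d = areas - self.areas0
        pos = np.maximum(d, 0.0).sum(axis=1)
        neg = np.maximum(-d, 0.0).sum(axis=1)
        churn = np.minimum(pos, neg)
        net = pos - neg
        c = self.costs
        return float(
            (churn * c.conversion_cost_cropland_pasture
             + np.maximum(net, 0.0) * c.conversion_cost_natural_to_ag
             + np.maximum(-net, 0.0) * c.conversion_cost_ag_to_natural).sum()
        )

    def produce(self, areas, fert, irr, mgmt):
        """Commodity production (t) and pasture output (t)."""
        y = self.surfaces.evaluate(fert, irr, mgmt, self.year)
        out = y * areas
        prod = {c: 0.0 for c in self.commodities}
        for j, lu in enumerate(self.lus):
            if lu == PASTURE:
                continue
            prod[CROP_COMMODITY[lu]] += float(out[:, j].sum())
        return prod, float(out[:, self.pasture_j].sum())

    def production_cost_total(self, areas, fert, irr, mgmt):
        water_ha = irr * self.req / self.costs.irrigation_efficiency
        per_ha = (self.base_c[None, :] + self.costs.fertiliser_price * fert
                  + self.p_w[:, None] * water_ha + self.mgmt_c[None, :] * mgmt)
        return float((areas * per_ha).sum())

    # -- country-level trade and feed (closed form) ------------------------
    def trade_and_feed(self, prod: dict[str, float], pasture_out: float):
        c = self.costs
        dem = self.demand
        fg = self.firstgen
        imports = {}
        exports = {}
        feed = {"ruminant": 0.0, "monogastric": 0.0}
        cost = 0.0

        cereal_price = self.prices.get("cereals", 200.0)
        if self.net_imports is None:
            # scenario mode: endogenous trade
            dem_r = dem.get("ruminant", 0.0)
            dem_m = dem.get("monogastric", 0.0)
            graze_cap = pasture_out / c.fcr_ruminant if c.fcr_ruminant > 0 else 0.0
            grazed = min(dem_r, graze_cap)
            deficit_r = dem_r - grazed
            prod_r = grazed
            if deficit_r > 0:
                if c.fcr_ruminant * cereal_price < c.import_unit_price(
                    self.prices.get("ruminant", 0.0)
                ):
                    feed["ruminant"] = c.fcr_ruminant * deficit_r
                    prod_r += deficit_r
                    imports["ruminant"] = 0.0
                else:
                    imports["ruminant"] = deficit_r
                exports["ruminant"] = 0.0
            else:
                exports["ruminant"] = graze_cap - dem_r  # surplus grazing exported
                prod_r += exports["ruminant"]
                imports["ruminant"] = 0.0
            if c.fcr_monogastric * cereal_price < c.import_unit_price(
                self.prices.get("monogastric", 0.0)
            ):
                feed["monogastric"] = c.fcr_monogastric * dem_m
                prod_m, imports["monogastric"] = dem_m, 0.0
            else:
                prod_m, imports["monogastric"] = 0.0, dem_m
            exports["monogastric"] = 0.0
            prod = dict(prod)
            prod["ruminant"], prod["monogastric"] = prod_r, prod_m
            feed_by_com = {"cereals": feed["ruminant"] + feed["monogastric"]}
            crop_coms = sorted(
                set(self.commodities)
                | {c for c in dem if c not in LIVESTOCK_COMMODITIES}
                | set(fg)
            )
            for com in crop_coms:
                req = dem.get(com, 0.0) + fg.get(com, 0.0) + feed_by_com.get(com, 0.0)
                if com == ENERGY:
                    exports[com] = prod.get(com, 0.0)  # energy crops are export-only
                    imports[com] = 0.0
                    continue
                net = prod.get(com, 0.0) - req
                imports[com] = max(0.0, -net)
                exports[com] = max(0.0, net)
            for com in imports:
                cost += imports[com] * c.import_unit_price(self.prices.get(com, 0.0))
                cost -= exports[com] * self.prices.get(com, 0.0)
            shortfall = {}
        else:
            # spin-up mode: net imports fixed at baseline
            ni = self.net_imports
            prod = dict(prod)
            targets = {}
            for lv in LIVESTOCK_COMMODITIES:
                targets[lv] = max(0.0, dem.get(lv, 0.0) - ni.get(lv, 0.0))
            bal = livestock_balance(
                targets["ruminant"], targets["monogastric"], pasture_out,
                c.fcr_ruminant, c.fcr_monogastric,
            )
            feed = {"ruminant": bal["ruminant_feed"], "monogastric": bal["monogastric_feed"]}
            shortfall = {}
            feed_by_com = {"cereals": feed["ruminant"] + feed["monogastric"]}
            crop_coms = sorted(
                set(self.commodities)
                | {c for c in dem if c not in LIVESTOCK_COMMODITIES}
                | set(fg)
            )
            for com in crop_coms:
                req = (dem.get(com, 0.0) + fg.get(com, 0.0) + feed_by_com.get(com, 0.0)
                       - ni.get(com, 0.0))
                if com == ENERGY:
                    req = max(0.0, -ni.get(com, 0.0))
                if com not in self.commodities:
                    if com == ENERGY:
                        # an export-only commodity this country cannot grow
                        imports[com], exports[com] = 0.0, 0.0
                        shortfall[com] = 0.0
                        continue
                    # not producible here: met entirely by (extra) imports
                    imports[com] = max(0.0, ni.get(com, 0.0)) + max(0.0, req)
                    exports[com] = max(0.0, -ni.get(com, 0.0))
                    shortfall[com] = 0.0
                    continue
                short = max(0.0, req - prod.get(com, 0.0))
                shortfall[com] = short
                cost += (short * c.shortfall_penalty_mult
                         * c.import_unit_price(self.prices.get(com, 100.0)))
                imports[com] = max(0.0, ni.get(com, 0.0))
                exports[com] = max(0.0, -ni.get(com, 0.0))
            for lv in LIVESTOCK_COMMODITIES:
                prod[lv] = targets[lv]  # feed fills any grazing gap by construction
                imports[lv] = max(0.0, ni.get(lv, 0.0))
                exports[lv] = max(0.0, -ni.get(lv, 0.0))
        return prod, imports, exports, feed, cost, shortfall

    # -- objective ---------------------------------------------------------
    def objective(self, x: np.ndarray) -> float:
        areas, fert, irr, mgmt = self.decode(x)
        cost = self.production_cost_total(areas, fert, irr, mgmt)
        cost += self.conversion_cost(areas)
        prod, pasture_out = self.produce(areas, fert, irr, mgmt)
        _, _, _, _, trade_cost, _ = self.trade_and_feed(prod, pasture_out)
        cost += trade_cost
        # penalties (relative overshoots)
        pen = 0.0
        over_land = (areas.sum(axis=1) - self.avail) / np.maximum(self.cluster_area, 1.0)
        pen += float(np.maximum(over_land, 0.0).sum())
        wu = self.water_use(areas, irr)
        over_w = (wu - self.water) / np.maximum(self.water, 1e-6)
        pen += float(np.maximum(over_w, 0.0).sum())
        if self.state.china_flag:
            cap = self.costs.china_deforestation_cap * float(self.forest0.sum())
            over_f = (self.forest_loss(areas).sum() - cap) / max(float(self.forest0.sum()), 1.0)
            pen += max(over_f, 0.0)
        return cost + self.pen_scale * (pen + pen * pen)

    # -- projection to the feasible set ------------------------------------
    def project(self, areas, irr):
        areas = areas.copy()
        irr = irr.copy()
        tot = areas.sum(axis=1)
        over = tot > self.avail
        if over.any():
            scale = np.where(over, self.avail / np.maximum(tot, 1e-12), 1.0)
            areas *= scale[:, None]
        if self.state.china_flag:
            cap = self.costs.china_deforestation_cap * float(self.forest0.sum())
            for _ in range(8):
                loss = float(self.forest_loss(areas).sum())
                if loss <= cap + 1e-9:
                    break
                # shrink positive expansion towards the baseline
                d = areas - self.areas0
                pos = np.maximum(d, 0.0)
                if pos.sum() <= 0:
                    break
                alpha = max(0.0, min(1.0, cap / loss))
                areas = self.areas0 + pos * alpha + np.minimum(d, 0.0)
        wu = self.water_use(areas, irr)
        over = wu > self.water
        if over.any():
            scale = np.where(over, self.water / np.maximum(wu, 1e-12), 1.0)
            irr *= scale[:, None]
        return areas, irr


def _natural_after(problem: _Problem, areas):
    """Forest and other-natural areas after realising the solution."""
    net = (areas - problem.areas0).sum(axis=1)
    gain = np.maximum(net, 0.0)
    back = np.maximum(-net, 0.0)
    take_f = np.minimum(gain / 2.0, problem.unprot_forest)
    take_o = np.minimum(gain - take_f, problem.unprot_other)
    take_f = gain - take_o
    return problem.forest0 - take_f, problem.othernat0 - take_o + back


def optimise_country(
    state: CountryState,
    demand: dict[str, float],
    prices: dict[str, float],
    surfaces: SurfaceArray,
    costs: CostParameters,
    year: int,
    firstgen: dict[str, float] | None = None,
    net_imports: dict[str, float] | None = None,
    seed: int = 0,
    maxiter: int | None = None,
    solve: bool = True,
) -> CountrySolution:
    """Solve the least-cost problem for one country and year.

    ``net_imports`` switches to spin-up (fixed-trade) mode.  Deterministic:
    the multi-start list is fixed and the seed only orders tie-breaks.
    With ``solve=False`` the current state is packaged (projected and, in
    fixed-trade mode, repaired) without searching.
    """
    if any(not np.isfinite(v) for v in demand.values()):
        raise ValueError("demand must be finite")
    prob = _Problem(state, demand, firstgen, prices, surfaces, costs, year, net_imports)
    n = 4 * prob.nk * prob.nlu
    bounds = [(0.0, 1.0)] * n

    x_warm = prob.encode(state.areas, state.fert, state.irr, state.mgmt)
    starts = [x_warm]
    mid = x_warm.copy()
    mid[prob.nk * prob.nlu:] = 0.5
    starts.append(mid)
    low = x_warm.copy()
    low[prob.nk * prob.nlu:] = 0.15
    starts.append(low)

    warm_objective = float(prob.objective(x_warm))
    best_x, best_f = x_warm, warm_objective
    opts = {"maxiter": maxiter if maxiter is not None else 40, "xtol": 1e-4, "ftol": 1e-7}
    for x0 in starts if solve else []:
        res = minimize(prob.objective, x0, method="Powell", bounds=bounds, options=opts)
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = np.clip(res.x, 0, 1), float(res.fun)

    areas, fert, irr, mgmt = prob.decode(best_x)
    areas, irr = prob.project(areas, irr)

    if net_imports is not None:
        areas, fert, irr, mgmt = _repair_shortfall(prob, areas, fert, irr, mgmt)

    prod, pasture_out = prob.produce(areas, fert, irr, mgmt)
    prod, imports, exports, feed, trade_cost, shortfall = prob.trade_and_feed(prod, pasture_out)
    objective = (
        prob.production_cost_total(areas, fert, irr, mgmt)
        + prob.conversion_cost(areas)
        + trade_cost
    )
    forest, othernat = _natural_after(prob, areas)
    return CountrySolution(
        country_id=state.country_id,
        land_uses=state.land_uses,
        areas=areas,
        fert=fert,
        irr=irr,
        mgmt=mgmt,
        forest=forest,
        other_natural=othernat,
        production=prod,
        pasture_output=pasture_out,
        imports=imports,
        exports=exports,
        feed=feed,
        water_use=prob.water_use(areas, irr),
        objective=float(objective),
        diagnostics={
            "warm_objective": warm_objective,
            "best_penalised_objective": best_f,
            "shortfall": shortfall,
            "mode": "spin_up" if net_imports is not None else "scenario",
        },
    )


def _repair_shortfall(prob: _Problem, areas, fert, irr, mgmt, tol: float = 1e-9):
    """Deterministic minimal repair guaranteeing commodity balances in
    fixed-trade mode.

    For each short commodity the knobs of the best-yielding clusters are
    raised — management, then fertiliser, then irrigation (water-capped),
    then area (land- and cap-limited) — each by *just enough* (monotone
    scalar bisection) to close the gap, so the repaired point stays close
    to the optimiser's solution.
    """
    from scipy.optimize import brentq as _brentq

    areas, fert, irr, mgmt = areas.copy(), fert.copy(), irr.copy(), mgmt.copy()

    def shortfalls():
        prod, pasture_out = prob.produce(areas, fert, irr, mgmt)
        return prob.trade_and_feed(prod, pasture_out)[5]

    def com_production(com):
        prod, _ = prob.produce(areas, fert, irr, mgmt)
        return prod.get(com, 0.0)

    for com in sorted(shortfalls()):
        lus = [j for j, lu in enumerate(prob.lus)
               if lu != PASTURE and CROP_COMMODITY[lu] == com]
        if not lus:
            continue
        short = shortfalls().get(com, 0.0)
        if short <= tol:
            continue
        ymax = prob.surfaces.evaluate(
            np.full_like(fert, F_MAX), np.ones_like(irr), np.ones_like(mgmt), prob.year
        )
        ranked = sorted(
            ((k, j) for k in range(prob.nk) for j in lus),
            key=lambda kj: -ymax[kj],
        )
        for k, j in ranked:
            short = shortfalls().get(com, 0.0)
            if short <= tol:
                break
            target = com_production(com) + short

            def _close(arr, lo, hi):
                """Raise arr[k, j] within [lo, hi] to hit the target if
                attainable; else move to hi.  Returns True when closed."""
                if hi <= lo + 1e-12:
                    return False
                cur = arr[k, j]

                def gap(v):
                    arr[k, j] = v
                    return com_production(com) - target

                if gap(hi) < -tol:
                    return False  # knob saturates below target; keep at hi
                if gap(lo) >= -tol:
                    arr[k, j] = max(lo, cur)
                    return True
                arr[k, j] = _brentq(gap, lo, hi, xtol=1e-10)
                return True

            if _close(mgmt, mgmt[k, j], 1.0):
                break
            if _close(fert, fert[k, j], F_MAX):
                break
            head = prob.water - prob.water_use(areas, irr)
            if prob.req[k, j] > 0 and areas[k, j] > 0:
                irr_cap = min(
                    1.0,
                    irr[k, j] + head[k] * prob.costs.irrigation_efficiency
                    / (prob.req[k, j] * areas[k, j]),
                )
            else:
                irr_cap = 1.0
            if _close(irr, irr[k, j], irr_cap):
                break
            area_cap = areas[k, j] + max(0.0, prob.avail[k] - areas[k].sum())
            if prob.state.china_flag:
                cap = prob.costs.china_deforestation_cap * float(prob.forest0.sum())
                head_f = max(0.0, cap - float(prob.forest_loss(areas).sum()))
                area_cap = min(area_cap, areas[k, j] + 2.0 * head_f)
            if _close(areas, areas[k, j], area_cap):
                break
    return areas, fert, irr, mgmt


def candidate_cost(
    state: CountryState,
    demand: dict[str, float],
    prices: dict[str, float],
    surfaces: SurfaceArray,
    costs: CostParameters,
    year: int,
    areas: np.ndarray,
    fert: np.ndarray,
    irr: np.ndarray,
    mgmt: np.ndarray,
    firstgen: dict[str, float] | None = None,
    net_imports: dict[str, float] | None = None,
) -> float:
    """Unpenalised objective of an arbitrary (feasible) candidate solution:
    production + conversion + trade cost - export revenue.  Useful for
    external optimality checks."""
    prob = make_problem(state, demand, prices, surfaces, costs, year,
                        firstgen=firstgen, net_imports=net_imports)
    return evaluate_candidate(prob, areas, fert, irr, mgmt)


def make_problem(state, demand, prices, surfaces, costs, year,
                 firstgen=None, net_imports=None) -> "_Problem":
    """Precompute a country problem for repeated candidate evaluation."""
    return _Problem(state, demand, firstgen, prices, surfaces, costs, year, net_imports)


def evaluate_candidate(prob: "_Problem", areas, fert, irr, mgmt) -> float:
    """Unpenalised objective of a candidate on a prebuilt problem."""
    prod, pasture_out = prob.produce(areas, fert, irr, mgmt)
    trade_cost = prob.trade_and_feed(prod, pasture_out)[4]
    return (
        prob.production_cost_total(areas, fert, irr, mgmt)
        + prob.conversion_cost(areas)
        + trade_cost
    )


# ---------------------------------------------------------------------------
# Feasibility audit
# ---------------------------------------------------------------------------


def audit_solution(
    prob_state: CountryState,
    solution: CountrySolution,
    demand: dict[str, float],
    costs: CostParameters,
    firstgen: dict[str, float] | None = None,
    rtol: float = 1e-6,
) -> dict[str, bool]:
    """Check the six feasibility classes of a returned solution.

    Returns a dict of named boolean checks; all must be true.
    """
    firstgen = firstgen or {}
    sol = solution
    cls = prob_state.clusters
    cluster_area = np.array([c.area_ha for c in cls])
    urban = np.array([c.areas["urban"] for c in cls])
    protected = np.array([c.protected_ha for c in cls])
    reserved = np.array([c.reserved_ha(costs.min_natural_fraction) for c in cls])
    avail = np.maximum(cluster_area - urban - reserved, 0.0)
    water = np.array([c.available_water for c in cls])
    checks = {}
    # (i) commodity balance
    ok = True
    feed_by_com = {"cereals": sol.feed.get("ruminant", 0.0) + sol.feed.get("monogastric", 0.0)}
    for com, d in demand.items():
        if com == ENERGY:
            continue
        supply = (sol.production.get(com, 0.0) + sol.imports.get(com, 0.0)
                  - sol.exports.get(com, 0.0) - feed_by_com.get(com, 0.0))
        need = d + firstgen.get(com, 0.0)
        if supply < need * (1 - rtol) - 1e-6:
            ok = False
    checks["commodity_balance"] = ok
    # (ii) water budget
    checks["water_budget"] = bool((sol.water_use <= water * (1 + rtol) + 1e-12).all())
    # (iii) protected areas never converted: natural area >= protected area
    nat = sol.forest + sol.other_natural
    checks["protected_areas"] = bool((nat >= protected * (1 - rtol) - 1e-6).all())
    # (iv) minimum natural fraction
    checks["min_natural_fraction"] = bool(
        (nat >= costs.min_natural_fraction * cluster_area * (1 - rtol) - 1e-6).all()
    )
    # (v) equal debit from forest and other natural (up to availability)
    net = (sol.areas - prob_state.areas).sum(axis=1)
    gain = np.maximum(net, 0.0)
    f_loss = prob_state.forest - sol.forest
    o_loss = prob_state.other_natural - sol.other_natural
    ok = True
    for k in range(len(cls)):
        if gain[k] <= 1e-6:
            continue
        lo, hi = sorted((f_loss[k], o_loss[k]))
        if abs(f_loss[k] - o_loss[k]) > max(1e-6, rtol * max(hi, 1.0)):
            # unequal split is only allowed when the smaller pool ran dry
            unprot_f = max(prob_state.forest[k] - min(reserved[k], prob_state.forest[k]), 0.0)
            unprot_o = max(prob_state.forest[k] + prob_state.other_natural[k]
                           - reserved[k] - unprot_f, 0.0)
            if abs(lo - min(unprot_f, unprot_o)) > max(1e-6, rtol * max(hi, 1.0)):
                ok = False
    checks["equal_debit"] = ok
    # (vi) deforestation cap
    if prob_state.china_flag:
        cap = costs.china_deforestation_cap * float(prob_state.forest.sum())
        checks["deforestation_cap"] = float(f_loss.sum()) <= cap * (1 + rtol) + 1e-6
    else:
        checks["deforestation_cap"] = True
    # area sanity
    checks["land_availability"] = bool(
        (sol.areas.sum(axis=1) <= avail * (1 + rtol) + 1e-6).all()
    )
    checks["no_round_tripping"] = all(
        not (sol.imports.get(c, 0.0) > 1e-9 and sol.exports.get(c, 0.0) > 1e-9)
        for c in set(sol.imports) | set(sol.exports)
    )
    return checks
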