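"""Coupled annual simulation: spin-up, scenario runs and ensembles.

The annual loop follows the coupling design: (1) potential yields are a
trailing mean of the anchor sets over the averaging window, (2) demand is
projected from income and population, (3) every country is optimised
independently against the last settled world prices, (4) the global market
settles (stocks absorb the imbalance, prices adjust), (5) cluster-level
land-use changes are disaggregated to grid cells.

Spin-up iterates the base-year country optimisation on its own output,
with net imports fixed at their baseline values, until no cluster area or
intensity value changes by more than the convergence threshold (default
0.4 %).  An iteration that fails to improve a country's objective by more
than a small relative amount keeps the previous state, so the iteration is
a contraction onto a fixed point.

The public surface is statsmodels-like: :class:`LandUseModel` is built
from a world (or synthesised), ``spin_up()`` returns a
:class:`SpinUpResults`, ``simulate()`` a :class:`ScenarioResults`.
"""

from __future__ import annotations

import copy
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .commodities import ENERGY, PASTURE, land_uses
from .country_optimiser import (
    CostParameters,
    CountrySolution,
    CountryState,
    attach_water,
    audit_solution,
    build_water_budget,
    optimise_country,
)
from .demand import DemandResults, bioenergy_demand, fit_demand_model
from .global_market import DEFAULT_LAMBDA, MarketState, settle_market
from .grid import WorldGrid, YieldAnchorSet
from .spatial_clustering import Cluster, choose_k, cluster_country, disaggregate
from .synthetic_world import REFERENCE_CROPLAND_HA, generate_history, generate_world
from .yield_response import SurfaceArray

#: Relative objective improvement below which a spin-up iteration keeps the
#: previous country state.
_SPINUP_ACCEPT_RTOL = 1e-4
#: Scale floors for the relative-change metric.
_AREA_CHANGE_FLOOR_FRAC = 1e-4  # of available land
_INTENSITY_CHANGE_FLOOR = 1e-3


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class ScenarioConfig:
    """Everything a run needs besides the world itself."""

    start_year: int = 2010
    end_year: int = 2020
    yield_window: int = 5  # trailing averaging window, years
    spinup_threshold: float = 0.004  # max relative change at convergence
    max_spinup_iterations: int = 15
    ensemble_size: int = 1
    perturbation_half_width: float = 0.5
    seed: int = 0
    convergence_on: bool = False  # dietary convergence
    kappa: float = 1.0
    price_lambda: float = DEFAULT_LAMBDA
    initial_prices: dict[str, float] | None = None
    stocks_to_use: float = 0.2
    water_reserve_fraction: float = 0.1
    secondgen_scale: float | None = None  # None -> cropland share of 1,500 Mha
    n_history_years: int = 40
    history_seed: int = 11
    tech_rate: float = 0.002  # annual exogenous yield increment
    costs: CostParameters = field(default_factory=CostParameters)
    solver_maxiter: int = 40
    max_cluster_count: int = 8

    def validation_errors(self) -> list[str]:
        e = []
        if self.end_year < self.start_year:
            e.append("end_year before start_year")
        if not 2010 <= self.start_year <= 2100 or self.end_year > 2100:
            e.append("years must lie in [2010, 2100]")
        if self.yield_window < 1:
            e.append("yield_window must be >= 1")
        if self.spinup_threshold <= 0:
            e.append("spinup_threshold must be > 0")
        if self.max_spinup_iterations < 1:
            e.append("max_spinup_iterations must be >= 1")
        if self.ensemble_size < 1:
            e.append("ensemble_size must be >= 1")
        if not 0 <= self.perturbation_half_width <= 1:
            e.append("perturbation_half_width must be in [0, 1] "
                     "(parameters would go negative)")
        if self.price_lambda <= 0:
            e.append("price_lambda must be > 0")
        if self.stocks_to_use < 0:
            e.append("stocks_to_use must be >= 0")
        if not 0 <= self.water_reserve_fraction < 1:
            e.append("water_reserve_fraction must be in [0, 1)")
        if self.n_history_years < 3:
            e.append("n_history_years must be >= 3")
        return e

    def validate(self) -> "ScenarioConfig":
        errs = self.validation_errors()
        if errs:
            raise ConfigError(errs)
        return self


#: Cost/market parameters perturbed by the uncertainty ensemble.
PERTURBABLE_PARAMETERS: tuple[str, ...] = (
    "base_cost",
    "pasture_base_cost",
    "management_cost",
    "pasture_management_cost",
    "fertiliser_price",
    "irrigation_cost_per_km3",
    "conversion_cost_natural_to_ag",
    "conversion_cost_ag_to_natural",
    "conversion_cost_cropland_pasture",
    "fcr_ruminant",
    "fcr_monogastric",
)


# ---------------------------------------------------------------------------
# Results objects
# ---------------------------------------------------------------------------


@dataclass
class SpinUpResults:
    """Converged (or flagged) baseline land-use state."""

    iterations: int
    converged: bool
    max_rel_change: float  # at the terminating iteration
    change_history: list[float]
    solutions: dict[str, CountrySolution]
    threshold: float

    def summary(self) -> str:
        status = "converged" if self.converged else "NOT converged (max iterations)"
        return (
            f"Spin-up {status} after {self.iterations} iterations\n"
            f"terminal max relative change: {100 * self.max_rel_change:.4f}% "
            f"(threshold {100 * self.threshold:.2f}%)\n"
            f"countries: {', '.join(sorted(self.solutions))}"
        )


@dataclass
class ScenarioResults:
    """Annual global/country/market time series of one scenario run."""

    config: ScenarioConfig
    global_series: pd.DataFrame  # indexed by year
    country_series: pd.DataFrame
    market_series: pd.DataFrame
    spin_up: SpinUpResults
    final_cells: pd.DataFrame
    audits: pd.DataFrame

    def summary(self) -> str:
        g = self.global_series
        first, last = g.index.min(), g.index.max()
        lines = [
            f"Scenario {first}-{last} "
            f"(seed {self.config.seed}, lambda {self.config.price_lambda})",
            self.spin_up.summary(),
            f"{'year':>6}{'cropland_Mha':>14}{'pasture_Mha':>13}"
            f"{'nitrogen_Mt':>13}{'irrigation_km3':>16}",
        ]
        for y in (first, last):
            r = g.loc[y]
            lines.append(
                f"{y:>6}{r.cropland_ha / 1e6:>14.3f}{r.pasture_ha / 1e6:>13.3f}"
                f"{r.nitrogen_t / 1e6:>13.4f}{r.irrigation_km3:>16.3f}"
            )
        return "\n".join(lines)


@dataclass
class EnsembleResults:
    """Median and dispersion of global outputs across a parameter ensemble."""

    n: int
    half_width: float
    member_series: list[pd.DataFrame]
    samples: pd.DataFrame

    @property
    def median(self) -> pd.DataFrame:
        return pd.concat(self.member_series).groupby(level=0).median()

    @property
    def std(self) -> pd.DataFrame:
        return pd.concat(self.member_series).groupby(level=0).std(ddof=0)

    def summary(self) -> str:
        med = self.median
        return (
            f"Ensemble of {self.n} members (half-width {self.half_width:+.0%})\n"
            f"final-year median cropland: {med.cropland_ha.iloc[-1] / 1e6:.3f} Mha, "
            f"std {self.std.cropland_ha.iloc[-1] / 1e6:.3f} Mha"
        )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class LandUseModel:
    """Coupled land-use/food-system model over a world grid.

    Parameters
    ----------
    world, anchors:
        The spatial world and its factorial yield anchors.
    config:
        Scenario configuration; validated on construction.
    demand:
        Optionally a pre-fitted :class:`DemandResults`; otherwise the Engel
        model is fitted on a generated synthetic history.
    """

    def __init__(self, world: WorldGrid, anchors: YieldAnchorSet,
                 config: ScenarioConfig | None = None,
                 demand: DemandResults | None = None):
        self.world = world
        self.anchors = anchors
        self.config = (config or ScenarioConfig()).validate()
        if demand is None:
            history = generate_history(world, self.config.n_history_years,
                                       seed=self.config.history_seed)
            demand = fit_demand_model(history, base_year=world.base_year,
                                      kappa=self.config.kappa)
        self.demand = demand
        self._prepared = False

    @classmethod
    def from_synthetic(cls, n_countries: int = 3, cells_per_country: int = 20,
                       n_crops: int = 7, seed: int = 0,
                       config: ScenarioConfig | None = None) -> "LandUseModel":
        config = config or ScenarioConfig(seed=seed)
        world, anchors = generate_world(n_countries, cells_per_country, n_crops, seed=seed)
        return cls(world, anchors, config)

    # -- preparation -------------------------------------------------------
    def _prepare(self) -> None:
        if self._prepared:
            return
        cfg = self.config
        self.land_use_names = land_uses(self.world.crops)
        self.water_budget = build_water_budget(
            self.world, self.anchors, reserve_fraction=cfg.water_reserve_fraction
        )
        self.clusters: dict[str, list[Cluster]] = {}
        self.states: dict[str, CountryState] = {}
        self.surfaces: dict[str, SurfaceArray] = {}
        self._anchor_window: deque[np.ndarray] = deque(maxlen=cfg.yield_window)
        for rec in sorted(self.world.countries, key=lambda r: r.id):
            k = min(choose_k(self.world, self.anchors, rec.id), cfg.max_cluster_count)
            cls = cluster_country(self.world, self.anchors, rec.id, k, seed=cfg.seed)
            attach_water(cls, self.water_budget)
            self.clusters[rec.id] = cls
            self.states[rec.id] = CountryState.from_clusters(
                cls, self.land_use_names, china_flag=rec.china_flag
            )
        self._push_anchors(self.anchors.yields)
        cropland = self._global_cropland_baseline()
        if cfg.secondgen_scale is None:
            cfg.secondgen_scale = cropland / REFERENCE_CROPLAND_HA
        groups = tuple(
            sorted({c for r in self.world.countries for c in r.baseline_consumption})
        )
        self.market = MarketState.initial(
            groups if ENERGY in groups else groups + (ENERGY,),
            prices=cfg.initial_prices,
            annual_use=self._baseline_use(),
            stocks_to_use=cfg.stocks_to_use,
            price_lambda=cfg.price_lambda,
        )
        self._prepared = True

    def _global_cropland_baseline(self) -> float:
        t = self.world.cells_table
        cols = [f"cover_{c}" for c in self.world.crops]
        return float((t[cols].sum(axis=1) * t.area_ha).sum())

    def _baseline_use(self) -> dict[str, float]:
        use: dict[str, float] = {}
        for rec in self.world.countries:
            for c, v in rec.baseline_consumption.items():
                use[c] = use.get(c, 0.0) + v
        use[ENERGY] = 34e6 * (self.config.secondgen_scale or 1.0)
        return use

    def _push_anchors(self, yields: np.ndarray) -> None:
        """Append this year's anchor block and refit surfaces on the
        trailing-window mean."""
        self._anchor_window.append(yields)
        mean = np.mean(list(self._anchor_window), axis=0)
        id_to_pos = {int(c): i for i, c in enumerate(self.world.cells_table.cell_id)}
        for cid, cls in self.clusters.items():
            blocks, reqs = [], []
            for cl in cls:
                pos = [id_to_pos[c] for c in cl.cell_ids]
                w = self.world.cells_table.area_ha.to_numpy()[pos]
                w = w / w.sum()
                blocks.append(np.einsum("c,cluw->luw", w, mean[pos]))
                reqs.append(cl.mean_irrigation_requirement)
            self.surfaces[cid] = SurfaceArray.from_anchor_block(
                np.stack(blocks), np.stack(reqs),
                tech_rate=self.config.tech_rate,
                base_year=self.world.base_year,
            )

    # -- demand ------------------------------------------------------------
    def _food_demand(self, year: int) -> dict[str, dict[str, float]]:
        gdp = {r.id: float(r.gdp_pc_trajectory[year]) for r in self.world.countries}
        pop = {r.id: float(r.population_trajectory[year]) for r in self.world.countries}
        gdp0 = {r.id: float(r.gdp_pc_trajectory[self.world.base_year])
                for r in self.world.countries}
        proj = self.demand.project(year, gdp, pop, gdp0,
                                   convergence_on=self.config.convergence_on)
        out: dict[str, dict[str, float]] = {r.id: {} for r in self.world.countries}
        for row in proj.itertuples(index=False):
            out[row.country_id][row.commodity] = row.total_t
        return out

    def _bioenergy(self, year: int):
        baseline = {r.id: getattr(r, "baseline_firstgen", {}) for r in self.world.countries}
        firstgen, secondgen = bioenergy_demand(year, baseline)
        return firstgen, secondgen * (self.config.secondgen_scale or 1.0)

    # -- spin-up -----------------------------------------------------------
    def spin_up(self) -> SpinUpResults:
        """Iterative baseline initialisation at fixed demand and net imports."""
        self._prepare()
        cfg = self.config
        year = self.world.base_year
        demand = {r.id: dict(r.baseline_consumption) for r in self.world.countries}
        firstgen, _ = self._bioenergy(year)
        solutions: dict[str, CountrySolution] = {}
        history: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.max_spinup_iterations + 1):
            max_change = 0.0
            for rec in sorted(self.world.countries, key=lambda r: r.id):
                cid = rec.id
                state = self.states[cid]
                sol = optimise_country(
                    state, demand[cid], self.market.prices, self.surfaces[cid],
                    cfg.costs, year, firstgen=firstgen.get(cid, {}),
                    net_imports=rec.baseline_net_imports, seed=cfg.seed,
                    maxiter=cfg.solver_maxiter,
                )
                improvement = (sol.diagnostics["warm_objective"]
                               - sol.diagnostics["best_penalised_objective"])
                scale = abs(sol.diagnostics["warm_objective"]) + 1.0
                if improvement < _SPINUP_ACCEPT_RTOL * scale:
                    # no material improvement: freeze the current state
                    sol = optimise_country(
                        state, demand[cid], self.market.prices, self.surfaces[cid],
                        cfg.costs, year, firstgen=firstgen.get(cid, {}),
                        net_imports=rec.baseline_net_imports, seed=cfg.seed,
                        solve=False,
                    )
                change = self._state_change(state, sol)
                max_change = max(max_change, change)
                self.states[cid] = self._adopt(state, sol)
                solutions[cid] = sol
            history.append(max_change)
            if max_change < cfg.spinup_threshold:
                converged = True
                break
        if not converged:
            import warnings

            warnings.warn(
                f"spin-up did not converge in {cfg.max_spinup_iterations} iterations "
                f"(last max change {100 * history[-1]:.3f}%)"
            )
        self._disaggregate_all(solutions)
        return SpinUpResults(
            iterations=it,
            converged=converged,
            max_rel_change=history[-1] if history else 0.0,
            change_history=history,
            solutions=solutions,
            threshold=cfg.spinup_threshold,
        )

    def _state_change(self, state: CountryState, sol: CountrySolution) -> float:
        avail = np.array([cl.area_ha for cl in state.clusters])[:, None]
        floor_a = _AREA_CHANGE_FLOOR_FRAC * np.maximum(avail, 1.0)
        rel_a = np.abs(sol.areas - state.areas) / np.maximum(
            np.maximum(np.abs(state.areas), np.abs(sol.areas)), floor_a
        )
        changes = [rel_a.max() if rel_a.size else 0.0]
        for new, old, scale in (
            (sol.fert, state.fert, 1000.0 * _INTENSITY_CHANGE_FLOOR),
            (sol.irr, state.irr, _INTENSITY_CHANGE_FLOOR),
            (sol.mgmt, state.mgmt, _INTENSITY_CHANGE_FLOOR),
        ):
            rel = np.abs(new - old) / np.maximum(
                np.maximum(np.abs(old), np.abs(new)), scale
            )
            changes.append(rel.max() if rel.size else 0.0)
        return float(max(changes))

    @staticmethod
    def _adopt(state: CountryState, sol: CountrySolution) -> CountryState:
        return replace(
            state,
            areas=sol.areas.copy(),
            fert=sol.fert.copy(),
            irr=sol.irr.copy(),
            mgmt=sol.mgmt.copy(),
            forest=sol.forest.copy(),
            other_natural=sol.other_natural.copy(),
        )

    def _disaggregate_all(self, solutions: dict[str, CountrySolution]) -> None:
        """Map cluster deltas to cells and update the world cover table."""
        table = self.world.cells_table
        for cid, sol in solutions.items():
            cls = self.clusters[cid]
            for k, cl in enumerate(cls):
                deltas = {}
                for j, lu in enumerate(self.land_use_names):
                    deltas[lu] = float(sol.areas[k, j] - cl.areas[lu])
                rows = disaggregate(
                    self.world, cl, deltas,
                    min_natural_fraction=self.config.costs.min_natural_fraction,
                )
                table.loc[rows.index, rows.columns] = rows
                for j, lu in enumerate(self.land_use_names):
                    cl.areas[lu] = float(sol.areas[k, j])
                cl.areas["forest"] = float(sol.forest[k])
                cl.areas["other_natural"] = float(sol.other_natural[k])

    # -- annual step -------------------------------------------------------
    def run_timestep(self, year: int) -> dict:
        """One annual step; returns the per-year record."""
        cfg = self.config
        self._push_anchors(self.anchors.yields)  # trailing-window refresh
        food = self._food_demand(year)
        firstgen, secondgen_dem = self._bioenergy(year)
        solutions: dict[str, CountrySolution] = {}
        audits = {}
        for rec in sorted(self.world.countries, key=lambda r: r.id):
            cid = rec.id
            state = self.states[cid]
            sol = optimise_country(
                state, food[cid], self.market.prices, self.surfaces[cid],
                cfg.costs, year, firstgen=firstgen.get(cid, {}),
                seed=cfg.seed, maxiter=cfg.solver_maxiter,
            )
            audits[cid] = audit_solution(state, sol, food[cid], cfg.costs,
                                         firstgen.get(cid, {}))
            solutions[cid] = sol
        exports = {c: 0.0 for c in self.market.prices}
        imports = {c: 0.0 for c in self.market.prices}
        secondgen_prod = 0.0
        for sol in solutions.values():
            for c in self.market.prices:
                if c == ENERGY:
                    secondgen_prod += sol.exports.get(c, 0.0)
                    continue
                exports[c] += sol.exports.get(c, 0.0)
                imports[c] += sol.imports.get(c, 0.0)
        self.market = settle_market(
            self.market, exports, imports,
            secondgen_production=secondgen_prod, secondgen_demand=secondgen_dem,
        )
        for cid, sol in solutions.items():
            self.states[cid] = self._adopt(self.states[cid], sol)
        self._disaggregate_all(solutions)
        return {
            "year": year,
            "solutions": solutions,
            "audits": audits,
            "food": food,
            "firstgen": firstgen,
            "secondgen_demand": secondgen_dem,
            "secondgen_production": secondgen_prod,
        }

    # -- scenario ----------------------------------------------------------
    def simulate(self, spin_up_results: SpinUpResults | None = None) -> ScenarioResults:
        """Run the configured scenario; deterministic under the seed."""
        self._prepare()
        cfg = self.config
        spin = spin_up_results or self.spin_up()
        grows, crows, mrows, arows = [], [], [], []
        for year in range(cfg.start_year, cfg.end_year + 1):
            rec = self.run_timestep(year)
            grows.append(self._global_record(year, rec))
            for cid, sol in rec["solutions"].items():
                crows.append(self._country_record(year, cid, sol, rec))
                for name, ok in rec["audits"][cid].items():
                    arows.append({"year": year, "country_id": cid,
                                  "check": name, "ok": bool(ok)})
            for com in self.market.prices:
                mrows.append(
                    {
                        "year": year,
                        "commodity": com,
                        "price": self.market.prices[com],
                        "stock": self.market.stocks[com],
                        "exports": self.market.exports.get(com, 0.0),
                        "imports": self.market.imports.get(com, 0.0),
                        "oversupply": self.market.oversupply.get(com, 0.0),
                        "unmet": self.market.unmet.get(com, 0.0),
                    }
                )
        return ScenarioResults(
            config=cfg,
            global_series=pd.DataFrame(grows).set_index("year"),
            country_series=pd.DataFrame(crows),
            market_series=pd.DataFrame(mrows),
            spin_up=spin,
            final_cells=self.world.cells_table.copy(),
            audits=pd.DataFrame(arows),
        )

    def _global_record(self, year: int, rec: dict) -> dict:
        crop_idx = [j for j, lu in enumerate(self.land_use_names) if lu != PASTURE]
        pj = self.land_use_names.index(PASTURE)
        cropland = pasture = nitrogen = water = forest = othernat = 0.0
        for cid, sol in rec["solutions"].items():
            cropland += float(sol.areas[:, crop_idx].sum())
            pasture += float(sol.areas[:, pj].sum())
            nitrogen += float((sol.fert * sol.areas).sum() / 1000.0)  # kg -> t
            water += float(sol.water_use.sum())
            forest += float(sol.forest.sum())
            othernat += float(sol.other_natural.sum())
        return {
            "year": year,
            "cropland_ha": cropland,
            "pasture_ha": pasture,
            "forest_ha": forest,
            "other_natural_ha": othernat,
            "nitrogen_t": nitrogen,
            "irrigation_km3": water,
            "secondgen_production_t": rec["secondgen_production"],
            "secondgen_demand_t": rec["secondgen_demand"],
        }

    def _country_record(self, year: int, cid: str, sol: CountrySolution,
                        rec: dict) -> dict:
        out = {"year": year, "country_id": cid, "objective": sol.objective}
        feed_by_com = {"cereals": sol.feed.get("ruminant", 0.0)
                       + sol.feed.get("monogastric", 0.0)}
        for com in self.market.prices:
            out[f"production_{com}"] = sol.production.get(com, 0.0)
            out[f"imports_{com}"] = sol.imports.get(com, 0.0)
            out[f"exports_{com}"] = sol.exports.get(com, 0.0)
            out[f"food_{com}"] = rec["food"][cid].get(com, 0.0)
            out[f"firstgen_{com}"] = rec["firstgen"].get(cid, {}).get(com, 0.0)
            out[f"feed_{com}"] = feed_by_com.get(com, 0.0)
        return out


# ---------------------------------------------------------------------------
# Functional entry points
# ---------------------------------------------------------------------------


def spin_up(world: WorldGrid, anchors: YieldAnchorSet,
            config: ScenarioConfig | None = None) -> tuple[LandUseModel, SpinUpResults]:
    """Build a model and run the iterative baseline initialisation."""
    model = LandUseModel(world, anchors, config)
    return model, model.spin_up()


def run_scenario(config: ScenarioConfig, world: WorldGrid | None = None,
                 anchors: YieldAnchorSet | None = None,
                 n_countries: int = 3, cells_per_country: int = 20,
                 n_crops: int = 7) -> ScenarioResults:
    """Run one scenario end to end (generating a world if none is given)."""
    config.validate()
    if world is None:
        world, anchors = generate_world(n_countries, cells_per_country, n_crops,
                                        seed=config.seed)
    model = LandUseModel(world, anchors, config)
    return model.simulate()


def run_ensemble(config: ScenarioConfig, n: int | None = None,
                 half_width: float | None = None,
                 world: WorldGrid | None = None,
                 anchors: YieldAnchorSet | None = None,
                 **world_kw) -> EnsembleResults:
    """Sobol-sampled parameter-uncertainty ensemble.

    The perturbable cost parameters are drawn from uniform boxes
    ``[c*(1-h), c*(1+h)]`` around their central values with a scrambled
    Sobol low-discrepancy sequence; each member runs the full scenario and
    the per-year median and standard deviation of the global outputs are
    available on the result.
    """
    n = config.ensemble_size if n is None else n
    h = config.perturbation_half_width if half_width is None else half_width
    if n < 1:
        raise ConfigError(["ensemble size must be >= 1"])
    if not PERTURBABLE_PARAMETERS:
        raise ConfigError(["empty perturbable parameter set"])
    if world is None:
        world, anchors = generate_world(
            world_kw.pop("n_countries", 3), world_kw.pop("cells_per_country", 12),
            world_kw.pop("n_crops", 3), seed=config.seed,
        )
    import warnings as _warnings

    sampler = qmc.Sobol(d=len(PERTURBABLE_PARAMETERS), scramble=True, seed=config.seed)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n)
    central = np.array([getattr(config.costs, p) for p in PERTURBABLE_PARAMETERS])
    samples = central * (1 - h) + u * (central * 2 * h)
    members = []
    for i in range(n):
        costs = replace(config.costs, **{
            p: float(samples[i, j]) for j, p in enumerate(PERTURBABLE_PARAMETERS)
        })
        member_cfg = replace(config, costs=costs)
        model = LandUseModel(copy.deepcopy(world), copy.deepcopy(anchors), member_cfg)
        res = model.simulate()
        members.append(res.global_series)
    return EnsembleResults(
        n=n, half_width=h, member_series=members,
        samples=pd.DataFrame(samples, columns=list(PERTURBABLE_PARAMETERS)),
    )
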