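"""Readers and writers for every artifact format.

Gridded fields go to CF-style NetCDF (lat/lon dims, units attributes,
written with xarray's scipy backend); tabular artifacts are tidy CSV;
configs are YAML validated exhaustively before any compute.  All writers
are deterministic: the same state produces byte-identical files.  Monetary
fields are 2010 US$ and stamped as such in metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .commodities import FERT_LEVELS
from .grid import CountryRecord, FPURecord, WorldGrid, YieldAnchorSet
from .simulation_driver import ConfigError, CostParameters, ScenarioConfig

CURRENCY = "2010 US$"


class SchemaError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


# ---------------------------------------------------------------------------
# World round-trip
# ---------------------------------------------------------------------------

_GRID_VARS = ("area_ha", "protected_fraction", "aridity_index", "runoff")


def write_world(world: WorldGrid, anchors: YieldAnchorSet, path: str | Path) -> Path:
    """Write the world as grid.nc + countries.csv + trajectories.csv + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = world.cells_table.sort_values("cell_id")
    lats = np.unique(t.lat)
    lons = np.unique(t.lon)
    li = {v: i for i, v in enumerate(lats)}
    lj = {v: j for j, v in enumerate(lons)}
    shape = (len(lats), len(lons))

    def rasterise(values: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        for (la, lo, v) in zip(t.lat, t.lon, values):
            out[li[la], lj[lo]] = v
        return out

    data = {}
    for cls in world.cover_classes:
        data[f"cover_{cls}"] = (("lat", "lon"), rasterise(t[f"cover_{cls}"].to_numpy()),
                                {"units": "1"})
    for var in ("area_ha", "protected_fraction", "aridity_index"):
        units = "ha" if var == "area_ha" else "1"
        data[var] = (("lat", "lon"), rasterise(t[var].to_numpy()), {"units": units})
    order = t.cell_id.to_numpy()
    data["cell_id"] = (("lat", "lon"), rasterise(order.astype(float)), {"units": "1"})
    data["runoff"] = (("lat", "lon"), rasterise(anchors.runoff[order]), {"units": "km3 yr-1"})
    n_lu = len(anchors.land_uses)
    yld = np.full((n_lu, 3, 2) + shape, np.nan)
    req = np.full((n_lu,) + shape, np.nan)
    for row, (la, lo) in enumerate(zip(t.lat, t.lon)):
        cid = order[row]
        yld[:, :, :, li[la], lj[lo]] = anchors.yields[cid]
        req[:, li[la], lj[lo]] = anchors.irrigation_requirement[cid]
    data["yield_anchor"] = (("land_use", "fert_level", "water_regime", "lat", "lon"),
                            yld, {"units": "t ha-1"})
    data["irrigation_requirement"] = (("land_use", "lat", "lon"), req,
                                      {"units": "km3 ha-1 yr-1"})
    ds = xr.Dataset(
        data,
        coords={
            "lat": ("lat", lats, {"units": "degrees_north"}),
            "lon": ("lon", lons, {"units": "degrees_east"}),
            "fert_level": ("fert_level", np.asarray(FERT_LEVELS), {"units": "kgN ha-1"}),
            "water_regime": ("water_regime", np.arange(2)),
            "land_use": ("land_use", np.arange(n_lu)),
        },
        attrs={"resolution_deg": world.resolution_deg, "currency": CURRENCY,
               "base_year": world.base_year},
    )
    ds.to_netcdf(path / "grid.nc", engine="scipy")

    crows, trows = [], []
    for c in world.countries:
        row = {"id": c.id, "china_flag": int(c.china_flag)}
        for com, v in sorted(c.baseline_consumption.items()):
            row[f"consumption_{com}"] = v
        for com, v in sorted(c.baseline_net_imports.items()):
            row[f"net_imports_{com}"] = v
        for com, v in sorted(getattr(c, "baseline_firstgen", {}).items()):
            row[f"firstgen_{com}"] = v
        crows.append(row)
        for year in c.gdp_pc_trajectory.index:
            trows.append({"id": c.id, "year": int(year),
                          "gdp_pc": float(c.gdp_pc_trajectory[year]),
                          "population": float(c.population_trajectory[year])})
    pd.DataFrame(crows).to_csv(path / "countries.csv", index=False)
    pd.DataFrame(trows).to_csv(path / "trajectories.csv", index=False)

    meta = {
        "resolution_deg": world.resolution_deg,
        "base_year": world.base_year,
        "crops": list(world.crops),
        "currency": CURRENCY,
        "cell_country": {str(int(c)): str(cc) for c, cc in zip(t.cell_id, t.country_id)},
        "cell_fpu": {str(int(c)): str(f) for c, f in zip(t.cell_id, t.fpu_id)},
        "fpus": [{"id": f.id, "country_id": f.country_id,
                  "cell_ids": [int(x) for x in f.cell_ids]} for f in world.fpus],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_world(path: str | Path) -> tuple[WorldGrid, YieldAnchorSet]:
    """Read a world written by :func:`write_world`, validating the schema."""
    path = Path(path)
    errors = []
    for fname in ("grid.nc", "countries.csv", "trajectories.csv", "meta.json"):
        if not (path / fname).exists():
            errors.append(f"missing file {fname}")
    if errors:
        raise SchemaError(errors)
    meta = json.loads((path / "meta.json").read_text())
    with xr.open_dataset(path / "grid.nc", engine="scipy") as dsf:
        ds = dsf.load()
    crops = tuple(meta["crops"])
    classes = crops + ("pasture", "forest", "other_natural", "urban")
    required = [f"cover_{c}" for c in classes] + list(_GRID_VARS) + [
        "cell_id", "yield_anchor", "irrigation_requirement"]
    errors = [f"grid.nc missing variable {v}" for v in required if v not in ds]
    if errors:
        raise SchemaError(errors)

    lat2d, lon2d = np.meshgrid(ds.lat.values, ds.lon.values, indexing="ij")
    flat_id = ds.cell_id.values.ravel()
    mask = ~np.isnan(flat_id)
    order = np.argsort(flat_id[mask])

    def flat(var):
        return ds[var].values.ravel()[mask][order]

    n = int(mask.sum())
    rows = {
        "cell_id": flat("cell_id").astype(int),
        "lat": lat2d.ravel()[mask][order],
        "lon": lon2d.ravel()[mask][order],
        "area_ha": flat("area_ha"),
        "protected_fraction": flat("protected_fraction"),
        "aridity_index": flat("aridity_index"),
    }
    rows["country_id"] = [meta["cell_country"][str(c)] for c in rows["cell_id"]]
    rows["fpu_id"] = [meta["cell_fpu"][str(c)] for c in rows["cell_id"]]
    for cls in classes:
        rows[f"cover_{cls}"] = flat(f"cover_{cls}")
    table = pd.DataFrame(rows)

    n_lu = ds.sizes["land_use"]
    yields = np.empty((n, n_lu, 3, 2))
    req = np.empty((n, n_lu))
    y = ds.yield_anchor.values.reshape(n_lu, 3, 2, -1)[..., mask][..., order]
    r = ds.irrigation_requirement.values.reshape(n_lu, -1)[:, mask][:, order]
    yields = np.moveaxis(y, -1, 0)
    req = np.moveaxis(r, -1, 0)
    runoff = flat("runoff")

    ctab = pd.read_csv(path / "countries.csv")
    ttab = pd.read_csv(path / "trajectories.csv")
    countries = []
    for row in ctab.itertuples(index=False):
        traj = ttab[ttab.id == row.id].set_index("year").sort_index()
        cons = {c.removeprefix("consumption_"): getattr(row, c)
                for c in ctab.columns if c.startswith("consumption_")}
        ni = {c.removeprefix("net_imports_"): getattr(row, c)
              for c in ctab.columns if c.startswith("net_imports_")}
        rec = CountryRecord(
            id=row.id,
            gdp_pc_trajectory=traj.gdp_pc,
            population_trajectory=traj.population,
            baseline_consumption=cons,
            baseline_net_imports=ni,
            china_flag=bool(row.china_flag),
        )
        rec.baseline_firstgen = {c.removeprefix("firstgen_"): getattr(row, c)
                                 for c in ctab.columns if c.startswith("firstgen_")}
        countries.append(rec)
    fpus = [FPURecord(**f) for f in meta["fpus"]]
    world = WorldGrid(
        resolution_deg=float(meta["resolution_deg"]),
        crops=crops,
        cells_table=table,
        countries=countries,
        fpus=fpus,
        base_year=int(meta["base_year"]),
    )
    anchors = YieldAnchorSet(
        crops=crops, yields=yields, irrigation_requirement=req, runoff=runoff
    )
    world.validate()
    anchors.validate()
    return world, anchors


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


def validate_config(path: str | Path) -> ScenarioConfig:
    """Parse and exhaustively validate a YAML scenario config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors = []
    cost_fields = set(CostParameters.__dataclass_fields__)
    cfg_fields = set(ScenarioConfig.__dataclass_fields__) - {"costs"}
    costs_raw = raw.pop("costs", {}) or {}
    unknown = [k for k in raw if k not in cfg_fields]
    errors += [f"unknown config field: {k}" for k in unknown]
    errors += [f"unknown cost field: {k}" for k in costs_raw if k not in cost_fields]
    if errors:
        raise ConfigError(errors)
    try:
        costs = CostParameters(**costs_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError([f"costs: {exc}"]) from exc
    cfg = ScenarioConfig(costs=costs, **{k: v for k, v in raw.items() if k in cfg_fields})
    errs = cfg.validation_errors()
    if cfg.price_lambda is not None and cfg.price_lambda < 0:
        errs.append("price_lambda must be positive")
    if errs:
        raise ConfigError(errs)
    return cfg


def write_config(cfg: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    d = asdict(cfg)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------


def write_run(results, path: str | Path) -> Path:
    """Write a scenario run: CSV time series, final cover maps, manifest."""
    from . import __version__

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    results.global_series.to_csv(path / "global_series.csv")
    results.country_series.to_csv(path / "country_series.csv", index=False)
    results.market_series.to_csv(path / "market_series.csv", index=False)
    results.audits.to_csv(path / "audits.csv", index=False)
    manifest = {
        "config": _jsonable(asdict(results.config)),
        "seeds": {"master": results.config.seed},
        "versions": {"plumlite": __version__},
        "currency": CURRENCY,
        "invariant_audit": {
            "all_passed": bool(results.audits.ok.all()) if len(results.audits) else True,
            "checks": int(len(results.audits)),
        },
        "spin_up": {
            "iterations": results.spin_up.iterations,
            "converged": results.spin_up.converged,
            "max_rel_change": results.spin_up.max_rel_change,
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
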