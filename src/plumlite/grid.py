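"""World grid containers: cells, countries, FPUs and factorial yield anchors.

The grid is deliberately array-oriented: cell attributes live in a pandas
DataFrame (one row per cell) and the factorial yield anchors in a dense
numpy block indexed ``(cell, land_use, fertiliser_level, water_regime)``.
Light dataclass views (:class:`GridCell`) are provided for per-cell access.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lattice
from .commodities import FERT_LEVELS, NATURAL_CLASSES, PASTURE, URBAN, land_uses


class WorldInvariantError(ValueError):
    """A generated or loaded world violates a structural invariant."""


@dataclass
class GridCell:
    """Read-only view of one grid cell."""

    cell_id: int
    lat: float
    lon: float
    area_ha: float
    cover: dict[str, float]
    protected_fraction: float
    country_id: str
    fpu_id: str
    aridity_index: float


@dataclass
class CountryRecord:
    """Socio-economic record for one country (or aggregated region)."""

    id: str
    gdp_pc_trajectory: pd.Series  # currency per capita, indexed by year
    population_trajectory: pd.Series  # persons, indexed by year
    baseline_consumption: dict[str, float]  # tonnes per commodity at base year
    baseline_net_imports: dict[str, float]  # tonnes per commodity at base year
    china_flag: bool = False  # subject to the annual deforestation cap

    def validate(self) -> None:
        if (self.gdp_pc_trajectory <= 0).any():
            raise WorldInvariantError(f"country {self.id}: non-positive GDP per capita")
        if (self.population_trajectory <= 0).any():
            raise WorldInvariantError(f"country {self.id}: non-positive population")
        if any(v < 0 for v in self.baseline_consumption.values()):
            raise WorldInvariantError(f"country {self.id}: negative baseline consumption")


@dataclass
class FPURecord:
    """Food production unit: a runoff-pooling group of cells within a country."""

    id: str
    country_id: str
    cell_ids: list[int]


@dataclass
class WorldGrid:
    """The spatial world: cell table plus country and FPU membership.

    ``cells_table`` columns: cell_id, lat, lon, area_ha, country_id, fpu_id,
    protected_fraction, aridity_index and one ``cover_<class>`` column per
    land-cover class (per-crop cropland, pasture, forest, other natural,
    urban+barren).
    """

    resolution_deg: float
    crops: tuple[str, ...]
    cells_table: pd.DataFrame
    countries: list[CountryRecord]
    fpus: list[FPURecord]
    base_year: int = 2010

    @property
    def cover_classes(self) -> tuple[str, ...]:
        return land_uses(self.crops) + NATURAL_CLASSES + (URBAN,)

    @property
    def n_cells(self) -> int:
        return len(self.cells_table)

    @property
    def cells(self) -> list[GridCell]:
        out = []
        for row in self.cells_table.itertuples(index=False):
            cover = {c: getattr(row, f"cover_{c}") for c in self.cover_classes}
            out.append(
                GridCell(
                    cell_id=int(row.cell_id),
                    lat=float(row.lat),
                    lon=float(row.lon),
                    area_ha=float(row.area_ha),
                    cover=cover,
                    protected_fraction=float(row.protected_fraction),
                    country_id=str(row.country_id),
                    fpu_id=str(row.fpu_id),
                    aridity_index=float(row.aridity_index),
                )
            )
        return out

    def country(self, country_id: str) -> CountryRecord:
        for c in self.countries:
            if c.id == country_id:
                return c
        raise KeyError(country_id)

    def country_cells(self, country_id: str) -> pd.DataFrame:
        return self.cells_table[self.cells_table.country_id == country_id]

    def cover_matrix(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Cover fractions as (n_cells, n_classes) in ``cover_classes`` order."""
        t = self.cells_table if rows is None else rows
        return t[[f"cover_{c}" for c in self.cover_classes]].to_numpy()

    def validate(self) -> None:
        t = self.cells_table
        if (t.area_ha <= 0).any():
            raise WorldInvariantError("non-positive cell area")
        for axis in ("lat", "lon"):
            if not lattice.is_on_lattice(t[axis].to_numpy(), self.resolution_deg).all():
                raise WorldInvariantError(f"{axis} coordinates off the resolution lattice")
        cov = self.cover_matrix()
        if (cov < -1e-12).any() or (cov > 1 + 1e-12).any():
            raise WorldInvariantError("cover fraction outside [0, 1]")
        if np.abs(cov.sum(axis=1) - 1.0).max() > 1e-9:
            raise WorldInvariantError("land-cover fractions do not sum to 1")
        pf = t.protected_fraction.to_numpy()
        nat = t.cover_forest.to_numpy() + t.cover_other_natural.to_numpy()
        if (pf < -1e-12).any() or (pf > nat + 1e-9).any():
            raise WorldInvariantError("protected fraction outside [0, forest + other natural]")
        country_ids = {c.id for c in self.countries}
        if not set(t.country_id).issubset(country_ids):
            raise WorldInvariantError("cell assigned to unknown country")
        fpu_members: dict[int, int] = {}
        for f in self.fpus:
            for cid in f.cell_ids:
                fpu_members[cid] = fpu_members.get(cid, 0) + 1
        if sorted(fpu_members) != sorted(t.cell_id) or any(v != 1 for v in fpu_members.values()):
            raise WorldInvariantError("cells must belong to exactly one FPU")
        for c in self.countries:
            c.validate()


@dataclass
class YieldAnchorSet:
    """Factorial yield potentials and water variables for every cell.

    ``yields`` has shape ``(n_cells, n_land_uses, 3, 2)`` — fertiliser axis
    over 0/200/1000 kgN/ha, water axis over rain-fed/irrigated — in t/ha.
    Pasture is the final land-use row; its rain-fed mid-fertiliser anchor is
    exposed as :attr:`pasture_yield`.  ``irrigation_requirement`` is the
    full-irrigation water demand in km3 per hectare per year;  ``runoff`` is
    km3 per cell per year.
    """

    crops: tuple[str, ...]
    yields: np.ndarray
    irrigation_requirement: np.ndarray  # (n_cells, n_land_uses) km3/ha/yr
    runoff: np.ndarray  # (n_cells,) km3/yr
    fert_levels: tuple[float, ...] = FERT_LEVELS

    @property
    def land_uses(self) -> tuple[str, ...]:
        return land_uses(self.crops)

    @property
    def pasture_yield(self) -> np.ndarray:
        return self.yields[:, -1, 1, 0]

    def validate(self) -> None:
        y = self.yields
        if y.ndim != 4 or y.shape[1] != len(self.crops) + 1 or y.shape[2:] != (3, 2):
            raise WorldInvariantError("anchor block has wrong shape")
        if (y < 0).any():
            raise WorldInvariantError("negative yield anchor")
        if (np.diff(y, axis=2) < -1e-9).any():
            raise WorldInvariantError("yield anchors decrease with fertiliser")
        if (y[..., 1] - y[..., 0] < -1e-9).any():
            raise WorldInvariantError("irrigated anchor below rain-fed anchor")
        if (self.irrigation_requirement < 0).any():
            raise WorldInvariantError("negative irrigation requirement")
        if (self.runoff < 0).any():
            raise WorldInvariantError("negative runoff")
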