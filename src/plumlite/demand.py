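"""Country-level commodity demand: Engel regression, projection, bioenergy.

Food demand per commodity group follows a log-log Engel relationship fitted
on pooled country history, weighted by population:

    ln(consumption per capita) = a + b * ln(GDP per capita) + d_i

Country offsets ``d_i`` capture persistent dietary differences from the
global curve at the base year.  Under dietary convergence the offsets decay
exponentially with subsequent log-income growth:

    d_i(t) = d_i(0) * exp(-kappa * max(0, ln g_i(t) - ln g_i(base)))

Bioenergy demand is exogenous: first-generation (food-commodity) demand
rises linearly to double its 2010 level by 2030 and is constant thereafter;
the global dedicated energy-crop trajectory rises from 34 Mt DM/yr in 2010
to 4,000 Mt DM/yr in 2100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_world import History

BASE_YEAR = 2010
DEFAULT_KAPPA = 1.0

FIRSTGEN_DOUBLING_YEAR = 2030
SECONDGEN_START_T = 34e6  # tonnes DM/yr at 2010
SECONDGEN_END_T = 4000e6  # tonnes DM/yr at 2100


class DemandDataError(ValueError):
    """History contains no usable observations."""


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (a, b, se_a, se_b)."""
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    dof = max(len(x) - 2, 1)
    sigma2 = float((w * resid**2).sum() / dof)
    cov = sigma2 * np.linalg.inv(XtW @ X)
    se = np.sqrt(np.diag(cov))
    return float(beta[0]), float(beta[1]), float(se[0]), float(se[1])


class DemandModel:
    """Population-weighted log-log Engel model of per-capita food demand.

    Parameters
    ----------
    history:
        Either a :class:`~plumlite.synthetic_world.History` or a tidy frame
        with columns country_id, year, commodity, gdp_pc, population,
        consumption_pc.
    base_year:
        Year at which country offsets are evaluated.
    kappa:
        Dietary-convergence rate per unit log-income growth.
    """

    def __init__(self, history, base_year: int = BASE_YEAR, kappa: float = DEFAULT_KAPPA):
        self.table = history.table if isinstance(history, History) else history
        self.base_year = base_year
        self.kappa = kappa

    @classmethod
    def from_history(cls, history, **kw) -> "DemandModel":
        return cls(history, **kw)

    def fit(self) -> "DemandResults":
        t = self.table
        bad = (t.gdp_pc <= 0) | (t.consumption_pc <= 0) | (t.population <= 0)
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} rows with non-positive income/consumption")
            t = t[~bad]
        if t.empty:
            raise DemandDataError("no usable observations after dropping non-positive rows")

        params, bse, offsets = {}, {}, {}
        for com, grp in t.groupby("commodity"):
            x = np.log(grp.gdp_pc.to_numpy())
            if np.unique(np.round(x, 12)).size < 2:
                raise DemandDataError(f"commodity {com}: fewer than 2 distinct income levels")
            y = np.log(grp.consumption_pc.to_numpy())
            w = grp.population.to_numpy()
            a, b, se_a, se_b = _wls_line(x, y, w / w.mean())
            params[com] = (a, b)
            bse[com] = (se_a, se_b)
            base = grp[grp.year == self.base_year]
            for row in base.itertuples(index=False):
                d0 = np.log(row.consumption_pc) - (a + b * np.log(row.gdp_pc))
                offsets.setdefault(row.country_id, {})[com] = float(d0)
        return DemandResults(
            model=self, params=params, bse=bse, offsets=offsets, kappa=self.kappa
        )


@dataclass
class DemandResults:
    """Fitted Engel curves, their uncertainties and country offsets."""

    model: DemandModel | None
    params: dict[str, tuple[float, float]]  # commodity -> (a, b)
    bse: dict[str, tuple[float, float]]  # standard errors of (a, b)
    offsets: dict[str, dict[str, float]]  # country -> commodity -> d0
    kappa: float = DEFAULT_KAPPA

    @property
    def base_year(self) -> int:
        return self.model.base_year if self.model is not None else BASE_YEAR

    def params_frame(self) -> pd.DataFrame:
        rows = [
            {
                "commodity": c,
                "intercept": a,
                "income_slope": b,
                "se_intercept": self.bse.get(c, (np.nan, np.nan))[0],
                "se_slope": self.bse.get(c, (np.nan, np.nan))[1],
            }
            for c, (a, b) in self.params.items()
        ]
        return pd.DataFrame(rows).set_index("commodity")

    def offset(self, country_id: str, commodity: str, gdp_pc: float, gdp_pc_base: float,
               convergence_on: bool) -> float:
        d0 = self.offsets.get(country_id, {}).get(commodity, 0.0)
        if not convergence_on:
            return d0
        growth = max(0.0, np.log(gdp_pc) - np.log(gdp_pc_base))
        return d0 * float(np.exp(-self.kappa * growth))

    def project(
        self,
        year: int,
        gdp_pc: dict[str, float],
        population: dict[str, float],
        gdp_pc_base: dict[str, float] | None = None,
        convergence_on: bool = False,
    ) -> pd.DataFrame:
        """Total food demand (tonnes/yr) per country x commodity at ``year``."""
        if year < self.base_year:
            raise ValueError(f"projection year {year} before base year {self.base_year}")
        if any(p < 0 for p in population.values()):
            raise ValueError("negative population")
        gdp_pc_base = gdp_pc_base or gdp_pc
        rows = []
        for cid, g in gdp_pc.items():
            for com, (a, b) in self.params.items():
                d = self.offset(cid, com, g, gdp_pc_base[cid], convergence_on)
                pc = float(np.exp(a + b * np.log(g) + d))
                rows.append(
                    {
                        "country_id": cid,
                        "commodity": com,
                        "year": year,
                        "per_capita_t": pc,
                        "total_t": pc * population[cid],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Engel demand model (population-weighted log-log WLS)",
            f"base year: {self.base_year}   convergence rate kappa: {self.kappa}",
            f"{'commodity':<15}{'intercept':>12}{'slope':>10}{'se(slope)':>12}",
        ]
        for c, (a, b) in sorted(self.params.items()):
            lines.append(f"{c:<15}{a:>12.4f}{b:>10.4f}{self.bse.get(c, (np.nan, np.nan))[1]:>12.4f}")
        lines.append(f"countries with offsets: {len(self.offsets)}")
        return "\n".join(lines)


def fit_demand_model(history, base_year: int = BASE_YEAR, kappa: float = DEFAULT_KAPPA) -> DemandResults:
    """Fit the Engel demand model on pooled country history."""
    return DemandModel(history, base_year=base_year, kappa=kappa).fit()


def project_demand(model: DemandResults, year, gdp_pc, population, gdp_pc_base=None,
                   convergence_on: bool = False) -> pd.DataFrame:
    """Project total food demand; see :meth:`DemandResults.project`."""
    return model.project(year, gdp_pc, population, gdp_pc_base, convergence_on)


def bioenergy_demand(year: int, baseline_firstgen: dict[str, dict[str, float]]):
    """Exogenous bioenergy demand at ``year``.

    Returns ``(firstgen, secondgen)``: first-generation demand per country
    and commodity (tonnes/yr; linear ramp from the 2010 baseline to twice
    the baseline at 2030, constant thereafter) and the global
    second-generation energy-crop demand (tonnes DM/yr; linear from 34 Mt
    in 2010 to 4,000 Mt in 2100).
    """
    if not BASE_YEAR <= year <= 2100:
        raise ValueError(f"year {year} outside [{BASE_YEAR}, 2100]")
    ramp = min(1.0, (year - BASE_YEAR) / (FIRSTGEN_DOUBLING_YEAR - BASE_YEAR))
    factor = 1.0 + ramp
    firstgen = {
        cid: {com: v * factor for com, v in coms.items()}
        for cid, coms in baseline_firstgen.items()
    }
    frac = (year - BASE_YEAR) / (2100 - BASE_YEAR)
    secondgen = SECONDGEN_START_T + (SECONDGEN_END_T - SECONDGEN_START_T) * frac
    return firstgen, secondgen
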