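# plumlite

A desk-scale simulator of the coupled global land-use and food system.

Large-scale land-use models answer questions like: *as incomes, diets and
bioenergy demand grow, how much cropland and pasture does the world need,
where does it expand, and what happens to fertiliser use, irrigation
water and commodity prices?*  The full-scale machinery — a dynamic
vegetation model supplying yield potentials, country-level least-cost
optimisation on a 0.5° grid, and a world commodity market — needs
supercomputer runs and licensed datasets.  `plumlite` re-implements the
*mechanisms* of such a model at a scale that runs in minutes on one CPU,
on a self-consistent synthetic world, so the coupled behaviour can be
studied, tested and taught.

It is aimed at land-system and integrated-assessment researchers who want
an inspectable, fully testable implementation of this model class.

## The model in brief

- **Yield surfaces.** Six factorial yield anchors per cell × crop
  (F ∈ {0, 200, 1000} kgN/ha × rain-fed/irrigated) are interpolated by
  saturating exponentials solved exactly through the anchors:
  y(F, x, m, t) = c·g(m)·[y_rf(F) + (y_irr(F) − y_rf(F))·w(x)]·(1+r)^(t−2010),
  with concave irrigation blend w, concave management multiplier g,
  slope-only calibration factor c, and technology increment r = 0.2 %/yr.
- **Demand.** Per-capita demand per commodity group follows
  ln q = a + b·ln(gdp_pc) + d_i, fitted by population-weighted WLS;
  country offsets d_i optionally converge toward the global curve as
  income grows.  First-generation bioenergy doubles from 2010 to 2030;
  dedicated energy-crop demand ramps from 34 to 4,000 Mt DM/yr by 2100.
- **Country optimisation.** Per cluster of similar cells (K-means within
  country) and per land-use type (7 crops + pasture), four decision
  variables — area, fertiliser, irrigation, management — minimise
  production + conversion + trade cost subject to commodity balances,
  FPU water budgets (irrigation efficiency 0.5), protected areas, a
  minimum natural fraction, equal debiting of expansion from forest and
  other natural land, and a 1.1 %/yr deforestation cap where flagged.
- **Market.** A single world price per commodity adjusts exponentially
  against relative oversupply (λ = 0.2) while global stocks buffer the
  imbalance — supply and demand need not clear within a year.
- **Driver.** Annual loop (5-yr trailing yield averaging → demand →
  country optimisation → market settlement → disaggregation to cells),
  iterative spin-up of the base year to < 0.4 % change, and Sobol-sampled
  parameter-uncertainty ensembles (±50 %).

## Worked example

```python
import plumlite as pl

cfg = pl.ScenarioConfig(start_year=2010, end_year=2014, seed=1)
res = pl.run_scenario(cfg, n_countries=2, cells_per_country=9, n_crops=2)
print(res.summary())
```

prints (exact numbers from this run):

```
Scenario 2010-2014 (seed 1, lambda 0.2)
Spin-up converged after 2 iterations
terminal max relative change: 0.0000% (threshold 0.40%)
countries: C00, C01
  year  cropland_Mha  pasture_Mha  nitrogen_Mt  irrigation_km3
  2010         0.920        0.912       0.1222           0.592
  2014         0.920        0.912       0.0342           0.005
```

Reading the output: the synthetic two-country world enters the scenario
with about 0.92 Mha each of cropland and pasture; under constant
drivers the land-use pattern is essentially stationary (the spin-up
fixed point), while fertiliser and irrigation inputs adjust sharply in
the first years as the non-equilibrium market discovers prices
consistent with marginal production costs — the world price of cereals
falls, countries substitute imports from stocks for high-input domestic
production, and the price feedback then pulls the system back.
`res.global_series`, `res.country_series` and `res.market_series` hold
the full annual records; `res.audits` records every feasibility check
(land closure, water budgets, protected areas, trade consistency) for
every country-year.

The same model is scriptable from the shell:

```bash
plumlite make-world --countries 3 --cells 20 --seed 1 --out world/
plumlite run --world world/ --seed 1 --out runs/baseline/
plumlite ensemble --n 8 --half-width 0.5 --seed 1 --out runs/ensemble/
```

## Layout

```
src/plumlite/
  synthetic_world.py    # miniature-world generator (grid, anchors, countries)
  yield_response.py     # anchor fitting, surface evaluation, calibration
  demand.py             # Engel model (Model/Results), bioenergy trajectories
  spatial_clustering.py # K-means clusters, disaggregation to cells
  country_optimiser.py  # per-country least-cost problem and solver
  global_market.py      # prices, stocks, settlement
  simulation_driver.py  # LandUseModel, spin-up, scenarios, ensembles
  io_formats.py         # NetCDF/CSV/YAML round-trips, run manifests
  cli.py                # plumlite command-line interface
docs/methods.md         # full model description and design rationale
```
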