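# Methods

`plumlite` is a desk-scale simulator of the coupled global land-use and
food system.  It reproduces the *mechanisms* of a country-level
partial-equilibrium land-use model driven by vegetation-model yield
potentials — yield-response surfaces, income-driven demand, least-cost
spatial optimisation on clustered grid cells, and a non-equilibrium world
market — on a synthetic miniature world small enough to run on a laptop.
This note documents the model equations, the parameters that matter, the
synthetic world's construction, the numerical choices, and the limits of
what the test suite demonstrates.

## 1. Yield-response surfaces

The biophysical input is a set of six *yield anchors* per grid cell and
crop: attainable yield at fertiliser rates F ∈ {0, 200, 1000} kgN/ha,
each rain-fed and fully irrigated, plus the full-irrigation water
requirement (km³/ha/yr).  A continuous surface is built as

    y(F, x, m, t) = c · g(m) · [ y_rf(F) + (y_irr(F) − y_rf(F)) · w(x) ]
                      · (1 + r_tech)^(t − 2010)

with, per water regime,

    y_w(F) = y0 + (y∞ − y0) · (1 − e^(−k_F F)),

where `k_F` is solved by bisection so the curve passes *exactly* through
all three anchors.  An exact concave-exponential fit exists iff the anchor
ratio (y200 − y0)/(y1000 − y0) lies in (0.2, 1); the synthetic generator
draws responses inside (0.35, 0.9) by construction.  Noisy anchors with
y200 > y1000 are clamped to y1000 (with a warning); sub-exponential
anchors fall back to a near-linear curve and warn, as no exact concave
form exists.

The irrigation blend `w(x) = (1 − e^(−k_I x))/(1 − e^(−k_I))` (default
k_I = 2) satisfies w(0) = 0, w(1) = 1 and is concave; the management
multiplier `g(m) = g0 + (1 − g0)(1 − e^(−k_M m))/(1 − e^(−k_M))`
(defaults g0 = 0.5, k_M = 2) reaches the anchor yields at m = 1 and a
floor g0 at m = 0.  Both shapes are design choices — the anchor data only
pin the endpoints — chosen to give diminishing returns in every input.
The surface is separable in F and irrigation; interactions enter only
through the difference of the two regime curves.

The calibration factor `c` maps vegetation-model output onto observed
per-area yields via a slope-only (through-origin) weighted regression,
`c = Σ w·s·o / Σ w·s²`.  Technology change is a multiplicative exogenous
increment, central value **0.2 %/yr**, compounding annually.

## 2. Demand

Per-capita food demand for six commodity groups (cereals, oil crops,
pulses, starchy roots, ruminant and monogastric products) follows a
log-log Engel relationship,

    ln q_pc = a + b · ln(gdp_pc) + d_i,

fitted by population-weighted least squares on pooled country history
(closed-form normal equations; standard errors as in ordinary WLS).
Country offsets `d_i` are fixed at the base year (2010).  Under dietary
convergence the offset decays with subsequent log-income growth,
`d_i(t) = d_i(0)·exp(−κ·max(0, Δln gdp_pc))`, κ default 1.  The log-log
form supports both saturating growth (b ∈ (0,1)) and bounded decline of
staples (b < 0).  There is no price elasticity of demand.

Bioenergy is exogenous: first-generation demand ramps linearly from the
2010 baseline to twice that level by 2030, constant thereafter; the
global second-generation (dedicated energy-crop) trajectory ramps
linearly from 34 Mt DM/yr (2010) to 4,000 Mt DM/yr (2100).  Because the
synthetic world is tiny, scenario runs scale the global second-gen
trajectory by the world's cropland share of a 1,500 Mha reference — the
trajectory itself always evaluates at full scale.

## 3. Clustering and disaggregation

Countries are optimised on K-means clusters of their cells
(scikit-learn, z-scored features: per-crop anchor yields at 200 kgN/ha in
both water regimes, plus cover fractions; fixed seed; cells canonically
sorted so the result is order-invariant).  The cluster count heuristic is
`k = clamp(⌈2·√n_cells·cv⌉, 1, n_cells)` with `cv` the mean coefficient
of variation of the features — it grows with country size and
heterogeneity and collapses to 1 for a homogeneous country.

Cluster-level land-use deltas are mapped back to cells: contraction in
proportion to each cell's current area of the shrinking class; expansion
in proportion to each cell's *supply capacity* — available natural area
(unprotected forest + other natural above the minimum-natural reserve)
plus any agricultural area freed by simultaneously contracting classes.
The natural-land debit of each cell's net expansion is split equally
between forest and other natural vegetation, falling back proportionally
when one pool runs dry; abandonment is credited to other natural
vegetation.  Cluster totals are conserved to 1e-9 and no cover fraction
leaves [0, 1].

## 4. Country optimisation

For each country and year the model chooses, per cluster and land-use
type (seven crops + pasture), an area and three intensities (F, irrigation
fraction, management), plus country-level trade and feed, minimising

    production cost + conversion cost + import cost − export revenue.

Costs per hectare are `base + p_N·F + p_W·(x·req)/η + p_M·m`, with the
irrigation efficiency η = 0.5 (withdrawal = requirement/η) and a spatial
irrigation-cost index increasing in aridity.  Pasture has low base and
management costs (extensive grazing).  Conversion is charged per hectare
on natural↔agriculture net flows and on cropland↔pasture churn.  Water is
constrained per cluster by runoff pooled into food production units
(FPUs), less an environmental reserve and non-agricultural use, split
equally over FPU cells.  Protected areas and a minimum natural fraction
(default 0.05, configurable) are reserved per cell; countries flagged for
forest protection face an annual forest-loss cap of 1.1 % of forest area.

Monogastric livestock eat feed (drawn from cereals); ruminants graze
first and the residual requirement is met with feed.  Imports are priced
at the world price inflated by tariff + transport + loss rates; exports
earn the world price.  Given cluster-level production, the trade and feed
variables are linear and solved in closed form inside the objective:
deficits are imported (or, for livestock, produced via feed where that is
cheaper than importing), surpluses exported, surplus grazing exported as
ruminant product, and energy crops exported entirely.  Feed-based
livestock production for *export* is excluded, which removes the
import-cereal/export-meat arbitrage loop.

The outer search over cluster variables is a deterministic multi-start
bounded Powell method (scipy), with soft penalties on land, water and
deforestation-cap overshoots followed by an exact projection onto the
feasible set.  During spin-up (see below) net imports are fixed and any
residual production shortfall is closed by a minimal deterministic repair
pass (bisection on one knob at a time, best-yielding clusters first), so
every returned solution satisfies the commodity balance exactly.  A local
derivative-free search on a non-convex objective carries no global
guarantee; on instances small enough for exhaustive coarse-lattice
search, the solver lands within 2 % of the lattice optimum (tested).

## 5. Market

One tariff-free world price per commodity.  Each year, oversupply
`O = Σexports + secondgen production − Σimports − secondgen demand` flows
into a global stock (floored at zero; shortfalls beyond the stock are
recorded as unmet demand) and the price adjusts exponentially against
relative oversupply:

    p' = p · exp(−λ · clip(O / max(imports + secondgen demand, ε), ±2)).

λ defaults to 0.2.  The clip bounds the response when one side of the
market vanishes; without it, a one-sided year drives the price to
numerical zero.  Price therefore moves strictly opposite to the sign of
O, and stays positive for any bounded flow sequence.  Initial prices are
exogenous config values chosen near the synthetic world's marginal
production costs so the baseline starts close to competitive equilibrium;
initial stocks are a stocks-to-use ratio (default 0.2) of baseline use.

## 6. Coupled loop, spin-up, ensembles

The annual step is: (1) potential yields = trailing mean of the anchor
sets over the averaging window (default 5 yr; trailing, not centred, for
causality); (2) demand projection; (3) every country optimised
independently against the last settled prices (no within-year price
iteration — one market settlement per year); (4) market settlement;
(5) disaggregation to cells.  Countries are processed in sorted-id order;
since they only share the pre-settled prices, results are order-independent.

Spin-up initialises the base year: the country optimisation is iterated
on its own output at fixed baseline demand and *net imports held equal to
the baseline values*, until the maximum relative change of any cluster
area or intensity value falls below the threshold (default 0.4 %), or a
maximum number of iterations is reached (then flagged with a warning).
The relative-change metric uses `|Δ|/max(|old|, |new|, floor)` with small
floors (10⁻⁴ of cluster area for areas; 10⁻³ for intensities in natural
units) so that numerically-zero values cannot stall termination.  An
iteration that fails to improve a country's objective by more than 10⁻⁴
(relative) keeps the previous state, making the iteration a contraction
onto a fixed point; spin-up therefore terminates by convergence, not by
the iteration cap, on all worlds exercised here.

Parameter uncertainty: the declared cost parameters are sampled with a
scrambled Sobol sequence in `[c(1−h), c(1+h)]` (default half-width
h = 0.5, n configurable; the classical reference design uses n = 50);
each member runs the full scenario and per-year medians and standard
deviations of global cropland, pasture, nitrogen and irrigation water are
reported.

## 7. The synthetic world

Spatial fields (fertility, aridity, cover propensities, protection) are
Gaussian-filtered white noise per country — cheap, with controllable
spatial autocorrelation (tested via Moran's I > 0).  Fields are centred
and scaled before use; cover fractions come from a softmax over class
propensities and close to 1 exactly.  Yield anchors are monotone in
fertiliser and irrigation by construction, with irrigation response
increasing in aridity; pasture gets a six-anchor block derived from its
reference yield with fixed multipliers, so pasture carries the same four
decision variables as crops.  Irrigation requirements (2,000–10,000
m³/ha/yr rising with aridity) and per-cell runoff are on realistic orders
of magnitude so the FPU water constraint can bind without strangling the
problem.

Socio-economics: GDP per capita, population and growth rates are drawn in
realistic ranges; baseline consumption follows the generating Engel
curves with country offsets (σ = 0.15 log units); populations are scaled
so baseline crop demand is ~30 % of mid-fertiliser cropland capacity and
grazing demand ≤ 40 % of pasture capacity (the ruminant clamp is folded
into the country's dietary offset so the generating relationship stays
exactly consistent).  Net imports are recentred to sum to zero per
commodity.  The historical series ends noise-free at the base year, so
fitted offsets reproduce baseline consumption exactly and the spin-up and
scenario demands agree at 2010.  Because country offsets act as
confounders in a pooled regression, slope-recovery tests use the
offset-free variant of the generator (`include_offsets=False`); the
fitted model itself always absorbs offsets into the base-year residuals,
as designed.

What the synthetic world does *not* emulate: real geography and borders,
crop physiology and its climate response (anchors are static, so scenario
dynamics come only from income, population, bioenergy, technology and
market feedback), seasonality, multi-cropping, and bilateral trade.
Passing tests therefore demonstrate the correctness and stability of the
*mechanisms*, not fidelity to any observed dataset.

## 8. Numerical choices and problem sizes

- Bisection tolerances: anchor-rate solve to machine precision; repair
  pass to 1e-10 on the knob.
- Powell options: 40 iterations, xtol 1e-4, three fixed starts (warm,
  mid-intensity, low-intensity).  Deterministic under the run seed.
- Defaults used in the shipped configuration: tests and examples run on
  worlds of 2–3 countries × 6–20 cells × 1–7 crops, chosen as the
  smallest instances on which every mechanism (clustering, water limits,
  trade, livestock substitution) is active.
- The baseline "fixed point" is an aggregate property: individual
  clusters can exchange area along cost-neutral (flat) directions of the
  objective between iterations, so single-step stationarity is asserted
  on country-level land-use totals, and long-run stability on global
  totals (< 1 %/decade drift under constant drivers).
- Degenerate inputs: flat anchors give constant curves (k_F = 0); empty
  K-means clusters cannot occur (library re-seeding); zero available
  water forces rain-fed production; all-zero simulated yields make the
  calibration slope undefined and raise.

## 9. Known limitations

- The country problem is solved by local search; optimality is verified
  only against coarse exhaustive oracles on small instances.
- The inner trade rule is greedy-myopic (single-year): conversion costs
  are weighed against one year of margin, which makes land use sticky —
  a deliberate match to the annual decision structure, but it understates
  multi-year investment logic.
- Livestock feed is drawn from cereals only, and within-group commodity
  shares are fixed at base-year proportions.
- Second-generation bioenergy is allocated purely by export economics;
  no sustainability constraints beyond the land rules apply.
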