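"""Non-equilibrium global commodity market.

A single tariff-free world price exists per commodity.  Supply and demand
need not balance within a year: the gap (oversupply) flows into a global
stock, and the price responds exponentially to the *relative* oversupply,

    price' = price * exp(-lambda * O / max(imports + second-gen demand, eps))

so oversupply pushes the price down and undersupply pushes it up, creating
a corrective feedback.  Stocks are floored at zero; demand beyond the
available stock in a shortage year is recorded as unmet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAMBDA = 0.2
_EPS = 1e-9
#: Bound on the relative oversupply entering the price exponent; keeps the
#: price response finite when one side of the market is near zero.
REL_OVERSUPPLY_CAP = 2.0

#: Exogenous initial world prices, $/t.  Chosen near the marginal
#: production costs of the synthetic world so the baseline starts close to
#: a competitive equilibrium.
DEFAULT_PRICES: dict[str, float] = {
    "cereals": 150.0,
    "oilcrops": 350.0,
    "pulses": 400.0,
    "starchy_roots": 120.0,
    "ruminant": 600.0,
    "monogastric": 900.0,
    "energy": 80.0,
}

#: Initial stocks as a fraction of annual use.
DEFAULT_STOCKS_TO_USE = 0.2


class MarketConfigError(ValueError):
    pass


@dataclass
class MarketState:
    """World price, stock and trade flows per commodity."""

    prices: dict[str, float]
    stocks: dict[str, float]
    price_lambda: float = DEFAULT_LAMBDA
    exports: dict[str, float] = field(default_factory=dict)  # last settled, t/yr
    imports: dict[str, float] = field(default_factory=dict)
    unmet: dict[str, float] = field(default_factory=dict)
    oversupply: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.price_lambda <= 0:
            raise MarketConfigError(f"price adjustment rate must be > 0, got {self.price_lambda}")
        if any(p <= 0 for p in self.prices.values()):
            raise MarketConfigError("initial prices must be positive")
        if any(s < 0 for s in self.stocks.values()):
            raise MarketConfigError("initial stocks must be non-negative")

    @classmethod
    def initial(cls, commodities, prices=None, annual_use=None,
                stocks_to_use: float = DEFAULT_STOCKS_TO_USE,
                price_lambda: float = DEFAULT_LAMBDA) -> "MarketState":
        prices = dict(prices or {})
        p = {c: prices.get(c, DEFAULT_PRICES.get(c, 100.0)) for c in commodities}
        use = annual_use or {}
        s = {c: stocks_to_use * use.get(c, 0.0) for c in commodities}
        return cls(prices=p, stocks=s, price_lambda=price_lambda)


def import_price(price: float, tariff: float, transport: float, loss: float) -> float:
    """Import unit cost: world price inflated by tariff, transport and loss
    rates (fractions of the price)."""
    if min(tariff, transport, loss) < 0:
        raise ValueError("import inflation rates must be >= 0")
    return price * (1.0 + tariff + transport + loss)


def settle_market(
    state: MarketState,
    exports: dict[str, float],
    imports: dict[str, float],
    secondgen_production: float = 0.0,
    secondgen_demand: float = 0.0,
    energy_commodity: str = "energy",
) -> MarketState:
    """Settle one year of world trade and return the next market state.

    ``exports``/``imports`` are global totals per commodity (country flows
    already aggregated).  Second-generation energy-crop production counts
    as export of the energy commodity and its global demand as import-side
    use.
    """
    new_prices, new_stocks, unmet, overs = {}, {}, {}, {}
    for com, price in state.prices.items():
        exp = exports.get(com, 0.0)
        imp = imports.get(com, 0.0)
        if com == energy_commodity:
            exp += secondgen_production
            imp += secondgen_demand
        O = exp - imp
        s = state.stocks.get(com, 0.0) + O
        unmet[com] = max(0.0, -s)
        new_stocks[com] = max(0.0, s)
        denom = max(imp, _EPS)
        rel = float(np.clip(O / denom, -REL_OVERSUPPLY_CAP, REL_OVERSUPPLY_CAP))
        new_prices[com] = price * float(np.exp(-state.price_lambda * rel))
        overs[com] = O
    return MarketState(
        prices=new_prices,
        stocks=new_stocks,
        price_lambda=state.price_lambda,
        exports=dict(exports),
        imports=dict(imports),
        unmet=unmet,
        oversupply=overs,
    )
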