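"""Engel demand fitting, projection with dietary convergence, and the
exogenous bioenergy trajectories."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import plumlite as pl
from plumlite.demand import DemandDataError, DemandResults, bioenergy_demand
from plumlite.synthetic_world import TRUE_ENGEL, generate_history, generate_world


@pytest.fixture(scope="module")
def fitted(small_world):
    world, _ = small_world
    history = generate_history(world, 40, seed=2)
    return world, history, pl.fit_demand_model(history)


def _frame(rows):
    return pd.DataFrame(rows)


def test_two_exact_points_recovered_exactly():
    rows = []
    for cid, gdp, cons in (("A", 1000.0, 0.05), ("B", 20000.0, 0.25)):
        rows.append({"country_id": cid, "year": 2010, "commodity": "cereals",
                     "gdp_pc": gdp, "population": 1e6, "consumption_pc": cons})
    res = pl.fit_demand_model(_frame(rows))
    a, b = res.params["cereals"]
    b_true = (np.log(0.25) - np.log(0.05)) / (np.log(20000) - np.log(1000))
    assert b == pytest.approx(b_true, rel=1e-10)
    assert a == pytest.approx(np.log(0.05) - b_true * np.log(1000), rel=1e-10)
    # both countries sit on the curve, so base-year offsets vanish
    assert res.offsets["A"]["cereals"] == pytest.approx(0.0, abs=1e-10)
    assert res.offsets["B"]["cereals"] == pytest.approx(0.0, abs=1e-10)


def test_fit_matches_statsmodels_wls_oracle(fitted):
    _, history, res = fitted
    for com, grp in history.table.groupby("commodity"):
        w = grp.population / grp.population.mean()
        X = sm.add_constant(np.log(grp.gdp_pc))
        ref = sm.WLS(np.log(grp.consumption_pc), X, weights=w).fit()
        a, b = res.params[com]
        assert a == pytest.approx(ref.params.iloc[0], rel=1e-8)
        assert b == pytest.approx(ref.params.iloc[1], rel=1e-8)
        assert res.bse[com][1] == pytest.approx(ref.bse.iloc[1], rel=1e-6)


def test_slope_recovered_within_three_se():
    world, _ = generate_world(4, 4, 3, seed=2)
    history = generate_history(world, 40, seed=2, include_offsets=False)
    res = pl.fit_demand_model(history)
    for com, (a, b) in res.params.items():
        assert abs(b - TRUE_ENGEL[com][1]) < 3 * res.bse[com][1]


def test_nonpositive_rows_dropped_with_warning_and_all_dropped_is_error():
    rows = [{"country_id": "A", "year": 2010, "commodity": "cereals",
             "gdp_pc": 0.0, "population": 1e6, "consumption_pc": 0.1}]
    with pytest.raises(DemandDataError):
        with pytest.warns(UserWarning):
            pl.fit_demand_model(_frame(rows))


class TestProjection:
    def test_population_proportionality(self, fitted):
        _, _, res = fitted
        p1 = res.project(2020, {"C00": 5000.0}, {"C00": 1e6})
        p2 = res.project(2020, {"C00": 5000.0}, {"C00": 2e6})
        merged = p1.merge(p2, on=["country_id", "commodity"])
        np.testing.assert_allclose(merged.total_t_y, 2 * merged.total_t_x, rtol=1e-12)

    def test_constant_drivers_give_constant_demand(self, fitted):
        _, _, res = fitted
        a = res.project(2015, {"C00": 5000.0}, {"C00": 1e6})
        b = res.project(2040, {"C00": 5000.0}, {"C00": 1e6})
        np.testing.assert_allclose(a.total_t, b.total_t, rtol=1e-12)

    def test_infinite_kappa_collapses_to_global_curve(self, fitted):
        _, _, res = fitted
        strong = DemandResults(model=res.model, params=res.params, bse=res.bse,
                               offsets=res.offsets, kappa=1e9)
        proj = strong.project(2050, {"C00": 20000.0}, {"C00": 1e6},
                              gdp_pc_base={"C00": 5000.0}, convergence_on=True)
        for row in proj.itertuples(index=False):
            a, b = res.params[row.commodity]
            assert row.per_capita_t == pytest.approx(
                np.exp(a + b * np.log(20000.0)), rel=1e-9
            )

    def test_convergence_shrinks_offsets_without_sign_flip(self, fitted):
        _, _, res = fitted
        cid = next(iter(res.offsets))
        for com, d0 in res.offsets[cid].items():
            prev = abs(d0)
            for gdp in (6000.0, 12000.0, 50000.0):
                d = res.offset(cid, com, gdp, 5000.0, convergence_on=True)
                assert abs(d) <= prev + 1e-15
                assert d * d0 >= 0.0  # never flips sign
                prev = abs(d)

    def test_negative_population_rejected(self, fitted):
        _, _, res = fitted
        with pytest.raises(ValueError):
            res.project(2020, {"C00": 5000.0}, {"C00": -1.0})

    def test_engel_monotone_in_income(self, fitted):
        _, _, res = fitted
        gdps = np.linspace(2000, 80000, 20)
        for com, (a, b) in res.params.items():
            pc = [res.project(2020, {"X": g}, {"X": 1.0}).per_capita_t.iloc[
                      list(res.params).index(com)] for g in (gdps[0], gdps[-1])]
            if b > 0:
                assert pc[1] > pc[0]
            elif b < 0:
                assert pc[1] < pc[0] and pc[1] >= 0.0


def test_benchmark_split_projection_tracks_generating_curve():
    """Fitting on the first two-thirds of history and projecting the rest
    reproduces the generating curve within noise."""
    world, _ = generate_world(3, 4, 3, seed=6)
    history = generate_history(world, 45, seed=6, include_offsets=False)
    t = history.table
    cut = t.year.quantile(2 / 3)
    res = pl.fit_demand_model(t[t.year <= cut], base_year=int(cut))
    held_out = t[t.year > cut]
    logerr = []
    for row in held_out.itertuples(index=False):
        a, b = res.params[row.commodity]
        pred = np.exp(a + b * np.log(row.gdp_pc))
        logerr.append(np.log(pred) - np.log(row.consumption_pc))
    rmse = float(np.sqrt(np.mean(np.square(logerr))))
    assert rmse < 3 * history.noise_sd


class TestBioenergy:
    def test_printed_anchor_values(self):
        base = {"A": {"cereals": 100.0, "oilcrops": 50.0}}
        fg, sg = bioenergy_demand(2010, base)
        assert fg["A"]["cereals"] == pytest.approx(100.0)
        assert sg == pytest.approx(34e6)
        fg, sg = bioenergy_demand(2030, base)
        assert fg["A"]["cereals"] == pytest.approx(200.0)
        fg, _ = bioenergy_demand(2050, base)
        assert fg["A"]["oilcrops"] == pytest.approx(100.0)  # constant after 2030
        _, sg = bioenergy_demand(2100, base)
        assert sg == pytest.approx(4000e6)

    def test_linear_interpolation_between_endpoints(self):
        _, sg = bioenergy_demand(2055, {})
        assert sg == pytest.approx(34e6 + (4000e6 - 34e6) * 0.5)
        fg, _ = bioenergy_demand(2020, {"A": {"cereals": 100.0}})
        assert fg["A"]["cereals"] == pytest.approx(150.0)

    def test_out_of_range_year_rejected(self):
        for year in (2009, 2101):
            with pytest.raises(ValueError):
                bioenergy_demand(year, {})
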