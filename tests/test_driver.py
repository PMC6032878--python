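"""Coupled simulation: spin-up convergence and idempotence, annual-step
conservation, determinism, and the uncertainty ensemble."""

import numpy as np
import pandas as pd
import pytest

import plumlite as pl
from plumlite.simulation_driver import ConfigError, ScenarioConfig, run_ensemble


@pytest.fixture(scope="module")
def spun_model():
    model = pl.LandUseModel.from_synthetic(
        n_countries=2, cells_per_country=9, n_crops=2, seed=1
    )
    results = model.spin_up()
    return model, results


def test_config_validation_lists_all_errors():
    cfg = ScenarioConfig(end_year=2005, yield_window=0, spinup_threshold=-1.0,
                         perturbation_half_width=2.0)
    with pytest.raises(ConfigError) as exc:
        cfg.validate()
    assert len(exc.value.errors) >= 4


def test_spin_up_terminates_below_threshold(spun_model):
    _, res = spun_model
    assert res.converged
    assert res.max_rel_change < res.threshold


def test_spin_up_on_own_output_converges_immediately(spun_model):
    model, _ = spun_model
    again = model.spin_up()
    assert again.converged
    assert again.iterations == 1
    assert again.max_rel_change == pytest.approx(0.0, abs=1e-12)


def test_spin_up_solutions_meet_fixed_trade_balances(spun_model):
    model, res = spun_model
    from plumlite.country_optimiser import audit_solution

    for rec in model.world.countries:
        sol = res.solutions[rec.id]
        checks = audit_solution(
            model.states[rec.id], sol, rec.baseline_consumption, model.config.costs,
            getattr(rec, "baseline_firstgen", {}),
        )
        assert all(checks.values()), (rec.id, checks)


def test_timestep_with_constant_drivers_keeps_land_use_near_fixed_point(spun_model):
    """A converged baseline stays (in aggregate land use) where spin-up left
    it when drivers are constant; individual clusters may trade area along
    cost-neutral directions."""
    model, res = spun_model
    before = {cid: st.areas.copy() for cid, st in model.states.items()}
    model.run_timestep(model.world.base_year)
    for cid, st in model.states.items():
        crop_before = before[cid][:, :-1].sum()
        crop_after = st.areas[:, :-1].sum()
        past_before = before[cid][:, -1].sum()
        past_after = st.areas[:, -1].sum()
        assert abs(crop_after - crop_before) / max(crop_before, 1.0) < 0.01
        assert abs(past_after - past_before) / max(past_before, 1.0) < 0.01


def test_scenario_outputs_only_initial_year_when_end_equals_start():
    cfg = ScenarioConfig(start_year=2010, end_year=2010, seed=2)
    res = pl.run_scenario(cfg, n_countries=2, cells_per_country=6, n_crops=2)
    assert list(res.global_series.index) == [2010]


def test_full_scenario_is_deterministic_under_fixed_seed():
    runs = []
    for _ in range(2):
        cfg = ScenarioConfig(start_year=2010, end_year=2011, seed=5)
        runs.append(pl.run_scenario(cfg, n_countries=2, cells_per_country=6, n_crops=2))
    pd.testing.assert_frame_equal(runs[0].global_series, runs[1].global_series)
    pd.testing.assert_frame_equal(runs[0].market_series, runs[1].market_series)
    pd.testing.assert_frame_equal(runs[0].final_cells, runs[1].final_cells)


def test_averaging_window_is_irrelevant_for_constant_yields():
    outs = []
    for window in (1, 5):
        cfg = ScenarioConfig(start_year=2010, end_year=2011, seed=4, yield_window=window)
        outs.append(pl.run_scenario(cfg, n_countries=2, cells_per_country=6, n_crops=2))
    pd.testing.assert_frame_equal(outs[0].global_series, outs[1].global_series)


def test_land_cover_closure_every_simulated_year(short_run):
    cells = short_run.final_cells
    classes = [c for c in cells.columns if c.startswith("cover_")]
    cov = cells[classes].to_numpy()
    np.testing.assert_allclose(cov.sum(axis=1), 1.0, atol=1e-9)
    assert (cov >= -1e-9).all()
    assert short_run.audits.ok.all(), short_run.audits[~short_run.audits.ok]


def test_commodity_accounting_closes_every_year(short_run):
    """World production + imports - exports = food + bioenergy + feed, and
    the stock ledger equals cumulative oversupply floored at zero."""
    cs = short_run.country_series
    market = short_run.market_series
    for (year, com), grp in market.groupby(["year", "commodity"]):
        if com == "energy":
            continue
        sub = cs[cs.year == year]
        lhs = (sub[f"production_{com}"].sum() + sub[f"imports_{com}"].sum()
               - sub[f"exports_{com}"].sum())
        rhs = (sub[f"food_{com}"].sum() + sub[f"firstgen_{com}"].sum()
               + sub[f"feed_{com}"].sum())
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-3)
    for com, grp in market.groupby("commodity"):
        grp = grp.sort_values("year")
        stock = None
        for row in grp.itertuples(index=False):
            prev = (short_run.config.stocks_to_use * 0 + stock) if stock is not None else None
            if prev is not None:
                want = max(0.0, prev + row.oversupply)
                assert row.stock == pytest.approx(want, rel=1e-9, abs=1e-6)
            stock = row.stock


def test_market_feedback_direction_every_step(short_run):
    market = short_run.market_series.sort_values(["commodity", "year"])
    for com, grp in market.groupby("commodity"):
        prices = grp.price.to_numpy()
        overs = grp.oversupply.to_numpy()
        for i in range(1, len(prices)):
            if overs[i] > 1e-9:
                assert prices[i] < prices[i - 1]
            elif overs[i] < -1e-9:
                assert prices[i] > prices[i - 1]


def test_constant_drivers_run_is_stable(long_run):
    """Land-cover totals drift by less than 1% per decade after spin-up."""
    g = long_run.global_series
    for col in ("cropland_ha", "pasture_ha", "forest_ha", "other_natural_ha"):
        start, end = g[col].iloc[0], g[col].iloc[-1]
        decades = (g.index[-1] - g.index[0]) / 10.0
        drift = abs(end - start) / max(abs(start), 1.0) / decades
        assert drift < 0.01, f"{col} drifts {100 * drift:.2f}%/decade"


class TestEnsemble:
    def test_zero_half_width_gives_identical_members(self):
        cfg = ScenarioConfig(start_year=2010, end_year=2010, seed=6)
        res = run_ensemble(cfg, n=2, half_width=0.0,
                           n_countries=2, cells_per_country=6, n_crops=2)
        pd.testing.assert_frame_equal(res.member_series[0], res.member_series[1])
        assert res.std.cropland_ha.iloc[-1] == pytest.approx(0.0, abs=1e-6)

    def test_samples_respect_half_width_box(self):
        cfg = ScenarioConfig(start_year=2010, end_year=2010, seed=6)
        res = run_ensemble(cfg, n=4, half_width=0.5,
                           n_countries=2, cells_per_country=6, n_crops=2)
        central = {p: getattr(cfg.costs, p) for p in res.samples.columns}
        for p in res.samples.columns:
            lo, hi = 0.5 * central[p], 1.5 * central[p]
            assert ((res.samples[p] >= lo - 1e-9) & (res.samples[p] <= hi + 1e-9)).all()

    def test_dispersion_grows_with_half_width(self):
        stds = []
        for h in (0.05, 0.5):
            cfg = ScenarioConfig(start_year=2010, end_year=2010, seed=6)
            res = run_ensemble(cfg, n=4, half_width=h,
                               n_countries=2, cells_per_country=6, n_crops=2)
            member_final = [m.nitrogen_t.iloc[-1] for m in res.member_series]
            stds.append(np.std(member_final))
        assert stds[1] > stds[0]
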