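import numpy as np
import pytest

from mangrofate.compartments import AGE_CODES, AgeClass, KineticParams, SoilContext
from mangrofate.fixtures import make_tidal_channel
from mangrofate.grid import LandType
from mangrofate.hydro import TideBoundary
from mangrofate.scenario import (MassBudget, Scenario, WetlandUnit,
                                 build_scenario, expected_injection_kg,
                                 mass_budget, run_simulation, scenario_ordering,
                                 wetland_pretreatment)
from mangrofate.transport import DischargeSource


class TestBuildScenario:
    def test_unknown_name_rejected(self, catchment):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("SC9", catchment)

    def test_baseline_leaves_land_untouched(self, catchment):
        sc = build_scenario("SC1", catchment)
        assert np.array_equal(sc.grid.landtype, catchment.grid.landtype)
        assert sc.exchange_enabled and not sc.wetland_units

    def test_deforestation_strictly_reduces_mangroves(self, catchment):
        base = build_scenario("SC1", catchment)
        defo = build_scenario("SC2", catchment)
        n_base = base.grid.landtype_mask(LandType.MANGROVE_FLOODPLAIN).sum()
        n_defo = defo.grid.landtype_mask(LandType.MANGROVE_FLOODPLAIN).sum()
        assert n_defo < n_base
        assert np.all(defo.age_field[catchment.west_columns]
                      == AGE_CODES[AgeClass.NONE])

    def test_deforestation_keeps_roughness(self, catchment):
        defo = build_scenario("SC2", catchment)
        assert np.array_equal(defo.grid.manning, catchment.grid.manning)

    def test_wetland_scenario_routes_all_sources(self, catchment):
        sc3 = build_scenario("SC3", catchment)
        assert all(s.wetland_id is not None for s in sc3.sources)
        assert sc3.grid.landtype_mask(LandType.CONSTRUCTED_WETLAND).sum() > 0
        for unit in sc3.wetland_units:
            for j, i in unit.cells:
                assert sc3.age_field[j, i] == AGE_CODES[AgeClass.YOUNG]

    def test_identical_discharges_across_scenarios(self, catchment):
        rates = {name: sorted(s.rate for s in build_scenario(name, catchment).sources)
                 for name in ("SC1", "SC2", "SC3", "NonEco")}
        assert len({tuple(v) for v in rates.values()}) == 1


class TestWetlandUnit:
    def _unit(self, tau=1000.0, gamma=1.0):
        return WetlandUnit("W", [(0, 0)], tau=tau, depth=0.5, area=100.0,
                           soil=SoilContext(), gamma=gamma)

    def test_passthrough_without_uptake(self):
        # with k01 = 0 and a spun-up tank, effluent equals influent
        unit = self._unit()
        k = KineticParams(k01=0.0, k10=0.0, k12=0.0, k21=0.0)
        for _ in range(500):
            eff = wetland_pretreatment(10.0, unit, k, 50.0)
        assert eff == pytest.approx(10.0, rel=1e-6)

    def test_cstr_steady_state_transfer(self):
        # single removal pathway: effluent/influent -> 1 / (1 + k01 tau)
        tau, k01 = 1000.0, 1e-3
        unit = self._unit(tau=tau)
        k = KineticParams(k01=k01, k10=0.0, k12=0.0, k21=0.0, k13_young=0.0)
        for _ in range(400):
            eff = wetland_pretreatment(10.0, unit, k, 50.0)
        assert eff / 10.0 == pytest.approx(1.0 / (1.0 + k01 * tau), rel=1e-6)

    def test_strong_removal_limit(self):
        unit = self._unit(tau=1000.0)
        k = KineticParams(k01=1.0, k10=0.0, k12=0.0, k21=0.0, k13_young=0.0)
        for _ in range(100):
            eff = wetland_pretreatment(10.0, unit, k, 50.0)
        assert eff / 10.0 < 1e-2

    def test_step_longer_than_residence_time_rejected(self):
        with pytest.raises(ValueError, match="residence"):
            self._unit(tau=10.0).step(1.0, KineticParams(), 50.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            WetlandUnit("W", [(0, 0)], tau=-1.0, depth=0.5, area=1.0)


def _closed_basin_scenario(exchange=False, rate=1.0, duration=7200.0):
    grid, _ = make_tidal_channel(2000.0, 200.0, 10.0, 100.0, closed_both=True)
    src = DischargeSource("s", (1, 10), rate, window=(0.0, 24.0))
    age = np.full((grid.ny, grid.nx), AGE_CODES[AgeClass.NONE], dtype=np.int8)
    return Scenario(name="SC1", grid=grid,
                    tide=TideBoundary([], mean_level=0.0), sources=[src],
                    stations={"S": (1, 10)}, age_field=age,
                    exchange_enabled=exchange, duration=duration,
                    save_interval=600.0, snapshot_interval=3600.0)


class TestRunSimulation:
    def test_zero_duration_returns_initial_conditions(self):
        sc = _closed_basin_scenario(duration=0.0)
        run = run_simulation(sc)
        assert np.all(run.final_transport.c == 0.0)
        assert np.all(run.final_hydro.zeta == 0.0)
        assert run.budget.injected == 0.0

    def test_runs_are_bit_reproducible(self, catchment):
        sc_a = build_scenario("SC1", catchment, duration=0.25 * 86400.0)
        sc_b = build_scenario("SC1", catchment, duration=0.25 * 86400.0)
        a, b = run_simulation(sc_a), run_simulation(sc_b)
        assert a.records.equals(b.records)
        assert np.array_equal(a.final_transport.c, b.final_transport.c)

    def test_engines_agree(self, catchment):
        sc_a = build_scenario("SC3", catchment, duration=3600.0)
        run_a = run_simulation(sc_a, engine="numba")
        sc_b = build_scenario("SC3", catchment, duration=3600.0)
        run_b = run_simulation(sc_b, engine="numpy")
        assert np.allclose(run_a.final_hydro.zeta, run_b.final_hydro.zeta,
                           atol=1e-12)
        assert np.allclose(run_a.final_transport.c, run_b.final_transport.c,
                           atol=1e-15)
        assert np.allclose(run_a.final_pools.Pl, run_b.final_pools.Pl,
                           atol=1e-18)
        assert run_a.ledger["exported_g"] == pytest.approx(
            run_b.ledger["exported_g"], rel=1e-9, abs=1e-15)

    def test_closed_basin_without_exchange_stores_everything(self):
        run = run_simulation(_closed_basin_scenario(exchange=False))
        b = run.budget
        assert b.exported_boundary == 0.0
        assert b.stored_water == pytest.approx(b.injected, rel=1e-12)
        assert b.stored_Sl == b.stored_Ss == b.stored_Pl == 0.0

    def test_noneco_pools_stay_exactly_zero(self, runs_8d):
        pools = runs_8d["NonEco"].final_pools
        assert np.all(pools.total == 0.0)

    def test_station_series_extraction(self, runs_8d):
        ts = runs_8d["SC1"].station_series("M5", "c")
        assert ts.values.shape == ts.times.shape and len(ts.values) > 50
        with pytest.raises(KeyError):
            runs_8d["SC1"].station_series("M99")

    def test_deforestation_shifts_mass_into_soil(self, runs_8d, catchment):
        # clear-cutting stops plant uptake, so soil pools can only grow
        west = catchment.west_columns
        soil_sc1 = (runs_8d["SC1"].final_pools.Sl
                    + runs_8d["SC1"].final_pools.Ss)[west].sum()
        soil_sc2 = (runs_8d["SC2"].final_pools.Sl
                    + runs_8d["SC2"].final_pools.Ss)[west].sum()
        assert soil_sc2 >= soil_sc1
        assert runs_8d["SC2"].final_pools.Pl[west].sum() == 0.0
        assert runs_8d["SC1"].final_pools.Pl[west].sum() > 0.0

    def test_budget_recompute_matches_run(self, runs_8d):
        for run in runs_8d.values():
            again = mass_budget(run)
            assert again.residual == pytest.approx(run.budget.residual, abs=1e-12)
            assert again.injected == run.budget.injected

    def test_budget_validate_flags_large_residual(self):
        bad = MassBudget(injected=1.0, stored_water=0.5)
        with pytest.raises(ValueError, match="does not close"):
            bad.validate()

    def test_no_sources_no_mass_anywhere(self):
        sc = _closed_basin_scenario(rate=0.0, duration=3600.0)
        run = run_simulation(sc)
        assert all(v == 0.0 for v in run.budget.as_dict().values())

    def test_save_writes_complete_run_directory(self, tmp_path, runs_8d):
        from mangrofate.scenario import RunResult

        run = runs_8d["SC3"]
        out = tmp_path / "sc3"
        run.save(out)
        assert (out / "stations.csv").exists()
        assert (out / "fields.nc").exists()
        assert (out / "manifest.json").exists()
        reloaded = RunResult.load_budget(out)
        assert reloaded.injected == pytest.approx(run.budget.injected)

    def test_ordering_helper_sorts_by_concentration(self, runs_8d):
        assert scenario_ordering(runs_8d) == ["NonEco", "SC2", "SC1", "SC3"]

    def test_injection_oracle(self, runs_8d, catchment):
        # injected mass independently equals sum(rate x active time)
        expected = expected_injection_kg(catchment.sources, 8 * 86400.0)
        for run in runs_8d.values():
            assert run.budget.injected == pytest.approx(expected, rel=1e-9)
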