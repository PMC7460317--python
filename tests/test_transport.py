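import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mangrofate import (DischargeSource, HydroParams, HydroState,
                        KineticParams, StabilityError, TransportParams,
                        TransportState, apply_sources, exchange_terms,
                        make_tidal_channel, step_transport)


def uniform_flow(length, depth, dx, u0=0.0):
    grid, _ = make_tidal_channel(length, dx, depth, dx, closed_both=True)
    hydro = HydroState.at_rest(grid)
    hydro.u[:, 1:-1] = u0
    return grid, hydro


class TestDischargeSource:
    def test_window_validation(self):
        with pytest.raises(ValueError):
            DischargeSource("s", (0, 0), 1.0, window=(23.0, 25.0))
        with pytest.raises(ValueError):
            DischargeSource("s", (0, 0), -1.0)

    def test_active_seconds_full_window(self):
        src = DischargeSource("s", (0, 0), 2.0, window=(12.0, 14.0))
        assert src.active_seconds(12 * 3600.0, 7200.0) == 7200.0

    def test_active_seconds_partial_overlap(self):
        src = DischargeSource("s", (0, 0), 2.0, window=(12.0, 14.0))
        assert src.active_seconds(11.5 * 3600.0, 3600.0) == 1800.0

    def test_active_seconds_across_midnight(self):
        src = DischargeSource("s", (0, 0), 2.0, window=(0.0, 1.0))
        assert src.active_seconds(86400.0 - 100.0, 300.0) == 200.0


class TestApplySources:
    def _grid(self):
        grid, _ = make_tidal_channel(300, 100, 10, 100, closed_both=True)
        return grid

    def test_daily_mass_of_largest_source(self):
        # 2 mg/s over the two-hour window adds 14.4 g per day
        grid = self._grid()
        src = DischargeSource("Go Dau", (0, 1), 2.0, window=(12.0, 14.0))
        state = TransportState.zeros(grid)
        ledger = {}
        h = np.full((1, 3), 10.0)
        state = apply_sources(state, [src], 12 * 3600.0, 7200.0, grid, h,
                              ledger=ledger)
        assert ledger["injected_g"] == pytest.approx(14.4)
        assert state.c[0, 1] == pytest.approx(14.4 / (10.0 * grid.cell_area))

    def test_outside_window_is_inert(self):
        grid = self._grid()
        src = DischargeSource("s", (0, 1), 2.0, window=(12.0, 14.0))
        state = apply_sources(TransportState.zeros(grid), [src], 0.0, 3600.0,
                              grid, np.full((1, 3), 10.0))
        assert np.all(state.c == 0.0)

    def test_ledger_matches_rate_times_active_time(self):
        # injected mass must equal sum(rate x active seconds) exactly, even
        # when steps are uneven and cut across the discharge windows
        grid = self._grid()
        srcs = [DischargeSource("a", (0, 0), 0.5, window=(12.0, 14.0)),
                DischargeSource("b", (0, 2), 2.0, window=(6.0, 7.0))]
        state = TransportState.zeros(grid)
        ledger = {}
        rng = np.random.default_rng(3)
        t, t_end = 0.0, 2 * 86400.0
        while t < t_end:
            dt = min(float(rng.uniform(300, 2000)), t_end - t)
            state = apply_sources(state, srcs, t, dt, grid,
                                  np.full((1, 3), 10.0), ledger=ledger)
            t += dt
        expected_g = (0.5 * 7200.0 + 2.0 * 3600.0) * 2 * 1e-3
        assert ledger["injected_g"] == pytest.approx(expected_g, rel=1e-12)

    def test_dry_cell_buffers_until_rewetted(self):
        grid = self._grid()
        src = DischargeSource("s", (0, 1), 1.0, window=(0.0, 24.0))
        state = TransportState.zeros(grid)
        h = np.full((1, 3), 10.0)
        wet = np.array([[True, False, True]])
        state = apply_sources(state, [src], 0.0, 100.0, grid, h, wet=wet)
        assert state.c[0, 1] == 0.0
        assert state.buffered[(0, 1)] == pytest.approx(0.1)   # 1 mg/s * 100 s
        wet[0, 1] = True
        state = apply_sources(state, [src], 0.0, 0.0, grid, h, wet=wet)
        assert (0, 1) not in state.buffered
        assert state.c[0, 1] == pytest.approx(0.1 / (10.0 * grid.cell_area))

    def test_source_outside_grid_rejected(self):
        grid = self._grid()
        src = DischargeSource("s", (5, 5), 1.0)
        with pytest.raises(ValueError, match="outside grid"):
            apply_sources(TransportState.zeros(grid), [src], 0.0, 1.0, grid,
                          np.full((1, 3), 10.0))


class TestExchangeTerms:
    def test_null_state_null_exchange(self):
        k = KineticParams()
        out = exchange_terms(np.zeros((2, 2)), np.zeros((2, 2)), k,
                             np.ones((2, 2), bool), gamma=0.5)
        assert np.all(out == 0.0)

    def test_dry_cells_do_not_exchange(self):
        k = KineticParams(k01=0.1)
        out = exchange_terms(np.ones((1, 2)), np.zeros((1, 2)), k,
                             np.array([[True, False]]), gamma=1.0)
        assert out[0, 0] < 0.0 and out[0, 1] == 0.0

    def test_uptake_only_sign_and_magnitude(self):
        k = KineticParams(k01=0.1, k10=0.0)
        out = exchange_terms(np.array([[1.0]]), np.array([[5.0]]), k,
                             np.array([[True]]), gamma=1.0)
        assert out[0, 0] == pytest.approx(-0.1)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k01=-1e-6)


class TestStepTransport:
    def test_null_field_stays_null(self):
        grid, hydro = uniform_flow(2000, 10, 100, u0=0.3)
        state = TransportState.zeros(grid)
        tp = TransportParams(Dx=5.0, Dy=5.0)
        out = step_transport(state, hydro, grid, tp, hydro_params=HydroParams(f=0.0))
        assert np.all(out.c == 0.0)

    def test_unit_courant_upwind_advection_is_exact(self):
        grid, hydro = uniform_flow(3000, 10, 100, u0=0.5)
        c0 = np.zeros((1, grid.nx))
        c0[0, 10:15] = np.array([1.0, 3.0, 2.0, 0.5, 1.5])
        state = TransportState(c=c0.copy(), t=0.0)
        tp = TransportParams(Dx=0.0, Dy=0.0)
        dt = grid.dx / 0.5                       # Courant number exactly one
        out = step_transport(state, hydro, grid, tp,
                             hydro_params=HydroParams(f=0.0), dt=dt, check=False)
        assert np.allclose(out.c[0, 1:], c0[0, :-1], atol=1e-14)

    def test_profile_translates_at_flow_speed(self):
        grid, hydro = uniform_flow(8000, 10, 100, u0=0.4)
        x = (np.arange(grid.nx) + 0.5) * grid.dx
        state = TransportState(c=np.exp(-((x - 2000.0) / 300.0) ** 2)[None, :], t=0.0)
        tp = TransportParams(Dx=0.0, Dy=0.0)
        dt = 100.0                               # Courant 0.4
        steps = 75                               # 7500 s -> 3000 m shift
        for _ in range(steps):
            state = step_transport(state, hydro, grid, tp,
                                   hydro_params=HydroParams(f=0.0), dt=dt,
                                   check=False)
        com = float((state.c[0] * x).sum() / state.c[0].sum())
        assert abs(com - (2000.0 + 0.4 * dt * steps)) < grid.dx

    def test_mass_conserved_in_closed_channel(self):
        grid, hydro = uniform_flow(4000, 10, 100, u0=0.3)
        rng = np.random.default_rng(5)
        c0 = rng.uniform(0, 2, (1, grid.nx))
        h = grid.bed_depth + hydro.zeta
        state = TransportState(c=c0, t=0.0, m=c0 * h)
        tp = TransportParams(Dx=8.0, Dy=8.0)
        total0 = float(state.m.sum())
        for _ in range(200):
            state = step_transport(state, hydro, grid, tp,
                                   hydro_params=HydroParams(f=0.0), dt=20.0,
                                   check=False)
        assert float(state.m.sum()) == pytest.approx(total0, rel=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_concentration_stays_nonnegative(self, seed):
        # coupled sloshing flow over a nonnegative tracer field: the upwind
        # mass update shares the continuity fluxes, so c cannot go negative
        from mangrofate.hydro import step_hydro

        grid, hydro = uniform_flow(2000, 10, 100)
        rng = np.random.default_rng(seed)
        hydro.zeta[:] = rng.uniform(-0.5, 0.5, (1, grid.nx))
        h0 = grid.bed_depth + hydro.zeta
        c0 = rng.uniform(0, 3, (1, grid.nx))
        state = TransportState(c=c0, t=0.0, m=c0 * h0)
        tp = TransportParams(Dx=4.0, Dy=4.0)
        hp = HydroParams(f=0.0)
        for _ in range(15):
            dt = 0.5 * min(4.0, 1e3)
            state = step_transport(state, hydro, grid, tp, hydro_params=hp,
                                   dt=dt, check=False)
            hydro = step_hydro(hydro, grid, hp, dt=dt, check=False)
        assert state.m.min() >= 0.0
        assert state.c.min() >= 0.0

    def test_stability_violation_raises(self):
        grid, hydro = uniform_flow(2000, 10, 100, u0=1.0)
        state = TransportState.zeros(grid)
        with pytest.raises(StabilityError):
            step_transport(state, hydro, grid, TransportParams(),
                           hydro_params=HydroParams(f=0.0), dt=1e5)
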