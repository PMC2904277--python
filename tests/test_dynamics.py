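"""Regulatory-loop dynamics: hormone drive, colon adaptation, full simulation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from osmotrap.solutes import Beverage, dilute, hfcs_composition
from osmotrap.dynamics import (
    IngestionSchedule,
    PhysiologyParams,
    colon_adaptation_step,
    daily_schedule,
    fit_colon_parameters,
    hormone_drive,
    simulate_schedule,
    steady_state_summary,
)
from osmotrap.trapping import analyze_beverage


class TestHormoneDrive:
    def test_zero_deficit_zero_drive(self, params):
        assert hormone_drive(0.0, params) == (0.0, 0.0)

    def test_monotone_in_deficit(self, params, hfcs, sucrose_drink):
        """A larger trapped volume (HFCS vs sucrose drink) drives more
        aldosterone; checked on the two drinks and over a deficit grid."""
        d_hfcs = analyze_beverage(hfcs).V_d
        d_suc = analyze_beverage(sucrose_drink).V_d
        assert hormone_drive(d_hfcs, params)[0] > hormone_drive(d_suc, params)[0]
        grid = np.linspace(0, 2.0, 41)
        aldos = [hormone_drive(d, params)[0] for d in grid]
        assert all(a <= b for a, b in zip(aldos, aldos[1:]))

    def test_saturation_cap(self, params):
        aldo, adh = hormone_drive(100.0, params)
        assert aldo == params.aldo_saturation
        assert adh == params.aldo_saturation

    def test_sodium_rich_meal_gates_aldosterone(self, params, soup):
        """While unabsorbed luminal sodium remains, the aldosterone index is
        held at zero but ADH still responds to the volume deficit."""
        traj = simulate_schedule(daily_schedule(soup, 3, 3.0), params)
        assert traj.aldo.max() == 0.0
        assert traj.adh.max() > 0.0


class TestColonAdaptation:
    def test_fixed_point_at_baseline(self, params):
        assert colon_adaptation_step(params.C0, 0.0, 0.01, params) == params.C0

    def test_converges_to_closed_form(self, params):
        """Under constant exposure a, capacity approaches C0 + C_gain*a and
        passes 63.2% of the increment at one time constant, matching the exact
        exponential solution to <0.1% of the increment."""
        a = 1.0
        dt = 1.0 / 1440.0  # one minute
        C = params.C0
        n_tau = int(round(params.tau_colon / dt))
        for i in range(10 * n_tau):
            C = colon_adaptation_step(C, a, dt, params)
            if i + 1 == n_tau:
                exact_tau = params.C0 + params.C_gain * a * (1 - math.exp(-1))
                assert abs(C - exact_tau) / params.C_gain < 1e-3
        assert C == pytest.approx(params.C0 + params.C_gain * a, rel=1e-3)

    def test_invalid_dt(self, params):
        with pytest.raises(ValueError):
            colon_adaptation_step(params.C0, 0.0, 0.0, params)


class TestScheduleValidation:
    def test_event_outside_duration(self, hfcs):
        with pytest.raises(ValueError, match="outside"):
            IngestionSchedule(((30 * 24.0, hfcs),), duration_days=1.0)

    def test_unsorted_events(self, hfcs):
        with pytest.raises(ValueError, match="sorted"):
            IngestionSchedule(((10.0, hfcs), (5.0, hfcs)), duration_days=1.0)

    def test_daily_schedule_counts(self, hfcs):
        sched = daily_schedule(hfcs, 3, 14.0)
        assert len(sched.events) == 42


class TestBaselineFixedPoint:
    def test_empty_schedule_is_constant(self, params):
        """With no ingestion events every state variable stays at baseline to
        1e-9 over 30 simulated days, and MAP equals its baseline."""
        traj = simulate_schedule(IngestionSchedule((), 30.0), params)
        assert np.abs(traj.ecf - params.V_ecf0).max() < 1e-9
        assert np.abs(traj.na_total - params.na_total0).max() < 1e-9
        assert np.abs(traj.colon_capacity - params.C0).max() < 1e-9
        assert np.abs(traj.map - params.MAP0).max() < 1e-9
        assert traj.aldo.max() == 0.0 and traj.adh.max() == 0.0


class TestConservationAndAccuracy:
    def test_water_ledger_closes(self, params, hfcs):
        """At every step, the change of body + luminal water equals cumulative
        intake minus urine to 1e-8 relative."""
        traj = simulate_schedule(daily_schedule(hfcs, 3, 7.0), params)
        lhs = traj.ecf + traj.luminal - params.V_ecf0
        rhs = traj.intake_cum - traj.urine_cum
        scale = max(1.0, np.abs(traj.intake_cum).max())
        assert np.abs(lhs - rhs).max() / scale < 1e-8

    def test_step_halving_stability(self, params, hfcs):
        sched = daily_schedule(hfcs, 3, 8.0)
        m1 = steady_state_summary(
            simulate_schedule(sched, params, dt_fine_min=1.0, dt_coarse_min=15.0), 3.0
        ).mean_map_mmHg
        m2 = steady_state_summary(
            simulate_schedule(sched, params, dt_fine_min=0.5, dt_coarse_min=7.5), 3.0
        ).mean_map_mmHg
        assert abs(m1 - m2) / m1 < 1e-3

    def test_deterministic_given_seed(self, params, hfcs):
        sched = daily_schedule(hfcs, 2, 4.0)
        a = simulate_schedule(sched, params, seed=7)
        b = simulate_schedule(sched, params, seed=7)
        assert np.array_equal(a.map, b.map)
        assert np.array_equal(a.na_total, b.na_total)


class TestDoseResponseMonotonicity:
    def test_monotone_in_drinks_per_day(self, params, hfcs):
        maps, ecfs = [], []
        for d in range(0, 5):
            s = steady_state_summary(
                simulate_schedule(daily_schedule(hfcs, d, 10.0), params), 3.0
            )
            maps.append(s.mean_map_mmHg)
            ecfs.append(s.ecf_expansion_pct)
        assert all(a <= b for a, b in zip(maps, maps[1:]))
        assert all(a <= b for a, b in zip(ecfs, ecfs[1:]))
        assert maps[3] > params.MAP0 and ecfs[3] > 0.0

    def test_monotone_in_osmolarity(self, params):
        maps = []
        for O in (400.0, 600.0, 800.0):
            bev = Beverage(
                f"sugar {O:.0f}", 0.5,
                tuple(hfcs_composition(O * 180.16 / 1000.0)),
                declared_osmolarity=O,
            )
            s = steady_state_summary(
                simulate_schedule(daily_schedule(bev, 3, 8.0), params), 3.0
            )
            maps.append(s.mean_map_mmHg)
        assert all(a <= b for a, b in zip(maps, maps[1:]))

    def test_monotone_in_fructose_completion(self, params, hfcs):
        maps, aldos = [], []
        for completion in (4.0, 6.0, 8.0):
            p = replace(params, fructose_completion_h=completion)
            s = steady_state_summary(
                simulate_schedule(daily_schedule(hfcs, 3, 8.0), p), 3.0
            )
            maps.append(s.mean_map_mmHg)
            aldos.append(s.mean_daily_aldo_exposure)
        assert all(a <= b for a, b in zip(maps, maps[1:]))
        assert all(a <= b for a, b in zip(aldos, aldos[1:]))


class TestDilutionMitigation:
    def test_isotonic_dilution_matches_baseline_drive(self, params, hfcs):
        """Drinks pre-diluted to the isotonic reference leave aldosterone and
        colon capacity exactly at their no-ingestion baselines."""
        diluted = dilute(hfcs, hfcs.osmolarity / params.O_iso)
        traj = simulate_schedule(daily_schedule(diluted, 3, 5.0), params)
        assert traj.aldo.max() == 0.0
        assert np.abs(traj.colon_capacity - params.C0).max() == 0.0


class TestSteadyStateSummary:
    def test_baseline_summary(self, params):
        traj = simulate_schedule(IngestionSchedule((), 10.0), params)
        s = steady_state_summary(traj, 3.0)
        assert s.ecf_expansion_pct == pytest.approx(0.0, abs=1e-9)
        assert s.mean_map_mmHg == pytest.approx(params.MAP0)

    def test_window_invariance_after_convergence(self, params, hfcs):
        traj = simulate_schedule(daily_schedule(hfcs, 3, 14.0), params)
        s2 = steady_state_summary(traj, 2.0)
        s3 = steady_state_summary(traj, 3.0)
        assert s2.mean_map_mmHg == pytest.approx(s3.mean_map_mmHg, rel=2e-3)

    def test_window_longer_than_trajectory(self, params):
        traj = simulate_schedule(IngestionSchedule((), 2.0), params)
        with pytest.raises(ValueError, match="exceeds"):
            steady_state_summary(traj, 5.0)


class TestParameterRecovery:
    def test_grid_search_recovers_colon_parameters(self, hfcs):
        """A synthetic trajectory generated with known (C_gain, tau_colon) is
        identified on a parameter grid to within one grid cell."""
        true = PhysiologyParams(C_gain=25.0, tau_colon=2.0)
        traj = simulate_schedule(daily_schedule(hfcs, 3, 10.0), true)
        c_grid = [15.0, 20.0, 25.0, 30.0, 35.0]
        t_grid = [1.0, 1.5, 2.0, 2.5, 3.0]
        cg, tau = fit_colon_parameters(traj, c_grid, t_grid)
        assert abs(c_grid.index(cg) - c_grid.index(25.0)) <= 1
        assert abs(t_grid.index(tau) - t_grid.index(2.0)) <= 1


class TestParamsIO:
    def test_yaml_round_trip_identical_simulation(self, tmp_path, hfcs):
        params = PhysiologyParams(C_gain=30.0, tau_colon=2.5)
        path = tmp_path / "params.yaml"
        params.save(path)
        back = PhysiologyParams.load(path)
        assert back == params
        sched = daily_schedule(hfcs, 2, 3.0)
        a = simulate_schedule(sched, params)
        b = simulate_schedule(sched, back)
        assert np.array_equal(a.map, b.map)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PhysiologyParams(tau_colon=0.5)
        with pytest.raises(ValueError):
            PhysiologyParams(V_ecf0=-1.0)
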