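"""Integration engine: dose events, resampling, protocols, self-convergence."""

import numpy as np
import pytest

import dopasim as ds
from dopasim.dynamics import (
    IntegrationError,
    SolverSettings,
    Trajectory,
    integrate,
    resample_uniform,
    run_protocol,
)
from dopasim.metrics import window_stats


class TestIntegrate:
    def test_equilibrium_is_fixed_point(self, nominal_equilibrium):
        model = ds.ReducedModel(forcing=ds.ForcingContext(circadian=ds.CircadianConfig.off()))
        y0 = nominal_equilibrium.as_array()
        traj = integrate(model.rhs, y0, (0.0, 48.0), settings=SolverSettings(output_dt=0.5),
                         columns=model.names)
        assert np.allclose(traj.states, y0[None, :], rtol=1e-6)

    def test_dose_event_causes_eda_spike(self, limit_cycle):
        sched = ds.DoseSchedule(dose=0.5, times=(18.0,), half_life=15.0)
        model = ds.ReducedModel(forcing=ds.ForcingContext(schedule=sched))
        traj = integrate(model.rhs, limit_cycle.state_at(17.0), (17.0, 20.0),
                         schedule=sched, settings=SolverSettings(), columns=model.names)
        before = traj.slice(17.5, 18.0).column("eda").max()
        after = traj.slice(18.0, 18.5).column("eda").max()
        assert after > 1.15 * before

    def test_occupancy_jump_exact(self):
        sched = ds.DoseSchedule(dose=0.3, times=(6.0,), half_life=15.0)
        ctx = ds.ForcingContext(schedule=sched)
        x_before = ctx.x_dose(6.0 - 1e-12)
        assert ctx.x_dose(6.0) == x_before + 0.3  # bit-exact jump at the event

    def test_nonnegativity_along_trajectory(self, limit_cycle):
        sched = ds.DoseSchedule(dose=1.0, times=(6.0,), half_life=15.0)
        model = ds.ReducedModel(forcing=ds.ForcingContext(schedule=sched))
        traj = integrate(model.rhs, limit_cycle.state_at(6.0), (6.0, 30.0),
                         schedule=sched, settings=SolverSettings(), columns=model.names)
        assert traj.states.min() >= 0.0

    def test_bad_span_rejected(self):
        model = ds.ReducedModel()
        with pytest.raises(ValueError):
            integrate(model.rhs, np.ones(4), (5.0, 5.0))


class TestResample:
    def test_constant_series(self):
        traj = Trajectory(np.linspace(0, 10, 37), np.full((37, 2), 3.5), ("a", "b"))
        out = resample_uniform(traj, 0.5)
        assert np.allclose(out.states, 3.5)
        assert out.times.size == 20
        assert out.times[-1] == pytest.approx(10.0)

    def test_grid_arithmetic(self):
        traj = Trajectory(np.linspace(2.0, 8.0, 100), np.zeros((100, 1)), ("a",))
        out = resample_uniform(traj, 0.25)
        assert out.times.size == 24
        assert out.times[0] == pytest.approx(2.25)

    def test_dt_larger_than_span_rejected(self):
        traj = Trajectory(np.linspace(0, 1, 10), np.zeros((10, 1)), ("a",))
        with pytest.raises(ValueError):
            resample_uniform(traj, 2.0)

    def test_median_grid_refinement(self, limit_cycle):
        """24-h medians at dt and dt/2 agree to < 0.05%."""
        cyc = limit_cycle.cycle
        m1 = window_stats(resample_uniform(cyc, 0.02), "eda",
                          (cyc.t0 + 0.1, cyc.t0 + 23.9)).median
        m2 = window_stats(resample_uniform(cyc, 0.01), "eda",
                          (cyc.t0 + 0.1, cyc.t0 + 23.9)).median
        assert abs(m1 - m2) / m2 < 5e-4


class TestProtocol:
    def test_seven_equal_occupancy_jumps(self):
        sched = ds.DoseSchedule.daily(0.2, 6.0, 7)
        ctx = ds.ForcingContext(schedule=sched)
        jumps = [ctx.x_dose(t) - ctx.x_dose(t - 1e-9) for t in sched.times]
        assert np.allclose(jumps, 0.2)

    def test_zero_dose_protocol_is_periodic(self, forced_two_days):
        """Drug-free forced trajectory repeats with 24-h period after burn-in."""
        traj = forced_two_days
        day1 = traj.slice(traj.t0, traj.t0 + 24.0)
        day2 = traj.slice(traj.t0 + 24.0, traj.t0 + 48.0)
        n = min(day1.times.size, day2.times.size)
        scale = np.max(np.abs(day1.states[:n]), axis=0)
        err = np.max(np.abs(day1.states[:n] - day2.states[:n]) / scale)
        assert err < 1e-4

    def test_repeated_dosing_elevates_moving_mean(self):
        from dopasim.experiments import repeated_dose_experiment
        res = repeated_dose_experiment(dose=0.2, dose_time=6.0, days=3)
        mv = res["moving_stats"]["mean_pct_above"]
        # first window is the drug-free baseline; accumulating drug lifts it
        assert mv.iloc[-1] > mv.iloc[0] + 5.0
        assert mv.iloc[-1] > 5.0

    def test_self_convergence_under_tolerance_refinement(self, limit_cycle, eda_reference):
        """Halving solver tolerances moves the 24-h post-dose median by < 0.1%."""
        sched = ds.DoseSchedule(dose=0.5, times=(6.0,), half_life=15.0)
        model = ds.ReducedModel(forcing=ds.ForcingContext(schedule=sched))
        y0 = limit_cycle.state_at(6.0)
        meds = []
        for settings in (SolverSettings(), SolverSettings().refined(0.5)):
            traj = integrate(model.rhs, y0, (6.0, 30.0), schedule=sched,
                             settings=settings, columns=model.names)
            meds.append(window_stats(traj, "eda", (6.0, 30.0), eda_reference).median)
        assert abs(meds[0] - meds[1]) / meds[1] < 1e-3
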