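"""Figure-level computational experiments as reproducible, configured runs.

Every experiment shares the same scaffolding: spin the circadian-forced
reduced model up to its 24-h limit cycle, start the protocol from the
limit-cycle state at the relevant clock time, and summarise extracellular
dopamine relative to the drug-free, circadian-free nominal equilibrium
eda* (the "percent above steady state" reference used throughout).

Default grids are desk-scale; the full figure-scale grids are a matter of
passing denser arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forcing import CircadianConfig, DoseSchedule, ForcingContext
from .model import (
    AutoreceptorCalibration,
    EquilibriumError,
    FrozenForcing,
    ReducedParams,
    find_equilibrium,
)
from .duo import DUOParams, DUO_PARAM_NAMES, LHSRanges, duo_initial_state, lhs_sample_duo
from .dynamics import (
    DUOModel,
    ReducedModel,
    SolverSettings,
    Trajectory,
    integrate,
    resample_uniform,
)
from .metrics import (
    InsufficientOscillationData,
    estimate_period_amplitude,
    moving_window_stats,
    window_stats,
)

__all__ = [
    "ForcedLimitCycle",
    "forced_limit_cycle",
    "dose_time_sweep",
    "repeated_dose_experiment",
    "halflife_dose_grid",
    "homeostasis_sweeps",
    "sensitivity_ridge",
    "lhs_oscillation_search",
    "nominal_eda_reference",
]

DEFAULT_BURN_IN = 240.0  # hours; ten forced periods discarded before metrics


def nominal_eda_reference(
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
) -> float:
    """Drug-free, circadian-free equilibrium eda* (uM), the percent reference."""
    return find_equilibrium(params, FrozenForcing(), calib).eda


@dataclass(frozen=True)
class ForcedLimitCycle:
    """One post-burn-in 24-h cycle of the circadian-forced reduced model.

    ``cycle`` is a uniformly sampled trajectory over [0, 24) in clock time;
    ``state_at`` interpolates the limit-cycle state at any clock time, so a
    protocol starting at an arbitrary dose time can skip its own burn-in.
    """

    cycle: Trajectory

    def state_at(self, clock_time: float) -> np.ndarray:
        ct = float(np.mod(clock_time, 24.0))
        t = self.cycle.times - self.cycle.times[0]
        out = np.empty(self.cycle.states.shape[1])
        for j in range(out.size):
            out[j] = np.interp(ct, t, self.cycle.states[:, j], period=24.0)
        return out


def forced_limit_cycle(
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    circadian: CircadianConfig = CircadianConfig(),
    settings: SolverSettings = SolverSettings(),
    burn_in_hours: float = DEFAULT_BURN_IN,
) -> ForcedLimitCycle:
    """Integrate the drug-free forced model to its 24-h limit cycle."""
    forcing = ForcingContext(circadian=circadian)
    model = ReducedModel(params=params, calib=calib, forcing=forcing)
    y0 = find_equilibrium(params, forcing.frozen(0.0), calib).as_array()
    coarse = SolverSettings(settings.rel_tol, settings.abs_tol, settings.max_step,
                            settings.stiff_method, output_dt=None)
    burn = integrate(model.rhs, y0, (0.0, burn_in_hours), settings=coarse, columns=model.names)
    n_day = int(burn_in_hours // 24.0)
    start = 24.0 * (n_day - 1)
    cycle = integrate(model.rhs, _state_at_time(burn, start), (start, start + 24.0),
                      settings=settings, columns=model.names,
                      metadata={"burn_in_hours": burn_in_hours})
    return ForcedLimitCycle(cycle=cycle)


def _state_at_time(traj: Trajectory, t: float) -> np.ndarray:
    return np.array([np.interp(t, traj.times, traj.states[:, j])
                     for j in range(traj.states.shape[1])])


def dose_time_sweep(
    dose_values: Sequence[float] = (0.2, 0.5),
    time_grid: Sequence[float] = tuple(np.arange(0.0, 24.5, 0.5)),
    half_life: float = 15.0,
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    circadian: CircadianConfig = CircadianConfig(),
    settings: SolverSettings = SolverSettings(),
) -> pd.DataFrame:
    """24-h response statistics of eda for a single dose at each grid time.

    For each (dose, dose time): start on the forced limit cycle, apply the
    occupancy jump, integrate 24 h, and summarise eda over the half-open
    post-dose day as mean/median/SD in percent relative to the nominal
    steady state.  Dose 0 rows reproduce the drug-free circadian baseline.
    """
    lc = forced_limit_cycle(params, calib, circadian, settings)
    ref = nominal_eda_reference(params, calib)
    rows = []
    for dose in dose_values:
        for td in time_grid:
            schedule = DoseSchedule(dose=dose, times=(float(td),), half_life=half_life) \
                if dose > 0 else None
            forcing = ForcingContext(circadian=circadian, schedule=schedule)
            model = ReducedModel(params=params, calib=calib, forcing=forcing)
            traj = integrate(model.rhs, lc.state_at(td), (float(td), float(td) + 24.0),
                             schedule=schedule, settings=settings, columns=model.names)
            ws = window_stats(traj, "eda", (float(td), float(td) + 24.0), reference=ref)
            rows.append({
                "dose": float(dose), "dose_time": float(td), "half_life": float(half_life),
                "mean": ws.mean, "median": ws.median, "sd": ws.sd,
                "mean_pct_above": ws.mean_pct_above,
                "median_pct_above": ws.median_pct_above,
                "sd_pct_of_reference": ws.sd_pct_of_reference,
            })
    return pd.DataFrame(rows)


def repeated_dose_experiment(
    dose: float = 0.2,
    dose_time: float = 18.0,
    days: int = 7,
    half_life: float = 15.0,
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    circadian: CircadianConfig = CircadianConfig(),
    settings: SolverSettings = SolverSettings(),
    limit_cycle: Optional[ForcedLimitCycle] = None,
) -> dict:
    """Daily dosing at the same clock time for ``days`` days.

    Returns the trajectory (starting 24 h before the first dose so the
    trailing moving window is defined from dose onset), the 24-h moving
    mean/median/SD of eda, and the peak excursion of eda in percent above
    the nominal steady state over the dosing period.
    """
    if not 0.0 <= dose_time < 24.0:
        raise ValueError("dose_time must lie in [0, 24)")
    lc = limit_cycle or forced_limit_cycle(params, calib, circadian, settings)
    ref = nominal_eda_reference(params, calib)
    schedule = DoseSchedule.daily(dose, dose_time, days, half_life) if dose > 0 else None
    forcing = ForcingContext(circadian=circadian, schedule=schedule)
    model = ReducedModel(params=params, calib=calib, forcing=forcing)
    t_start = dose_time - 24.0
    traj = integrate(model.rhs, lc.state_at(t_start), (t_start, dose_time + 24.0 * days),
                     schedule=schedule, settings=settings, columns=model.names)
    moving = moving_window_stats(traj, "eda", window_width=24.0, reference=ref)
    dosing = traj.slice(dose_time, dose_time + 24.0 * days)
    peak_pct = float((dosing.column("eda").max() / ref - 1.0) * 100.0)
    return {"trajectory": traj, "moving_stats": moving, "peak_pct_above": peak_pct,
            "reference_eda": ref, "schedule": schedule}


def halflife_dose_grid(
    half_life_grid: Sequence[float] = tuple(np.linspace(1.0, 24.0, 6)),
    dose_grid: Sequence[float] = tuple(np.linspace(0.0, 1.0, 6)),
    dose_time: float = 6.0,
    days: int = 7,
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    circadian: CircadianConfig = CircadianConfig(),
    settings: SolverSettings = SolverSettings(),
) -> pd.DataFrame:
    """Mean eda over ``days`` of daily dosing, across (half-life, dose).

    Returns a long-format table with the mean eda of the full dosing window
    as a ratio to the nominal steady state (``mean_rel``); the dose-0 rows
    are the drug-free circadian baseline.
    """
    lc = forced_limit_cycle(params, calib, circadian, settings)
    ref = nominal_eda_reference(params, calib)
    rows = []
    for hl in half_life_grid:
        for dose in dose_grid:
            schedule = DoseSchedule.daily(float(dose), dose_time, days, float(hl)) \
                if dose > 0 else None
            forcing = ForcingContext(circadian=circadian, schedule=schedule)
            model = ReducedModel(params=params, calib=calib, forcing=forcing)
            traj = integrate(model.rhs, lc.state_at(dose_time),
                             (dose_time, dose_time + 24.0 * days),
                             schedule=schedule, settings=settings, columns=model.names)
            ws = window_stats(traj, "eda", (dose_time, dose_time + 24.0 * days), reference=ref)
            rows.append({"half_life": float(hl), "dose": float(dose),
                         "mean": ws.mean, "mean_rel": ws.mean / ref,
                         "mean_pct_above": ws.mean_pct_above})
    return pd.DataFrame(rows)


def homeostasis_sweeps(
    firing_grid: Sequence[float] = tuple(np.linspace(0.5, 2.0, 7)),
    th_scale_grid: Sequence[float] = tuple(np.linspace(0.1, 1.5, 8)),
    dat_scale_grid: Sequence[float] = tuple(np.linspace(0.1, 1.5, 8)),
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
) -> dict:
    """Steady-state robustness of eda to firing rate and enzyme expression.

    Part (a): equilibrium eda versus a constant firing-rate multiplier,
    once with the autoreceptor feedback active and once with the feedback
    factor pinned to 1 (without autoreceptors the response is proportional;
    with them it is strongly damped).  Part (b): equilibrium eda over a
    grid of TH and DAT maximal-rate scalings, in percent of nominal.
    Failed equilibrium solves are recorded as NaN.
    """
    ref = nominal_eda_reference(params, calib)
    rows = []
    for fire in firing_grid:
        for pinned in (False, True):
            try:
                eq = find_equilibrium(params, FrozenForcing(fire=float(fire),
                                                            pin_autoreceptor=pinned), calib)
                eda = eq.eda
            except EquilibriumError:
                eda = float("nan")
            rows.append({"fire": float(fire), "autoreceptors": not pinned,
                         "eda": eda, "eda_pct_of_nominal": eda / ref * 100.0})
    firing = pd.DataFrame(rows)

    rows = []
    for th in th_scale_grid:
        for dat in dat_scale_grid:
            scaled = params.scaled(Vmax_tyr=max(float(th), 1e-9),
                                   Vmax_eda=max(float(dat), 1e-9))
            try:
                eda = find_equilibrium(scaled, FrozenForcing(), calib).eda
            except EquilibriumError:
                eda = float("nan")
            rows.append({"th_scale": float(th), "dat_scale": float(dat),
                         "eda": eda, "eda_pct_of_nominal": eda / ref * 100.0})
    enzyme = pd.DataFrame(rows)
    return {"firing_response": firing, "enzyme_grid": enzyme}


def sensitivity_ridge(
    duo_preset: DUOParams,
    scale_range: tuple[float, float] = (0.75, 1.25),
    n_scales: int = 11,
    sim_days: float = 100.0,
    record_days: float = 4.0,
    settings: SolverSettings = SolverSettings(output_dt=0.02),
) -> pd.DataFrame:
    """One-at-a-time robustness scan of the DUO coupling parameters.

    Each coupling parameter is scaled over ``scale_range``; for each scaled
    set the DUO is integrated (circadian off) for ``sim_days`` days and the
    eda period/amplitude estimated from the final ``record_days`` days.
    Non-oscillatory points are recorded with zero amplitude, not fatal.
    """
    no_circ = ForcingContext(circadian=CircadianConfig.off())
    scales = np.linspace(scale_range[0], scale_range[1], n_scales)
    sim_hours = 24.0 * sim_days
    discard = sim_hours - 24.0 * record_days
    rows = []
    for name in DUO_PARAM_NAMES:
        for sc in scales:
            p = duo_preset.scaled(name, float(sc))
            model = DUOModel(params=p, forcing=no_circ)
            try:
                z0 = duo_initial_state(p).as_array()
                traj = integrate(model.rhs, z0, (0.0, sim_hours),
                                 settings=settings, columns=model.names)
                summ = estimate_period_amplitude(traj, "eda", discard=discard)
                period, amp = summ.period, summ.amplitude
            except (InsufficientOscillationData, EquilibriumError):
                period, amp = float("nan"), 0.0
            rows.append({"parameter": name, "scale": float(sc),
                         "period": period, "amplitude": amp})
    return pd.DataFrame(rows)


def lhs_oscillation_search(
    ranges: LHSRanges = LHSRanges(),
    n: int = 50,
    seed: int = 0,
    s_dat: float = 1.0,
    sim_hours: float = 480.0,
    settings: SolverSettings = SolverSettings(output_dt=0.02),
) -> pd.DataFrame:
    """Latin-hypercube search for parameter sets with sustained oscillations.

    Integrates each sampled DUO (circadian off) and keeps the peak-based
    period/amplitude; ``oscillatory`` marks sets with a sustained limit
    cycle in the second half of the run.
    """
    no_circ = ForcingContext(circadian=CircadianConfig.off())
    rows = []
    for params in lhs_sample_duo(ranges, n=n, seed=seed, s_dat=s_dat):
        row = {name: getattr(params, name) for name in DUO_PARAM_NAMES}
        row["s_dat"] = s_dat
        try:
            z0 = duo_initial_state(params).as_array()
            model = DUOModel(params=params, forcing=no_circ)
            traj = integrate(model.rhs, z0, (0.0, sim_hours),
                             settings=settings, columns=model.names)
            summ = estimate_period_amplitude(traj, "eda", discard=0.5 * sim_hours)
            row.update(period=summ.period, amplitude=summ.amplitude,
                       oscillatory=bool(summ.oscillatory))
        except (InsufficientOscillationData, EquilibriumError) as exc:
            row.update(period=float("nan"), amplitude=0.0, oscillatory=False)
        rows.append(row)
    return pd.DataFrame(rows)
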