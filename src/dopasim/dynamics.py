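"""Numerical integration with dose events and uniform resampling.

Doses are instantaneous jumps in transporter occupancy, so the model
right-hand side is discontinuous (in time) at administration times.  The
integrator therefore splits the time span at every dose time and restarts
the stiff solver on each piece; the model state itself is continuous and
the occupancy ``x_dose`` is evaluated in closed form, so the jump is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .forcing import DoseSchedule, ForcingContext
from .model import (
    AutoreceptorCalibration,
    ModelState,
    ReducedParams,
    find_equilibrium,
    rhs_reduced_array,
)
from .duo import DUOParams, DUOState, duo_initial_state, rhs_duo_array

__all__ = [
    "SolverSettings",
    "Trajectory",
    "ReducedModel",
    "DUOModel",
    "integrate",
    "resample_uniform",
    "run_protocol",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    """Solver tolerances and output control.

    ``max_step`` is capped at 0.1 h by default so the circadian forcing
    and the fast extracellular transients (rate constants up to 400/hr)
    are always resolved.  ``output_dt`` is the spacing of the recorded
    grid; ``None`` keeps the solver's own steps.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = 0.1
    stiff_method: bool = True
    output_dt: Optional[float] = 0.01

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")

    @property
    def method(self) -> str:
        return "LSODA" if self.stiff_method else "RK45"

    def refined(self, factor: float = 0.5) -> "SolverSettings":
        """Copy with both tolerances multiplied by ``factor`` (convergence checks)."""
        return SolverSettings(self.rel_tol * factor, self.abs_tol * factor,
                              self.max_step, self.stiff_method, self.output_dt)


@dataclass
class Trajectory:
    """Time-stamped state series.

    ``states`` has one row per time point and one column per state
    variable named in ``columns``.  ``metadata`` records how the run was
    produced (model kind, forcing, schedule).
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.columns)):
            raise ValueError("states shape does not match times/columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t1(self) -> float:
        return float(self.times[-1])

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.times)
        return bool(dt.size) and np.allclose(dt, dt[0], rtol=rtol)

    def slice(self, t_start: float, t_end: float) -> "Trajectory":
        """Restrict to the half-open window (t_start, t_end]."""
        mask = (self.times > t_start) & (self.times <= t_end + 1e-12)
        return Trajectory(self.times[mask], self.states[mask], self.columns, dict(self.metadata))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, index=pd.Index(self.times, name="time_hr"),
                            columns=list(self.columns))


@dataclass(frozen=True)
class ReducedModel:
    """Reduced 4-state dopamine model bundled with its forcing."""

    params: ReducedParams = field(default_factory=ReducedParams)
    calib: AutoreceptorCalibration = field(default_factory=AutoreceptorCalibration)
    forcing: ForcingContext = field(default_factory=ForcingContext)

    names: tuple[str, ...] = ("ldopa", "cda", "vda", "eda")

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        f = self.forcing
        return rhs_reduced_array(
            t, y, self.params, self.calib,
            float(f.cth(t)), float(f.cmao(t)), float(f.fire(t)),
            float(f.s_dat_effective(t)), f.pin_autoreceptor,
        )

    def equilibrium_state(self, t: float = 0.0) -> np.ndarray:
        """Feasible equilibrium under the forcing frozen at time t."""
        return find_equilibrium(self.params, self.forcing.frozen(t), self.calib).as_array()


@dataclass(frozen=True)
class DUOModel:
    """Six-state ultradian oscillator bundled with its forcing."""

    params: DUOParams
    forcing: ForcingContext = field(default_factory=ForcingContext)

    names: tuple[str, ...] = ("ldopa", "cda", "vda", "eda", "edapool", "D2")

    def rhs(self, t: float, z: np.ndarray) -> np.ndarray:
        f = self.forcing
        return rhs_duo_array(t, z, self.params, float(f.cth(t)), float(f.cmao(t)), float(f.fire(t)))

    def equilibrium_state(self, t: float = 0.0) -> np.ndarray:
        return duo_initial_state(self.params).as_array()


def _breakpoints(t_span: tuple[float, float], schedule: Optional[DoseSchedule]) -> list[float]:
    t0, t1 = t_span
    pts = [t0]
    if schedule is not None:
        pts += [ti for ti in schedule.times if t0 < ti < t1]
    pts.append(t1)
    return sorted(set(pts))


def integrate(
    model_rhs: Callable[[float, np.ndarray], np.ndarray],
    state0: np.ndarray,
    t_span: tuple[float, float],
    schedule: Optional[DoseSchedule] = None,
    settings: SolverSettings = SolverSettings(),
    columns: Optional[Sequence[str]] = None,
    metadata: Optional[dict] = None,
) -> Trajectory:
    """Integrate ``model_rhs`` over ``t_span``, restarting at dose times.

    ``schedule`` only marks the solver breakpoints; the occupancy itself is
    evaluated in closed form inside the forcing, so the jump at each
    administration time is exact.  Raises :class:`IntegrationError` if the
    solver fails or a state component drops below -1e-6.
    """
    t0, t1 = t_span
    if not t0 < t1:
        raise ValueError("t_span must be increasing")
    y0 = np.asarray(state0, dtype=float)
    if columns is None:
        columns = [f"y{i}" for i in range(y0.size)]
    pieces_t: list[np.ndarray] = []
    pieces_y: list[np.ndarray] = []
    for a, b in zip(_breakpoints(t_span, schedule)[:-1], _breakpoints(t_span, schedule)[1:]):
        if settings.output_dt is not None:
            n = max(int(np.ceil((b - a) / settings.output_dt)), 2)
            t_eval = np.linspace(a, b, n + 1)
        else:
            t_eval = None
        sol = solve_ivp(
            model_rhs, (a, b), y0,
            method=settings.method,
            rtol=settings.rel_tol, atol=settings.abs_tol,
            max_step=settings.max_step, t_eval=t_eval, dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a:g}, {b:g}]: {sol.message}")
        if sol.y.min() < -1e-6:
            raise IntegrationError(
                f"state integrity violated on [{a:g}, {b:g}]: min component {sol.y.min():g}"
            )
        y0 = sol.y[:, -1]
        # drop the duplicated left endpoint of continuation pieces
        start = 1 if pieces_t else 0
        pieces_t.append(sol.t[start:])
        pieces_y.append(np.clip(sol.y.T[start:], 0.0, None))
    times = np.concatenate(pieces_t)
    states = np.concatenate(pieces_y)
    keep = np.concatenate([[True], np.diff(times) > 0])
    return Trajectory(times[keep], states[keep], tuple(columns), metadata or {})


def resample_uniform(traj: Trajectory, dt: float) -> Trajectory:
    """Resample onto a uniform grid covering (t0, t0 + n*dt] by interpolation.

    Monotone piecewise-linear interpolation of each column; the right
    endpoint is preserved when the span is an integer number of steps.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = traj.t1 - traj.t0
    if dt > span:
        raise ValueError("dt larger than trajectory span")
    n = int(np.floor(span / dt + 1e-9))
    grid = traj.t0 + dt * np.arange(1, n + 1)
    states = np.column_stack([np.interp(grid, traj.times, traj.states[:, j])
                              for j in range(traj.states.shape[1])])
    meta = dict(traj.metadata)
    meta["resampled_dt"] = dt
    return Trajectory(grid, states, traj.columns, meta)


def run_protocol(
    model: "ReducedModel | DUOModel",
    schedule: Optional[DoseSchedule],
    days: int = 7,
    settings: SolverSettings = SolverSettings(),
    burn_in_hours: float = 240.0,
    record_from: Optional[float] = None,
) -> Trajectory:
    """Spin the model up to its forced limit cycle, then run the protocol.

    The burn-in starts at the frozen-forcing equilibrium ``burn_in_hours``
    before ``record_from`` (default: the first dose time, or 0) and is
    discarded; the recorded window spans ``days`` days from there.  Dose
    times in the schedule are interpreted in the same CT frame as the
    circadian forcing (t = 0 is CT0).
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if record_from is None:
        record_from = schedule.times[0] if schedule is not None and schedule.times else 0.0
    t_start = record_from - burn_in_hours
    burn_settings = SolverSettings(settings.rel_tol, settings.abs_tol,
                                   settings.max_step, settings.stiff_method, output_dt=None)
    y0 = model.equilibrium_state(t_start)
    if burn_in_hours > 0:
        burn = integrate(model.rhs, y0, (t_start, record_from), schedule=None,
                         settings=burn_settings, columns=model.names)
        y0 = burn.final_state()
    traj = integrate(model.rhs, y0, (record_from, record_from + 24.0 * days),
                     schedule=schedule, settings=settings, columns=model.names,
                     metadata={"model": type(model).__name__,
                               "schedule": None if schedule is None else
                               {"dose": schedule.dose, "times": list(schedule.times),
                                "half_life": schedule.half_life},
                               "burn_in_hours": burn_in_hours})
    return traj
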