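"""Circadian forcing, firing-rate profile, and DRI pharmacokinetics.

Circadian control enters as sinusoidal multipliers on two enzyme
activities: C_TH(t) on tyrosine hydroxylase (peak at t = 18 h) and
C_MAO(t) on extracellular catabolism (peak 8 h later).  A dopamine
reuptake inhibitor (DRI) is modelled as a transporter occupancy
``x_dose(t)`` that jumps by ``Dose`` at each administration time and
decays exponentially with rate r = ln(2)/half-life; the effective DAT
activity is ``max(1 - x_dose, 0)``.  Time is in hours with t = 0 at CT0
(circadian time zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CircadianConfig",
    "DoseSchedule",
    "ForcingContext",
    "c_th",
    "c_mao",
    "x_dose_trajectory",
]


@dataclass(frozen=True)
class CircadianConfig:
    """Sinusoidal circadian multipliers on TH and MAO activity.

    With defaults both multipliers vary over [0.75, 1.25] with a 24-h
    period; ``baseline_scale_*`` shifts the whole curve (0.75 or 1.25 of
    nominal in the baseline-robustness runs).  ``enabled=False`` pins both
    multipliers to 1.
    """

    amplitude: float = 0.25
    period: float = 24.0
    phase_th: float = 12.0
    phase_mao: float = 20.0
    baseline_scale_th: float = 1.0
    baseline_scale_mao: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @classmethod
    def off(cls) -> "CircadianConfig":
        return cls(enabled=False)


def c_th(t, cfg: CircadianConfig = CircadianConfig()):
    """Circadian multiplier on TH activity; maximum at t = 18 (mod 24)."""
    if not cfg.enabled:
        return np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else 1.0
    omega = 2.0 * math.pi / cfg.period
    return cfg.baseline_scale_th * (cfg.amplitude * np.sin(omega * (np.asarray(t) - cfg.phase_th)) + 1.0)


def c_mao(t, cfg: CircadianConfig = CircadianConfig()):
    """Circadian multiplier on extracellular catabolism; peaks 8 h after C_TH."""
    if not cfg.enabled:
        return np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else 1.0
    omega = 2.0 * math.pi / cfg.period
    return cfg.baseline_scale_mao * (cfg.amplitude * np.sin(omega * (np.asarray(t) - cfg.phase_mao)) + 1.0)


@dataclass(frozen=True)
class DoseSchedule:
    """DRI administration schedule.

    ``dose`` is the fraction of DAT occupied per administration (each dose
    in [0, 1]; stacked doses may transiently exceed full occupancy, which
    the effective-activity clamp absorbs).  ``times`` are hours in the CT
    frame, strictly increasing.  The decay rate is r = ln(2)/half_life.
    """

    dose: float
    times: tuple[float, ...]
    half_life: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dose <= 1.0:
            raise ValueError("dose must lie in [0, 1]")
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("dose times must be non-decreasing")

    @property
    def r(self) -> float:
        """Exponential decay rate of occupancy (1/hr)."""
        return math.log(2.0) / self.half_life

    @classmethod
    def daily(cls, dose: float, first_time: float, days: int, half_life: float = 15.0) -> "DoseSchedule":
        """Same dose at the same clock time each day for ``days`` days."""
        return cls(dose=dose, times=tuple(first_time + 24.0 * i for i in range(days)), half_life=half_life)


def x_dose_trajectory(schedule: DoseSchedule | None, t):
    """Transporter occupancy x_dose at time(s) t (right-continuous at doses).

    x(t) = sum over administered doses of Dose * exp(-r (t - t_i)).
    """
    tt = np.asarray(t, dtype=float)
    x = np.zeros_like(tt, dtype=float)
    if schedule is not None:
        for ti in schedule.times:
            x = x + np.where(tt >= ti, schedule.dose * np.exp(-schedule.r * (tt - ti)), 0.0)
    return float(x) if np.ndim(t) == 0 else x


@dataclass(frozen=True)
class ForcingContext:
    """Time-dependent forcing bundle consumed by the model right-hand side.

    ``s_dat_base`` is the constant DAT activity fraction (used by the DUO
    and quasi-static analyses); when a schedule is present the effective
    activity is ``s_dat_base * max(1 - x_dose(t), 0)``.  ``fire_profile``
    overrides the constant firing-rate multiplier when given.
    """

    circadian: CircadianConfig = field(default_factory=CircadianConfig)
    schedule: DoseSchedule | None = None
    s_dat_base: float = 1.0
    fire_const: float = 1.0
    fire_profile: Callable[[float], float] | None = None
    pin_autoreceptor: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_dat_base <= 1.0:
            raise ValueError("s_dat_base must lie in [0, 1]")
        if self.fire_const < 0:
            raise ValueError("fire_const must be non-negative")

    def cth(self, t):
        return c_th(t, self.circadian)

    def cmao(self, t):
        return c_mao(t, self.circadian)

    def fire(self, t):
        if self.fire_profile is not None:
            return self.fire_profile(t)
        return self.fire_const

    def x_dose(self, t):
        return x_dose_trajectory(self.schedule, t)

    def s_dat_effective(self, t):
        return self.s_dat_base * np.clip(1.0 - self.x_dose(t), 0.0, 1.0)

    def frozen(self, t: float) -> "FrozenForcing":
        """Snapshot of all multipliers at clock time t (quasi-static use)."""
        from .model import FrozenForcing

        return FrozenForcing(
            cth=float(self.cth(t)),
            cmao=float(self.cmao(t)),
            fire=float(self.fire(t)),
            s_dat=float(self.s_dat_effective(t)),
            pin_autoreceptor=self.pin_autoreceptor,
        )
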