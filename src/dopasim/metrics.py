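"""Trajectory summary statistics.

Windowed mean/median/SD (the three summaries used to characterise the
24-hour response to a reuptake-inhibitor dose), trailing moving-window
variants, circadian peak timing, and peak-based period/amplitude
estimation for the ultradian oscillator.  All statistics are computed on
uniformly sampled trajectories; medians and percentiles on a non-uniform
solver grid would be biased toward regions of small steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dynamics import Trajectory
from .model import ModelState

__all__ = [
    "WindowStats",
    "OscillationSummary",
    "InsufficientOscillationData",
    "window_stats",
    "moving_window_stats",
    "peak_time_in_cycle",
    "estimate_period_amplitude",
    "vesicular_fraction",
]

#: Oscillations with peak prominence or peak-to-trough amplitude below this
#: (uM) are classified as non-oscillatory.
NON_OSCILLATORY_THRESHOLD = 1e-6


class InsufficientOscillationData(RuntimeError):
    """Too few peaks after transient discard to estimate a period."""


@dataclass(frozen=True)
class WindowStats:
    """Mean/median/SD of one variable over a time window.

    ``reference`` is the steady-state value used for the
    percent-above-reference normalisation.
    """

    mean: float
    median: float
    sd: float
    window: tuple[float, float]
    variable: str
    reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed start")

    def _pct(self, value: float) -> float:
        if self.reference is None:
            raise ValueError("no reference value set")
        return (value / self.reference - 1.0) * 100.0

    @property
    def mean_pct_above(self) -> float:
        return self._pct(self.mean)

    @property
    def median_pct_above(self) -> float:
        return self._pct(self.median)

    @property
    def sd_pct_of_reference(self) -> float:
        if self.reference is None:
            raise ValueError("no reference value set")
        return self.sd / self.reference * 100.0


@dataclass(frozen=True)
class OscillationSummary:
    """Period/amplitude summary of a (possibly non-)oscillatory trace."""

    period: float  # hours; NaN when non-oscillatory
    amplitude: float  # peak-to-trough, units of the variable; 0 when non-oscillatory
    n_cycles: int
    peak_times: tuple[float, ...]
    oscillatory: bool


def _require_uniform(traj: Trajectory) -> float:
    if not traj.is_uniform():
        raise ValueError("trajectory is not uniformly sampled; use resample_uniform first")
    return float(traj.times[1] - traj.times[0])


def window_stats(
    traj: Trajectory,
    variable: str,
    window: tuple[float, float],
    reference: Optional[float] = None,
) -> WindowStats:
    """Mean, median and SD of ``variable`` over the half-open window (start, end]."""
    _require_uniform(traj)
    start, end = window
    if end > traj.t1 + 1e-9:
        raise ValueError("window extends past the trajectory end")
    sub = traj.slice(start, end)
    x = sub.column(variable)
    if x.size == 0:
        raise ValueError("window contains no samples")
    return WindowStats(
        mean=float(np.mean(x)), median=float(np.median(x)), sd=float(np.std(x)),
        window=(start, end), variable=variable, reference=reference,
    )


def moving_window_stats(
    traj: Trajectory,
    variable: str,
    window_width: float = 24.0,
    reference: Optional[float] = None,
) -> pd.DataFrame:
    """Trailing-window mean/median/SD series on the uniform grid.

    Returns a frame indexed by time with columns ``mean``, ``median``,
    ``sd`` (and percent-above-reference variants when a reference is
    given); the first value appears once a full window is available.
    """
    dt = _require_uniform(traj)
    n = int(round(window_width / dt))
    if n < 2:
        raise ValueError("window_width too small for the sampling step")
    s = pd.Series(traj.column(variable), index=traj.times)
    roll = s.rolling(window=n, min_periods=n)
    out = pd.DataFrame({"mean": roll.mean(), "median": roll.median(), "sd": roll.std(ddof=0)})
    out.index.name = "time_hr"
    out = out.dropna()
    if reference is not None:
        out["mean_pct_above"] = (out["mean"] / reference - 1.0) * 100.0
        out["median_pct_above"] = (out["median"] / reference - 1.0) * 100.0
        out["sd_pct_of_reference"] = out["sd"] / reference * 100.0
    return out


def _quadratic_refine(t: np.ndarray, x: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i-1, i, i+1 (local maximum)."""
    if i <= 0 or i >= x.size - 1:
        return float(t[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[i] - t[i - 1]
    return float(t[i] + np.clip(delta, -1.0, 1.0) * dt)


def peak_time_in_cycle(traj: Trajectory, variable: str, cycle_length: float = 24.0) -> float:
    """Clock time (mod cycle_length) of the variable's maximum over the final cycle.

    Intended for post-burn-in, circadian-forced trajectories; the sampled
    maximum is refined by local quadratic interpolation.
    """
    _require_uniform(traj)
    if traj.t1 - traj.t0 < cycle_length:
        raise ValueError("trajectory shorter than one cycle")
    sub = traj.slice(traj.t1 - cycle_length, traj.t1)
    x = sub.column(variable)
    i = int(np.argmax(x))
    t_peak = _quadratic_refine(sub.times, x, i)
    return float(np.mod(t_peak, cycle_length))


def estimate_period_amplitude(
    traj: Trajectory,
    variable: str,
    discard: float = 0.0,
    min_prominence: float = NON_OSCILLATORY_THRESHOLD,
) -> OscillationSummary:
    """Peak-based period and amplitude of an oscillatory variable.

    After discarding the first ``discard`` hours, local maxima with
    prominence at least ``min_prominence`` define the cycles: the period is
    the mean successive peak-to-peak interval (peak times refined by local
    quadratic interpolation) and the amplitude is the mean per-cycle
    max-minus-min.  A trace with no prominent peaks (e.g. one converging to
    a fixed point) is reported as non-oscillatory with zero amplitude; one
    or two peaks raise :class:`InsufficientOscillationData`.
    """
    _require_uniform(traj)
    sub = traj.slice(traj.t0 + discard, traj.t1)
    x = sub.column(variable)
    t = sub.times
    peaks, _ = find_peaks(x, prominence=min_prominence)
    if peaks.size == 0:
        return OscillationSummary(float("nan"), 0.0, 0, (), False)
    if peaks.size < 3:
        raise InsufficientOscillationData(
            f"only {peaks.size} prominent peak(s) after discarding {discard} h"
        )
    peak_times = np.array([_quadratic_refine(t, x, i) for i in peaks])
    period = float(np.mean(np.diff(peak_times)))
    amps = [float(x[a:b + 1].max() - x[a:b + 1].min()) for a, b in zip(peaks[:-1], peaks[1:])]
    amplitude = float(np.mean(amps))
    oscillatory = amplitude >= NON_OSCILLATORY_THRESHOLD
    return OscillationSummary(
        period=period if oscillatory else float("nan"),
        amplitude=amplitude if oscillatory else 0.0,
        n_cycles=len(amps),
        peak_times=tuple(float(pt) for pt in peak_times),
        oscillatory=oscillatory,
    )


def vesicular_fraction(state: ModelState) -> float:
    """Fraction of intracellular dopamine stored in vesicles, vda/(cda+vda)."""
    total = state.cda + state.vda
    if total <= 0:
        raise ValueError("cda + vda must be positive")
    return state.vda / total
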