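"""Linear stability analysis, quasi-static stability maps, and Hopf localization.

The Jacobians of the reduced 4-state model and of the 6-state ultradian
oscillator are derived symbolically once (and cached), then evaluated
numerically.  The circadian multipliers are treated quasi-statically: at
each (s_DAT, phase) pair the forcing is frozen, the feasible equilibrium
solved, and the eigenvalues of the Jacobian there decide local stability.
A Hopf point of the DUO is bracketed by bisection on the sign of the
largest real part of the spectrum along the s_DAT-dependent equilibrium
branch, with the crossing pair required to have nonzero imaginary part.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields, replace
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .forcing import CircadianConfig, c_mao, c_th
from .model import (
    AutoreceptorCalibration,
    EquilibriumError,
    FrozenForcing,
    ModelState,
    ReducedParams,
    find_equilibrium,
)
from .duo import DUOParams, DUOState, find_equilibrium_duo

__all__ = [
    "EquilibriumReport",
    "jacobian_reduced",
    "jacobian_duo",
    "finite_difference_jacobian",
    "stability_map_reduced",
    "hopf_locate",
    "amplitude_curve_duo",
    "HopfLocateError",
]


class HopfLocateError(RuntimeError):
    pass


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibrium, Jacobian and spectrum at one (s_DAT, phase) point."""

    s_dat: float
    phase: float
    equilibrium: "ModelState | DUOState | None"
    jacobian: Optional[np.ndarray]
    eigenvalues: Optional[np.ndarray]
    max_real: float  # NaN when the equilibrium solve failed
    failed: bool = False


# ---------------------------------------------------------------------------
# Symbolic Jacobians (derived once, cached)
# ---------------------------------------------------------------------------

_REDUCED_PARAM_NAMES = tuple(f.name for f in dc_fields(ReducedParams))
_CALIB_NAMES = ("a", "b", "c", "d", "hill_exponent")


def _safe_exp(x):
    # Clipped at 250 so products like exp(x)/(1+exp(x))**2 stay finite;
    # beyond the clip the true sigmoid-derivative terms are < 1e-100.
    return np.exp(np.clip(x, -250.0, 250.0))


@lru_cache(maxsize=None)
def _reduced_jacobian_fn(pin_autoreceptor: bool = False) -> Callable:
    import sympy as sp

    ldopa, cda, vda, eda = sp.symbols("ldopa cda vda eda", positive=True)
    p = {name: sp.Symbol(name, positive=True) for name in _REDUCED_PARAM_NAMES}
    a, b, c, d, h = sp.symbols("a b c d h", positive=True)
    cth, cmao, fire, sdat = sp.symbols("cth cmao fire sdat", nonnegative=True)

    factor = sp.Integer(1) if pin_autoreceptor else a / ((eda / c) ** h + d) + b
    const = sp.Rational(56, 100) / (1 + p["tyr_fixed"] / p["K_i_tyr"])
    vth = (
        cth * const * factor
        * (p["Vmax_tyr"] * p["tyr_fixed"] * p["bh4_fixed"])
        / (p["tyr_fixed"] * p["bh4_fixed"] + p["K_tyr"] * p["bh4_fixed"]
           + p["K_tyr"] * p["K_bh4"] * (1 + cda / p["K_i_cda"]))
    )
    vaadc = p["Vmax_ldopa"] * ldopa / (p["K_m_ldopa"] + ldopa)
    vmat = p["Vmax_cda"] * cda / (p["K_m_cda"] + cda) - p["k_out"] * vda
    vdat = sdat * p["Vmax_eda"] * eda / (p["K_m_eda"] + eda)
    vcatab = cmao * p["Vmax_catab"] * eda / (p["K_m_catab"] + eda)
    rhs = sp.Matrix([
        vth - vaadc,
        vaadc - vmat + vdat - p["k_cda"] * cda,
        vmat - fire * vda,
        fire * vda - vdat - vcatab - p["k_eda"] * eda,
    ])
    J = rhs.jacobian([ldopa, cda, vda, eda])
    args = (
        (ldopa, cda, vda, eda),
        tuple(p[name] for name in _REDUCED_PARAM_NAMES),
        (a, b, c, d, h),
        (cth, cmao, fire, sdat),
    )
    return sp.lambdify(args, J, modules=[{"exp": _safe_exp}, "numpy"])


def jacobian_reduced(
    state: "ModelState | np.ndarray",
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    forcing: FrozenForcing = FrozenForcing(),
) -> np.ndarray:
    """Analytic 4x4 Jacobian of the reduced model at a state, forcing frozen."""
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    fn = _reduced_jacobian_fn(forcing.pin_autoreceptor)
    return np.asarray(
        fn(
            tuple(y),
            tuple(getattr(params, n) for n in _REDUCED_PARAM_NAMES),
            tuple(getattr(calib, n) for n in _CALIB_NAMES),
            (forcing.cth, forcing.cmao, forcing.fire, forcing.s_dat),
        ),
        dtype=float,
    )


_DUO_COUPLING_NAMES = ("k1_pool", "k2_pool", "k3_pool", "k4_pool", "alpha", "beta", "gamma", "m")


@lru_cache(maxsize=None)
def _duo_jacobian_fn() -> Callable:
    import sympy as sp

    ldopa, cda, vda, eda, edapool, D2 = sp.symbols("ldopa cda vda eda edapool D2", positive=True)
    p = {name: sp.Symbol(name, positive=True) for name in _REDUCED_PARAM_NAMES}
    k1, k2, k3, k4, alpha, beta, gamma, m = sp.symbols(
        "k1 k2 k3 k4 alpha beta gamma m", positive=True
    )
    cth, cmao, fire, sdat = sp.symbols("cth cmao fire sdat", nonnegative=True)

    factor = alpha + beta / (1 + sp.exp((D2 - gamma * (2 - sdat)) / m))
    const = sp.Rational(56, 100) / (1 + p["tyr_fixed"] / p["K_i_tyr"])
    vth = (
        cth * const * factor
        * (p["Vmax_tyr"] * p["tyr_fixed"] * p["bh4_fixed"])
        / (p["tyr_fixed"] * p["bh4_fixed"] + p["K_tyr"] * p["bh4_fixed"]
           + p["K_tyr"] * p["K_bh4"] * (1 + cda / p["K_i_cda"]))
    )
    vaadc = p["Vmax_ldopa"] * ldopa / (p["K_m_ldopa"] + ldopa)
    vmat = p["Vmax_cda"] * cda / (p["K_m_cda"] + cda) - p["k_out"] * vda
    vdat = sdat * p["Vmax_eda"] * eda / (p["K_m_eda"] + eda)
    vcatab = cmao * p["Vmax_catab"] * eda / (p["K_m_catab"] + eda)
    rhs = sp.Matrix([
        vth - vaadc,
        vaadc - vmat + vdat - p["k_cda"] * cda,
        vmat - fire * vda,
        fire * vda - vdat - vcatab - p["k_eda"] * eda,
        k1 * eda - k2 * edapool,
        k3 * edapool - k4 * D2,
    ])
    J = rhs.jacobian([ldopa, cda, vda, eda, edapool, D2])
    args = (
        (ldopa, cda, vda, eda, edapool, D2),
        tuple(p[name] for name in _REDUCED_PARAM_NAMES),
        (k1, k2, k3, k4, alpha, beta, gamma, m),
        (cth, cmao, fire, sdat),
    )
    return sp.lambdify(args, J, modules=[{"exp": _safe_exp}, "numpy"])


def jacobian_duo(
    state: "DUOState | np.ndarray",
    params: DUOParams,
    forcing: FrozenForcing = FrozenForcing(),
) -> np.ndarray:
    """Analytic 6x6 Jacobian of the DUO at a state, forcing frozen.

    The DAT activity entering both the reuptake scaling and the feedback
    sigmoid is the constant ``params.s_dat``.
    """
    z = state.as_array() if isinstance(state, DUOState) else np.asarray(state, dtype=float)
    fn = _duo_jacobian_fn()
    return np.asarray(
        fn(
            tuple(z),
            tuple(getattr(params.reduced, n) for n in _REDUCED_PARAM_NAMES),
            tuple(getattr(params, n) for n in _DUO_COUPLING_NAMES),
            (forcing.cth, forcing.cmao, forcing.fire, params.s_dat),
        ),
        dtype=float,
    )


def finite_difference_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference Jacobian, the numerical cross-check for the analytic one."""
    y = np.asarray(y, dtype=float)
    n = y.size
    f0 = np.asarray(fun(y))
    J = np.empty((f0.size, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1e-8)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (np.asarray(fun(yp)) - np.asarray(fun(ym))) / (2.0 * h)
    return J


# ---------------------------------------------------------------------------
# Quasi-static stability map of the reduced model
# ---------------------------------------------------------------------------


def stability_map_reduced(
    s_dat_grid: Sequence[float],
    phase_grid: Sequence[float],
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    circadian: CircadianConfig = CircadianConfig(),
) -> list[EquilibriumReport]:
    """Equilibrium + spectrum for every (s_DAT, circadian phase) pair.

    The circadian multipliers are frozen at each phase (quasi-static
    assumption).  Failed equilibrium solves are flagged per point, not
    fatal.
    """
    reports = []
    for phase in phase_grid:
        frozen = FrozenForcing(cth=float(c_th(phase, circadian)),
                               cmao=float(c_mao(phase, circadian)))
        for s in sorted(s_dat_grid, reverse=True):  # continuation from s=1 downward
            f = replace(frozen, s_dat=float(s))
            try:
                eq = find_equilibrium(params, f, calib)
            except EquilibriumError:
                reports.append(EquilibriumReport(float(s), float(phase), None, None, None,
                                                 float("nan"), failed=True))
                continue
            J = jacobian_reduced(eq, params, calib, f)
            lam = np.linalg.eigvals(J)
            reports.append(EquilibriumReport(
                float(s), float(phase), eq, J, lam, float(np.max(lam.real))
            ))
    return reports


def stability_map_frame(reports: Sequence[EquilibriumReport]) -> pd.DataFrame:
    """Long-format table (s_dat, phase, max_real, equilibrium components)."""
    rows = []
    for r in reports:
        row = {"s_dat": r.s_dat, "phase": r.phase, "max_real": r.max_real, "failed": r.failed}
        if r.equilibrium is not None:
            for name in ("ldopa", "cda", "vda", "eda"):
                row[f"{name}_star"] = getattr(r.equilibrium, name)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hopf localization and amplitude curve for the DUO
# ---------------------------------------------------------------------------


def _duo_spectrum(params: DUOParams, s_dat: float, forcing: FrozenForcing) -> np.ndarray:
    p = params.with_s_dat(float(s_dat))
    eq = find_equilibrium_duo(p, forcing)
    return np.linalg.eigvals(jacobian_duo(eq, p, forcing))


def hopf_locate(
    duo_params: DUOParams,
    s_dat_interval: tuple[float, float],
    forcing: FrozenForcing = FrozenForcing(),
    tol: float = 1e-3,
) -> float:
    """Critical s_DAT where the dominant eigenvalue pair crosses the imaginary axis.

    Bisection on the sign of the largest real part of the DUO spectrum at
    the s_DAT-dependent equilibrium.  Raises :class:`HopfLocateError` if
    the endpoints do not bracket a sign change, or if the crossing
    eigenvalue is real (a non-Hopf zero crossing).
    """
    lo, hi = float(s_dat_interval[0]), float(s_dat_interval[1])
    if not lo < hi:
        raise HopfLocateError(f"degenerate interval [{lo}, {hi}]")

    def max_real(s: float) -> float:
        return float(np.max(_duo_spectrum(duo_params, s, forcing).real))

    f_lo, f_hi = max_real(lo), max_real(hi)
    if f_lo * f_hi > 0:
        raise HopfLocateError(
            f"no sign change of the dominant real part on [{lo}, {hi}] "
            f"(values {f_lo:.3g}, {f_hi:.3g})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = max_real(mid)
        if f_mid == 0.0:
            lo = hi = mid
            break
        if f_mid * f_lo < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    s_crit = 0.5 * (lo + hi)
    lam = _duo_spectrum(duo_params, s_crit, forcing)
    dominant = lam[np.argmax(lam.real)]
    if abs(dominant.imag) < 1e-9:
        raise HopfLocateError(
            f"dominant eigenvalue at crossing is real ({dominant}); not a Hopf point"
        )
    return float(s_crit)


def amplitude_curve_duo(
    duo_params: DUOParams,
    s_dat_grid: Sequence[float],
    sim_hours: float = 480.0,
    discard_fraction: float = 0.5,
    settings=None,
) -> pd.DataFrame:
    """Steady-oscillation amplitude and period of eda for each s_DAT.

    Integrates the DUO from near its equilibrium at each s_DAT and applies
    the peak-based estimator to the post-transient trace; points below the
    Hopf bifurcation converge to the stable equilibrium and report zero
    amplitude.
    """
    from .dynamics import DUOModel, SolverSettings, integrate
    from .duo import duo_initial_state
    from .forcing import CircadianConfig, ForcingContext
    from .metrics import InsufficientOscillationData, estimate_period_amplitude

    settings = settings or SolverSettings()
    no_circadian = ForcingContext(circadian=CircadianConfig.off())
    rows = []
    for s in s_dat_grid:
        p = duo_params.with_s_dat(float(s))
        model = DUOModel(params=p, forcing=no_circadian)
        z0 = duo_initial_state(p).as_array()
        traj = integrate(model.rhs, z0, (0.0, sim_hours), settings=settings,
                         columns=model.names)
        try:
            summ = estimate_period_amplitude(traj, "eda", discard=discard_fraction * sim_hours)
            rows.append({"s_dat": float(s), "period": summ.period,
                         "amplitude": summ.amplitude, "oscillatory": summ.oscillatory})
        except InsufficientOscillationData:
            rows.append({"s_dat": float(s), "period": float("nan"),
                         "amplitude": 0.0, "oscillatory": False})
    return pd.DataFrame(rows)
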