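"""Reduced four-state model of dopamine synthesis, release, and reuptake.

The model tracks levodopa (``ldopa``), cytosolic dopamine (``cda``),
vesicular dopamine (``vda``), and extracellular dopamine (``eda``), all in
micromolar, with time in hours.  Synthesis is catalysed by tyrosine
hydroxylase (TH) under D2-autoreceptor feedback from extracellular
dopamine; cytosolic dopamine is packaged into vesicles (MAT), released at
the firing rate, taken back up by the dopamine transporter (DAT), and
degraded by monoamine-oxidase-mediated catabolism.

Units are fixed globally: concentrations in uM, time in hours, reaction
velocities in uM/hr.  Tyrosine and tetrahydrobiopterin are held at their
steady-state concentrations (126 and 319 uM), which makes the first factor
of the TH velocity a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "ReducedParams",
    "AutoreceptorCalibration",
    "ModelState",
    "ReactionRates",
    "FrozenForcing",
    "autoreceptor_factor_eda",
    "v_th",
    "v_aadc",
    "v_mat",
    "v_dat",
    "v_catab",
    "reaction_rates",
    "rhs_reduced",
    "find_equilibrium",
    "EquilibriumError",
    "NOMINAL_EQUILIBRIUM",
]

# Round-off tolerance: the integrator may momentarily produce components a
# hair below zero; magnitudes up to this are clipped, anything more negative
# is a genuine violation.
NEGATIVE_CLIP = 1e-9


class EquilibriumError(RuntimeError):
    """Equilibrium solve failed or was ambiguous; carries the last iterate."""

    def __init__(self, message: str, last_iterate: Optional[np.ndarray] = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ReducedParams:
    """Kinetic constants of the reduced model.

    K's in uM, Vmax's in uM/hr, first-order k's in 1/hr.  Defaults are the
    published baseline set; tyrosine and tetrahydrobiopterin are fixed at
    their steady-state concentrations.
    """

    K_i_tyr: float = 160.0
    Vmax_tyr: float = 125.0
    K_tyr: float = 46.0
    K_bh4: float = 60.0
    K_i_cda: float = 110.0
    Vmax_ldopa: float = 10_000.0
    K_m_ldopa: float = 130.0
    Vmax_cda: float = 7082.0
    K_m_cda: float = 3.0
    k_out: float = 40.0
    Vmax_eda: float = 8000.0
    K_m_eda: float = 0.2
    Vmax_catab: float = 30.0
    K_m_catab: float = 3.0
    k_cda: float = 10.0
    k_eda: float = 400.0
    tyr_fixed: float = 126.0
    bh4_fixed: float = 319.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"ReducedParams.{name} must be strictly positive, got {value}")

    def scaled(self, **factors: float) -> "ReducedParams":
        """Return a copy with named fields multiplied by the given factors."""
        return replace(self, **{k: getattr(self, k) * v for k, v in factors.items()})


#: Extracellular dopamine concentration (uM) at which the autoreceptor
#: feedback factor equals exactly 1 (the nominal steady state).
EDA_REFERENCE = 0.002024


@dataclass(frozen=True)
class AutoreceptorCalibration:
    """Parameters of the D2-autoreceptor feedback factor on TH.

    The factor is ``a / ((eda/c)^n + d) + b`` with Hill exponent n = 4.
    The published coefficients a = 4.58, b = 0.5, d = 1 leave one free
    constant, the inner Hill scale ``c``; it is calibrated so the factor
    equals exactly 1 at the nominal steady-state concentration
    eda* = 0.002024 uM (c = eda* / (a/(1-b) - 1)^(1/4)), which pins TH
    activity to its nominal value at the nominal equilibrium.  Above/below
    eda* the factor falls/rises — the homeostatic negative feedback.  The
    slope of the feedback at the reference, d ln(factor)/d ln(eda) =
    -n (1-b)(1 - (1-b)/a), follows from this calibration and sets both the
    strength of dopamine homeostasis and the phase lead of the forced
    circadian rhythm.
    """

    a: float = 4.58
    b: float = 0.5
    c: float = field(default=EDA_REFERENCE / (4.58 / (1.0 - 0.5) - 1.0) ** 0.25)
    d: float = 1.0
    hill_exponent: float = 4.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.d <= 0:
            raise ValueError("AutoreceptorCalibration c and d must be positive")

    @classmethod
    def calibrated(cls, a: float = 4.58, b: float = 0.5, d: float = 1.0,
                   eda_ref: float = EDA_REFERENCE, hill_exponent: float = 4.0,
                   ) -> "AutoreceptorCalibration":
        """Construct with ``c`` chosen so the factor is exactly 1 at ``eda_ref``."""
        u = a / (1.0 - b) - d
        if u <= 0:
            raise ValueError("no positive Hill scale yields factor 1 at the reference")
        return cls(a=a, b=b, c=eda_ref / u ** (1.0 / hill_exponent), d=d,
                   hill_exponent=hill_exponent)


@dataclass(frozen=True)
class ModelState:
    """Concentration vector (uM) of the reduced model."""

    ldopa: float
    cda: float
    vda: float
    eda: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < -NEGATIVE_CLIP:
                raise ValueError(f"ModelState.{name} must be non-negative, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ldopa, self.cda, self.vda, self.eda], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        return cls(*y)


#: Printed nominal steady state of the reduced model (ldopa, cda, vda, eda).
NOMINAL_EQUILIBRIUM = ModelState(ldopa=0.36, cda=2.65, vda=80.96, eda=0.002024)


@dataclass(frozen=True)
class ReactionRates:
    """Instantaneous reaction velocities (uM/hr)."""

    v_th: float
    v_aadc: float
    v_mat: float
    v_dat: float
    v_catab: float


@dataclass(frozen=True)
class FrozenForcing:
    """Forcing multipliers frozen at constants (quasi-static analysis).

    ``pin_autoreceptor`` replaces the eda-dependent feedback factor with the
    constant 1 (the "no autoreceptors" condition of the homeostasis runs).
    """

    cth: float = 1.0
    cmao: float = 1.0
    fire: float = 1.0
    s_dat: float = 1.0
    pin_autoreceptor: bool = False

    def __post_init__(self) -> None:
        if self.cth <= 0 or self.cmao <= 0:
            raise ValueError("circadian multipliers must be positive")
        if self.fire < 0:
            raise ValueError("fire multiplier must be non-negative")
        if not 0.0 <= self.s_dat <= 1.0:
            raise ValueError("s_dat must lie in [0, 1]")


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        if value >= -NEGATIVE_CLIP:
            return 0.0
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def autoreceptor_factor_eda(eda: float, calib: AutoreceptorCalibration = AutoreceptorCalibration()) -> float:
    """D2-autoreceptor feedback factor on TH as a function of eda (uM).

    Strictly decreasing in eda; equals 1 at the reference concentration
    ``calib.c``; tends to ``b`` as eda grows and to ``a/d + b`` at eda = 0.
    """
    eda = _check_nonneg("eda", eda)
    return calib.a / ((eda / calib.c) ** calib.hill_exponent + calib.d) + calib.b


def v_th(
    cda: float,
    autoreceptor_factor: float,
    params: ReducedParams = ReducedParams(),
    cth_multiplier: float = 1.0,
) -> float:
    """Tyrosine hydroxylase velocity (uM/hr) with fixed tyr and bh4.

    Product of a constant substrate-inhibition factor 0.56/(1 + tyr/K_i_tyr),
    the autoreceptor feedback factor, and a saturating term weakly inhibited
    by cytosolic dopamine, all scaled by the circadian TH multiplier.
    """
    cda = _check_nonneg("cda", cda)
    if autoreceptor_factor <= 0:
        raise ValueError("autoreceptor_factor must be positive")
    if cth_multiplier <= 0:
        raise ValueError("cth_multiplier must be positive")
    p = params
    const = 0.56 / (1.0 + p.tyr_fixed / p.K_i_tyr)
    num = p.Vmax_tyr * p.tyr_fixed * p.bh4_fixed
    den = (
        p.tyr_fixed * p.bh4_fixed
        + p.K_tyr * p.bh4_fixed
        + p.K_tyr * p.K_bh4 * (1.0 + cda / p.K_i_cda)
    )
    return cth_multiplier * const * autoreceptor_factor * num / den


def v_aadc(ldopa: float, params: ReducedParams = ReducedParams()) -> float:
    """AADC decarboxylation velocity (uM/hr), Michaelis-Menten in ldopa."""
    ldopa = _check_nonneg("ldopa", ldopa)
    return params.Vmax_ldopa * ldopa / (params.K_m_ldopa + ldopa)


def v_mat(cda: float, vda: float, params: ReducedParams = ReducedParams()) -> float:
    """Net vesicular packaging velocity (uM/hr); may be negative (leak-back)."""
    cda = _check_nonneg("cda", cda)
    vda = _check_nonneg("vda", vda)
    return params.Vmax_cda * cda / (params.K_m_cda + cda) - params.k_out * vda


def v_dat(eda: float, s_dat_effective: float = 1.0, params: ReducedParams = ReducedParams()) -> float:
    """DAT reuptake velocity (uM/hr), scaled by the effective DAT fraction."""
    eda = _check_nonneg("eda", eda)
    if not 0.0 <= s_dat_effective <= 1.0:
        raise ValueError(f"s_dat_effective must lie in [0, 1], got {s_dat_effective}")
    return s_dat_effective * params.Vmax_eda * eda / (params.K_m_eda + eda)


def v_catab(eda: float, cmao_multiplier: float = 1.0, params: ReducedParams = ReducedParams()) -> float:
    """MAO-mediated catabolism velocity of extracellular dopamine (uM/hr)."""
    eda = _check_nonneg("eda", eda)
    if cmao_multiplier <= 0:
        raise ValueError("cmao_multiplier must be positive")
    return cmao_multiplier * params.Vmax_catab * eda / (params.K_m_catab + eda)


def reaction_rates(
    state: ModelState,
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    forcing: FrozenForcing = FrozenForcing(),
) -> ReactionRates:
    """All five reaction velocities at a state under frozen forcing."""
    factor = 1.0 if forcing.pin_autoreceptor else autoreceptor_factor_eda(state.eda, calib)
    return ReactionRates(
        v_th=v_th(state.cda, factor, params, forcing.cth),
        v_aadc=v_aadc(state.ldopa, params),
        v_mat=v_mat(state.cda, state.vda, params),
        v_dat=v_dat(state.eda, forcing.s_dat, params),
        v_catab=v_catab(state.eda, forcing.cmao, params),
    )


def rhs_reduced_array(
    t: float,
    y: np.ndarray,
    params: ReducedParams,
    calib: AutoreceptorCalibration,
    cth: float,
    cmao: float,
    fire: float,
    s_dat_effective: float,
    pin_autoreceptor: bool = False,
) -> np.ndarray:
    """Vector field of the reduced model on a raw state array.

    Fast path used by the integrator: forcing values are already evaluated
    at ``t``.  Components slightly below zero (solver round-off) are clipped
    before evaluating the kinetics.
    """
    ldopa, cda, vda, eda = np.clip(y, 0.0, None)
    p = params
    if pin_autoreceptor:
        factor = 1.0
    else:
        factor = calib.a / ((eda / calib.c) ** calib.hill_exponent + calib.d) + calib.b
    const = 0.56 / (1.0 + p.tyr_fixed / p.K_i_tyr)
    vth = (
        cth
        * const
        * factor
        * (p.Vmax_tyr * p.tyr_fixed * p.bh4_fixed)
        / (
            p.tyr_fixed * p.bh4_fixed
            + p.K_tyr * p.bh4_fixed
            + p.K_tyr * p.K_bh4 * (1.0 + cda / p.K_i_cda)
        )
    )
    vaadc = p.Vmax_ldopa * ldopa / (p.K_m_ldopa + ldopa)
    vmat = p.Vmax_cda * cda / (p.K_m_cda + cda) - p.k_out * vda
    vdat = s_dat_effective * p.Vmax_eda * eda / (p.K_m_eda + eda)
    vcatab = cmao * p.Vmax_catab * eda / (p.K_m_catab + eda)
    return np.array(
        [
            vth - vaadc,
            vaadc - vmat + vdat - p.k_cda * cda,
            vmat - fire * vda,
            fire * vda - vdat - vcatab - p.k_eda * eda,
        ]
    )


def rhs_reduced(
    t: float,
    state: ModelState,
    params: ReducedParams = ReducedParams(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    forcing: "object | FrozenForcing" = FrozenForcing(),
) -> np.ndarray:
    """Time derivative of the reduced model state (uM/hr).

    ``forcing`` is either a :class:`FrozenForcing` of constants or any
    object exposing ``cth(t)``, ``cmao(t)``, ``fire(t)`` and
    ``s_dat_effective(t)`` (see :class:`dopasim.forcing.ForcingContext`).
    The DRI effect scales the DAT velocity in both the cda and eda
    equations.
    """
    if isinstance(forcing, FrozenForcing):
        cth, cmao = forcing.cth, forcing.cmao
        fire, s_eff = forcing.fire, forcing.s_dat
        pin = forcing.pin_autoreceptor
    else:
        cth, cmao = forcing.cth(t), forcing.cmao(t)
        fire, s_eff = forcing.fire(t), forcing.s_dat_effective(t)
        pin = getattr(forcing, "pin_autoreceptor", False)
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    return rhs_reduced_array(t, y, params, calib, cth, cmao, fire, s_eff, pin)


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------
#
# At a fixed point the four balance equations telescope into a single scalar
# equation in eda: the eda equation gives vda, the vda equation gives cda,
# the cda equation gives the AADC flux and hence ldopa, and the remaining
# ldopa equation is the residual TH - AADC.  Solving that scalar equation by
# bracketing (and checking for multiple sign changes) is both the uniqueness
# check and a robust seed; the result is then polished by Newton iteration
# on the full 4-dimensional system.


def _chain_from_eda(
    eda: float,
    params: ReducedParams,
    forcing: FrozenForcing,
) -> Optional[np.ndarray]:
    """Candidate state implied by eda via flux balance; None if infeasible."""
    p = params
    vdat = forcing.s_dat * p.Vmax_eda * eda / (p.K_m_eda + eda)
    vcatab = forcing.cmao * p.Vmax_catab * eda / (p.K_m_catab + eda)
    if forcing.fire <= 0:
        return None
    vda = (vdat + vcatab + p.k_eda * eda) / forcing.fire
    # vda balance: Vmax_cda*cda/(K+cda) = (k_out + fire) * vda
    rate = (p.k_out + forcing.fire) * vda
    if rate >= p.Vmax_cda or rate < 0:
        return None
    cda = p.K_m_cda * rate / (p.Vmax_cda - rate)
    # cda balance: vaadc = vmat - vdat + k_cda*cda, and vmat = fire*vda
    vaadc = forcing.fire * vda - vdat + p.k_cda * cda
    if vaadc <= 0 or vaadc >= p.Vmax_ldopa:
        return None
    ldopa = p.K_m_ldopa * vaadc / (p.Vmax_ldopa - vaadc)
    return np.array([ldopa, cda, vda, eda])


def _scalar_residual(
    eda: float,
    params: ReducedParams,
    calib: AutoreceptorCalibration,
    forcing: FrozenForcing,
) -> float:
    state = _chain_from_eda(eda, params, forcing)
    if state is None:
        return np.nan
    factor = 1.0 if forcing.pin_autoreceptor else autoreceptor_factor_eda(eda, calib)
    return v_th(state[1], factor, params, forcing.cth) - v_aadc(state[0], params)


def find_equilibrium(
    params: ReducedParams = ReducedParams(),
    forcing: FrozenForcing = FrozenForcing(),
    calib: AutoreceptorCalibration = AutoreceptorCalibration(),
    eda_bracket: tuple[float, float] = (1e-8, 50.0),
    n_scan: int = 400,
) -> ModelState:
    """Biologically feasible equilibrium of the reduced model.

    Reduces the fixed-point conditions to a scalar equation in eda, brackets
    its root on a log grid over ``eda_bracket`` (raising if more than one
    feasible root is found), then polishes the full 4-dimensional root with
    a Newton-type solver.  Residual is verified to < 1e-10 relative to the
    dominant flux.
    """
    grid = np.geomspace(eda_bracket[0], eda_bracket[1], n_scan)
    res = np.array([_scalar_residual(e, params, calib, forcing) for e in grid])
    finite = np.isfinite(res)
    sign_changes = []
    idx = np.flatnonzero(finite)
    for i, j in zip(idx[:-1], idx[1:]):
        if res[i] == 0.0:
            sign_changes.append((grid[i], grid[i]))
        elif res[i] * res[j] < 0:
            sign_changes.append((grid[i], grid[j]))
    if not sign_changes:
        raise EquilibriumError(
            "no feasible equilibrium found in eda bracket "
            f"[{eda_bracket[0]:g}, {eda_bracket[1]:g}]"
        )
    if len(sign_changes) > 1:
        raise EquilibriumError(
            f"multiple feasible equilibria detected ({len(sign_changes)} brackets); "
            "refine the bracket to select one"
        )
    lo, hi = sign_changes[0]
    if lo == hi:
        eda_root = lo
    else:
        eda_root = optimize.brentq(
            _scalar_residual, lo, hi, args=(params, calib, forcing), xtol=1e-15, rtol=8.9e-16
        )
    seed = _chain_from_eda(eda_root, params, forcing)
    if seed is None:
        raise EquilibriumError("bracketed root became infeasible during refinement")

    def fun(y: np.ndarray) -> np.ndarray:
        return rhs_reduced_array(
            0.0, y, params, calib, forcing.cth, forcing.cmao, forcing.fire,
            forcing.s_dat, forcing.pin_autoreceptor,
        )

    sol = optimize.root(fun, seed, method="hybr", tol=1e-13)
    y = sol.x if sol.success else seed
    scale = max(abs(v_aadc(max(y[0], 0.0), params)), 1.0)
    if np.linalg.norm(fun(y)) / scale > 1e-10:
        raise EquilibriumError(
            f"equilibrium residual too large: {np.linalg.norm(fun(y)):g}", last_iterate=y
        )
    if np.any(y <= 0):
        raise EquilibriumError("equilibrium has non-positive components", last_iterate=y)
    return ModelState.from_array(y)
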