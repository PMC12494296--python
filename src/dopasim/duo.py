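"""Dopamine Ultradian Oscillator (DUO): the reduced model coupled to a pool.

Extracellular dopamine from a population of terminals accumulates in a
shared pool (``edapool``, dimensionless dopaminergic tone) which drives D2
autoreceptor signalling (``D2``, dimensionless).  The eda-based
autoreceptor factor of the reduced model is replaced inside the TH
velocity by a sigmoid of D2,

    A(D2) = alpha + beta / (1 + exp((D2 - gamma*(2 - s_dat)) / m)),

whose midpoint shifts right as DAT activity ``s_dat`` is lowered,
modelling autoreceptor adaptation to elevated tone.  The linear
pool/signalling chain introduces the delay that turns the negative
feedback into an intrinsic ultradian oscillator.  DAT activity is a fixed
constant here (not a decaying dose trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

from .model import (
    AutoreceptorCalibration,
    EquilibriumError,
    ReducedParams,
    _chain_from_eda,
    FrozenForcing,
    v_aadc,
    v_th,
)

__all__ = [
    "DUOParams",
    "DUOState",
    "LHSRanges",
    "FIG6_PRESET",
    "FIG7_PRESET",
    "a_of_d2",
    "rhs_duo",
    "rhs_duo_array",
    "find_equilibrium_duo",
    "duo_initial_state",
    "lhs_sample_duo",
]

#: Names of the eight coupling parameters, in the conventional order.
DUO_PARAM_NAMES = ("k1_pool", "k2_pool", "k3_pool", "k4_pool", "alpha", "beta", "gamma", "m")


@dataclass(frozen=True)
class DUOParams:
    """Coupling parameters of the ultradian oscillator.

    ``k1_pool``..``k4_pool`` (1/hr) govern the linear eda -> edapool -> D2
    chain; ``alpha``/``beta`` are the floor and range of the TH feedback
    sigmoid, ``gamma`` positions its midpoint in D2 units, ``m`` sets its
    steepness.  ``s_dat`` is the fixed DAT activity fraction.
    """

    k1_pool: float
    k2_pool: float
    k3_pool: float
    k4_pool: float
    alpha: float
    beta: float
    gamma: float
    m: float
    s_dat: float = 1.0
    reduced: ReducedParams = field(default_factory=ReducedParams)

    def __post_init__(self) -> None:
        for name in DUO_PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"DUOParams.{name} must be positive")
        if not 0.0 <= self.s_dat <= 1.0:
            raise ValueError("s_dat must lie in [0, 1]")

    def with_s_dat(self, s_dat: float) -> "DUOParams":
        return replace(self, s_dat=s_dat)

    def scaled(self, name: str, factor: float) -> "DUOParams":
        """Copy with one coupling parameter multiplied by ``factor``."""
        if name not in DUO_PARAM_NAMES:
            raise KeyError(f"unknown DUO parameter {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})


#: Parameter preset producing a ~4.6 h limit cycle at full DAT activity.
FIG6_PRESET = DUOParams(
    k1_pool=4519.93, k2_pool=0.38, k3_pool=22.3, k4_pool=2.34,
    alpha=0.5, beta=0.5, gamma=193.93, m=1.1,
)

#: Parameter preset used for the period/amplitude and Hopf analyses.
FIG7_PRESET = DUOParams(
    k1_pool=21118.5, k2_pool=1.89, k3_pool=34.45, k4_pool=0.47,
    alpha=0.5, beta=4.5, gamma=2139.25, m=0.01,
)

PRESETS = {"fig6": FIG6_PRESET, "fig7": FIG7_PRESET}


@dataclass(frozen=True)
class DUOState:
    """Concentrations (uM) plus the two dimensionless latent variables."""

    ldopa: float
    cda: float
    vda: float
    eda: float
    edapool: float
    D2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.ldopa, self.cda, self.vda, self.eda, self.edapool, self.D2])

    @classmethod
    def from_array(cls, z: np.ndarray) -> "DUOState":
        return cls(*np.clip(np.asarray(z, dtype=float), 0.0, None))


def a_of_d2(D2: float, params: DUOParams) -> float:
    """Sigmoidal TH feedback factor A(D2); strictly decreasing in D2.

    Evaluated through the logistic function so arbitrarily large arguments
    saturate to the plateaus alpha and alpha + beta without overflow.
    """
    arg = (D2 - params.gamma * (2.0 - params.s_dat)) / params.m
    return params.alpha + params.beta * expit(-arg)


def rhs_duo_array(
    t: float,
    z: np.ndarray,
    params: DUOParams,
    cth: float,
    cmao: float,
    fire: float,
) -> np.ndarray:
    """Vector field of the 6-state DUO on a raw array (integrator fast path)."""
    ldopa, cda, vda, eda, edapool, D2 = np.clip(z, 0.0, None)
    p = params.reduced
    factor = params.alpha + params.beta * expit(
        -(D2 - params.gamma * (2.0 - params.s_dat)) / params.m
    )
    const = 0.56 / (1.0 + p.tyr_fixed / p.K_i_tyr)
    vth = (
        cth * const * factor
        * (p.Vmax_tyr * p.tyr_fixed * p.bh4_fixed)
        / (p.tyr_fixed * p.bh4_fixed + p.K_tyr * p.bh4_fixed
           + p.K_tyr * p.K_bh4 * (1.0 + cda / p.K_i_cda))
    )
    vaadc = p.Vmax_ldopa * ldopa / (p.K_m_ldopa + ldopa)
    vmat = p.Vmax_cda * cda / (p.K_m_cda + cda) - p.k_out * vda
    vdat = params.s_dat * p.Vmax_eda * eda / (p.K_m_eda + eda)
    vcatab = cmao * p.Vmax_catab * eda / (p.K_m_catab + eda)
    return np.array(
        [
            vth - vaadc,
            vaadc - vmat + vdat - p.k_cda * cda,
            vmat - fire * vda,
            fire * vda - vdat - vcatab - p.k_eda * eda,
            params.k1_pool * eda - params.k2_pool * edapool,
            params.k3_pool * edapool - params.k4_pool * D2,
        ]
    )


def rhs_duo(t: float, state, params: DUOParams, forcing=None) -> np.ndarray:
    """Time derivative of the DUO state.

    ``forcing`` supplies the circadian multipliers and firing rate exactly
    as for the reduced model; ``None`` means all multipliers are 1.  The
    DAT fraction is the constant ``params.s_dat``.
    """
    if forcing is None:
        cth = cmao = fire = 1.0
    elif isinstance(forcing, FrozenForcing):
        cth, cmao, fire = forcing.cth, forcing.cmao, forcing.fire
    else:
        cth, cmao, fire = forcing.cth(t), forcing.cmao(t), forcing.fire(t)
    z = state.as_array() if isinstance(state, DUOState) else np.asarray(state, dtype=float)
    return rhs_duo_array(t, z, params, cth, cmao, fire)


# ---------------------------------------------------------------------------
# DUO equilibria
# ---------------------------------------------------------------------------
#
# At a fixed point the linear chain gives edapool* = (k1/k2) eda* and
# D2* = (k3/k4) edapool*, so the feedback factor is a known function of
# eda*, and the first four balance equations telescope exactly as in the
# reduced model.  The whole 6-dimensional fixed-point problem therefore
# collapses to one scalar equation in eda, which is bracketed and solved,
# then polished on the full system.


def _duo_scalar_residual(eda: float, params: DUOParams, forcing: FrozenForcing) -> float:
    frozen4 = replace(forcing, s_dat=params.s_dat)
    state4 = _chain_from_eda(eda, params.reduced, frozen4)
    if state4 is None:
        return np.nan
    D2 = (params.k3_pool / params.k4_pool) * (params.k1_pool / params.k2_pool) * eda
    factor = a_of_d2(D2, params)
    return v_th(state4[1], factor, params.reduced, forcing.cth) - v_aadc(state4[0], params.reduced)


def find_equilibrium_duo(
    params: DUOParams,
    forcing: FrozenForcing = FrozenForcing(),
    eda_bracket: tuple[float, float] = (1e-9, 50.0),
    n_scan: int = 800,
) -> DUOState:
    """Feasible equilibrium of the DUO at fixed forcing multipliers."""
    grid = np.geomspace(eda_bracket[0], eda_bracket[1], n_scan)
    res = np.array([_duo_scalar_residual(e, params, forcing) for e in grid])
    idx = np.flatnonzero(np.isfinite(res))
    brackets = [
        (grid[i], grid[j])
        for i, j in zip(idx[:-1], idx[1:])
        if res[i] * res[j] < 0
    ]
    if not brackets:
        raise EquilibriumError("no feasible DUO equilibrium in the eda bracket")
    if len(brackets) > 1:
        raise EquilibriumError(f"multiple DUO equilibria detected ({len(brackets)})")
    eda_root = optimize.brentq(
        _duo_scalar_residual, brackets[0][0], brackets[0][1],
        args=(params, forcing), xtol=1e-16, rtol=8.9e-16,
    )
    frozen4 = replace(forcing, s_dat=params.s_dat)
    state4 = _chain_from_eda(eda_root, params.reduced, frozen4)
    edapool = params.k1_pool / params.k2_pool * eda_root
    D2 = params.k3_pool / params.k4_pool * edapool
    seed = np.concatenate([state4, [edapool, D2]])

    def fun(z: np.ndarray) -> np.ndarray:
        return rhs_duo_array(0.0, z, params, forcing.cth, forcing.cmao, forcing.fire)

    # Newton polish in a scaled space: the latent variables are O(1e3-1e4)
    # while eda is O(1e-3), so solve for log-components instead.
    sol = optimize.root(lambda u: fun(np.exp(u)), np.log(seed), method="hybr", tol=1e-14)
    z = np.exp(sol.x) if sol.success else seed
    if np.linalg.norm(fun(z) / np.maximum(np.abs(z), 1e-12)) > 1e-6 and not sol.success:
        raise EquilibriumError("DUO equilibrium polish failed", last_iterate=z)
    return DUOState.from_array(z)


def duo_initial_state(params: DUOParams, calib: AutoreceptorCalibration = AutoreceptorCalibration()) -> DUOState:
    """Default initial condition for DUO simulations.

    The four concentrations start at the drug-free reduced-model
    equilibrium and the two latent variables at their linear-chain balance
    values for that eda, which keeps transients short without presuming
    anything about the DUO's own attractor.
    """
    from .model import find_equilibrium

    eq4 = find_equilibrium(params.reduced, calib=calib).as_array()
    edapool = params.k1_pool / params.k2_pool * eq4[3]
    D2 = params.k3_pool / params.k4_pool * edapool
    return DUOState.from_array(np.concatenate([eq4, [edapool, D2]]))


@dataclass(frozen=True)
class LHSRanges:
    """Sampling ranges for the Latin-hypercube search over DUO parameters.

    ``k1_pool`` and ``gamma`` span orders of magnitude and are sampled
    log-uniformly; the remaining parameters uniformly.
    """

    k1_pool: tuple[float, float] = (400.0, 40_000.0)
    k2_pool: tuple[float, float] = (0.1, 40.0)
    k3_pool: tuple[float, float] = (0.1, 40.0)
    k4_pool: tuple[float, float] = (0.1, 40.0)
    alpha: tuple[float, float] = (0.5, 4.5)
    beta: tuple[float, float] = (0.5, 4.5)
    gamma: tuple[float, float] = (100.0, 10_000.0)
    m: tuple[float, float] = (0.005, 5.0)

    LOG_PARAMS = ("k1_pool", "gamma")


def lhs_sample_duo(
    ranges: LHSRanges = LHSRanges(),
    n: int = 100,
    seed: int = 0,
    s_dat: float = 1.0,
    reduced: Optional[ReducedParams] = None,
) -> list[DUOParams]:
    """Latin-hypercube design of DUO coupling parameters.

    Each of the eight parameters is stratified into ``n`` equal-probability
    bins (on a log scale for ``k1_pool`` and ``gamma``); deterministic for a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(DUO_PARAM_NAMES), seed=seed)
    unit = sampler.random(n)
    out = []
    reduced = reduced if reduced is not None else ReducedParams()
    for row in unit:
        kwargs = {}
        for u, name in zip(row, DUO_PARAM_NAMES):
            lo, hi = getattr(ranges, name)
            if name in LHSRanges.LOG_PARAMS:
                kwargs[name] = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
            else:
                kwargs[name] = float(lo + u * (hi - lo))
        out.append(DUOParams(s_dat=s_dat, reduced=reduced, **kwargs))
    return out
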