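"""Reaction velocities, autoreceptor feedback, and equilibria of the reduced model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dopasim as ds
from dopasim.model import EquilibriumError, rhs_reduced_array


class TestVelocities:
    # closed-form values evaluated by hand from the kinetic constants
    @pytest.mark.parametrize(
        "fn, args, expected, rel",
        [
            (ds.v_aadc, (0.36,), 27.615833077631173, 1e-12),
            (ds.v_aadc, (0.0,), 0.0, 0),
            (ds.v_aadc, (130.0,), 5000.0, 1e-12),  # half-saturation
            (ds.v_mat, (2.65, 80.96), 83.24601769911487, 1e-12),
            (ds.v_mat, (0.0, 0.0), 0.0, 0),
            (ds.v_mat, (0.0, 1.0), -40.0, 1e-12),  # pure leak-back
            (ds.v_dat, (0.002024, 1.0), 80.14889320080782, 1e-12),
            (ds.v_dat, (0.002024, 0.0), 0.0, 0),  # full blockade
            (ds.v_dat, (0.0, 1.0), 0.0, 0),
            (ds.v_catab, (0.002024, 1.0), 0.020226353953199574, 1e-12),
            (ds.v_catab, (0.0, 1.0), 0.0, 0),
        ],
    )
    def test_closed_forms(self, fn, args, expected, rel):
        assert fn(*args) == pytest.approx(expected, rel=rel, abs=1e-15)

    def test_v_th_value_and_balance(self):
        # hand evaluation: 0.3132867 * 87.08370 with unit feedback factor
        assert ds.v_th(2.65, 1.0) == pytest.approx(27.282167576640315, rel=1e-12)
        # at equilibrium the TH and AADC fluxes balance within 2%
        assert ds.v_th(2.65, 1.0) == pytest.approx(ds.v_aadc(0.36), rel=0.02)

    def test_v_th_limits_and_scaling(self):
        assert ds.v_th(1e9, 1.0) < 1e-3  # cda inhibition kills synthesis
        base = ds.v_th(2.65, 1.0)
        assert ds.v_th(2.65, 1.0, cth_multiplier=1.25) == pytest.approx(1.25 * base, rel=1e-12)

    def test_v_catab_multiplier_linear(self):
        assert ds.v_catab(0.5, 0.75) == pytest.approx(0.75 * ds.v_catab(0.5, 1.0), rel=1e-12)

    @pytest.mark.parametrize("fn,args", [
        (ds.v_aadc, (-1.0,)),
        (ds.v_mat, (-1.0, 0.0)),
        (ds.v_catab, (-0.5, 1.0)),
        (ds.autoreceptor_factor_eda, (-1e-3,)),
    ])
    def test_negative_concentrations_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_s_dat_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ds.v_dat(0.1, 1.5)


class TestAutoreceptorFactor:
    def test_unity_at_reference(self, calib):
        assert ds.autoreceptor_factor_eda(0.002024, calib) == pytest.approx(1.0, abs=1e-9)

    def test_limits(self, calib):
        assert ds.autoreceptor_factor_eda(1e6, calib) == pytest.approx(calib.b, rel=1e-6)
        assert ds.autoreceptor_factor_eda(0.0, calib) == pytest.approx(
            calib.a / calib.d + calib.b, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=1.001, max_value=1e3))
    def test_strictly_decreasing(self, lo_scale, hi_scale):
        calib = ds.AutoreceptorCalibration()
        lo, hi = lo_scale * calib.c, hi_scale * calib.c
        assert ds.autoreceptor_factor_eda(lo, calib) > ds.autoreceptor_factor_eda(hi, calib)

    def test_calibrated_constructor_matches_default(self):
        assert ds.AutoreceptorCalibration.calibrated().c == pytest.approx(
            ds.AutoreceptorCalibration().c, rel=1e-14)


class TestRHS:
    def test_vanishes_at_equilibrium(self, nominal_equilibrium):
        dy = ds.rhs_reduced(0.0, nominal_equilibrium)
        assert np.all(np.abs(dy) < 0.5)  # < 1% of the dominant flux
        assert np.linalg.norm(dy) < 1e-9  # root-finder residual contract

    def test_firing_doubling_raises_eda_derivative(self, nominal_equilibrium):
        dy = ds.rhs_reduced(0.0, nominal_equilibrium, forcing=ds.FrozenForcing(fire=2.0))
        assert dy[3] > 0  # release doubles instantly, reuptake unchanged

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.01, 5.0), st.floats(0.01, 10.0),
           st.floats(1.0, 150.0), st.floats(1e-4, 0.05))
    def test_mass_balance_identity(self, ldopa, cda, vda, eda):
        """Internal transport cancels: (cda+vda+eda)' = VAADC - k_cda*cda - VCATAB - k_eda*eda."""
        p, c = ds.ReducedParams(), ds.AutoreceptorCalibration()
        y = np.array([ldopa, cda, vda, eda])
        dy = rhs_reduced_array(0.0, y, p, c, 1.0, 1.0, 1.0, 1.0)
        lhs = dy[1] + dy[2] + dy[3]
        rhs = ds.v_aadc(ldopa, p) - p.k_cda * cda - ds.v_catab(eda, 1.0, p) - p.k_eda * eda
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestEquilibrium:
    def test_nominal_values(self, nominal_equilibrium):
        eq = nominal_equilibrium
        assert eq.ldopa == pytest.approx(0.36, abs=0.005)
        assert eq.cda == pytest.approx(2.65, abs=0.005)
        assert eq.vda == pytest.approx(80.96, abs=0.01)
        assert eq.eda == pytest.approx(0.002024, rel=5e-4)

    def test_eda_increases_under_reuptake_inhibition(self, params, calib):
        full = ds.find_equilibrium(params, ds.FrozenForcing(s_dat=1.0), calib)
        half = ds.find_equilibrium(params, ds.FrozenForcing(s_dat=0.5), calib)
        assert half.eda > full.eda

    def test_aadc_flux_invariant_to_vmax_ldopa(self, params, calib, nominal_equilibrium):
        """Doubling Vmax_ldopa halves ldopa* but leaves the AADC flux (and the
        rest of the equilibrium) nearly unchanged."""
        doubled = params.scaled(Vmax_ldopa=2.0)
        eq2 = ds.find_equilibrium(doubled, ds.FrozenForcing(), calib)
        flux1 = ds.v_aadc(nominal_equilibrium.ldopa, params)
        flux2 = ds.v_aadc(eq2.ldopa, doubled)
        assert flux2 == pytest.approx(flux1, rel=1e-3)
        assert eq2.ldopa == pytest.approx(nominal_equilibrium.ldopa / 2, rel=0.01)
        assert eq2.eda == pytest.approx(nominal_equilibrium.eda, rel=1e-3)

    def test_homeostasis_to_firing(self, params, calib, nominal_equilibrium):
        """2x firing doubles eda without autoreceptors; feedback damps it."""
        pinned = ds.find_equilibrium(params, ds.FrozenForcing(fire=2.0, pin_autoreceptor=True), calib)
        active = ds.find_equilibrium(params, ds.FrozenForcing(fire=2.0), calib)
        ratio_pinned = pinned.eda / nominal_equilibrium.eda
        ratio_active = active.eda / nominal_equilibrium.eda
        assert ratio_pinned == pytest.approx(2.0, rel=0.05)
        assert ratio_active < 0.8 * ratio_pinned

    def test_infeasible_bracket_raises(self, params, calib):
        with pytest.raises(EquilibriumError):
            ds.find_equilibrium(params, ds.FrozenForcing(), calib,
                                eda_bracket=(10.0, 50.0), n_scan=50)
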