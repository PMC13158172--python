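"""OER curve, depletion efficiency, fixation calibration and LQ mapping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flashlpl import (
    FixationCalibration,
    LPLParameters,
    PrecursorParameters,
    depletion_efficiency,
    effective_yields,
    fixation_rates,
    lq_coefficients,
    oer,
)


@pytest.fixture(scope="module")
def calib(ref):
    return FixationCalibration.from_parameters(ref.lpl, ref.precursor)


class TestOERCurve:
    def test_floor_plateau_and_characteristic_scale(self, ref):
        p = ref.oer
        assert oer(0.0, p) == pytest.approx(p.oer_min)
        assert oer(1e6, p) == pytest.approx(p.oer_max)
        expected = p.oer_min + (1 - np.exp(-1)) * (p.oer_max - p.oer_min)
        assert oer(1.0 / p.omega, p) == pytest.approx(expected, rel=1e-12)

    @given(
        a=st.floats(min_value=0, max_value=30),
        b=st.floats(min_value=1e-3, max_value=10),
    )
    def test_monotone_and_bounded(self, ref, a, b):
        # domain kept where the exponential tail is resolvable in doubles
        p = ref.oer
        lo, hi = sorted((a, a + b))
        assert p.oer_min <= oer(lo, p) < oer(hi, p) < p.oer_max

    def test_negative_tension_rejected(self, ref):
        with pytest.raises(ValueError):
            oer(-0.1, ref.oer)

    def test_response_to_fixed_depletion_is_bell_shaped(self, ref):
        # sparing leverage: the OER drop from a fixed depletion Delta peaks
        # at intermediate baselines (depleted tension floors at anoxia)
        delta = 2.0
        grid = np.geomspace(0.05, 60, 200)
        drop = np.array(
            [oer(p, ref.oer) - oer(max(p - delta, 0.0), ref.oer) for p in grid]
        )
        peak = grid[np.argmax(drop)]
        assert grid[0] < peak < grid[-1]
        assert drop[np.argmax(drop)] > drop[0] and drop[np.argmax(drop)] > drop[-1]


class TestDepletionEfficiency:
    def test_anchor_points(self):
        assert depletion_efficiency(0.0, 0.21) == 0.0
        assert depletion_efficiency(0.21, 0.21) == pytest.approx(0.5)
        assert depletion_efficiency(3.0, 0.21) == pytest.approx(3 / 3.21, rel=1e-12)

    @given(st.floats(min_value=0, max_value=1e4), st.floats(min_value=1e-6, max_value=10))
    def test_bounded_below_one_and_monotone(self, p, Kg):
        phi = depletion_efficiency(p, Kg)
        assert 0 <= phi < 1
        assert depletion_efficiency(p + 1.0, Kg) > phi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            depletion_efficiency(-1.0, 0.21)
        with pytest.raises(ValueError):
            depletion_efficiency(1.0, 0.0)


class TestFixationCalibration:
    def test_anchor_to_classical_yields(self, ref, calib):
        scale = ref.precursor.eps_pre / ref.precursor.eta_pre
        assert calib.kappa_PL_sat == pytest.approx(ref.lpl.eta_PL * scale, rel=1e-12)
        assert calib.kappa_L_sat == pytest.approx(ref.lpl.eta_L * scale, rel=1e-12)

    def test_restitution_must_dominate_fixation(self, ref):
        # a tiny precursor yield would make fixation compete with restitution
        weak = PrecursorParameters(eta_pre=50.0, eps_pre=50.0)
        with pytest.raises(ValueError, match="restitution"):
            FixationCalibration.from_parameters(ref.lpl, weak)

    def test_plateau_and_floor_rates(self, ref, calib):
        kPL_inf, kL_inf = fixation_rates(1e6, calib, ref.oer)
        assert kPL_inf == pytest.approx(calib.kappa_PL_sat, rel=1e-9)
        assert kL_inf == pytest.approx(calib.kappa_L_sat, rel=1e-9)
        kPL_0, kL_0 = fixation_rates(0.0, calib, ref.oer)
        floor = ref.oer.oer_min / ref.oer.oer_max
        assert kPL_0 == pytest.approx(calib.kappa_PL_sat * floor, rel=1e-12)
        assert kL_0 == pytest.approx(calib.kappa_L_sat * floor, rel=1e-12)

    @pytest.mark.parametrize("pO2", [0.0, 0.2, 3.0, 30.0, 76.0])
    def test_yield_identity_at_any_tension(self, pO2, ref, calib):
        # eta_pre/eps_pre * kappa_PL(pO2) == eta_PL_Curtis * OER(pO2)/oer_max
        kPL, _ = fixation_rates(pO2, calib, ref.oer)
        lhs = ref.precursor.eta_pre / ref.precursor.eps_pre * kPL
        rhs = ref.lpl.eta_PL * oer(pO2, ref.oer) / ref.oer.oer_max
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestEffectiveYields:
    def test_plateau_equivalence_to_machine_precision(self, ref, calib):
        pO2 = 20.0 / ref.oer.omega  # omega * pO2 = 20, deep on the plateau
        eta_PL_eff, eta_L_eff = effective_yields(pO2, ref.precursor, calib, ref.oer)
        assert eta_PL_eff == pytest.approx(ref.lpl.eta_PL, rel=1e-8)
        assert eta_L_eff == pytest.approx(ref.lpl.eta_L, rel=1e-8)

    def test_anoxic_yields_scaled_by_oer_floor(self, ref, calib):
        eta_PL_eff, eta_L_eff = effective_yields(0.0, ref.precursor, calib, ref.oer)
        floor = ref.oer.oer_min / ref.oer.oer_max
        assert eta_PL_eff == pytest.approx(ref.lpl.eta_PL * floor, rel=1e-12)
        assert eta_L_eff == pytest.approx(ref.lpl.eta_L * floor, rel=1e-12)

    @pytest.mark.parametrize("pO2", [0.1, 1.0, 3.0, 10.0])
    def test_channel_ratio_is_oxygen_independent(self, pO2, ref, calib):
        eta_PL_eff, eta_L_eff = effective_yields(pO2, ref.precursor, calib, ref.oer)
        assert eta_PL_eff / eta_L_eff == pytest.approx(
            ref.lpl.eta_PL / ref.lpl.eta_L, rel=1e-12
        )


class TestLQMapping:
    def test_alpha_scales_with_oer(self, ref, calib):
        args = (ref.lpl, ref.precursor, calib, ref.oer)
        a1, _ = lq_coefficients(1.0, *args)
        a2, _ = lq_coefficients(8.0, *args)
        assert a1 / a2 == pytest.approx(oer(1.0, ref.oer) / oer(8.0, ref.oer), rel=1e-12)

    def test_beta_scales_with_oer_squared(self, ref, calib):
        args = (ref.lpl, ref.precursor, calib, ref.oer)
        _, b1 = lq_coefficients(1.0, *args)
        _, b2 = lq_coefficients(8.0, *args)
        assert b1 / b2 == pytest.approx(
            (oer(1.0, ref.oer) / oer(8.0, ref.oer)) ** 2, rel=1e-12
        )

    def test_reference_lq_values_are_plausible_for_photons(self, ref, calib):
        # sanity: plateau alpha/beta for the reference cell line
        alpha, beta = lq_coefficients(100.0, ref.lpl, ref.precursor, calib, ref.oer)
        assert 0.05 < alpha < 0.5
        assert 0.005 < beta < 0.1
        assert 2.0 < alpha / beta < 20.0
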