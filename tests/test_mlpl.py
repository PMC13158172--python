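"""Coupled precursor–oxygen solver: limits, conservation, consistency."""

import dataclasses

import numpy as np
import pytest

from flashlpl import (
    DoseRateHistory,
    FixationCalibration,
    constant_pulse,
    mlpl_rhs,
    precursor_mass_balance,
    pulse_train,
    qssa_precursor,
    simulate_classical,
    simulate_mlpl,
)
from flashlpl.parameters import SimulationSettings

from conftest import rk4


class TestRHS:
    def test_quiet_state_at_baseline_is_stationary(self, ref):
        h = DoseRateHistory(())
        rates = mlpl_rhs(0.0, (0.0, 0.0, 0.0, ref.oxygen.pO2_0), ref, h)
        assert rates == (0.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("pO2", [0.2, 3.0, 30.0])
    def test_fixation_channel_split_is_kappa_ratio(self, pO2, ref):
        # with repair/misrepair quiet, d(n_PL)/d(n_L) source flow = kPL/kL
        h = DoseRateHistory(())
        _, d_nPL, d_nL, _ = mlpl_rhs(0.0, (5.0, 0.0, 0.0, pO2), ref, h)
        assert d_nPL / d_nL == pytest.approx(ref.lpl.eta_PL / ref.lpl.eta_L, rel=1e-12)


class TestSimulation:
    def test_zero_dose_unit_survival_constant_oxygen(self, ref):
        res = simulate_mlpl(DoseRateHistory(()), ref)
        assert res.SF == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.pO2, ref.oxygen.pO2_0, atol=1e-9)

    def test_backward_compatible_with_classical_on_plateau(self, ref):
        # no depletion, baseline deep on the OER plateau: the coupled model
        # must reproduce the classical run with the plateau (Curtis) yields
        plateau = ref.replace(
            oxygen=dataclasses.replace(ref.oxygen, pO2_0=100.0, G=0.0)
        )
        h = constant_pulse(10.0, 0.05)
        full = simulate_mlpl(h, plateau)
        classical = simulate_classical(h, plateau)
        assert full.ln_SF == pytest.approx(classical.ln_SF, rel=5e-3)

    def test_flash_spares_at_intermediate_oxygen(self, ref):
        flash = simulate_mlpl(constant_pulse(10.0, 40.0), ref)
        conv = simulate_mlpl(constant_pulse(10.0, 0.05), ref)
        assert flash.SF > conv.SF

    def test_states_nonnegative_and_lethal_burden_monotone(self, ref):
        res = simulate_mlpl(constant_pulse(10.0, 40.0), ref)
        for arr in (res.n_pre, res.n_PL, res.n_L, res.pO2):
            assert arr.min() >= -1e-8
        assert np.all(np.diff(res.n_L) >= -1e-9)

    def test_dense_output_resolves_the_pulse(self, ref):
        h = constant_pulse(10.0, 40.0)
        res = simulate_mlpl(h, ref)
        assert np.sum((res.t > 0) & (res.t <= h.tau_pulse)) >= 100

    def test_tolerance_tightening_stability(self, ref):
        h = constant_pulse(10.0, 40.0)
        a = simulate_mlpl(h, ref)
        b = simulate_mlpl(h, ref, SimulationSettings(rel_tol=1e-7, abs_tol=1e-9))
        assert abs(a.ln_SF - b.ln_SF) / abs(b.ln_SF) < 1e-3

    def test_interpulse_recovery_with_long_gap(self, ref):
        # gap of 20 recovery times: oxygen back at baseline for pulse 2
        h = pulse_train(2, 5.0, 40.0, gap=1.0)
        res = simulate_mlpl(h, ref)
        before_second = (res.t < h.segments[1].t_start) & (res.t > h.segments[0].t_end)
        assert res.pO2[before_second][-1] == pytest.approx(ref.oxygen.pO2_0, rel=1e-6)

    def test_short_gap_train_spares_less_than_matched_long_gap_train(self, ref):
        # with gaps long against tau_reox the oxygen pool refills between
        # pulses, restoring fixation: less sparing than back-to-back delivery
        fast = simulate_mlpl(pulse_train(4, 2.5, 40.0, gap=0.005), ref)
        slow = simulate_mlpl(pulse_train(4, 2.5, 40.0, gap=2.0), ref)
        assert fast.SF > slow.SF


class TestQSSA:
    def test_precursor_quasi_steady_value(self, ref):
        assert qssa_precursor(0.0, ref.precursor) == 0.0
        assert qssa_precursor(0.05, ref.precursor) == pytest.approx(2.0, rel=1e-12)

    def test_full_system_settles_to_qssa_during_slow_delivery(self, ref):
        h = constant_pulse(10.0, 0.05)
        res = simulate_mlpl(h, ref, SimulationSettings(t_post=0.0))
        settle = 5.0 / ref.precursor.eps_pre  # ~5 precursor lifetimes
        window = (res.t > settle) & (res.t < h.tau_pulse)
        target = qssa_precursor(0.05, ref.precursor)
        # fixation removes a little on top of restitution: within 1 percent
        assert np.all(np.abs(res.n_pre[window] - target) / target < 1e-2)


class TestMassBalance:
    def test_reference_runs_conserve_precursors(self, ref):
        for rate in (0.05, 40.0):
            res = simulate_mlpl(constant_pulse(10.0, rate), ref)
            assert precursor_mass_balance(res) < 1e-4

    def test_zero_dose_residual_is_zero(self, ref):
        res = simulate_mlpl(DoseRateHistory(()), ref)
        assert precursor_mass_balance(res) == 0.0

    def test_residual_shrinks_with_tighter_tolerances(self, ref):
        h = constant_pulse(10.0, 40.0)
        loose = simulate_mlpl(h, ref, SimulationSettings(rel_tol=1e-4, abs_tol=1e-6))
        tight = simulate_mlpl(h, ref, SimulationSettings(rel_tol=1e-6, abs_tol=1e-8))
        assert precursor_mass_balance(tight) < precursor_mass_balance(loose)


def test_matches_fixed_step_oracle_over_acute_pulse(ref):
    """In-pulse coupled trajectory against naive explicit integration."""
    h = constant_pulse(10.0, 40.0)
    res = simulate_mlpl(h, ref, SimulationSettings(t_post=0.0))
    calib = FixationCalibration.from_parameters(ref.lpl, ref.precursor)
    lpl, pre, ox, oerp = ref.lpl, ref.precursor, ref.oxygen, ref.oer

    def f(t, y):
        n_pre, n_PL, n_L, pO2 = y
        frac = (
            oerp.oer_min + (oerp.oer_max - oerp.oer_min) * (1 - np.exp(-oerp.omega * pO2))
        ) / oerp.oer_max
        kPL, kL = calib.kappa_PL_sat * frac, calib.kappa_L_sat * frac
        mis = lpl.eps_2PL * n_PL**2
        phi = pO2 / (pO2 + ox.Kg)
        return np.array(
            [
                pre.eta_pre * 40.0 - pre.eps_pre * n_pre - (kPL + kL) * n_pre,
                kPL * n_pre - lpl.eps_PL * n_PL - mis,
                kL * n_pre + mis,
                ox.k_reox * (ox.pO2_0 - pO2) - ox.G * phi * 40.0,
            ]
        )

    oracle = rk4(f, [0.0, 0.0, 0.0, ox.pO2_0], 0.0, h.tau_pulse, 1e-5)
    assert res.n_pre[-1] == pytest.approx(oracle[0], rel=1e-5)
    assert res.n_PL[-1] == pytest.approx(oracle[1], rel=1e-5)
    assert res.n_L[-1] == pytest.approx(oracle[2], rel=1e-5)
    assert res.pO2[-1] == pytest.approx(oracle[3], rel=1e-5)
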