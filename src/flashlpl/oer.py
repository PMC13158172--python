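"""Oxygen-enhancement ratio, depletion efficiency and fixation calibration.

The oxygen-fixation hypothesis enters the kinetic model through two
functions of the instantaneous nuclear oxygen tension: the exponential OER
curve, which scales both fixation channels, and the Michaelis–Menten
depletion efficiency, which throttles radiolytic oxygen consumption as the
target runs out of oxygen.  The calibration anchors the saturated fixation
rates so that on the OER plateau the model reproduces the classical Curtis
yields exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import LPLParameters, OERParameters, PrecursorParameters

__all__ = [
    "oer",
    "depletion_efficiency",
    "FixationCalibration",
    "fixation_rates",
    "effective_yields",
    "lq_coefficients",
]

#: Minimum restitution-to-fixation dominance required for the precursor
#: pool to be meaningfully short-lived (quasi-steady at conventional rates).
_MIN_RESTITUTION_DOMINANCE = 100.0


def _check_nonnegative_pO2(pO2) -> np.ndarray:
    arr = np.asarray(pO2, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"pO2 must be non-negative, got {pO2!r}")
    return arr


def oer(pO2, oer_params: OERParameters):
    """Exponential oxygen-enhancement ratio at oxygen tension ``pO2`` (mmHg).

    OER(pO2) = oer_min + (oer_max − oer_min)·(1 − exp(−ω·pO2)).  Strictly
    increasing, equal to the floor at anoxia and approaching the plateau as
    ω·pO2 ≫ 1.  Accepts scalars or arrays.
    """
    p = _check_nonnegative_pO2(pO2)
    span = oer_params.oer_max - oer_params.oer_min
    out = oer_params.oer_min + span * (-np.expm1(-oer_params.omega * p))
    return out if out.ndim else float(out)


def depletion_efficiency(pO2, Kg: float):
    """Michaelis–Menten depletion efficiency φ(pO2) = pO2/(pO2 + Kg) ∈ [0, 1).

    Vanishes at anoxia (no oxygen left to consume) and saturates toward 1
    when pO2 ≫ Kg.
    """
    if Kg <= 0:
        raise ValueError(f"Kg must be positive, got {Kg!r}")
    p = _check_nonnegative_pO2(pO2)
    out = p / (p + Kg)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FixationCalibration:
    """Saturated (plateau) fixation rates κ_PL_sat and κ_L_sat in s⁻¹.

    Chosen so that the quasi-steady effective yields equal the classical
    Curtis yields on the OER plateau: κ_X_sat = η_X · ε_pre / η_pre.
    """

    kappa_PL_sat: float
    kappa_L_sat: float

    def __post_init__(self) -> None:
        if not (self.kappa_PL_sat > 0 and self.kappa_L_sat > 0):
            raise ValueError("saturated fixation rates must be positive")

    @classmethod
    def from_parameters(
        cls, lpl: LPLParameters, precursor: PrecursorParameters
    ) -> "FixationCalibration":
        """Calibrate against the classical yields (the equivalence anchor).

        Raises if chemical restitution does not dominate fixation by at
        least a factor of 100 — the regime in which the precursor pool is a
        fast intermediate and the quasi-steady reduction is meaningful.
        """
        scale = precursor.eps_pre / precursor.eta_pre
        calib = cls(kappa_PL_sat=lpl.eta_PL * scale, kappa_L_sat=lpl.eta_L * scale)
        dominance = precursor.eps_pre / (calib.kappa_PL_sat + calib.kappa_L_sat)
        if dominance < _MIN_RESTITUTION_DOMINANCE:
            raise ValueError(
                "chemical restitution must dominate saturated fixation: "
                f"eps_pre/(kappa_PL_sat + kappa_L_sat) = {dominance:.3g} < "
                f"{_MIN_RESTITUTION_DOMINANCE:g}"
            )
        return calib


def fixation_rates(pO2, calib: FixationCalibration, oer_params: OERParameters):
    """Oxygen-dependent fixation rates (κ_PL, κ_L) in s⁻¹ at tension ``pO2``.

    Both channels share the same oxygen scaling,
    κ_X(pO2) = κ_X_sat · OER(pO2)/oer_max, so the channel split κ_PL/κ_L is
    oxygen-independent and the plateau values are the saturated rates.
    """
    frac = oer(pO2, oer_params) / oer_params.oer_max
    return calib.kappa_PL_sat * frac, calib.kappa_L_sat * frac


def effective_yields(
    pO2,
    precursor: PrecursorParameters,
    calib: FixationCalibration,
    oer_params: OERParameters,
):
    """Quasi-steady effective lesion yields (η_PL_eff, η_L_eff) in Gy⁻¹.

    η_X_eff(pO2) = (η_pre/ε_pre)·κ_X(pO2): the yields the classical model
    inherits when the precursor pool is slaved to the instantaneous dose
    rate.  On the OER plateau they reduce to the Curtis yields.
    """
    kappa_PL, kappa_L = fixation_rates(pO2, calib, oer_params)
    scale = precursor.eta_pre / precursor.eps_pre
    return scale * kappa_PL, scale * kappa_L


def lq_coefficients(
    pO2,
    lpl: LPLParameters,
    precursor: PrecursorParameters,
    calib: FixationCalibration,
    oer_params: OERParameters,
):
    """Linear-quadratic coefficients (α in Gy⁻¹, β in Gy⁻²) at tension ``pO2``.

    α(pO2) = η_L_eff(pO2) and β(pO2) = η_PL_eff(pO2)²/(2ε) with
    ε = ε_PL/ε_2PL, so α scales with OER and β with OER².
    """
    eta_PL_eff, eta_L_eff = effective_yields(pO2, precursor, calib, oer_params)
    alpha = eta_L_eff
    beta = eta_PL_eff**2 / (2.0 * lpl.eps)
    return alpha, beta
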