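"""Curtis's classical lethal / potentially-lethal (LPL) kinetic model.

dn_PL/dt = η_PL·Ḋ(t) − ε_PL·n_PL − ε_2PL·n_PL²
dn_L/dt  = η_L·Ḋ(t) + ε_2PL·n_PL²

Potentially-lethal lesions either repair correctly (first order) or
misrepair pairwise into lethal lesions (second order); survival is the
Poisson null probability SF = exp(−n_L) evaluated after a post-irradiation
relaxation window.  This module doubles as the backward-compatibility
oracle for the precursor-resolved model: with ``pO2_fixed`` given, the
Curtis yields are replaced by the oxygen-dependent effective yields at that
fixed tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._integrate import PiecewiseSolution, integrate_piecewise
from .oer import FixationCalibration, effective_yields
from .parameters import LPLParameters, ModelParameters, SimulationSettings
from .protocols import DoseRateHistory

__all__ = ["lpl_rhs", "ClassicalResult", "simulate_classical", "very_low_dose_rate"]


def lpl_rhs(
    t: float,
    state: tuple[float, float],
    params: LPLParameters,
    history: DoseRateHistory,
) -> tuple[float, float]:
    """Instantaneous (dn_PL/dt, dn_L/dt) for inspection and testing."""
    from .protocols import rate_at

    n_PL, n_L = state
    rate = rate_at(history, t)
    misrepair = params.eps_2PL * n_PL**2
    return (
        params.eta_PL * rate - params.eps_PL * n_PL - misrepair,
        params.eta_L * rate + misrepair,
    )


@dataclass
class ClassicalResult:
    """Classical-LPL trajectory and terminal survival."""

    t: np.ndarray
    n_PL: np.ndarray
    n_L: np.ndarray
    misrepair_integral: float  # ∫ ε_2PL n_PL² dt — lethality from misrepair
    eta_PL: float
    eta_L: float
    total_dose: float
    solution: PiecewiseSolution

    @property
    def n_L_final(self) -> float:
        return float(self.n_L[-1])

    @property
    def ln_SF(self) -> float:
        return -self.n_L_final

    @property
    def SF(self) -> float:
        return float(np.exp(self.ln_SF))

    @property
    def misrepair_fraction(self) -> float:
        """Share of the final lethal burden produced by binary misrepair."""
        return self.misrepair_integral / self.n_L_final if self.n_L_final else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "n_PL": self.n_PL, "n_L": self.n_L})


def simulate_classical(
    history: DoseRateHistory,
    params: ModelParameters,
    settings: SimulationSettings | None = None,
    pO2_fixed: float | None = None,
) -> ClassicalResult:
    """Integrate the classical LPL system over delivery plus relaxation.

    With ``pO2_fixed`` set, the Curtis yields are replaced by the effective
    yields η_X_eff(pO2_fixed) — the quasi-steady reduction of the
    precursor-resolved model at a frozen oxygen tension.
    """
    settings = settings or params.settings
    lpl = params.lpl
    if pO2_fixed is None:
        eta_PL, eta_L = lpl.eta_PL, lpl.eta_L
    else:
        calib = FixationCalibration.from_parameters(lpl, params.precursor)
        eta_PL, eta_L = effective_yields(pO2_fixed, params.precursor, calib, params.oer)

    def rhs(t, y, rate):
        n_PL = y[0]
        misrepair = lpl.eps_2PL * n_PL * n_PL
        return np.array(
            [
                eta_PL * rate - lpl.eps_PL * n_PL - misrepair,
                eta_L * rate + misrepair,
                misrepair,  # bookkeeping: cumulative misrepair lethality
            ]
        )

    t_end = history.tau_pulse + settings.t_post
    if t_end <= 0:
        t_end = 1.0
    sol = integrate_piecewise(rhs, history, np.zeros(3), t_end, settings)
    return ClassicalResult(
        t=sol.t,
        n_PL=sol.y[0],
        n_L=sol.y[1],
        misrepair_integral=float(sol.y[2, -1]),
        eta_PL=eta_PL,
        eta_L=eta_L,
        total_dose=history.total_dose,
        solution=sol,
    )


def very_low_dose_rate(lpl: LPLParameters, misrepair_budget: float = 1e-3) -> float:
    """Dose rate low enough that binary misrepair is negligible.

    During slow delivery the PL pool sits at quasi-equilibrium
    n_PL* ≈ η_PL·Ḋ/ε_PL, so misrepair contributes
    ε_2PL·η_PL²·Ḋ·D/ε_PL² lethal lesions against the direct η_L·D — a share
    of ε_2PL·η_PL²·Ḋ/(ε_PL²·η_L), independent of dose.  Returns the rate at
    which that share equals ``misrepair_budget`` (default 0.1%); callers
    should verify via :attr:`ClassicalResult.misrepair_fraction`.
    """
    return misrepair_budget * lpl.eps_PL**2 * lpl.eta_L / (lpl.eps_2PL * lpl.eta_PL**2)
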