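"""Nuclear-oxygen dynamics under radiolytic depletion and recovery.

dpO2/dt = k_reox·(pO2_0 − pO2) − G·φ(pO2)·Ḋ(t)

Depletion competes with lumped recovery toward baseline; the
Michaelis–Menten efficiency φ shuts depletion off as oxygen runs out, which
keeps the tension non-negative without clamping.  In the ultra-fast limit
(delivery ≪ 1/k_reox) recovery is negligible and the tension obeys the
separable dose-parameterized equation dpO2/dD = −G·φ(pO2), solved here in
closed implicit form as a cross-check and for quick estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._integrate import PiecewiseSolution, SolverError, integrate_piecewise
from .parameters import OxygenParameters, SimulationSettings
from .protocols import DoseRateHistory

__all__ = [
    "oxygen_rhs",
    "OxygenTrajectory",
    "solve_oxygen",
    "flash_limit_depletion",
    "SolverError",
]


def oxygen_rhs(
    t: float, pO2: float, history: DoseRateHistory, ox: OxygenParameters
) -> float:
    """Instantaneous dpO2/dt (mmHg/s) at time ``t``.

    Looks up the piecewise-constant dose rate at ``t``; intended for
    inspection and testing — the solvers bind the segment rate directly.
    """
    from .protocols import rate_at

    return _rhs_value(pO2, rate_at(history, t), ox)


def _rhs_value(pO2: float, rate: float, ox: OxygenParameters) -> float:
    phi = pO2 / (pO2 + ox.Kg)
    return ox.k_reox * (ox.pO2_0 - pO2) - ox.G * phi * rate


@dataclass
class OxygenTrajectory:
    """pO2(t) on the output grid, with solver statistics."""

    t: np.ndarray
    pO2: np.ndarray
    solution: PiecewiseSolution

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "pO2_mmHg": self.pO2})


def solve_oxygen(
    history: DoseRateHistory,
    ox: OxygenParameters,
    settings: SimulationSettings | None = None,
    t_end: float | None = None,
) -> OxygenTrajectory:
    """Integrate the oxygen ODE alone from baseline over the protocol.

    Starts at pO2_0; integrates through delivery plus (by default) the
    post-irradiation relaxation window.  Raises :class:`SolverError` with
    the failing segment if the stiff integrator does not converge.
    """
    settings = settings or SimulationSettings()
    if t_end is None:
        t_end = history.tau_pulse + settings.t_post
    if t_end <= 0:
        t_end = 1.0  # zero-dose, zero-relaxation: still report a flat second

    def rhs(t, y, rate):
        return np.array([_rhs_value(y[0], rate, ox)])

    sol = integrate_piecewise(rhs, history, np.array([ox.pO2_0]), t_end, settings)
    return OxygenTrajectory(t=sol.t, pO2=sol.y[0], solution=sol)


def flash_limit_depletion(dose: float, ox: OxygenParameters) -> float:
    """Oxygen depletion (mmHg) after ``dose`` Gy with recovery switched off.

    Solves the separable limit dpO2/dD = −G·φ(pO2).  Integrating gives the
    implicit relation (p0 − p) + Kg·ln(p0/p) = G·D, solved for p by bisection
    on (0, p0]; the tension approaches but never crosses zero, so the
    returned depletion lies in [0, p0).  With Kg → 0 this reduces to the
    linear result min(G·D, p0).
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose!r}")
    if dose == 0:
        return 0.0
    p0 = ox.pO2_0
    target = ox.G * dose

    def f(p: float) -> float:
        return (p0 - p) + ox.Kg * np.log(p0 / p) - target

    # f(p0) = -target < 0; f(p→0+) → +inf, so a root exists in (0, p0)
    lo = p0
    while f(lo) < 0:
        lo *= 0.5
        if lo < 1e-300:
            return p0
    p = brentq(f, lo, p0, xtol=1e-14, rtol=1e-14)
    return p0 - p
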