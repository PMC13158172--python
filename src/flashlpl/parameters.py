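"""Model constants for the precursor-lesion FLASH survival model.

Every rate handed to the solvers is in s⁻¹; doses in Gy; oxygen tensions in
mmHg.  Constructors accept SI-per-second values only — the single place where
per-hour configuration input is converted is :func:`per_hour` (used by the
config loader), so double conversion is impossible by design.

The reference set combines Curtis's classical LPL fit for the C3H10T1/2 cell
line (lesion yields and repair/misrepair kinetics), millisecond-scale
precursor-lesion chemistry, and the reduced-order nuclear-oxygen parameters
(radiolytic depletion coefficient, Michaelis–Menten depletion saturation,
lumped reoxygenation rate) together with the exponential oxygen-enhancement
curve.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

__all__ = [
    "LPLParameters",
    "PrecursorParameters",
    "OxygenParameters",
    "OERParameters",
    "SimulationSettings",
    "ModelParameters",
    "per_hour",
    "reference_parameters",
    "baseline_preset",
    "BASELINE_PRESETS",
]

#: Seconds per hour — the single unit-conversion site.
_SECONDS_PER_HOUR = 3600.0


def per_hour(value: float) -> float:
    """Convert a first-order rate given in h⁻¹ to s⁻¹."""
    return value / _SECONDS_PER_HOUR


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class LPLParameters:
    """Classical LPL lesion-kinetic constants.

    Attributes
    ----------
    eta_PL : float
        Potentially-lethal lesion yield per unit dose (Gy⁻¹).
    eta_L : float
        Directly lethal lesion yield per unit dose (Gy⁻¹).
    eps_PL : float
        First-order correct-repair rate of PL lesions (s⁻¹).
    eps_2PL : float
        Second-order binary-misrepair rate constant (per lesion per second).
    """

    eta_PL: float
    eta_L: float
    eps_PL: float
    eps_2PL: float

    def __post_init__(self) -> None:
        _require_positive(
            eta_PL=self.eta_PL,
            eta_L=self.eta_L,
            eps_PL=self.eps_PL,
            eps_2PL=self.eps_2PL,
        )

    @property
    def eps(self) -> float:
        """Repair-to-misrepair ratio ε = ε_PL/ε_2PL (a lesion count)."""
        return self.eps_PL / self.eps_2PL


@dataclass(frozen=True)
class PrecursorParameters:
    """Precursor-lesion induction and chemical-restitution constants.

    ``eta_pre`` aggregates the yield of all fixable radical DNA sites
    (Gy⁻¹); ``eps_pre`` is the fast chemical-restitution rate (s⁻¹), whose
    reciprocal (~20 ms at the reference 50 s⁻¹) sets the oxygen-fixation
    time window.
    """

    eta_pre: float
    eps_pre: float

    def __post_init__(self) -> None:
        _require_positive(eta_pre=self.eta_pre, eps_pre=self.eps_pre)

    @property
    def tau_pre(self) -> float:
        """Mean precursor lifetime 1/ε_pre in seconds."""
        return 1.0 / self.eps_pre


@dataclass(frozen=True)
class OxygenParameters:
    """Reduced-order nuclear-oxygen kinetics.

    Attributes
    ----------
    pO2_0 : float
        Baseline nuclear oxygen tension (mmHg).
    G : float
        Radiolytic depletion coefficient (mmHg/Gy).
    Kg : float
        Michaelis–Menten saturation constant of the depletion efficiency
        (mmHg); suppresses further depletion at very low oxygen.
    k_reox : float
        Lumped recovery rate toward baseline (s⁻¹).
    """

    pO2_0: float
    G: float
    Kg: float
    k_reox: float

    def __post_init__(self) -> None:
        _require_positive(pO2_0=self.pO2_0, Kg=self.Kg, k_reox=self.k_reox)
        if self.G < 0:
            # G = 0 is admitted as the no-depletion diagnostic limit
            raise ValueError(f"G must be >= 0, got {self.G!r}")

    @property
    def tau_reox(self) -> float:
        """Recovery time constant 1/k_reox in seconds."""
        return 1.0 / self.k_reox


@dataclass(frozen=True)
class OERParameters:
    """Exponential oxygen-enhancement-ratio curve parameters.

    OER(pO2) = oer_min + (oer_max − oer_min)·(1 − exp(−ω·pO2)), with floor
    ``oer_min`` at radiobiological anoxia and plateau ``oer_max`` under full
    aeration; 1/ω is the characteristic oxygen scale (~3.8 mmHg at the
    reference ω = 0.26 mmHg⁻¹).
    """

    oer_min: float
    oer_max: float
    omega: float

    def __post_init__(self) -> None:
        _require_positive(omega=self.omega)
        if not 1.0 <= self.oer_min:
            raise ValueError(f"oer_min must be >= 1, got {self.oer_min!r}")
        if not self.oer_min < self.oer_max:
            raise ValueError(
                f"oer_min ({self.oer_min!r}) must be < oer_max ({self.oer_max!r})"
            )


@dataclass(frozen=True)
class SimulationSettings:
    """Stiff-integrator tolerances and post-irradiation relaxation time."""

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    t_post: float = 24.0 * _SECONDS_PER_HOUR

    def __post_init__(self) -> None:
        _require_positive(rel_tol=self.rel_tol, abs_tol=self.abs_tol)
        if self.t_post < 0:
            raise ValueError(f"t_post must be >= 0, got {self.t_post!r}")


@dataclass(frozen=True)
class ModelParameters:
    """Bundle of every constant the coupled simulator needs."""

    lpl: LPLParameters
    precursor: PrecursorParameters
    oxygen: OxygenParameters
    oer: OERParameters
    settings: SimulationSettings = SimulationSettings()

    def replace(self, **sections: Any) -> "ModelParameters":
        """Return a copy with whole sections swapped (e.g. ``oxygen=...``)."""
        return dataclasses.replace(self, **sections)

    def to_dict(self) -> dict[str, dict[str, float]]:
        """Flatten to plain nested dicts (for JSON manifests, round-trips)."""
        return {
            "lpl": dataclasses.asdict(self.lpl),
            "precursor": dataclasses.asdict(self.precursor),
            "oxygen": dataclasses.asdict(self.oxygen),
            "oer": dataclasses.asdict(self.oer),
            "settings": dataclasses.asdict(self.settings),
        }

    @classmethod
    def from_dict(cls, data: dict[str, dict[str, float]]) -> "ModelParameters":
        return cls(
            lpl=LPLParameters(**data["lpl"]),
            precursor=PrecursorParameters(**data["precursor"]),
            oxygen=OxygenParameters(**data["oxygen"]),
            oer=OERParameters(**data["oer"]),
            settings=SimulationSettings(**data["settings"]),
        )


# Reference parameter set.  Lesion yields and the misrepair constant follow
# Curtis's C3H10T1/2 analysis; via the model's LQ mapping they correspond to
# alpha = eta_L = 0.19 Gy⁻² and beta = eta_PL²/(2 eps) ≈ 0.026 Gy⁻², typical
# photon values for this line.  eps_PL = 0.5 h⁻¹ (2 h mean repair time).
_REFERENCE_LPL = LPLParameters(
    eta_PL=3.0,
    eta_L=0.19,
    eps_PL=per_hour(0.5),
    eps_2PL=per_hour(0.5) / 170.0,
)
_REFERENCE_PRECURSOR = PrecursorParameters(eta_pre=2000.0, eps_pre=50.0)
_REFERENCE_OXYGEN = OxygenParameters(pO2_0=3.0, G=0.42, Kg=0.21, k_reox=20.0)
_REFERENCE_OER = OERParameters(oer_min=1.0, oer_max=3.0, omega=0.26)
_REFERENCE_SETTINGS = SimulationSettings()

#: Baseline nuclear oxygen tensions for the three reference compartments:
#: a quiescent normal stem-cell niche (steep part of the OER curve), a
#: perinecrotic tumor compartment (OER floor), and a well-oxygenated
#: perivascular compartment (OER plateau).
BASELINE_PRESETS: dict[str, float] = {
    "quiescent_niche": 3.0,
    "perinecrotic_tumor": 0.2,
    "perivascular": 30.0,
}


def reference_parameters() -> ModelParameters:
    """Return the reference parameter set (quiescent-niche baseline).

    All rates are in s⁻¹; values originally quoted in h⁻¹ are converted at
    construction.
    """
    return ModelParameters(
        lpl=_REFERENCE_LPL,
        precursor=_REFERENCE_PRECURSOR,
        oxygen=_REFERENCE_OXYGEN,
        oer=_REFERENCE_OER,
        settings=_REFERENCE_SETTINGS,
    )


def baseline_preset(name: str) -> OxygenParameters:
    """Oxygen parameters for one of the named baseline-oxygenation presets.

    ``quiescent_niche`` → 3 mmHg, ``perinecrotic_tumor`` → 0.2 mmHg,
    ``perivascular`` → 30 mmHg, each with reference G, Kg and k_reox.
    """
    try:
        pO2_0 = BASELINE_PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(BASELINE_PRESETS))
        raise ValueError(f"unknown baseline preset {name!r}; valid presets: {valid}") from None
    return dataclasses.replace(_REFERENCE_OXYGEN, pO2_0=pO2_0)
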