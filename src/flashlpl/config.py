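"""TOML configuration loading.

One canonical config dialect: TOML with sections ``[lpl]``, ``[precursor]``,
``[oxygen]``, ``[oer]``, ``[settings]`` and an optional ``[protocol]``.
Every field is optional and defaults to the reference value.  Rates may be
given in h⁻¹ through an explicit ``_per_h``-suffixed key (e.g.
``eps_PL_per_h = 0.5``); the suffix is the only unit tag and this loader is
the only conversion site.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .parameters import (
    ModelParameters,
    SimulationSettings,
    per_hour,
    reference_parameters,
)
from .protocols import DoseRateHistory, constant_pulse, pulse_train

__all__ = ["load_config", "load_protocol", "ConfigError"]

#: Fields that may alternatively be supplied in h⁻¹ via a ``_per_h`` key.
_PER_HOUR_FIELDS = {
    "lpl": {"eps_PL", "eps_2PL"},
    "precursor": {"eps_pre"},
    "oxygen": {"k_reox"},
    "settings": set(),
    "oer": set(),
}


class ConfigError(ValueError):
    """Malformed configuration: unknown key, bad unit tag, or bad value."""


def _merge_section(section: str, defaults: Any, data: dict[str, Any]) -> Any:
    valid = {f.name for f in dataclasses.fields(defaults)}
    hourly = _PER_HOUR_FIELDS.get(section, set())
    updates: dict[str, float] = {}
    for key, value in data.items():
        if key in valid:
            updates[key] = float(value)
        elif key.endswith("_per_h") and key[: -len("_per_h")] in hourly:
            base = key[: -len("_per_h")]
            if base in data:
                raise ConfigError(
                    f"[{section}] gives both {base!r} and {key!r}; supply one"
                )
            updates[base] = per_hour(float(value))
        else:
            raise ConfigError(f"unknown key {key!r} in section [{section}]")
    return dataclasses.replace(defaults, **updates) if updates else defaults


def load_config(path: str | Path | None = None) -> ModelParameters:
    """Load model parameters from a TOML file over the reference defaults.

    ``None`` returns the pure reference set.  Raises :class:`ConfigError`
    naming the offending key for anything unrecognized.
    """
    params = reference_parameters()
    if path is None:
        return params
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sections = {
        "lpl": params.lpl,
        "precursor": params.precursor,
        "oxygen": params.oxygen,
        "oer": params.oer,
        "settings": params.settings,
    }
    merged: dict[str, Any] = {}
    for name, payload in raw.items():
        if name == "protocol":
            continue  # handled by load_protocol
        if name not in sections:
            raise ConfigError(
                f"unknown section [{name}]; valid sections: "
                f"{', '.join(sections)}, protocol"
            )
        merged[name] = _merge_section(name, sections[name], payload)
    for name, defaults in sections.items():
        merged.setdefault(name, defaults)
    return ModelParameters(
        lpl=merged["lpl"],
        precursor=merged["precursor"],
        oxygen=merged["oxygen"],
        oer=merged["oer"],
        settings=merged["settings"],
    )


def load_protocol(path: str | Path) -> DoseRateHistory | None:
    """Read the optional ``[protocol]`` section of a config file.

    Accepts either ``{dose, dose_rate}`` (single constant pulse) or
    ``{n_pulses, pulse_dose, in_pulse_rate, gap}`` (pulse train); returns
    ``None`` if the section is absent.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    proto = raw.get("protocol")
    if proto is None:
        return None
    keys = set(proto)
    if keys == {"dose", "dose_rate"}:
        return constant_pulse(float(proto["dose"]), float(proto["dose_rate"]))
    if keys == {"n_pulses", "pulse_dose", "in_pulse_rate", "gap"}:
        return pulse_train(
            int(proto["n_pulses"]),
            float(proto["pulse_dose"]),
            float(proto["in_pulse_rate"]),
            float(proto["gap"]),
        )
    raise ConfigError(
        "[protocol] must be either {dose, dose_rate} or "
        "{n_pulses, pulse_dose, in_pulse_rate, gap}; got keys "
        f"{sorted(keys)}"
    )
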