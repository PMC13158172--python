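"""CSV/JSON writers and run manifests.

Single-run results go to JSON, sweeps to CSV; floats are written with 12
significant digits, a fixed column order, a header row and a plain decimal
point, independent of locale.  Every command writes a manifest alongside
its outputs recording the resolved parameters, software version and files
produced, so a run can be reproduced bit-identically from the manifest.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .parameters import ModelParameters

__all__ = ["write_csv", "write_result_json", "write_manifest", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.12g"


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a data frame as locale-independent CSV (12 sig. digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def _round12(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    return obj


def write_result_json(payload: dict, path: str | Path) -> Path:
    """Write a single-run result (dose, rate, SF, ...) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round12(payload), indent=2) + "\n")
    return path


def write_manifest(
    command: str,
    params: ModelParameters,
    outputs: list[str | Path],
    path: str | Path,
    extra: dict | None = None,
) -> Path:
    """Write the run manifest: command, resolved parameters, version, files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "parameters": _round12(params.to_dict()),
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(_round12(extra))
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
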