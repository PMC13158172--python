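"""Dose-rate dependence of sparing at the quiescent-niche baseline.

Sweeps Lambda against dose rate for a fixed 10 Gy dose at 3 mmHg: sparing
stays negligible until delivery outpaces the ~50 ms oxygen recovery
timescale, then rises steeply past a few tens of Gy/s.
"""

import numpy as np

from flashlpl import dose_rate_sweep, reference_parameters

rates = sorted(set(np.geomspace(0.01, 400.0, 13)) | {0.05, 40.0})
sweep = dose_rate_sweep(dose=10.0, rates=rates, pO2_0=3.0, params=reference_parameters())

for _, row in sweep.table.iterrows():
    marker = "  <- FLASH reference" if row["value"] == 40.0 else ""
    print(f"rate = {row['value']:8.3f} Gy/s   Lambda = {row['Lambda']:+.4f}{marker}")

# Each row compares one delivery speed against the fixed 0.05 Gy/s
# conventional arm; the transition sits where the pulse duration D/rate
# drops below a few oxygen-recovery time constants.
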