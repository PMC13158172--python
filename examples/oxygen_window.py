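"""Map the physiologic-hypoxia sparing window.

Scans the sparing metric Lambda = ln(SF_FLASH/SF_CONV) for a 10 Gy dose
(40 vs 0.05 Gy/s) over a log-spaced grid of baseline nuclear oxygen
tensions and reports where it peaks.
"""

import numpy as np

from flashlpl import oxygen_window_scan, reference_parameters

# a coarse grid keeps this example quick; the default driver uses 60 points
grid = np.geomspace(0.1, 30.0, 20)
scan = oxygen_window_scan(doses=(10.0,), pO2_grid=grid, params=reference_parameters())

table = scan.curves[10.0].table
for _, row in table.iloc[::3].iterrows():
    print(f"pO2_0 = {row['value']:7.3f} mmHg   Lambda = {row['Lambda']:+.4f}")

pO2_peak, lam_peak = scan.peaks[10.0]
print(f"\npeak sparing Lambda = {lam_peak:.3f} at pO2_0 = {pO2_peak:.2f} mmHg")
print(f"survival ratio at the peak  : {np.exp(lam_peak):.3f}x")

# Lambda is bell-shaped: near anoxia the OER is already at its floor, on
# the plateau depletion barely moves the OER — only intermediate baselines
# (the 1-5 mmHg stem-cell-niche regime) convert transient oxygen depletion
# into appreciable sparing.
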