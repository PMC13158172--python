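"""One coupled simulation: 10 Gy at 40 Gy/s into a quiescent niche.

Runs the precursor-resolved survival model at the reference 3 mmHg
baseline and prints the survival fraction, the transient oxygen minimum,
and the precursor conservation audit.
"""

from flashlpl import (
    constant_pulse,
    precursor_mass_balance,
    reference_parameters,
    simulate_mlpl,
)

params = reference_parameters()
history = constant_pulse(dose=10.0, dose_rate=40.0)
result = simulate_mlpl(history, params)

print(f"pulse duration        : {history.tau_pulse:.3f} s")
print(f"survival fraction     : {result.SF:.4f}  (ln SF = {result.ln_SF:.4f})")
print(f"lethal lesions        : {result.n_L_final:.4f} per cell (expectation)")
print(f"oxygen nadir          : {result.pO2.min():.3f} mmHg "
      f"(baseline {params.oxygen.pO2_0} mmHg)")
print(f"mass-balance residual : {precursor_mass_balance(result):.2e}")

# The oxygen nadir sits well below baseline because a 0.25 s pulse outruns
# the 50 ms recovery timescale; the reduced OER during the pulse fixes
# fewer precursor lesions, so survival is higher than at 0.05 Gy/s.
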