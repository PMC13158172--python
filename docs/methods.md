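# Methods

## Model structure and assumptions

The simulator couples ensemble-averaged lesion kinetics to a reduced-order
description of nuclear oxygen.  Four state variables are integrated as one
stiff system: the precursor-lesion count n_pre, the potentially-lethal and
lethal lesion counts n_PL and n_L, and the nuclear oxygen tension pO2.

Assumptions worth stating explicitly:

- **Ensemble ODEs, not per-cell stochastics.**  Lesion counts are
  expectations; survival is the Poisson null SF = exp(−n_L).  No
  cell-to-cell heterogeneity, no microdosimetric track structure.
- **Oxygen acts only through fixation.**  Both fixation channels share one
  oxygen scaling, κ_X(pO2) = κ_X_sat · OER(pO2)/OER_max, evaluated on the
  instantaneous tension with no lag.  The Michaelis–Menten efficiency
  φ(pO2) = pO2/(pO2+Kg) throttles *depletion* only — it never modifies the
  fixation rates, whose oxygen dependence enters solely through the OER.
- **The baseline pO2,0 is an effective DNA-target-level quantity.**  The
  three named presets (quiescent_niche = 3, perinecrotic_tumor = 0.2,
  perivascular = 30 mmHg) are working points on the OER curve, not tissue
  measurements; niche-to-nucleus gradients are absorbed into pO2,0 and not
  modeled as a computed decomposition.
- **Lumped oxygen recovery.**  k_reox is a single effective local rate (no
  diffusion geometry); its reciprocal (50 ms at reference) should be read
  as a target-level recovery timescale, not a bulk tissue one.
- **Only n_L kills.**  Precursor and PL lesions remaining after the 24 h
  relaxation window do not contribute to lethality; they are exposed as
  `SimulationResult.residual_transients` for transparency (at reference
  parameters they are zero to solver precision).

## Reference parameters

| parameter | value | unit | meaning |
|---|---|---|---|
| η_PL | 3.0 | Gy⁻¹ | PL-lesion yield (classical fit, C3H10T1/2) |
| η_L | 0.19 | Gy⁻¹ | lethal-lesion yield (reciprocal of the 1/e dose at very low dose rate) |
| ε_PL | 0.5 h⁻¹ | → s⁻¹ | PL repair (2 h mean repair time) |
| ε_2PL | ε_PL/170 | s⁻¹ | binary misrepair; ε = ε_PL/ε_2PL = 170 lesions |
| η_pre | 2000 | Gy⁻¹ | aggregate yield of fixable radical sites |
| ε_pre | 50 | s⁻¹ | chemical restitution (20 ms lifetime) |
| G | 0.42 | mmHg/Gy | radiolytic depletion coefficient (aqueous value) |
| Kg | 0.21 | mmHg | depletion-efficiency saturation constant |
| k_reox | 20 | s⁻¹ | lumped recovery rate (τ = 50 ms) |
| OER_min, OER_max | 1.0, 3.0 | — | OER floor and plateau |
| ω | 0.26 | mmHg⁻¹ | oxygen-fixation constant (1/ω ≈ 3.8 mmHg) |

The classical lesion-kinetic constants are the package's adopted
C3H10T1/2 reference set; through the model's LQ mapping
(α = η_L_eff, β = η_PL_eff²/2ε) they correspond to plateau values
α = 0.19 Gy⁻¹ and β ≈ 0.026 Gy⁻² — typical published photon values for
this line.  The code treats them as free parameters, so any alternative
fit drops in unchanged.  The saturated fixation rates are *derived*, not
free: κ_X_sat = η_X·ε_pre/η_pre, which anchors the quasi-steady effective
yields to the classical yields on the OER plateau (verified to 1e-8
relative in the tests).  Construction rejects parameter sets where
restitution does not dominate saturated fixation by at least 100×, since
the precursor state is meaningful only as a fast intermediate.

All internal computation is in seconds, Gy and mmHg.  The config loader is
the single h⁻¹→s⁻¹ conversion site (`_per_h`-tagged keys), so double
conversion cannot occur.

## Numerics

- **Integrator.**  `scipy.integrate.solve_ivp` with the implicit Radau
  method, rtol 1e-6 / atol 1e-8, restarted exactly at every dose-rate
  discontinuity so the piecewise-constant drive is never sampled across a
  boundary.  The system is stiff: restitution (50 s⁻¹) and recovery
  (20 s⁻¹) against repair (1.4e-4 s⁻¹) over a 24 h horizon.
- **Positivity without clamps.**  φ(pO2) → 0 at anoxia makes the oxygen
  equation self-limiting; non-negativity is asserted post hoc to within
  solver tolerance rather than enforced by clipping.
- **Bookkeeping as quadrature states.**  Cumulative restitution and
  channel fixation are integrated alongside the states, so the precursor
  mass-balance audit (residual < 1e-4 required, ~1e-9 typical) inherits
  solver accuracy.
- **Output grid.**  Dense output on a log-spaced grid inside each delivery
  segment (120 points, resolving sub-millisecond transients), linear grids
  across interpulse gaps, and a log-spaced relaxation grid out to
  τ_pulse + 24 h.  Terminal time is exact; no early-exit heuristics.
- **Peak location.**  Window-scan peaks are located by fitting a parabola
  in (log pO2, Λ) through the grid maximum and its neighbours, falling
  back to the grid point at edges or non-concave triples.
- **Closed-form cross-checks.**  The ultra-fast depletion limit
  dpO2/dD = −G·φ(pO2) integrates to the implicit relation
  (p0−p) + Kg·ln(p0/p) = G·D, solved by bisection; it agrees with the ODE
  at frozen recovery and degenerates gracefully (depletion capped at the
  baseline) when G·D exceeds the available oxygen.
- **"Very low" dose rate** for classical-limit checks is chosen, not
  assumed: the quasi-equilibrium estimate of the misrepair share,
  ε_2PL·η_PL²·Ḋ/(ε_PL²·η_L), is inverted for the rate giving a 0.1% share,
  and every consumer re-verifies the realized share from the bookkeeping
  integral.  At the reference set this lands near 5e-7 Gy/s; integration
  over the resulting ~10⁷ s is cheap because the system is smooth there.

## Design choices that were genuinely open

- **Fixation normalization.**  κ is normalized by OER_max (plateau
  anchoring) rather than by the OER at some finite reference tension, so
  equivalence with the classical yields holds where ω·pO2 ≫ 1.
- **Right-continuity** of the dose-rate lookup at segment boundaries (a
  pure convention; the integrators never rely on it).
- **Conventional reference rate** fixed at 0.05 Gy/s and FLASH reference
  at 40 Gy/s, both configurable per call.
- **G = 0 is admitted** (depletion off) as a diagnostic limit used by the
  quasi-steady-state equivalence checks, although the physical reference
  value is strictly positive.
- **Config dialect** is TOML (stdlib `tomllib`), one canonical format.

## What the acceptance computation reports

`scripts/acceptance.py` reruns, from scratch: (i) the classical model at
dose 1/η_L under a verified-negligible-misrepair dose rate, reporting
survival as a rounded percentage (1/e → 37%); (ii) a 60-point log-spaced
scan of Λ(pO2,0) for 10 Gy at 40 vs 0.05 Gy/s, reporting the interpolated
peak location (the same number serves as both window-bound checks).  The
model has no randomness; the `--seed` flag is recorded verbatim.

## Problem sizes

Single simulations integrate 7 ODE states over τ_pulse + 24 h in tens of
milliseconds.  The default window scan is 60 baselines × 2 arms (120
runs, ~6 s on one core); the sweep drivers behind `reproduce-all` total
roughly 1300 runs.  Test-suite scans use coarser 10–12-point grids that
still bracket the peak.

## Known limitations

- No spatial oxygen transport or vascular geometry; k_reox lumps all of
  it.  Predictions at tissue scale inherit that reduction.
- G is a single constant: no LET or beam-quality dependence of the
  radiolytic yield.
- The exponential OER form is fixed (the curve is a swappable callable,
  but no alternative hyperbolic form ships).
- Accelerator microsecond pulse microstructure is representable via
  `pulse_train` but not studied; defaults use the mean-dose-rate single
  pulse.
- No fitting machinery: parameters are inputs, never estimated from
  survival data.
- Because the generator of all study conditions is the deterministic model
  itself, passing tests demonstrate internal consistency (limits,
  conservation, orderings, oracle agreement) — not agreement with any
  experimental FLASH dataset.
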