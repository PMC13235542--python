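# Methods

## The model

Sulfidic cave streams are circumneutral (pH ≈ 7.1–7.5, 13–14 °C) and carry
tens to hundreds of micromolar NH_x with δ15N near +3 ‰. Cave-wall
condensation droplets a few meters above them are extremely acidic
(pH < 1) yet hold millimolar NH4+ at δ15N near −29 to −25 ‰. `cavenit`
models the physical chain connecting the two observations:

NH4+(aq) ⇌ NH3(aq) ⇌ NH3(g) → transport → NH4+ (acid-trapped)

Each arrow carries an equilibrium nitrogen-isotope enrichment factor
ε = (α − 1)·10³ with α = R_substrate/R_product (positive ε ⇒ product
depleted in 15N). The acid trap is treated as quantitative: at droplet pH,
any NH3 contacting the surface protonates, so the trap expresses ε ≈ 0 and
the droplet inherits the gas-phase δ15N. The observed droplet and air
δ15N field is then interpreted as a two-endmember mixture between this
volatilized-NH3 pole and a surface organic-N pole.

### Assumptions

- **Dilute solutions.** Activity coefficients are 1 throughout the
  speciation and Henry calculations. An ionic-strength hook
  (`speciate_nhx(..., gamma_nh4=...)`) exists for waters where this
  matters; it is off by default because the streams modelled here are
  dilute and the major-ion data needed to do better are not part of the
  package's inputs.
- **Equilibrium end-to-end.** The fractionation chain assumes each step
  expresses its full equilibrium isotope effect. Kinetic or
  transport-limited expression would shrink the net depletion; step (c)
  of the chain accepts a user-supplied transport ε (default 0) to explore
  this, but no magnitude is asserted.
- **Ideal gas at 1 atm.** ppbv = mole fraction × 1e9 with fugacity
  coefficient 1.

## Parameters, units, defaults

| parameter | default | units | why |
|---|---|---|---|
| pKa(NH4+, 25 °C) | 9.25 | — | standard value for the ammonium acid constant |
| ΔH°(dissociation) | 52.21 | kJ/mol | standard enthalpy; drives the van't Hoff pKa correction (pKa 9.63 at 13 °C) |
| K_H(NH3, 25 °C) | 59 | M/atm | standard Henry solubility of ammonia |
| −Δ_sol H/R | 4200 | K | van't Hoff coefficient; K_H ≈ 107 M/atm at 13 °C |
| ε(NH4+→NH3(aq)) | 30 | ‰ | the value used in the printed −26.7 ‰ prediction; the experimental literature value 32 ‰ is selectable by config, and the 2 ‰ discrepancy is surfaced rather than resolved |
| ε(NH3(aq)→NH3(g)) | 8.3 | ‰ | experimental air–water interface effect |
| ε(transport), ε(trap) | 0 | ‰ | no published transport magnitude; trapping is near-quantitative |
| fractionation mode | linear | — | the field arithmetic (+3.3 → −26.7; 30 + 8.3 → 38.3) is linear; exact-alpha mode is provided for rigor and differs by ε(ε−δ)/(10³α) |
| mixing endmembers | −27.3 / +15 | ‰ | lowest passive-sampler value just above a stream (a direct NH3(g) measurement) and guano near cave entrances; the lowest droplet value (−29.0) is a selectable alternative for the stream-air pole |
| ΔG conditions | 25 °C, pO2 0.209 atm, a(NO2−)=a(NO3−)=10⁻¹² | | air-referenced oxygen, trace products typical of environments with no measurable nitrification |

All concentrations are carried internally in molar; tables use μM for
waters and mM for droplets, matching field reporting conventions. Missing
measurements are `None`/empty cells, never sentinel zeros.

### Formation energies

ΔG° is assembled from standard Gibbs energies of formation at 25 °C
(Stumm & Morgan, *Aquatic Chemistry*, 3rd ed. compilation; see
`src/cavenit/data/gibbs_formation.csv`): NH4+ −79.31, NH3(aq) −26.50,
NO2− −32.20, NO3− −111.30, H2O(l) −237.18 kJ/mol. This gives
ΔG° = −190.07 kJ/mol for oxidation to nitrite and −269.17 kJ/mol to
nitrate, per mole of N. Element and charge balance of every reaction is
machine-checked at construction. The reaction quotient uses NH4+ as the
nitrogen substrate by default (the dominant species at every pH on the
grid); the NH3-written form is supported and agrees to within 0.05 kJ/mol
because the formation-energy table implies pKa 9.252 versus the 9.25 used
for speciation. Temperature is fixed at 25 °C with no heat-capacity
corrections, and H2O activity is 1.

## Synthetic campaign

The generator emulates the statistical shape of a field campaign, not its
physics:

- Stream pH, temperature and NH_x are uniform within the observed ranges;
  stream δ15N is Gaussian (+3.3 ± 1.1 ‰, matching the observed +0.3 to
  +4.7 ‰ spread).
- The stream-air mixing fraction decays exponentially with distance,
  f(d) = exp(−d/L). **This is a synthetic convention, not a transport
  law.** L = 34 m is chosen so that droplets at 27.5 m average −3.8 ‰, the
  observed distal value, given the −27.3/+15 ‰ poles.
- Droplet NH4+ is log-normal (relative σ 0.3) about a median that decays
  geometrically from 2.23 mM (near) to 0.018 mM (27.5 m).
- Analytical noise on every δ15N is Gaussian with σ = 0.3 ‰, the
  denitrifier-method precision.
- Droplets beyond 15 m sit at pH 4 (non-trapping); nearer droplets are
  pH < 1.
- One integer seed feeds a `SeedSequence`; per-table child streams are
  spawned deterministically, so enlarging one table leaves the others
  byte-identical.

Because the generator *is* the two-endmember mixing model plus noise,
pipeline tests against it demonstrate internal consistency (the estimator
inverts the generative model correctly at realistic noise), not that real
cave air obeys exponential mixing. Features of real data it does not
emulate: compromised samplers, aerosol NH4+ contributions, the occasional
near-stream samples with anomalously high δ15N, filter-breakthrough
enrichment, and any airflow physics.

## Numerical choices

- Endmember recovery is ordinary least squares on the design
  [f, 1 − f] with f from the known decay length — the exact inverse of
  the generative mixing law; no intercept, both coefficients free.
- Mixing fractions outside [0, 1] are returned as computed and flagged
  out-of-hull, never clamped, so samples inconsistent with two-endmember
  mixing stay visible.
- `apply_fractionation` short-circuits ε = 0 to return δ bit-exactly in
  both conventions.
- In exact-alpha mode sequential steps compose by multiplying alphas;
  this is commutative, so the chain's a→b→c→d order is physical
  bookkeeping rather than a numerical decision.
- CSV round-trips are bit-exact: floats are written with 17 significant
  digits and parsed with round-trip precision.
- Degenerate inputs raise typed errors (`DomainError`,
  `MissingFieldError`, `DegenerateEndmemberError`,
  `InfeasibleBalanceError`, `UnbalancedReactionError`) rather than
  returning NaN.
- The ΔG grid is evaluated cell-by-cell (plain loops); grids of interest
  are ≤ a few thousand cells, so clarity wins over vectorization.
- Analysis reports serialize with sorted keys and no timestamps, so
  identical inputs give bitwise-identical reports; provenance records the
  constants hash and SHA-256 of each input table.

## Problem sizes

Default drivers use 8 streams, 120 droplets and 12 air samples; the
endmember-recovery check uses 1,200 droplets, and the Monte-Carlo
calibration check 10,000 droplets at a single distance. ΔG grids are
29 × 25 (drivers) and 50 × 50 (checks). These sizes make every standard
error comfortably smaller than the tolerances being tested while keeping
the full suite under a minute.

## Known limitations

- The upper bound of the stream NH3(g) equilibrium range is not
  reproducible from printed endpoint values alone: combining the extreme
  pH, NH_x and temperature in one water gives ~12 ppbv, whereas
  per-sample field combinations top out near 9 ppbv. Only the lower
  endmember is treated as a pinned value.
- ΔG results are property-level (signs, monotonicity, additivity), not
  matched to any published number; formation-energy compilations differ
  at the few-kJ level.
- No carbonate or sulfide speciation, no δ18O modelling, no kinetic
  isotope effects, no biomass-yield or rate modelling.
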