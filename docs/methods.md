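# Methods

## Free-energy bookkeeping

All availabilities and affinities are expressed as free energies of
forming the half-saturated complex, ΔG = *RT* ln *c* with *c* either the
buffered available concentration or the dissociation constant
(ΔG = *RT* ln *K*_D = −*RT* ln *K*_A). Natural logarithms, kJ mol⁻¹,
*R* = 8.314×10⁻³ kJ K⁻¹ mol⁻¹ and *T* = 298.15 K throughout. The standard
temperature is retained even though the cells the presets describe grew at
37 °C: the availability ladder is conventionally tabulated at 298.15 K,
and both constants are overridable (`ThermoConstants`) for sensitivity
analysis. Copper is treated exclusively as Cu⁺, the dominant cytosolic
oxidation state.

## The competitive occupancy calculator

A single preformed 1:1 site with per-metal ratios
*r*ᵢ = [Mᵢ]/*K*_D,ᵢ has occupancies *r*ᵢ/(1 + Σ*r*ⱼ). The "1+" term is the
unmetalated site, which is how competition from the intracellular buffer
enters: the buffered free concentrations are held fixed (the molecule of
interest is assumed not to deplete the pools), so no explicit buffer
species is needed. The identical Boltzmann form over ΔΔG values is
implemented separately (`occupancy_from_free_energies`) purely as a
cross-check; tests require agreement to 10⁻¹⁰ relative. Out of scope by
design: cooperative or multi-site binding, metal-dependent assemblies with
β (M⁻²) constants, and pool depletion by overexpressed protein.

The three shipped presets store the published availability table exactly
as printed (values rounded, decimal places matched to the standard
deviations; boundary-derived entries carry no SD). Because the original
calculators used unrounded two-significant-figure internals, predictions
from the presets can drift from published occupancies by up to about
2 percentage points; acceptance tests encode that band. The zinc entry
defaults to the midpoint of the Zur- and ZntR-derived estimates, with
either single-sensor value selectable (`load_preset(..., zinc="zur")`) —
the two sensors bracket the zinc pool and the log-scale midpoint is the
natural single number for a calculator.

## Sensor equilibrium model

Each metalloregulator is a five-species system — apo sensor P, holo sensor
PM, free operator D, and the two operator complexes PD and PMD — governed
by three dissociation constants (K_metal for the tightest allosteric site,
K_DNA of the apo sensor, K_DNA of the holo sensor) and two mass balances.
The buffered metal is an infinite reservoir ([M] fixed). Metal binding to
DNA-bound sensor is not an independent constant: it follows from
thermodynamic cycle closure, K_metal·K_DNA_holo/K_DNA_apo. This is the
minimal model consistent with the five measurable quantities a sensor
characterization provides (two DNA affinities, one metal affinity, two
abundances, plus the operator count).

Substituting the equilibrium relations into the balances collapses the
system to one quadratic in free operator D, solved in closed form with the
cancellation-stable root (the linear coefficient spans ~15 orders of
magnitude across realistic parameters). Solutions are validated in place:
mass balances to 10⁻⁸ relative, reconstructed constants to 10⁻⁶. The test
suite additionally checks the solver against a brute-force oracle that
solves the same balances by nested interval bisection on (D, P) — a
numerically independent route.

Sensor totals convert molecules-per-cell through Avogadro's number and a
cell volume defaulting to 1 fL (a typical bacterial cytosol; configurable
per sensor set, since published per-cell abundances are only meaningful
jointly with the volume used to derive them). Between the low- and
high-metal abundances the default blending is linear in the sensor's
fractional metal saturation [M]/([M]+K_metal) — the apo/holo partition of
free sensor, which is independent of the DNA equilibria — with fixed-low,
fixed-high and mean modes available. Any blending choice here is a modelling
convention: measurements provide two endpoint abundances, not a rule, and
the interpolated response remains monotone for co-repressors and
activators (whose abundance rises with metal). De-repressor abundances are
taken equal at both ends, which real de-repressor expression approximates
and which guarantees monotonicity under interpolation.

The regulatory readout is θ_D = PD/D_total (de-repressors),
θ_D = PMD/D_total (co-repressors) or θ_DM = PMD/D_total (activators);
monotonicity in [M] makes the response invertible. Inversion brackets
log₁₀[M] in [−25, −1] — beyond any plausible cytosolic availability — and
uses Brent root-finding (≤200 iterations, concentration tolerance well
below the 10⁻⁴ relative round-trip requirement). Targets outside the
attainable occupancy interval (finite sensor abundance caps the curves
below 1) raise an error reporting that interval.

### Sensor parameter provenance

The thermodynamic constants of the seven sensors were measured elsewhere
and are not reproduced in this package. The packaged
`sensors_synthetic.yaml` is a clearly-labelled synthetic stand-in:
internally consistent, order-of-magnitude-plausible constants whose
dynamic ranges sit near the availabilities of their cognate metals and
attain both 0.01/0.99 calibration anchors. It makes curves, calibrations
and simulations runnable and testable out of the box; quantitative
availability estimation requires substituting measured constants. The
availability *presets* are published values and are unaffected by this
placeholder.

## qPCR calibration pipeline

1. **QC.** A sample is rejected when its no-template or minus-RT control
   Cq, rounded to the nearest integer, is fewer than 10 cycles above the
   sample Cq. A condition is dropped when its mean reference-gene (*rpoD*)
   Cq shifts by more than 2 cycles from the control condition, unless a
   second reference gene (*gyrA*) passes the same test. All exclusions are
   logged and reported machine-readably; silent dropping is forbidden.
2. **Fold change.** 2^−ΔΔCq against the reference gene, baselined on each
   gene's minimum-expression condition (fold change 1 there by
   construction). ΔCq is computed per biological replicate; per-replicate
   fold changes (vs the baseline mean) feed SD propagation.
3. **Fractional response.** Linear map of fold change onto
   θ ∈ [0.01, 0.99]: θ_D = 0.99 − 0.98·(fc−1)/(fc_max−1) for repressors,
   θ_DM = 0.01 + 0.98·(same) for activators, so θ_D + θ_DM = 1 for equal
   inputs. Anchors use the *mean* fold change of the boundary conditions,
   consistent with baselining on condition means. Outside [1, fc_max] the
   expression no longer tracks availability, so fold changes are clamped
   to the nearest anchor with a warning, never extrapolated.
4. **Inversion and aggregation.** Each replicate's θ is inverted to a
   concentration; the estimate is the mean of replicate concentrations
   with their SD (scatter is reported on the scale of the quantity of
   interest, raw concentration, not through the log transform).
   Boundary-defining conditions are anchored exactly at 0.01/0.99 and
   carry no SD. Sensors needing regime-specific anchors (nickel sensing
   differs between aerobic and anaerobic growth) take one boundary set per
   regime, each listing the conditions it governs.
5. **Zinc midpoint.** When both Zur and ZntR yield an estimate for a
   condition, their geometric mean (log-scale midpoint) is appended; the
   geometric choice is what reproduces the published midpoint rows from
   the published single-sensor rows.

Upstream amplicon-efficiency correction is out of scope: the pipeline
takes (optionally efficiency-corrected) Cq values and uses base-2
amplification exactly as the 2^−ΔΔCq method prescribes.

## Synthetic data generator

`generate_synthetic_qpcr` runs the pipeline forwards from chosen
ground-truth concentrations: truth → θ (sensor model) → fold change
(inverse of the linear calibration) → ΔΔCq → per-replicate Cq with
Gaussian noise, emitting two boundary pseudo-conditions whose fold changes
are exactly 1 and fc_max. Defaults mirror the structure of the experiments
the pipeline targets: biological triplicates, 0.1-cycle Cq scatter
(instrument-level noise; recovery tests also use 0 and a pessimistic 0.3),
reference gene near Cq 15, regulated genes near Cq 22 at minimum
expression, clean controls at Cq 40. A configurable reference-gene drift
exercises the 2-cycle QC rule. What it does *not* emulate: amplification
efficiency differences between amplicons, technical-replicate structure,
non-Gaussian outliers, and correlated condition effects on multiple genes
— so passing recovery tests demonstrate correctness of the computational
chain, not robustness to every real-world artefact.

Recovery behaviour (asserted in tests): noiseless single-replicate
round-trips recover truth to 10⁻³ relative; at 0.3-cycle noise the
ensemble mean over 100 simulated experiments stays within 2 SD of truth on
the log-concentration scale for every (condition, sensor) pair. Problem
sizes — three sensors covering the three regulatory classes, two
conditions, triplicates, 100 runs — keep the full suite under ten seconds
while still exercising every pipeline stage.

## Numerical choices and degenerate inputs

- Occupancies are clamped to [0,1] only against floating-point dust; the
  solver itself cannot produce negative species.
- [M] = 0 is exact (PM = PMD = 0, single-site apo binding closed form).
- Percentages are reported to one decimal place; availability tables keep
  full precision with SDs alongside.
- Degenerate calibration windows (fc_max ≤ 1) are an error, not a warning:
  no dynamic range means no calibration.
- Inversion of θ targets marginally outside the attainable range (e.g. a
  noisy replicate at 0.999999 of an anchor) drops that replicate with a
  warning and estimates from the remainder.

## Known limitations

- Availability presets are specific to *E. coli* JM109 (DE3) in LB;
  strains aberrant in metal homeostasis (e.g. BL21) need their own
  calibration.
- The calculator assumes equilibrium; kinetically trapped or
  chaperone-delivered metalation (SodA folding, HypB→hydrogenase flux)
  can depart from predictions — such disparities are informative, not
  failures of arithmetic.
- Single-metal response per sensor: cross-reactivity (e.g. Zur responding
  to Co²⁺) and sensor-abundance hysteresis are not modelled.
- The packaged sensor constants are synthetic placeholders (see above).
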