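# metalation

Predict which metal a protein will acquire inside a living cell — and
calibrate the intracellular metal availabilities that prediction rests on.

Proteins usually bind the *wrong* metals more tightly than the ones they
need: in vitro affinities follow the Irving–Williams series
(Mn²⁺ < Fe²⁺ < Co²⁺ < Ni²⁺ < Cu⁺ > Zn²⁺) regardless of function. Cells
solve this by buffering the tight-binding metals to vanishingly small
available concentrations, so correct metalation is set by the *free-energy
gradient* from the buffered pool to the protein, not by affinity alone.
This package implements that thermodynamic framework for *E. coli* grown in
LB medium under aerobic, anaerobic and H₂O₂-exposed conditions, for users
who express metalloproteins in *E. coli* (recombinant production,
industrial biotechnology) or study metal homeostasis.

## The model

**Occupancy calculator.** For a 1:1 metal site with dissociation constants
*K*<sub>D,*i*</sub> competing for metals buffered at available
concentrations [M<sub>*i*</sub>], the site is a binding polynomial with
ratios *r*<sub>*i*</sub> = [M<sub>*i*</sub>]/*K*<sub>D,*i*</sub>:

    θ_i = r_i / (1 + Σ_j r_j),        Σ_i θ_i < 1

Equivalently, with ΔG<sub>*i*</sub> = *RT* ln *K*<sub>D,*i*</sub> and
ΔG<sub>available,*i*</sub> = *RT* ln[M<sub>*i*</sub>],
θ<sub>*i*</sub> ∝ exp(−ΔΔG<sub>*i*</sub>/*RT*): the metal with the most
favourable gradient dominates, and total occupancy never exceeds a
stoichiometry of 1.

**Availability calibration.** The buffered concentrations themselves come
from seven DNA-binding metal sensors (MntR, Fur, RcnR, NikR, Zur, ZntR,
CueR). Each sensor is modelled as a five-species equilibrium
(apo/holo sensor × free/operator-bound DNA) whose operator occupancy
θ<sub>D</sub> (repressors) or θ<sub>DM</sub> (activators) is monotone in
the buffered metal concentration. qPCR fold changes of the regulated
transcripts (2^−ΔΔCq, *rpoD* reference) are mapped linearly onto
θ ∈ [0.01, 0.99] between the minimum- and maximum-expression boundary
conditions, and the sensor model is inverted per biological replicate to
yield concentrations; the two zinc sensors are summarised by their
log-scale midpoint.

## Worked example

Predict the metalation of the HypB nickel chaperone
(*K*<sub>D</sub>(Ni²⁺) = 6×10⁻¹⁴ M, *K*<sub>D</sub>(Zn²⁺) = 2.2×10⁻¹¹ M,
other metals excluded) in anaerobically grown cells:

```python
from metalation import load_preset, packaged_affinity_set, compute_occupancy, render_report

result = compute_occupancy(load_preset("anaerobic"), packaged_affinity_set("hypb"))
print(render_report(result, "text"))
```

```
Metalation of hypb (anaerobic availabilities)
metal     K_D (M)    [M] (M)   dG_prot  dG_avail      ddG   occ %
Ni2+     6.00e-14   9.00e-14    -75.47    -74.46    -1.01    58.5
Zn2+     2.20e-11   1.40e-12    -60.83    -67.66     6.83     2.5
total                                                        61.0
```

Despite binding Zn²⁺ only ~370-fold more weakly than Ni²⁺, HypB is
predicted to be predominantly nickel-loaded: only Ni²⁺ has a favourable
gradient (ΔΔG < 0) from the anaerobic buffered pool. The same call from
the shell:

```sh
metalation calculate --preset anaerobic --affinities src/metalation/data/affinities/hypb.tsv
```

Other entry points: `metalation curve` tabulates/plots a sensor's response
curve with its 0.01/0.99 anchors, `metalation calibrate` turns a Cq table
into an availability table, and `metalation simulate` fabricates synthetic
Cq tables with known ground truth (see `docs/methods.md`).

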