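# SYNTHETIC placeholder sensor parameter set.
#
# The thermodynamic constants of the seven metalloregulators (metal and DNA
# affinities, cellular abundances) were measured for the Salmonella sensor
# set and are not redistributed here.  This file ships internally
# consistent, order-of-magnitude-plausible stand-ins so that response
# curves, calibration runs and simulations work out of the box.  Each
# sensor's dynamic range is positioned near the availability of its cognate
# metal, and every range attains the 0.01/0.99 calibration anchors.
# Replace with measured constants for quantitative work.
provenance: "SYNTHETIC placeholder values for simulation and testing; not measured constants"
cell_volume: 1.0e-15
sensors:
  MntR:
    metal: Mn2+
    class: co-repressor
    gene: mntS
    k_metal: 5.0e-06
    k_dna_apo: 1.0e-06
    k_dna_holo: 1.0e-09
    abundance_low: 100
    abundance_high: 200
    n_targets: 1
  Fur:
    metal: Fe2+
    class: co-repressor
    gene: fepD
    k_metal: 1.0e-06
    k_dna_apo: 1.0e-06
    k_dna_holo: 1.0e-09
    abundance_low: 200
    abundance_high: 400
    n_targets: 2
  RcnR:
    metal: Co2+
    class: de-repressor
    gene: rcnA
    k_metal: 5.0e-11
    k_dna_apo: 5.0e-10
    k_dna_holo: 1.0e-06
    abundance_low: 100
    abundance_high: 100
    n_targets: 1
  NikR:
    metal: Ni2+
    class: co-repressor
    gene: nikA
    k_metal: 1.0e-13
    k_dna_apo: 1.0e-06
    k_dna_holo: 1.0e-09
    abundance_low: 100
    abundance_high: 200
    n_targets: 1
  Zur:
    metal: Zn2+
    class: co-repressor
    gene: znuA
    k_metal: 5.0e-12
    k_dna_apo: 1.0e-06
    k_dna_holo: 1.0e-09
    abundance_low: 100
    abundance_high: 150
    n_targets: 1
  ZntR:
    metal: Zn2+
    class: activator
    gene: zntA
    k_metal: 2.0e-13
    k_dna_apo: 1.0e-07
    k_dna_holo: 5.0e-10
    abundance_low: 30
    abundance_high: 60
    n_targets: 1
  CueR:
    metal: Cu1+
    class: activator
    gene: copA
    k_metal: 1.0e-19
    k_dna_apo: 1.0e-07
    k_dna_holo: 5.0e-10
    abundance_low: 30
    abundance_high: 60
    n_targets: 2
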