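# Buffered available metal concentrations (molar) in E. coli JM109 (DE3)
# grown in LB, estimated from qPCR readouts of metal-sensor-regulated
# transcripts under three growth conditions.  Values are stored exactly as
# published (rounded, decimal places rationalized to the standard
# deviation); entries marked boundary anchored a calibration boundary and
# therefore carry no standard deviation.  Zn2+ carries the two single-sensor
# estimates (Zur, ZntR) plus their log-scale midpoint, the default.
provenance: "JM109 (DE3) LB-grown cells; sensor-calibrated qPCR estimates"
presets:
  aerobic:
    Mn2+: {concentration: 7.0e-06, sd: 4.0e-06}
    Fe2+: {concentration: 1.9e-06, sd: 2.0e-07}
    Co2+: {concentration: 7.0e-11, sd: 1.0e-11}
    Ni2+: {concentration: 1.3e-13, sd: 7.0e-14}
    Cu1+: {concentration: 4.5e-20, sd: 6.0e-21}
    Zn2+:
      zur: {concentration: 7.0e-12, sd: 1.0e-12}
      zntr: {concentration: 4.0e-13, sd: 1.0e-13}
      midpoint: {concentration: 2.0e-12}
  anaerobic:
    Mn2+: {concentration: 1.0e-05, sd: 3.0e-06}
    Fe2+: {concentration: 7.0e-07, sd: 2.0e-07}
    Co2+: {concentration: 7.1e-11, sd: 5.0e-12}
    Ni2+: {concentration: 9.0e-14, sd: 2.0e-14}
    Cu1+: {concentration: 1.5e-19, sd: 2.0e-20}
    Zn2+:
      zur: {concentration: 6.7e-12, sd: 9.0e-13}
      zntr: {concentration: 2.9e-13, sd: 3.0e-14}
      midpoint: {concentration: 1.4e-12}
  h2o2:
    Mn2+: {concentration: 9.0e-05, sd: 2.0e-05}
    Fe2+: {concentration: 3.4e-06, boundary: true}
    Co2+: {concentration: 2.4e-11, boundary: true}
    Ni2+: {concentration: 5.0e-13, sd: 2.0e-13}
    Cu1+: {concentration: 1.1e-20, boundary: true}
    Zn2+:
      zur: {concentration: 3.2e-11, boundary: true}
      zntr: {concentration: 1.6e-13, sd: 4.0e-14}
      midpoint: {concentration: 2.2e-12}
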