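# Mean-value parameterization of the torsemide / OH-torsemide (M1) pair.
# Both compounds are very highly protein bound, so the capillary endothelium
# is treated as a true barrier: permeability scaled 0.001 in all organs
# except the fenestrated liver endothelium (0.1).
# The printed fraction unbound "1.25E-01 %" is taken literally (0.00125 as a
# fraction); see the genotype/config tables for overrides.
parent:
  name: torsemide
  fraction_unbound: {value: 1.25e-01, unit: "%"}
  lipophilicity: {value: 2.023, unit: "log"}
  molecular_weight: {value: 348.8, unit: "g/mol"}
  intestinal_permeability: {value: 1.66e-05, unit: "cm/min"}
  renal_clearance: {value: 0.0013, unit: "l/min/kg"}
  endothelial_permeability_scale:
    gut_wall: 0.001
    liver: 0.1
    kidney: 0.001
    rest: 0.001
  processes:
    - protein: CYP2C9
      kind: metabolism
      product: OH-torsemide
      kcat: {value: 20.0, unit: "1/min"}
      km: {value: 1.0, unit: "umol/l"}
    - protein: OATP1B1
      kind: transport
      product: null
      kcat: {value: 30.0, unit: "1/min"}
      km: {value: 1.0, unit: "umol/l"}
metabolite:
  name: OH-torsemide
  fraction_unbound: {value: 1.91e-01, unit: "%"}
  lipophilicity: {value: 2.139, unit: "log"}
  molecular_weight: {value: 364.42, unit: "g/mol"}
  renal_clearance: {value: 0.007, unit: "l/min/kg"}
  endothelial_permeability_scale:
    gut_wall: 0.001
    liver: 0.1
    kidney: 0.001
    rest: 0.001
  processes:
    # second, independent CYP2C9 step: M1 -> M5; M5 is not modelled, so the
    # flux drains into the terminal-metabolism ledger
    - protein: CYP2C9
      kind: metabolism
      product: null
      kcat: {value: 70.0, unit: "1/min"}
      km: {value: 1.0, unit: "umol/l"}
    - protein: OATP1B1
      kind: transport
      product: null
      kcat: {value: 50.0, unit: "1/min"}
      km: {value: 1.0, unit: "umol/l"}
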