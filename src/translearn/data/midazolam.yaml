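# Mean-value parameterization of the midazolam / 1'-OH-midazolam pair.
# Units are declared per entry and validated at load; percent fraction
# unbound is converted to a fraction exactly once by the loader.
parent:
  name: midazolam
  fraction_unbound: {value: 3.0, unit: "%"}
  lipophilicity: {value: 3.6, unit: "log"}
  molecular_weight: {value: 325.77, unit: "g/mol"}
  intestinal_permeability: {value: 5.55e-04, unit: "cm/min"}
  solubility_ref_pH: {value: 0.03, unit: "mg/ml"}
  processes:
    - protein: CYP3A4
      kind: metabolism
      product: OH-midazolam
      kcat: {value: 0.1, unit: "1/min"}
      km: {value: 2.1, unit: "umol/l"}
    - protein: ABCB1
      kind: transport
      product: null
      kcat: {value: 177.64, unit: "1/min"}
      km: {value: 40.45, unit: "umol/l"}
metabolite:
  name: OH-midazolam
  fraction_unbound: {value: 10.0, unit: "%"}
  lipophilicity: {value: 3.13, unit: "log"}
  molecular_weight: {value: 341.8, unit: "g/mol"}
  processes:
    # glucuronidation of the metabolite; the glucuronide itself is not
    # modelled, so this process drains into the terminal-metabolism ledger
    - protein: UGT1A4
      kind: metabolism
      product: null
      kcat: {value: 10.0, unit: "1/min"}
      km: {value: 1.41, unit: "umol/l"}
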