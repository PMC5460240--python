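# Diplotype -> catalytic activity multiplier applied to the kcat of the
# matching enzyme.  Only the phenotype direction is established knowledge
# (CYP2C9 *3/*3 homozygotes are poor metabolizers); the numeric factors are
# package defaults and can be overridden by pointing the loader at a
# different table.
CYP2C9:
  "*1/*1": 1.0
  "*1/*2": 0.8
  "*2/*2": 0.6
  "*1/*3": 0.6
  "*2/*3": 0.4
  "*3/*3": 0.2
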