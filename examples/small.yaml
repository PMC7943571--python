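n_species:
  GreaterAntilles: 8
  PrimaryMainland: 6
  SecondaryMainland: 7
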