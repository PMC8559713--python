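# Toy configuration: a small, fast instance of the full study design.
# Used by the end-to-end CLI example in the README and by the determinism
# checks; analysis thresholds keep their standard defaults.
simulation:
  n_genes: 120
  n_tissues: 6
  seed: 7
analysis:
  n_permutations: 300
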