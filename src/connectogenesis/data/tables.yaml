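# In-text reference tables for the first-mover analysis.

# Example strategy profile: joint probability over (synaptic role x birth
# order) for a hypothetical cell. Conformity (pre born first + post born
# second) is 0.75.
strategy_profile:
  presynaptic:
    born_first: 0.375
    born_second: 0.125
  postsynaptic:
    born_first: 0.125
    born_second: 0.375

# Newly differentiated neuron counts per cell family between the 300 min and
# 400 min developmental snapshots (87 cells total).
family_counts_300_400:
  AF: 2
  AI: 6
  AL: 1
  AS: 10
  AU: 2
  AV: 14
  AW: 2
  CEP: 3
  DV: 3
  IL1: 4
  IL2: 1
  LU: 2
  OLQ: 2
  PD: 1
  PH: 2
  PV: 5
  RI: 9
  RM: 7
  SI: 1
  SM: 4
  UR: 6

# Published frequency of each strategy in the cell population (percent), and
# the published per-strategy proportions of synaptic stability classes
# (percent; denominators not derivable from the text, carried verbatim).
strategy_frequencies_pct:
  NP: 41.5
  XOR_FIRST: 7.5
  XOR_SECOND: 18.9
  XNOR: 15.1
  PN: 45.3
strategy_stability_pct:
  NP: {transient: 38.0, developmental: 36.0, stable: 43.0}
  XOR_FIRST: {transient: 8.0, developmental: 24.0, stable: 6.0}
  XOR_SECOND: {transient: 8.0, developmental: 24.0, stable: 8.0}
  XNOR: {transient: 17.0, developmental: 24.0, stable: 13.0}
  PN: {transient: 86.2, developmental: 91.1, stable: 85.0}

# Share of each stability class among chemical synaptic connections in the
# adult connectome.
stability_class_mix:
  transient: 0.43
  developmental: 0.14
  stable: 0.43
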