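# Embryogenesis timeline constants, minutes post-fertilization.
fertilization: 0
first_neuron_birth: 265
sampling_window: [265, 400]
comma_stage: 400
axonal_outgrowth: 450
twitching: 470
pharyngeal_pumping: [760, 780]
hatch: 800

# Developmental cell-birth bursts overlapping the neuronal sampling window,
# and the quiescent window between the second and third bursts.
burst_windows:
  - [210, 285]
  - [285, 345]
  - [365, 400]
quiescent_window: [345, 365]
birth_histogram_bin_width: 8
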