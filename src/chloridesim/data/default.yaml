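# Canonical default configuration for the chloridesim model neuron.
# Lengths and diameters in micrometres. Any key may be overridden by a
# user-supplied YAML file with the same structure.
geometry:
  n_primary_dendrites: 3
  comps_per_dendrite: 10
  dend_comp_length: 20.0
  dend_diam_proximal: 2.0
  dend_diam_distal: 0.5
  soma_diameter: 20.0
  soma_length: 20.0
  ais_length: 20.0
  ais_diameter: 1.0
  include_axon: true
  n_internodes: 10
  internode_length: 100.0
  internode_diameter: 1.0
  node_length: 1.0
  node_diameter: 1.0
  n_annuli: 4
  proximal_cutoff: 100.0
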