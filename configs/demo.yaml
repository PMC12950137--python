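# Demo pipeline configuration: a small synthetic anesthesia session.
# All omitted parameters keep their defaults (see caldyn.pipeline.RunConfig).
simulation:
  n_neurons: 120
k_temporal: 5      # the five-state cut, as in the anesthesia paradigm
k_neuron: 3
seed: 1
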