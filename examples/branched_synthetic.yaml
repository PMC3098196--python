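# Branched toolbox model with multi-substrate reactions on a synthetic
# critical-like universe of ~2000 metabolites.
model: branched
synthetic:
  n_metabolites: 2000
  n_layers: 40
n_realizations: 9
seed: 1
out: results/branched_synthetic
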