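# Toolbox model on critical Galton-Watson universal trees of size ~2000;
# nine realizations pooled into one quadratic-scaling fit.
model: tree
p0: 0.25
p1: 0.5
p2: 0.25
tree_size: 2000
n_realizations: 9
seed: 1
out: results/critical_tree
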