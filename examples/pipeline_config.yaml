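# Full-pipeline configuration for `floravision run-pipeline --config ...`
# With simulate: true the inputs are generated under <output_dir>/study;
# set simulate: false and fill in `paths:` to analyse your own files.

output_dir: floravision_out
seed: 0
simulate: true

simulation:
  classes: [white, pink, yellow, green]
  taxa_per_class: 5
  replicates: 3
  hybrids: 6
  transgressive_prob: 0.25

clustering:
  # optional fixed category counts; omit to use the top elbow
  # spectral_k: 8
  # bee_k: 11
  # bird_k: 11

mantel:
  nperm: 999
  alpha: 0.05

# paths:                      # used when simulate: false
#   spectra: my/spectra_wide.csv
#   trios: my/trios.csv
#   trees: my/tree_sample.nwk
#   consensus: my/consensus.nwk
#   traits: my/traits.csv
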