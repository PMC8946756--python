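# Demo pipeline configuration: a small synthetic cohort that exercises every
# stage (synthesis -> preprocessing -> SBA + ICA -> scoring -> group
# statistics -> classification) in a few minutes on one CPU.
seed: 7
cohort:
  n_vs: 10
  n_mcs: 10
  n_sd: 4
  n_controls: 3
groupstats:
  n_permutations: 99
classify:
  models: [intensity]
  n_boot: 200
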