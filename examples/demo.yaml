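# End-to-end demo: simulate a small in vivo screen, count it, split internal
# replicates, estimate clones, run the gene test and the SSMD quality score.
# Rerunning with the same seed reproduces every output byte-for-byte.
stages:
  - simulate
  - count
  - split_replicates
  - clones
  - test
  - ssmd
seed: 7
outdir: cropscreen_demo
simulate:
  n_target_genes: 8
  guides_per_gene: 4
  n_essential: 8
  n_nonessential: 8
  n_safe_harbour: 4
  n_clones_founding: 2000
  bottleneck_fraction: 0.5
  n_generations: 6
  depth: 50000
  error_rate: 0.003
  fitness_by_gene:
    TG001: 0.6
split_replicates:
  prefix_length: 1
clones:
  exclude_top: 50
  min_reads: 10
test:
  n_perm: 5000
  lfc_threshold: 1.5
  fdr_threshold: 0.01
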