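# Desk-scale demo: simulate a small multi-tissue study and run every stage.
out_dir: results/demo
seed: 42
library: unstranded
simulation:
  n_tissues: 3
  samples_per_tissue: 8
  n_coding_genes: 40
  n_known_lincRNAs: 10
  n_true_novel_lincRNAs: 20
  n_specific_genes_per_tissue: 6
  n_snps: 1000
  snp_enrichment_odds: 6.0
min_samples: 2
min_count: 5
max_per_tissue: 100
min_log2fc: 2.0
max_fdr: 0.05
margin: 2.0
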