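# lincatlas

Novel lincRNA discovery and tissue-specific expression analysis over
transcript models and RNA-seq count matrices, at desk scale.

Large multi-tissue RNA-seq compendia hide thousands of unannotated long
intergenic non-coding RNAs (lincRNAs): transcripts longer than 200 nt that
overlap no annotated gene. Because the big compendia use unstranded library
protocols, sense/antisense relationships to coding genes cannot be resolved,
and the only lncRNA class that can be called reliably is the cleanly
intergenic one. `lincatlas` implements the full chain of that analysis for
anyone who has per-sample transcript assemblies (GTF) and a count matrix:

1. **Merge** per-sample transcript models into per-tissue consensus loci and
   consolidate tissues into one genome-wide locus set. Two models merge when
   their spans overlap and their intron chains agree (identical, or one a
   contiguous sub-chain of the other; single-exon models need >= 1 bp exon
   overlap). Clusters are the transitive closure of this relation.
2. **Classify** merged loci against the known annotation. Unstranded mode
   keeps a locus only if it has no overlap — exonic or span, either strand —
   with any known gene and its exonic length exceeds 200 bp; a stranded
   classifier (antisense / sense-intronic / sense-overlapping) is included.
   Multi-exon novel lincRNAs (junction-supported) go forward; single-exon
   calls are set aside as possible fragmentation artifacts.
3. **Quantify**: build the genes x samples count matrix (known genes + novel
   multi-exon lincRNAs), drop genes never seen above 5 reads, compute
   TMM-style scaling factors (trimmed mean of log ratios, geometric mean 1)
   and log2 CPM with a 0.5 pseudo-count.
4. **Call tissue-specific genes** one tissue vs all the rest, capping each
   tissue at 100 samples. Counts are negative binomial with per-gene
   dispersion phi estimated by method of moments and shrunk toward a trimmed
   common value; the p-value is a two-sided exact test on depth-scaled group
   sums conditional on their total. Tier 1: mean log2 CPM > 0, BH FDR < 0.05,
   one-vs-rest log2 FC > 2 (up-regulated only). Tier 2 adds a dominance rule:
   the tissue's log2 FC must exceed the maximum over all other tissues' by
   >= 2 log2 units. Sub-organ contrasts (e.g. brain subregions) reuse the
   machinery with log2 FC > 0.585 (1.5-fold).
5. **Test GWAS SNP enrichment**: map SNPs to gene spans, tabulate specific vs
   non-specific genes by ">= 1 mapped SNP", and test the 2x2 table with a
   Pearson chi-square (df = 1, no continuity correction).

A synthetic-data generator (`lincatlas.synthetic_data`) produces toy genomes,
noisy per-sample assemblies, NB count matrices with planted tissue-specific
genes, and SNP sets with planted enrichment — with the ground truth recorded —
so the whole pipeline is testable without access-controlled data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(seed 42) and write their tables under `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/02_merge_assemblies.py
python analysis/03_classify_novel.py
python analysis/04_expression_matrix.py
python analysis/05_tissue_specificity.py
python analysis/06_gwas_enrichment.py
```

Step 3 prints:

```
merged loci screened: 170
novel lincRNAs: 20 (10 multi-exon, 10 single-exon; exonic length > 200 bp, no overlap with any known gene)
novel exonic coverage: 20.0 kb
planted multi-exon truth recovered: 10/10
```

All 20 planted intergenic loci survive merging across 40 noisy per-sample
assemblies and the novelty screen, and every multi-exon one is recovered
exactly. Step 5 then calls planted 16-fold tissue markers:

```
tier-1 calls: 60; tier-2 (dominant): 60
60 of 160 genes (37.50%) are tissue-specific in at least one tissue
recovery of planted truth: sensitivity 1.000, false-discovery proportion 0.000
```

and step 6 shows SNPs planted at 8-fold odds into one tissue's specific genes
are detected as enrichment:

```
SNPs mapped to genic regions: 136/800 (17.0%)
genes with >= 1 SNP: specific 80.00% vs non-specific 33.79%
chi-square = 12.30, p = 0.000452
```

The same stages are scriptable through one config:
`lincatlas run-all --config configs/demo.yaml`, or per stage via
`lincatlas simulate|merge|classify|count|specificity|enrich`.

## Layout

- `src/lincatlas/` — the library: `genome_model` (types, intervals, GTF I/O),
  `assembly_merge`, `lncrna_classify`, `expression`, `tissue_specificity`,
  `gwas_enrichment`, `synthetic_data`, `validation` (brute-force oracles),
  `experiments` (self-contained validation experiments), `pipeline` + `cli`.
- `analysis/` — the numbered study drivers.
- `docs/methods.md` — models, estimators, thresholds, and design choices.
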