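# Methods

This note records the models, estimators, and numerical conventions behind
`lincatlas`, the parameters that matter, and what the synthetic-data
experiments do and do not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open; GTF I/O (1-based closed)
converts at the boundary and nowhere else. Chromosome names are compared as
exact strings — no "chr" normalization. Strand is `+`, `-`, or `.` (unknown);
any comparison against `.` counts as "not strand-confirmed", so an
unknown-strand locus can never be called sense or antisense, only intergenic
or excluded. A transcript is an ordered chain of non-overlapping exons on one
chromosome; its intron chain is the gap list between consecutive exons, empty
iff single-exon. Known genes carry a biotype collapsed to three tokens
(protein_coding, known_lincRNA, other_known); per-chromosome interval trees
index gene spans and union exons.

## Merging transcript models

Two transcripts are mergeable when they share a chromosome, strands do not
conflict (unknown matches either), spans overlap, and intron chains agree:
identical, or one a contiguous sub-chain of the other, or both single-exon
with >= 1 bp exon overlap. Contiguous sub-chain containment, rather than mere
exon overlap, prevents chaining unrelated genes through shared single exons —
standard assembler-merge behavior. Clusters are the transitive closure of
pairwise compatibility (union-find over a sorted sweep; verified against an
exhaustive pairwise-closure oracle).

The cluster consensus takes the union-merge of member exons; its intron chain
is the gap chain of that union. The two natural definitions — "union of
member exons" and "intron chain of the longest member" — coincide except when
a single-exon fragment sits strictly inside a retained intron; there we keep
the union, because dropping fragment bases would violate the guarantee that
no input transcript's exonic signal is lost. Consensus strand is the majority
known strand (unknown on ties); the consensus id is the first member's id by
(chrom, span start, span end, id), which makes merging order-invariant.

Tissue-level merging drops clusters supported by fewer than `min_samples`
distinct samples (default 2: recurrence across samples is the cheapest
reliability filter, and the threshold is exposed because no canonical value
exists). Cross-tissue consolidation (`meta_merge`) re-clusters the tissue
consensi with min_samples = 1, summing supports and unioning tissue labels,
and iterates to a fixed point: merging two consensi can widen a span and
create new compatibilities, and only the fixed point makes the operation
idempotent.

## Novel lincRNA classification

Unstranded mode (the default, matching unstranded library protocols): a locus
is excluded if it overlaps any known gene at all — exonic or span, either
strand — because without read strand, a locus inside an intron cannot be
separated from sense-intronic or antisense transcription. What remains is
intergenic; it is kept as a novel lincRNA if its exonic length (sum of exon
lengths, i.e. mature transcript length, not genomic span — two 100 bp exons
bridging 10 kb are a 200 bp transcript) is strictly greater than 200 bp.

Stranded mode implements the positional classes against protein-coding genes
with precedence sense_overlapping > antisense > sense_intronic (most specific
conflict wins): confirmed same-strand exonic overlap; confirmed
opposite-strand exonic overlap; fully inside an intron of a confirmed
same-strand coding gene with zero exonic overlap. Span overlaps that fit no
class (non-coding genes, unconfirmed strands, partial intron overlap) are
excluded. The ORF-based "processed transcript" class requires sequence and is
out of scope. Both modes are checked label-for-label against an independent
per-base bitmap classifier on random instances.

Downstream analysis uses only multi-exon novel lincRNAs together with known
genes: single-exon calls lack exon-junction support and can be fragments
produced during multi-GTF merging.

## Expression and normalization

Fragment counting (when counts are not supplied): a fragment is assigned to a
gene iff >= 50% of its length overlaps the gene's union exons; fragments
passing that bar for two or more genes are discarded as ambiguous. The rule
is deliberately simple, deterministic, and oracle-testable; assigned +
ambiguous + unassigned always equals the input count.

Genes are kept if some sample shows count > 5 (strict). Scaling factors are
trimmed-mean-of-log-ratios: reference = the sample whose 75th-percentile
count fraction is the median; per sample, gene-wise log2 ratios vs the
reference over genes positive in both, trimmed 30% by ratio and 5% by
abundance (rank-based), averaged with delta-method precision weights, then
renormalized to geometric mean 1. With heavily tied counts the rank trimming
can empty the kept set; the factor falls back to 1. log2 CPM =
log2((y + 0.5) / (L*f + 1) * 1e6); the 0.5 pseudo-count matters because the
expression threshold "mean log2 CPM > 0" (equivalently, average count per
million > 1) is applied to it.

## Tissue-specificity testing

Design: each tissue vs all remaining samples pooled, after capping every
tissue at 100 randomly chosen samples (without replacement, fixed seed) so no
tissue dominates the "rest".

Model: counts ~ NB with variance mu + phi*mu^2. Dispersion is estimated per
gene by method of moments on depth-scaled counts within tissue groups,
phi_g = (s^2 - mean)/mean^2 pooled across groups with df weights, clipped at
0, then shrunk toward the 25%-trimmed-mean common dispersion with weight
n_prior / (n_prior + df), n_prior = 10. With ~100+ residual df the shrinkage
is mild; it mainly stabilizes low-count genes. This deliberately reimplements
a fully specified estimator rather than reproducing any particular package's
numbers: statistical calibration, not numerical parity, is the goal, and the
calibration is measured (below).

Test: samples are scaled to the geometric-mean effective library size; group
sums are compared with a two-sided exact test conditional on the pooled sum,
accumulating all outcomes whose probability does not exceed the observed one
(relative tolerance 1e-7, the usual guard against ties in floating point).
Group sums are treated as NB with sizes n_A/phi and n_B/phi. As phi -> 0 this
reduces exactly to the conditional binomial (Poisson) test; below phi = 1e-8
the Poisson form is used directly for numerical stability. The double-tail
sum is evaluated vectorized over genes in flattened support chunks (about
2e6 points per chunk) to bound memory.

Fold change is the difference of prior-augmented mean log2 CPM between the
groups — deterministic and consistent with the CPM thresholds — rather than a
fitted GLM coefficient. FDR is Benjamini-Hochberg within each contrast (not
pooled across the 30 contrasts; per-contrast adjustment is standard
one-vs-rest practice). Tier 1 keeps genes with mean log2 CPM > 0, FDR < 0.05,
and log2 FC > 2, strict inequalities, up-regulated only. Tier 2 (the
dominance rule) additionally requires the tissue's one-vs-rest log2 FC to be
>= the per-gene maximum over all other tissues' one-vs-rest log2 FCs plus 2
log2 units — "2-fold above the maximum" read on the log2 scale; the pairwise
tissue-vs-tissue reading would need all 435 pairwise contrasts and is not
what the one-vs-rest fold-change matrix supports. Tier 2 is a subset of
tier 1 by construction.

Sub-organ analysis runs the same machinery within one organ's samples only
(subregion vs the organ's remaining subregions) with the fold threshold
relaxed to log2 FC > 0.585 (1.5-fold), since subregions of one organ are far
more alike than distinct organs. Genes called in exactly one subregion are
"unique"; genes called in two or more are "shared" and counted once.

## SNP enrichment

A SNP maps to every gene whose genic region contains its position; the genic
region is the gene span (TSS to TES of the union model) by default,
configurable to union exons — the span reading matches the spirit of
"mapped to genic regions" summaries. SNP input positions are 1-based and
converted on read. A SNP inside two overlapping genes counts for both genes'
tallies but once in the genome-level mapped total. The 2x2 table (specific /
non-specific x >= 1 SNP / none) over an explicitly supplied gene universe is
tested with Pearson's chi-square, df = 1, no continuity correction (flag
available); zero marginals raise rather than silently degrade.

## Synthetic data

The generator emulates the study design the pipeline targets. Defaults:
6 tissues x 20 samples; NB dispersion 0.1 (typical bulk RNA-seq biological
variability); baseline mean count 50 with log-normal gene abundances
(sigma = 0.5) and log-normal library-size factors (sigma = 0.3, realistic
depth spread without extremes); 50 planted specific genes per tissue at
log2 FC 4 (16-fold, the magnitude the tier-1 threshold targets); per-sample
transcript detection probability 0.8 and fragmentation probability 0.2
(a detected multi-exon transcript is replaced by 1-3 single-exon pieces of
>= 50 bp, mimicking merge artifacts); 70% of planted novel loci multi-exon;
SNP enrichment odds 4 by default. The toy genome places non-overlapping known
genes and strictly intergenic novel loci (exonic length > 200 by
construction), so planted truth passes the pipeline's own filters and
recovery can be scored exactly. Every generator draws from its own stream
seeded by (seed, per-operation offset), so changing one stage's draw count
never perturbs another stage.

What the simulations do not model: read-level error, alignment artifacts,
positional coverage bias, isoform switching, correlated library composition,
batch structure, or linkage disequilibrium between SNPs. Passing the planted
recovery experiments therefore demonstrates the correctness and calibration
of the algorithms under their stated model, not performance on real tissue
compendia.

## Validation experiments and problem sizes

`lincatlas.experiments` fixes the conditions used by the test suite and
`scripts/acceptance.py`; sizes were chosen to finish in minutes on one core
while keeping the statistics meaningful:

- classifier vs per-base oracle: 500 random loci, both library modes;
- noise-free recovery: detection 1.0, fragmentation 0, min_samples 2 — the
  recovered multi-exon set must equal the planted set exactly;
- planted-marker recovery: 2,000 genes, 6 x 20 samples, 50 markers/tissue at
  16-fold, phi = 0.1, three seeds (sensitivity and empirical FDP of tier 1);
- null calibration of the exact test: same design with nothing planted,
  fraction of p < 0.05 in one contrast;
- chi-square null: 300 genes over 2 x 8 Mb, 2,000 SNPs, odds 1, 1,000
  replicates. The genome is large enough that expected cell counts support
  the asymptotic chi-square reference. The "specific" label is redrawn each
  replicate: under the null the label must be exchangeable with SNP
  placement — a fixed label set carries a fixed span-length imbalance into
  every replicate and simulates a false null;
- merge stability: 100 random inputs, idempotence and shuffle-invariance;
- Poisson limit: 200 genes at phi = 1e-12 against the conditional binomial.

## Known limitations

- The exact test scales samples to a common library size before summing;
  as in any equalized-library exact test, extreme depth imbalance distorts
  the NB variance model slightly (calibration is verified at sigma = 0.3
  depth spread).
- Method-of-moments dispersion is noisier than likelihood-based estimators at
  very small group sizes; groups need >= 2 samples and benefit from >= 10.
- The unstranded novelty screen is conservative by design: genuinely novel
  transcripts inside known-gene introns or antisense to known exons are
  discarded, mirroring what unstranded data can support.
- The merge consensus can absorb fragmentation noise into extra exons when a
  fragment lands inside a retained intron (see above); with the default
  min_samples = 2 this is rare in practice.
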