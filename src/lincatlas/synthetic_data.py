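"""Synthetic study generator: toy genomes, noisy per-sample assemblies,
negative-binomial count matrices with planted tissue-specific genes, and SNP
sets with planted enrichment.

Every generator is deterministic under the configuration seed; each operation
draws from its own stream (seeded from cfg.seed plus a fixed per-operation
offset) so changing one stage's draw count never perturbs the others. Ground
truth (planted novel loci, planted tissue-specific genes, the SNP-enriched
gene set) is recorded so downstream stages can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .expression import CountMatrix, TissueDesign
from .genome_model import (
    FORWARD,
    KNOWN_LINCRNA,
    OTHER_KNOWN,
    PROTEIN_CODING,
    REVERSE,
    UNKNOWN,
    AnnotationCatalog,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from .gwas_enrichment import SNPRecord

# per-operation RNG stream offsets
_STREAM_GENOME = 1
_STREAM_ASSEMBLY = 2
_STREAM_COUNTS = 3
_STREAM_SNPS = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic data.

    Defaults emulate a desk-scale version of a multi-tissue RNA-seq cohort:
    a few dozen annotated genes on two small chromosomes, six tissues with
    twenty samples each, NB counts with moderate dispersion, planted
    tissue-specific up-regulation at 16-fold, and SNP sets with elevated odds
    of landing in a chosen gene set.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_coding_genes: int = 40
    n_known_lincRNAs: int = 10
    n_true_novel_lincRNAs: int = 20
    n_tissues: int = 6
    samples_per_tissue: int = 20
    transcript_detection_prob: float = 0.8
    fragmentation_prob: float = 0.2
    nb_dispersion: float = 0.1
    baseline_mean_count: float = 50.0
    n_specific_genes_per_tissue: int = 50
    specific_log2fc: float = 4.0
    n_snps: int = 2000
    snp_enrichment_odds: float = 4.0
    multi_exon_fraction: float = 0.7
    libsize_sigma: float = 0.3
    gene_abundance_sigma: float = 0.5
    min_fragment_len: int = 50

    def __post_init__(self) -> None:
        for name in ("transcript_detection_prob", "fragmentation_prob",
                     "multi_exon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_coding_genes",
                     "n_known_lincRNAs", "n_true_novel_lincRNAs", "n_tissues",
                     "samples_per_tissue", "n_specific_genes_per_tissue",
                     "n_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nb_dispersion", "baseline_mean_count",
                     "snp_enrichment_odds", "libsize_sigma",
                     "gene_abundance_sigma"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not math.isfinite(self.specific_log2fc):
            raise ValueError("specific_log2fc must be finite")


@dataclass
class GroundTruth:
    """What was planted, for scoring the pipeline's recoveries."""

    true_novel_loci: list[TranscriptModel] = field(default_factory=list)
    specific_gene_map: dict[str, set[str]] = field(default_factory=dict)
    enriched_gene_set: set[str] = field(default_factory=set)


def _rng(cfg: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, offset])


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, strand: str,
    n_exons: int, exon_len_range: tuple[int, int], intron_len_range: tuple[int, int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    cur = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len_range))
        exons.append(GenomicInterval(chrom, cur, cur + length, strand))
        cur += length
        if i < n_exons - 1:
            cur += int(rng.integers(*intron_len_range))
    return tuple(exons)


def make_genome(cfg: SimulationConfig) -> tuple[AnnotationCatalog, GroundTruth]:
    """Place non-overlapping known genes and strictly intergenic true novel
    lincRNA loci (exonic length > 200 bp, a configurable fraction multi-exon)
    on the toy chromosomes. Deterministic under seed."""
    rng = _rng(cfg, _STREAM_GENOME)
    specs = (
        [("coding", i) for i in range(cfg.n_coding_genes)]
        + [("known_linc", i) for i in range(cfg.n_known_lincRNAs)]
        + [("novel", i) for i in range(cfg.n_true_novel_lincRNAs)]
    )
    rng.shuffle(specs)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom: dict[str, list] = {c: [] for c in chroms}
    for i, spec in enumerate(specs):
        per_chrom[chroms[i % len(chroms)]].append(spec)

    genes: list[GeneModel] = []
    novel: list[TranscriptModel] = []
    for chrom in chroms:
        cursor = int(rng.integers(1_000, 5_000))
        for kind, idx in per_chrom[chrom]:
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            if kind == "coding":
                n_ex = int(rng.integers(2, 9))
                exons = _make_exons(rng, chrom, cursor, strand, n_ex,
                                    (100, 501), (200, 2001))
            elif kind == "known_linc":
                n_ex = int(rng.integers(1, 4))
                exons = _make_exons(rng, chrom, cursor, strand, n_ex,
                                    (200, 801), (200, 1501))
            else:
                if rng.random() < cfg.multi_exon_fraction:
                    n_ex = int(rng.integers(2, 5))
                    exons = _make_exons(rng, chrom, cursor, strand, n_ex,
                                        (150, 601), (200, 1501))
                else:
                    exons = _make_exons(rng, chrom, cursor, strand, 1,
                                        (300, 1501), (0, 1))
            end = exons[-1].end
            if end > cfg.chrom_length:
                raise ValueError(
                    "genome too small to place requested genes without overlap; "
                    "increase chrom_length or n_chroms"
                )
            if kind == "coding":
                gid = f"PCG{idx + 1:04d}"
                genes.append(GeneModel(gid, PROTEIN_CODING, (TranscriptModel(
                    f"{gid}.t1", chrom, strand, exons, source="annotation"),)))
            elif kind == "known_linc":
                gid = f"KLINC{idx + 1:04d}"
                genes.append(GeneModel(gid, KNOWN_LINCRNA, (TranscriptModel(
                    f"{gid}.t1", chrom, strand, exons, source="annotation"),)))
            else:
                tid = f"NOVEL{idx + 1:04d}"
                novel.append(TranscriptModel(tid, chrom, strand, exons,
                                             source="truth"))
            cursor = end + int(rng.integers(2_000, 10_001))
    novel.sort(key=lambda t: (t.chrom, t.span.start, t.id))
    return AnnotationCatalog(genes), GroundTruth(true_novel_loci=novel)


def make_design(cfg: SimulationConfig) -> TissueDesign:
    """Tissue labels tissue01.. with samples_per_tissue samples each."""
    labels = {}
    for ti in range(cfg.n_tissues):
        tissue = f"tissue{ti + 1:02d}"
        for si in range(cfg.samples_per_tissue):
            labels[f"{tissue}_s{si + 1:02d}"] = tissue
    return TissueDesign(labels)


def _fragments_of(
    rng: np.random.Generator, t: TranscriptModel, sample: str, min_len: int
) -> list[TranscriptModel]:
    """Replace a detected multi-exon transcript by 1-3 single-exon sub-pieces
    (>= min_len bp each) of randomly chosen exons, emulating assembly
    fragmentation. Fragments carry unknown strand."""
    k = int(rng.integers(1, 4))
    frags = []
    for i in range(k):
        ex = t.exons[int(rng.integers(0, len(t.exons)))]
        if ex.length <= min_len:
            s, e = ex.start, ex.end
        else:
            length = int(rng.integers(min_len, ex.length + 1))
            s = ex.start + int(rng.integers(0, ex.length - length + 1))
            e = s + length
        frags.append(
            TranscriptModel(
                id=f"{sample}.{t.id}.frag{i + 1}",
                chrom=t.chrom,
                strand=UNKNOWN,
                exons=(GenomicInterval(t.chrom, s, e, UNKNOWN),),
                source=sample,
            )
        )
    return frags


def simulate_assemblies(
    catalog: AnnotationCatalog, truth: GroundTruth, cfg: SimulationConfig
) -> dict[str, dict[str, list[TranscriptModel]]]:
    """Per-tissue, per-sample transcript models.

    Each sample independently detects each true novel locus (and each known
    transcript) with ``transcript_detection_prob``; a detected multi-exon novel
    transcript is, with ``fragmentation_prob``, replaced by 1-3 single-exon
    fragments of its exons. Known transcripts are emitted intact so the
    downstream novelty filter is exercised.
    """
    rng = _rng(cfg, _STREAM_ASSEMBLY)
    design = make_design(cfg)
    known = [t for g in catalog for t in g.transcripts]
    out: dict[str, dict[str, list[TranscriptModel]]] = {}
    for tissue in design.tissues:
        out[tissue] = {}
        for sample in design.samples_for(tissue):
            models: list[TranscriptModel] = []
            for t in truth.true_novel_loci:
                if rng.random() >= cfg.transcript_detection_prob:
                    continue
                if t.is_multi_exon and rng.random() < cfg.fragmentation_prob:
                    models.extend(
                        _fragments_of(rng, t, sample, cfg.min_fragment_len)
                    )
                else:
                    models.append(replace(t, id=f"{sample}.{t.id}", source=sample))
            for t in known:
                if rng.random() < cfg.transcript_detection_prob:
                    models.append(replace(t, id=f"{sample}.{t.id}", source=sample))
            models.sort(key=lambda m: (m.chrom, m.span.start, m.id))
            out[tissue][sample] = models
    return out


class CountSimulation(NamedTuple):
    matrix: CountMatrix
    specific_gene_map: dict[str, set[str]]
    lib_factor: dict[str, float]


def simulate_counts(
    gene_ids: Sequence[str],
    design: TissueDesign,
    cfg: SimulationConfig,
    specific_gene_map: dict[str, set[str]] | None = None,
) -> CountSimulation:
    """NB counts with planted tissue-specific up-regulation.

    Gene relative abundances are log-normal (sigma = gene_abundance_sigma,
    mean 1); per-sample library factors are log-normal (sigma = libsize_sigma).
    mu_gs = baseline_mean_count * r_g * f_s, multiplied by 2**specific_log2fc
    for planted (gene, tissue) pairs; counts ~ NB(mu, nb_dispersion)
    (Poisson when the dispersion is 0). If no planting map is given, each
    tissue receives ``n_specific_genes_per_tissue`` distinct genes (disjoint
    across tissues).
    """
    rng = _rng(cfg, _STREAM_COUNTS)
    gene_ids = list(gene_ids)
    samples = design.sample_ids
    tissues = design.tissues
    if specific_gene_map is None:
        need = cfg.n_specific_genes_per_tissue * len(tissues)
        if need > len(gene_ids):
            raise ValueError("not enough genes to plant disjoint specific sets")
        perm = rng.permutation(len(gene_ids))
        specific_gene_map = {}
        for ti, tissue in enumerate(tissues):
            block = perm[
                ti * cfg.n_specific_genes_per_tissue:
                (ti + 1) * cfg.n_specific_genes_per_tissue
            ]
            specific_gene_map[tissue] = {gene_ids[i] for i in block}

    r = rng.lognormal(mean=0.0, sigma=cfg.gene_abundance_sigma, size=len(gene_ids))
    f = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=len(samples))
    mu = cfg.baseline_mean_count * np.outer(r, f)
    fc = 2.0 ** cfg.specific_log2fc
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for tissue, genes in specific_gene_map.items():
        cols = [j for j, s in enumerate(samples) if design.labels[s] == tissue]
        rows = [gene_pos[g] for g in genes if g in gene_pos]
        if rows and cols:
            mu[np.ix_(rows, cols)] *= fc
    if cfg.nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    matrix = CountMatrix(gene_ids, list(samples), counts.astype(np.int64))
    return CountSimulation(matrix, specific_gene_map,
                           dict(zip(samples, f.tolist())))


def simulate_snps(
    catalog: AnnotationCatalog, truth: GroundTruth, cfg: SimulationConfig
) -> list[SNPRecord]:
    """SNP positions over the toy genome with odds of landing inside the
    spans of ``truth.enriched_gene_set`` elevated by ``snp_enrichment_odds``
    (odds 1 = uniform). Each SNP carries a synthetic GWAS p-value."""
    rng = _rng(cfg, _STREAM_SNPS)
    chroms = sorted({g.chrom for g in catalog}) or [
        f"chr{i + 1}" for i in range(cfg.n_chroms)
    ]
    genome_len = cfg.chrom_length * len(chroms)
    spans = [
        (g.chrom, g.span.start, g.span.end)
        for g in catalog
        if g.id in truth.enriched_gene_set
    ]
    enriched_len = sum(e - s for _, s, e in spans)
    other_len = genome_len - enriched_len
    odds = cfg.snp_enrichment_odds
    p_enriched = (
        odds * enriched_len / (odds * enriched_len + other_len)
        if enriched_len
        else 0.0
    )
    span_cum = np.cumsum([e - s for _, s, e in spans]) if spans else None
    snps = []
    for i in range(cfg.n_snps):
        if rng.random() < p_enriched:
            # uniform over the enriched spans
            off = int(rng.integers(0, span_cum[-1]))
            k = int(np.searchsorted(span_cum, off, side="right"))
            prev = 0 if k == 0 else int(span_cum[k - 1])
            chrom, s, _e = spans[k]
            pos = s + (off - prev)
        else:
            # uniform over the genome (rejection keeps it out of no region;
            # the complement is dominated by intergenic space)
            while True:
                off = int(rng.integers(0, genome_len))
                chrom = chroms[off // cfg.chrom_length]
                pos = off % cfg.chrom_length
                if not any(
                    c == chrom and s <= pos < e for c, s, e in spans
                ):
                    break
        gwas_p = float(10.0 ** (-rng.uniform(0.5, 12.0)))
        snps.append(SNPRecord(chrom=chrom, pos=pos, id=f"rs{i + 1:06d}",
                              gwas_p=gwas_p))
    return snps
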