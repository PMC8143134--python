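"""Independent brute-force reference computations.

These deliberately avoid the interval-index / sweep / vectorized code paths of
the main modules: classification is done per base on explicit bitmaps,
clustering by exhaustive pairwise closure, overlap and coverage on boolean
arrays, and the BH adjustment by the literal step-up definition. They exist to
cross-check the fast implementations on randomly generated instances.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .assembly_merge import MergedLocus, compatible
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
from .lncrna_classify import (
    ANTISENSE,
    EXCLUDED,
    LINCRNA,
    SENSE_INTRONIC,
    SENSE_OVERLAPPING,
)


def bitmap_overlap_bases(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]], length: int
) -> int:
    """Shared bases between two interval sets via per-base boolean arrays."""
    av = np.zeros(length, dtype=bool)
    bv = np.zeros(length, dtype=bool)
    for s, e in a:
        av[s:e] = True
    for s, e in b:
        bv[s:e] = True
    return int((av & bv).sum())


def bitmap_coverage(loci: Sequence[TranscriptModel], length: int) -> int:
    """Union of exonic bases across loci via a per-base bitmap (one chrom)."""
    v = np.zeros(length, dtype=bool)
    for t in loci:
        for s, e in t.exon_pairs():
            v[s:e] = True
    return int(v.sum())


def brute_force_clusters(
    models: Sequence[TranscriptModel],
) -> list[frozenset[str]]:
    """Transitive closure of pairwise compatibility by repeated sweeps over
    all pairs (no union-find, no sorting tricks). Returns id sets."""
    groups: list[set[int]] = [{i} for i in range(len(models))]
    changed = True
    while changed:
        changed = False
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                if not compatible(models[i], models[j]):
                    continue
                gi = next(g for g in groups if i in g)
                gj = next(g for g in groups if j in g)
                if gi is not gj:
                    gi |= gj
                    groups.remove(gj)
                    changed = True
    return sorted(
        (frozenset(models[i].id for i in g) for g in groups), key=sorted
    )


def brute_force_classify(
    locus: MergedLocus | TranscriptModel,
    catalog: AnnotationCatalog,
    chrom_length: int,
    library: str = "unstranded",
) -> str:
    """Per-base reimplementation of the positional classifier.

    Builds explicit base masks for gene spans, coding exons (per strand), and
    coding introns, then applies the category rules by inspecting the locus's
    bases directly.
    """
    t = locus.consensus if isinstance(locus, MergedLocus) else locus
    span_any = np.zeros(chrom_length, dtype=bool)
    for g in catalog:
        if g.chrom == t.chrom:
            span_any[g.span.start:g.span.end] = True

    locus_span = np.zeros(chrom_length, dtype=bool)
    locus_span[t.span.start:t.span.end] = True
    locus_exonic = np.zeros(chrom_length, dtype=bool)
    for s, e in t.exon_pairs():
        locus_exonic[s:e] = True

    if not (span_any & locus_span).any():
        return LINCRNA
    if library == "unstranded":
        return EXCLUDED

    coding = [g for g in catalog if g.chrom == t.chrom and g.biotype == PROTEIN_CODING]

    def exon_mask(g: GeneModel) -> np.ndarray:
        v = np.zeros(chrom_length, dtype=bool)
        for s, e in g.union_exons:
            v[s:e] = True
        return v

    same = [g for g in coding if t.strand != UNKNOWN and g.strand == t.strand]
    opposite = [
        g for g in coding
        if t.strand != UNKNOWN and g.strand != UNKNOWN and g.strand != t.strand
    ]
    if any((exon_mask(g) & locus_exonic).any() for g in same):
        return SENSE_OVERLAPPING
    if any((exon_mask(g) & locus_exonic).any() for g in opposite):
        return ANTISENSE
    for g in same:
        if (exon_mask(g) & locus_exonic).any():
            continue
        for s, e in g.union_introns:
            intron = np.zeros(chrom_length, dtype=bool)
            intron[s:e] = True
            if (intron & locus_span).sum() == locus_span.sum():
                return SENSE_INTRONIC
    return EXCLUDED


def brute_force_bh(p: Sequence[float]) -> np.ndarray:
    """Literal BH step-up: q_(i) = min over j>=i of p_(j) * n / j, capped."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------------------
# random instance generators for the oracle checks
# ---------------------------------------------------------------------------

def random_catalog(
    rng: np.random.Generator,
    chrom_length: int = 50_000,
    n_genes: int = 8,
    chrom: str = "chr1",
) -> AnnotationCatalog:
    """A random catalog of possibly closely spaced genes on one chromosome."""
    genes = []
    cursor = int(rng.integers(0, 2_000))
    for i in range(n_genes):
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        n_ex = int(rng.integers(1, 5))
        exons = []
        cur = cursor
        for k in range(n_ex):
            length = int(rng.integers(80, 400))
            exons.append(GenomicInterval(chrom, cur, cur + length, strand))
            cur += length + (int(rng.integers(100, 900)) if k < n_ex - 1 else 0)
        if cur >= chrom_length - 4_000:
            break
        biotype = [PROTEIN_CODING, KNOWN_LINCRNA, OTHER_KNOWN][
            int(rng.integers(0, 3))
        ]
        gid = f"G{i + 1:03d}"
        genes.append(
            GeneModel(gid, biotype, (TranscriptModel(
                f"{gid}.t1", chrom, strand, tuple(exons), source="ann"),))
        )
        cursor = cur + int(rng.integers(200, 2_500))
    return AnnotationCatalog(genes)


def random_locus(
    rng: np.random.Generator,
    chrom_length: int = 50_000,
    chrom: str = "chr1",
) -> TranscriptModel:
    """A random query transcript anywhere on the chromosome (any strand,
    including unknown), 1-4 exons."""
    strand = [FORWARD, REVERSE, UNKNOWN][int(rng.integers(0, 3))]
    n_ex = int(rng.integers(1, 5))
    start = int(rng.integers(0, chrom_length - 6_000))
    exons = []
    cur = start
    for k in range(n_ex):
        length = int(rng.integers(60, 500))
        exons.append(GenomicInterval(chrom, cur, cur + length, strand))
        cur += length + (int(rng.integers(80, 800)) if k < n_ex - 1 else 0)
    return TranscriptModel("q", chrom, strand, tuple(exons), source="query")


def random_transcript_set(
    rng: np.random.Generator,
    n: int = 12,
    chrom_length: int = 30_000,
    chrom: str = "chr1",
) -> list[TranscriptModel]:
    """Random overlapping transcripts for merge-oracle checks."""
    out = []
    for i in range(n):
        t = random_locus(rng, chrom_length=chrom_length, chrom=chrom)
        out.append(
            TranscriptModel(
                f"t{i + 1:03d}", t.chrom, t.strand, t.exons,
                source=f"s{int(rng.integers(1, 6))}",
            )
        )
    return out
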