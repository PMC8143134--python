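"""Positional classification of merged loci against the known annotation.

Five positional lncRNA categories are distinguished by overlap geometry and
strand relative to annotated genes. With an unstranded RNA-seq library the
read strand is lost, so sense/antisense relationships cannot be resolved: the
only class that can be called reliably is the long intergenic non-coding RNA
(lincRNA), a locus with no overlap (exonic or span, either strand) with any
annotated gene and a mature (exonic) length above 200 bp. The pipeline default
is therefore unstranded mode; the stranded classifier is implemented for
stranded assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .assembly_merge import MergedLocus
from .genome_model import (
    PROTEIN_CODING,
    AnnotationCatalog,
    GeneModel,
    TranscriptModel,
    exonic_overlap_bases,
    opposite_strand_confirmed,
    same_strand_confirmed,
)

LINCRNA = "lincRNA"
ANTISENSE = "antisense"
SENSE_INTRONIC = "sense_intronic"
SENSE_OVERLAPPING = "sense_overlapping"
EXCLUDED = "known_overlap_excluded"
CATEGORIES = (LINCRNA, ANTISENSE, SENSE_INTRONIC, SENSE_OVERLAPPING, EXCLUDED)

SINGLE_EXON = "single_exon"
MULTI_EXON = "multi_exon"


@dataclass(frozen=True)
class NovelLocus:
    locus: MergedLocus
    category: str
    exon_status: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        expected = MULTI_EXON if self.locus.consensus.is_multi_exon else SINGLE_EXON
        if self.exon_status != expected:
            raise ValueError("exon_status inconsistent with consensus exon count")

    @property
    def id(self) -> str:
        return self.locus.consensus.id


def _fully_in_intron(t: TranscriptModel, gene: GeneModel) -> bool:
    sp = t.span
    return any(s <= sp.start and sp.end <= e for s, e in gene.union_introns)


def classify_locus(
    locus: MergedLocus | TranscriptModel,
    catalog: AnnotationCatalog,
    library: str = "unstranded",
) -> str:
    """Assign a positional category to one merged locus.

    Unstranded mode: any overlap (exonic or span, either strand) with any
    known gene excludes the locus (``known_overlap_excluded``); otherwise it
    is a lincRNA candidate.

    Stranded mode: no gene-span overlap at all → lincRNA; otherwise, against
    protein-coding genes only, with precedence
    sense_overlapping > antisense > sense_intronic:
    confirmed same-strand exonic overlap → sense_overlapping; confirmed
    opposite-strand exonic overlap → antisense; fully inside an intron of a
    confirmed same-strand coding gene with zero exonic overlap →
    sense_intronic. A span overlap that fits none of these (non-coding gene,
    unconfirmed strand, or partial intronic overlap) is excluded.
    """
    t = locus.consensus if isinstance(locus, MergedLocus) else locus
    sp = t.span
    overlapping = catalog.query_spans(t.chrom, sp.start, sp.end)
    if not overlapping:
        return LINCRNA
    if library == "unstranded":
        return EXCLUDED
    if library != "stranded":
        raise ValueError(f"invalid library {library!r}")
    coding = [g for g in overlapping if g.biotype == PROTEIN_CODING]
    if any(
        exonic_overlap_bases(t, g) > 0 and same_strand_confirmed(t.strand, g.strand)
        for g in coding
    ):
        return SENSE_OVERLAPPING
    if any(
        exonic_overlap_bases(t, g) > 0
        and opposite_strand_confirmed(t.strand, g.strand)
        for g in coding
    ):
        return ANTISENSE
    if any(
        same_strand_confirmed(t.strand, g.strand)
        and exonic_overlap_bases(t, g) == 0
        and _fully_in_intron(t, g)
        for g in coding
    ):
        return SENSE_INTRONIC
    return EXCLUDED


def filter_novel_lincRNAs(
    loci: Sequence[MergedLocus],
    catalog: AnnotationCatalog,
    min_exonic_length: int = 201,
    library: str = "unstranded",
) -> list[NovelLocus]:
    """Keep loci classified lincRNA whose exonic length is at least
    ``min_exonic_length`` (default 201 bp, i.e. strictly > 200), and assign
    single-/multi-exon status. Deterministic (chrom, start, id) order."""
    out = []
    for ml in sorted(
        loci, key=lambda l: (l.consensus.chrom, l.consensus.span.start, l.consensus.id)
    ):
        if ml.consensus.exonic_length < min_exonic_length:
            continue
        if classify_locus(ml, catalog, library=library) != LINCRNA:
            continue
        status = MULTI_EXON if ml.consensus.is_multi_exon else SINGLE_EXON
        out.append(NovelLocus(locus=ml, category=LINCRNA, exon_status=status))
    return out


def split_by_exon_status(
    novel: Iterable[NovelLocus],
) -> tuple[list[NovelLocus], list[NovelLocus]]:
    """Partition into (multi_exon, single_exon). Only the multi-exon set — the
    loci with exon-junction support — joins known genes downstream; single-exon
    calls can be fragmentation artifacts of the multi-GTF merge."""
    multi = [n for n in novel if n.exon_status == MULTI_EXON]
    single = [n for n in novel if n.exon_status == SINGLE_EXON]
    return multi, single


def category_summary(loci: Sequence[NovelLocus]) -> dict[str, int]:
    """Counts per (category, exon_status) for the summary TSV."""
    out: dict[str, int] = {}
    for n in loci:
        key = f"{n.category}.{n.exon_status}"
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
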