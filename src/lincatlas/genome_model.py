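"""Core genomic data types, interval arithmetic, and GTF/BED/TSV I/O.

All internal coordinates are 0-based half-open ``[start, end)``. GTF input and
output (1-based, closed) are converted at the boundary, nowhere else. Strand is
one of ``"+"``, ``"-"``, ``"."`` (unknown); any strand comparison against ``"."``
counts as not-same-strand-confirmed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from intervaltree import IntervalTree

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."
STRANDS = (FORWARD, REVERSE, UNKNOWN)

PROTEIN_CODING = "protein_coding"
KNOWN_LINCRNA = "known_lincRNA"
OTHER_KNOWN = "other_known"
BIOTYPES = (PROTEIN_CODING, KNOWN_LINCRNA, OTHER_KNOWN)

# Ensembl biotype strings that count as lincRNA for our purposes.
_LINC_BIOTYPES = {"lincRNA", "lncRNA", "known_lincRNA"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = UNKNOWN

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def same_strand_confirmed(a: str, b: str) -> bool:
    """True only when both strands are known and equal."""
    return a != UNKNOWN and a == b


def opposite_strand_confirmed(a: str, b: str) -> bool:
    """True only when both strands are known and differ."""
    return a != UNKNOWN and b != UNKNOWN and a != b


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge (start, end) pairs into sorted disjoint intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _pairwise_overlap_bases(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Shared bases between two sorted disjoint interval sets (linear sweep)."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on one chromosome/strand; the unit of merging and
    classification.

    ``exons`` must be sorted by start, pairwise non-overlapping, and share the
    transcript's chrom/strand.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        if self.strand not in STRANDS:
            raise ValueError(f"transcript {self.id}: invalid strand {self.strand!r}")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.id}: exon on {ex.chrom}, expected {self.chrom}"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered gaps between consecutive exons; empty iff single-exon."""
        return tuple(
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) >= 2

    def exon_pairs(self) -> list[tuple[int, int]]:
        return [(ex.start, ex.end) for ex in self.exons]


@dataclass(frozen=True)
class GeneModel:
    """A known gene: one or more transcripts with a biotype."""

    id: str
    biotype: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.id}: invalid biotype {self.biotype!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.id}: transcripts on multiple chromosomes")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        strands = {t.strand for t in self.transcripts}
        return strands.pop() if len(strands) == 1 else UNKNOWN

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def union_exons(self) -> list[tuple[int, int]]:
        """Merged union of all transcript exons, sorted and disjoint."""
        return merge_intervals(
            (ex.start, ex.end) for t in self.transcripts for ex in t.exons
        )

    @property
    def union_introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive union exons."""
        ue = self.union_exons
        return [(ue[i][1], ue[i + 1][0]) for i in range(len(ue) - 1)]


class AnnotationCatalog:
    """Known genes with per-chromosome interval indexes over gene spans and
    union exons."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.span.start, g.span.end, g.id)
        )
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in catalog")
        self._by_id = {g.id: g for g in self.genes}
        self._span_index: dict[str, IntervalTree] = {}
        self._exon_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._span_index.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )
            tree = self._exon_index.setdefault(g.chrom, IntervalTree())
            for s, e in g.union_exons:
                tree.addi(s, e, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def query_spans(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span intersects [start, end) on chrom."""
        tree = self._span_index.get(chrom)
        if tree is None:
            return []
        hits = {iv.data.id: iv.data for iv in tree.overlap(start, end)}
        return sorted(hits.values(), key=lambda g: (g.span.start, g.id))

    def query_exons(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes with at least one union exon intersecting [start, end)."""
        tree = self._exon_index.get(chrom)
        if tree is None:
            return []
        hits = {iv.data.id: iv.data for iv in tree.overlap(start, end)}
        return sorted(hits.values(), key=lambda g: (g.span.start, g.id))


class Overlap(NamedTuple):
    bases: int
    opposite_strand: bool


def exonic_overlap_bases(a: TranscriptModel, b: GeneModel) -> int:
    """Bases shared between a's exons and b's union exons (0 if chroms differ)."""
    if a.chrom != b.chrom:
        return 0
    return _pairwise_overlap_bases(a.exon_pairs(), b.union_exons)


def exonic_overlap(a: TranscriptModel, b: GeneModel) -> Overlap:
    """As :func:`exonic_overlap_bases` but flagging confirmed opposite strands."""
    return Overlap(
        exonic_overlap_bases(a, b), opposite_strand_confirmed(a.strand, b.strand)
    )


class Coverage(NamedTuple):
    total: int
    per_chrom: dict[str, int]


def genome_coverage(loci: Iterable[TranscriptModel]) -> Coverage:
    """Size of the merged union of all exonic intervals, with a per-chromosome
    breakdown. Idempotent under duplication and monotone under addition."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in loci:
        by_chrom.setdefault(t.chrom, []).extend(t.exon_pairs())
    per_chrom = {
        chrom: sum(e - s for s, e in merge_intervals(ivs))
        for chrom, ivs in sorted(by_chrom.items())
    }
    return Coverage(sum(per_chrom.values()), per_chrom)


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl attribute dialect; 1-based closed coordinates on disk)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def _parse_exon_lines(path: str | Path):
    """Yield (line_no, chrom, start0, end, strand, attrs) for exon features."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {line_no}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GTF line {line_no}: non-integer coordinate"
                ) from exc
            if end_i < start_i:
                raise ValueError(
                    f"{path}: line {line_no}: exon end {end_i} < start {start_i}"
                )
            if strand not in STRANDS:
                raise ValueError(
                    f"{path}: line {line_no}: invalid strand {strand!r}"
                )
            parsed = _parse_attributes(attrs)
            if "transcript_id" not in parsed:
                raise ValueError(
                    f"{path}: line {line_no}: exon without transcript_id attribute"
                )
            yield line_no, chrom, start_i - 1, end_i, strand, parsed


def _group_transcripts(records, path) -> tuple[list[TranscriptModel], dict[str, dict]]:
    """Group parsed exon records into TranscriptModel, keeping gene metadata."""
    exons_by_tid: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for line_no, chrom, start, end, strand, attrs in records:
        tid = attrs["transcript_id"]
        info = meta.setdefault(
            tid,
            {
                "chrom": chrom,
                "strand": strand,
                "gene_id": attrs.get("gene_id", tid),
                "biotype": attrs.get("gene_biotype", attrs.get("gene_type")),
            },
        )
        if chrom != info["chrom"]:
            raise ValueError(
                f"{path}: line {line_no}: transcript {tid} has exons on multiple "
                f"chromosomes ({info['chrom']}, {chrom})"
            )
        exons_by_tid.setdefault(tid, []).append((start, end, strand))
    transcripts = []
    for tid, exons in exons_by_tid.items():
        info = meta[tid]
        exons.sort()
        strand = info["strand"]
        transcripts.append(
            TranscriptModel(
                id=tid,
                chrom=info["chrom"],
                strand=strand,
                exons=tuple(
                    GenomicInterval(info["chrom"], s, e, strand) for s, e, _ in exons
                ),
                source=str(Path(path).stem),
            )
        )
    return transcripts, meta


def _biotype_token(raw: str | None) -> str:
    if raw is None:
        return OTHER_KNOWN
    if raw == PROTEIN_CODING:
        return PROTEIN_CODING
    if raw in _LINC_BIOTYPES:
        return KNOWN_LINCRNA
    return OTHER_KNOWN


def read_gtf(
    path: str | Path, mode: str = "assembly"
) -> AnnotationCatalog | list[TranscriptModel]:
    """Read a GTF file.

    mode="assembly" returns a list of TranscriptModel (source = file stem).
    mode="known_annotation" groups transcripts by gene_id into GeneModel with
    the biotype taken from a gene_biotype/gene_type attribute (absent →
    other_known) and returns an AnnotationCatalog.
    """
    if mode not in ("assembly", "known_annotation"):
        raise ValueError(f"invalid mode {mode!r}")
    transcripts, meta = _group_transcripts(_parse_exon_lines(path), path)
    if mode == "assembly":
        return sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.id))
    by_gene: dict[str, list[TranscriptModel]] = {}
    biotype_by_gene: dict[str, str] = {}
    for t in transcripts:
        gid = meta[t.id]["gene_id"]
        by_gene.setdefault(gid, []).append(t)
        biotype_by_gene.setdefault(gid, _biotype_token(meta[t.id]["biotype"]))
    genes = [
        GeneModel(
            id=gid,
            biotype=biotype_by_gene[gid],
            transcripts=tuple(sorted(ts, key=lambda t: (t.span.start, t.id))),
        )
        for gid, ts in by_gene.items()
    ]
    return AnnotationCatalog(genes)


def _format_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)


def write_gtf(
    loci: Iterable[TranscriptModel],
    path: str | Path,
    gene_ids: dict[str, str] | None = None,
    extra_attrs: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write transcript models as a 1-based closed GTF, deterministically
    ordered by (chrom, span start, id).

    ``gene_ids`` maps transcript id → gene_id (default: the transcript id);
    ``extra_attrs`` maps transcript id → extra attribute dict.
    """
    loci = sorted(loci, key=lambda t: (t.chrom, t.span.start, t.id))
    with open(path, "w") as fh:
        fh.write("#gtf produced by lincatlas; 1-based closed coordinates\n")
        for t in loci:
            gid = (gene_ids or {}).get(t.id, t.id)
            extra = (extra_attrs or {}).get(t.id, {})
            for ex in t.exons:
                attrs = _format_attrs(gene_id=gid, transcript_id=t.id, **extra)
                fh.write(
                    f"{t.chrom}\tlincatlas\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def write_annotation_gtf(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write a known-gene catalog with gene_biotype attributes (round-trips
    through read_gtf(mode="known_annotation"))."""
    # invert biotype token back to an Ensembl-style string
    token_to_raw = {PROTEIN_CODING: "protein_coding", KNOWN_LINCRNA: "lincRNA",
                    OTHER_KNOWN: "misc_RNA"}
    transcripts = []
    gene_ids = {}
    extra = {}
    for g in catalog:
        for t in g.transcripts:
            transcripts.append(t)
            gene_ids[t.id] = g.id
            extra[t.id] = {"gene_biotype": token_to_raw[g.biotype]}
    write_gtf(transcripts, path, gene_ids=gene_ids, extra_attrs=extra)


def write_bed6(
    loci: Iterable[TranscriptModel], path: str | Path,
    names: dict[str, str] | None = None,
) -> None:
    """BED6 export of transcript spans (0-based half-open, as BED requires)."""
    loci = sorted(loci, key=lambda t: (t.chrom, t.span.start, t.id))
    with open(path, "w") as fh:
        for t in loci:
            name = (names or {}).get(t.id, t.id)
            sp = t.span
            fh.write(f"{t.chrom}\t{sp.start}\t{sp.end}\t{name}\t0\t{t.strand}\n")
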