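"""Two-level transcript-model merging.

Per-sample transcript models are clustered into per-tissue consensus loci
(:func:`merge_transcripts`), and the per-tissue sets are consolidated into one
genome-wide meta set (:func:`meta_merge`).

Two transcripts are *compatible* (mergeable) when they sit on the same
chromosome, strands do not conflict (unknown matches either), their spans
overlap, and their intron chains agree: identical, or one chain is a contiguous
sub-chain of the other (a single-exon transcript has the empty chain and is
compatible with any overlapping chain), or both are single-exon with >=1 bp of
exon overlap. Clusters are the transitive closure of pairwise compatibility.
Requiring intron-chain containment rather than mere exon overlap prevents
chaining unrelated genes through shared single exons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .genome_model import (
    UNKNOWN,
    GenomicInterval,
    TranscriptModel,
    merge_intervals,
)


@dataclass(frozen=True)
class MergedLocus:
    """A merged transcript cluster: consensus model plus support bookkeeping."""

    consensus: TranscriptModel
    n_supporting_samples: int
    source_tissues: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_supporting_samples < 1:
            raise ValueError("a merged locus needs >= 1 supporting sample")


def _strands_mergeable(a: str, b: str) -> bool:
    return a == UNKNOWN or b == UNKNOWN or a == b


def _is_contiguous_subchain(
    short: Sequence[tuple[int, int]], long: Sequence[tuple[int, int]]
) -> bool:
    if not short:
        return True
    k = len(short)
    return any(tuple(long[i : i + k]) == tuple(short) for i in range(len(long) - k + 1))


def compatible(a: TranscriptModel, b: TranscriptModel) -> bool:
    """Pairwise merge compatibility (symmetric)."""
    if a.chrom != b.chrom or not _strands_mergeable(a.strand, b.strand):
        return False
    if not a.span.overlaps(b.span):
        return False
    ia, ib = a.introns, b.introns
    if not ia and not ib:
        # both single-exon: span == exon, so span overlap is exon overlap
        return True
    if len(ia) <= len(ib):
        return _is_contiguous_subchain(ia, ib)
    return _is_contiguous_subchain(ib, ia)


def _cluster(models: Sequence[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Transitive closure of pairwise compatibility, via union-find over
    span-overlapping candidate pairs (sorted sweep limits comparisons)."""
    order = sorted(range(len(models)), key=lambda i: (
        models[i].chrom, models[i].span.start, models[i].span.end, models[i].id))
    parent = list(range(len(models)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    active: list[int] = []
    for idx in order:
        t = models[idx]
        still = []
        for j in active:
            o = models[j]
            if o.chrom == t.chrom and o.span.end > t.span.start:
                still.append(j)
                if compatible(t, o):
                    union(idx, j)
            elif o.chrom == t.chrom:
                continue
        # chromosome change resets the active set
        if active and models[active[0]].chrom != t.chrom:
            still = []
        active = still + [idx]
    groups: dict[int, list[TranscriptModel]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(models[i])
    clusters = list(groups.values())
    clusters.sort(key=lambda ms: (ms[0].chrom, ms[0].span.start, ms[0].id))
    return clusters


def _consensus(members: Sequence[TranscriptModel]) -> TranscriptModel:
    """Consensus of a compatible cluster: exon set = union-merge of member
    exons (no exonic base of any member is lost); the consensus intron chain
    is the gap chain of that union, which equals the longest member chain
    except when a single-exon fragment sits inside a retained intron; strand =
    majority known strand (else unknown); id = first member by
    (chrom, span start, span end, id)."""
    members = sorted(members, key=lambda t: (t.span.start, t.span.end, t.id))
    chrom = members[0].chrom
    exons = merge_intervals(p for t in members for p in t.exon_pairs())
    strand_votes = Counter(t.strand for t in members if t.strand != UNKNOWN)
    if strand_votes:
        top = strand_votes.most_common()
        strand = (
            top[0][0]
            if len(top) == 1 or top[0][1] > top[1][1]
            else UNKNOWN
        )
    else:
        strand = UNKNOWN
    return TranscriptModel(
        id=members[0].id,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        source="merged",
    )


def merge_transcripts(
    models: Sequence[TranscriptModel],
    min_samples: int = 2,
    tissue: str | None = None,
) -> list[MergedLocus]:
    """Cluster transcripts by compatibility (transitive closure) and emit one
    consensus per cluster; clusters supported by fewer than ``min_samples``
    distinct sources are dropped. Output sorted by (chrom, start)."""
    loci = []
    for members in _cluster(models):
        support = len({t.source for t in members})
        if support < min_samples:
            continue
        loci.append(
            MergedLocus(
                consensus=_consensus(members),
                n_supporting_samples=support,
                source_tissues=frozenset({tissue} if tissue else ()),
            )
        )
    loci.sort(key=lambda l: (l.consensus.chrom, l.consensus.span.start,
                             l.consensus.id))
    return loci


def meta_merge(per_tissue: Mapping[str, Sequence[MergedLocus]]) -> list[MergedLocus]:
    """Consolidate per-tissue merged sets into one meta set.

    Consensi from all tissues are re-clustered with min_samples=1;
    supporting-sample counts are summed and source tissues unioned. Clustering
    is iterated to a fixed point so the operation is idempotent (merging two
    consensi can widen a span and create new compatibilities).
    """
    entries: list[MergedLocus] = []
    for tissue in sorted(per_tissue):
        for ml in per_tissue[tissue]:
            tissues = ml.source_tissues or frozenset({tissue})
            entries.append(
                MergedLocus(ml.consensus, ml.n_supporting_samples, tissues)
            )
    while True:
        by_model = {id(e.consensus): e for e in entries}
        clusters = _cluster([e.consensus for e in entries])
        merged: list[MergedLocus] = []
        for members in clusters:
            parts = [by_model[id(m)] for m in members]
            merged.append(
                MergedLocus(
                    consensus=_consensus(members),
                    n_supporting_samples=sum(p.n_supporting_samples for p in parts),
                    source_tissues=frozenset().union(
                        *(p.source_tissues for p in parts)
                    ),
                )
            )
        if len(merged) == len(entries):
            merged.sort(key=lambda l: (l.consensus.chrom, l.consensus.span.start,
                                       l.consensus.id))
            return merged
        entries = merged


def support_table(loci: Iterable[MergedLocus]) -> list[dict]:
    """Per-locus support statistics, ready for a TSV writer."""
    rows = []
    for ml in loci:
        sp = ml.consensus.span
        rows.append(
            {
                "locus_id": ml.consensus.id,
                "chrom": ml.consensus.chrom,
                "start": sp.start,
                "end": sp.end,
                "strand": ml.consensus.strand,
                "n_exons": len(ml.consensus.exons),
                "exonic_length": ml.consensus.exonic_length,
                "n_supporting_samples": ml.n_supporting_samples,
                "source_tissues": ",".join(sorted(ml.source_tissues)),
            }
        )
    return rows
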