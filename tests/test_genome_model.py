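"""Interval arithmetic, catalog indexing, and GTF round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lincatlas.genome_model import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    AnnotationCatalog,
    GenomicInterval,
    exonic_overlap_bases,
    genome_coverage,
    read_gtf,
    write_annotation_gtf,
    write_gtf,
)
from lincatlas.validation import (
    bitmap_coverage,
    bitmap_overlap_bases,
    random_catalog,
    random_locus,
)

from conftest import make_gene, make_transcript


class TestGenomicInterval:
    def test_rejects_inverted_and_empty_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_length_and_overlap(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        assert a.length == 100
        assert a.overlap_bases(b) == 50
        assert a.overlap_bases(GenomicInterval("chr2", 0, 100)) == 0


class TestTranscriptModel:
    def test_intron_chain_and_lengths(self):
        t = make_transcript("t1", "chr1", FORWARD, [(100, 200), (300, 400)])
        assert t.introns == ((200, 300),)
        assert t.exonic_length == 200
        assert (t.span.start, t.span.end) == (100, 400)
        single = make_transcript("t2", "chr1", FORWARD, [(0, 500)])
        assert single.introns == ()
        assert not single.is_multi_exon

    def test_rejects_overlapping_or_unsorted_exons(self):
        with pytest.raises(ValueError):
            make_transcript("bad", "chr1", FORWARD, [(100, 300), (200, 400)])


class TestExonicOverlap:
    def test_basic_overlap_and_disjoint(self, toy_catalog):
        t = make_transcript("q", "chr1", FORWARD, [(1100, 1600)])
        # hits PC1 exons [1000,1200) and [1500,1800): 100 + 100 bases
        assert exonic_overlap_bases(t, toy_catalog.get("PC1")) == 200
        far = make_transcript("q2", "chr1", FORWARD, [(50_000, 50_100)])
        assert exonic_overlap_bases(far, toy_catalog.get("PC1")) == 0
        other_chrom = make_transcript("q3", "chr2", FORWARD, [(1000, 1200)])
        assert exonic_overlap_bases(other_chrom, toy_catalog.get("PC1")) == 0

    def test_matches_bitmap_oracle_on_random_exon_sets(self, rng):
        """Sweep-based overlap equals the per-base bitmap intersection."""
        length = 20_000
        for _ in range(200):
            t = random_locus(rng, chrom_length=length)
            g = make_gene("g", "chr1", FORWARD,
                          random_locus(rng, chrom_length=length).exon_pairs())
            assert exonic_overlap_bases(t, g) == bitmap_overlap_bases(
                t.exon_pairs(), g.union_exons, length
            )


class TestGenomeCoverage:
    def test_union_and_idempotence(self):
        a = make_transcript("a", "chr1", FORWARD, [(0, 100)])
        b = make_transcript("b", "chr1", FORWARD, [(50, 150)])
        assert genome_coverage([a, b]).total == 150
        assert genome_coverage([a, a]).total == genome_coverage([a]).total

    def test_monotone_and_matches_bitmap(self, rng):
        length = 30_000
        loci = [random_locus(rng, chrom_length=length) for _ in range(50)]
        prev = 0
        for k in range(0, 51, 10):
            cov = genome_coverage(loci[:k]).total
            assert cov >= prev
            prev = cov
        assert genome_coverage(loci).total == bitmap_coverage(loci, length)

    def test_per_chrom_breakdown_sums_to_total(self, rng):
        loci = [random_locus(rng, chrom=f"chr{i % 3 + 1}") for i in range(30)]
        cov = genome_coverage(loci)
        assert sum(cov.per_chrom.values()) == cov.total


class TestCatalogIndex:
    def test_lookup_equals_linear_scan(self, rng):
        """Interval-index queries agree with brute-force scans over gene
        spans (>= 1000 random queries)."""
        catalogs = [random_catalog(rng, n_genes=12) for _ in range(5)]
        for catalog in catalogs:
            for _ in range(200):
                start = int(rng.integers(0, 49_000))
                end = start + int(rng.integers(1, 3_000))
                got = {g.id for g in catalog.query_spans("chr1", start, end)}
                want = {
                    g.id for g in catalog
                    if g.span.start < end and start < g.span.end
                }
                assert got == want


class TestGtfIO:
    def test_coordinate_convention(self, tmp_path):
        """A 1-based closed GTF exon [101, 200] becomes [100, 200) in memory
        and round-trips back to '101 200'."""
        p = tmp_path / "one.gtf"
        p.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        (t,) = read_gtf(p, mode="assembly")
        assert t.exon_pairs() == [(100, 200), (300, 400)]
        assert t.exons[0].length == 100
        assert t.introns == ((200, 300),)
        out = tmp_path / "out.gtf"
        write_gtf([t], out)
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[3:5] == ["101", "200"]

    def test_write_empty_is_header_only(self, tmp_path):
        p = tmp_path / "empty.gtf"
        write_gtf([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tx\texon\t101\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gtf(p, mode="assembly")

    def test_inverted_exon_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t500\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="end"):
            read_gtf(p, mode="assembly")

    def test_multi_chromosome_transcript_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr2\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="multiple"):
            read_gtf(p, mode="assembly")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_random_models(self, tmp_path_factory, seed):
        """read_gtf(write_gtf(X)) == X: coordinates, strands, and ids survive
        exactly."""
        rng = np.random.default_rng(seed)
        models = []
        for i in range(rng.integers(1, 6)):
            t = random_locus(rng, chrom=f"chr{rng.integers(1, 4)}")
            models.append(
                make_transcript(f"t{i:03d}", t.chrom, t.strand, t.exon_pairs())
            )
        path = tmp_path_factory.mktemp("rt") / "x.gtf"
        write_gtf(models, path)
        back = read_gtf(path, mode="assembly")
        key = lambda t: (t.chrom, t.span.start, t.id)
        assert [(t.id, t.chrom, t.strand, t.exon_pairs())
                for t in sorted(models, key=key)] == [
            (t.id, t.chrom, t.strand, t.exon_pairs()) for t in back
        ]

    def test_annotation_round_trip_keeps_biotypes(self, tmp_path, toy_catalog):
        p = tmp_path / "ann.gtf"
        write_annotation_gtf(toy_catalog, p)
        back = read_gtf(p, mode="known_annotation")
        assert [g.id for g in back] == [g.id for g in toy_catalog]
        for a, b in zip(toy_catalog, back):
            assert a.biotype == b.biotype
            assert a.union_exons == b.union_exons

    def test_missing_biotype_becomes_other_known(self, tmp_path):
        p = tmp_path / "ann.gtf"
        p.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        cat = read_gtf(p, mode="known_annotation")
        assert cat.get("g").biotype == "other_known"
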