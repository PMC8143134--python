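import numpy as np
import pytest

from lincatlas.genome_model import (
    FORWARD,
    REVERSE,
    GenomicInterval,
    TranscriptModel,
    GeneModel,
    AnnotationCatalog,
    PROTEIN_CODING,
    KNOWN_LINCRNA,
)


def make_transcript(tid, chrom, strand, exon_pairs, source="s1"):
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs),
        source=source,
    )


def make_gene(gid, chrom, strand, exon_pairs, biotype=PROTEIN_CODING):
    return GeneModel(
        gid, biotype, (make_transcript(f"{gid}.t1", chrom, strand, exon_pairs,
                                       source="ann"),)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240614)


@pytest.fixture
def toy_catalog():
    """Two coding genes and one known lincRNA on chr1, one coding gene on
    chr2."""
    genes = [
        make_gene("PC1", "chr1", FORWARD, [(1000, 1200), (1500, 1800), (2500, 2900)]),
        make_gene("PC2", "chr1", REVERSE, [(10_000, 10_400), (11_000, 11_500)]),
        make_gene("LINC1", "chr1", FORWARD, [(20_000, 20_600)],
                  biotype=KNOWN_LINCRNA),
        make_gene("PC3", "chr2", FORWARD, [(5_000, 5_300), (6_000, 6_400)]),
    ]
    return AnnotationCatalog(genes)
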