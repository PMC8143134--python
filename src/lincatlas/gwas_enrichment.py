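"""SNP-to-gene mapping and chi-square enrichment of GWAS SNPs in
tissue-specific genes.

SNPs (e.g. disease-associated GWAS hits) are mapped to the genic region of
every gene whose span contains the position. Genes are then tabulated
specific vs non-specific by whether at least one SNP maps to them, and the
2x2 table is tested with a Pearson chi-square statistic (df=1, no continuity
correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .assembly_merge import MergedLocus
from .genome_model import AnnotationCatalog
from .lncrna_classify import NovelLocus

NOVEL_LINCRNA = "novel_lincRNA"


@dataclass(frozen=True)
class SNPRecord:
    """A SNP position (0-based internally; input TSVs are 1-based)."""

    chrom: str
    pos: int
    id: str
    gwas_p: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"SNP {self.id}: negative position")


class GeneRegion(NamedTuple):
    """A genic region used for SNP assignment: the gene span by default,
    optionally the union exons."""

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    category: str


def regions_from_catalog(
    catalog: AnnotationCatalog, use: str = "span"
) -> list[GeneRegion]:
    """Genic regions for known genes; ``use`` is "span" or "exons"."""
    out = []
    for g in catalog:
        ivs = (
            ((g.span.start, g.span.end),)
            if use == "span"
            else tuple(g.union_exons)
        )
        out.append(GeneRegion(g.id, g.chrom, ivs, g.biotype))
    return out


def regions_from_novel(
    novel: Iterable[NovelLocus | MergedLocus], use: str = "span"
) -> list[GeneRegion]:
    out = []
    for n in novel:
        t = n.locus.consensus if isinstance(n, NovelLocus) else n.consensus
        ivs = ((t.span.start, t.span.end),) if use == "span" else tuple(t.exon_pairs())
        out.append(GeneRegion(t.id, t.chrom, ivs, NOVEL_LINCRNA))
    return out


class MappingResult(NamedTuple):
    per_gene: dict[str, int]  # gene id -> number of mapped SNPs
    per_snp: dict[str, list[str]]  # snp id -> gene ids (empty = intergenic)
    mapped: int  # SNPs mapped to >= 1 gene
    total: int
    mapped_percent: float
    per_category: dict[str, int]  # category -> SNP-to-gene assignment tallies


def mapped_percent(total: int, mapped: int) -> float:
    """Mapped percentage = mapped/total*100, rounded to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(mapped / total * 100.0, 2)


def map_snps(snps: Sequence[SNPRecord], genes: Sequence[GeneRegion]) -> MappingResult:
    """Assign each SNP to every gene whose genic region contains its position.

    A SNP inside two overlapping genes counts for both genes (gene-level and
    per-category tallies) but once in the genome-level mapped total.
    """
    index: dict[str, IntervalTree] = {}
    for g in genes:
        tree = index.setdefault(g.chrom, IntervalTree())
        for s, e in g.intervals:
            tree.addi(s, e, g)
    per_gene = {g.gene_id: 0 for g in genes}
    per_snp: dict[str, list[str]] = {}
    per_category: dict[str, int] = {}
    mapped = 0
    for snp in snps:
        tree = index.get(snp.chrom)
        hits = (
            sorted({iv.data for iv in tree.at(snp.pos)}, key=lambda g: g.gene_id)
            if tree is not None
            else []
        )
        per_snp[snp.id] = [g.gene_id for g in hits]
        if hits:
            mapped += 1
        for g in hits:
            per_gene[g.gene_id] += 1
            per_category[g.category] = per_category.get(g.category, 0) + 1
    total = len(snps)
    pct = mapped_percent(total, mapped) if total else 0.0
    return MappingResult(per_gene, per_snp, mapped, total, pct, per_category)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: specific/non-specific; cols: >=1 SNP / none
    row_proportions: tuple[float, float]
    chi2_statistic: float
    p_value: float
    per_category: dict[str, int]


def enrichment_table(
    specific: set[str], all_genes: set[str], snp_counts: Mapping[str, int]
) -> np.ndarray:
    """2x2 table: rows {specific, non-specific}, cols {>=1 mapped SNP, none};
    cells sum to |all_genes|."""
    if not all_genes:
        raise ValueError("empty gene universe")
    if not specific <= all_genes:
        raise ValueError("specific genes must be a subset of the gene universe")
    table = np.zeros((2, 2), dtype=np.int64)
    for g in all_genes:
        row = 0 if g in specific else 1
        col = 0 if snp_counts.get(g, 0) >= 1 else 1
        table[row, col] += 1
    return table


def chi_square(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (df=1); no continuity correction by
    default. Zero marginals raise (an exact test would be needed)."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "zero marginal in contingency table; use an exact test instead"
        )
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def enrichment_analysis(
    snps: Sequence[SNPRecord],
    genes: Sequence[GeneRegion],
    specific: set[str],
    correction: bool = False,
) -> tuple[EnrichmentResult, MappingResult]:
    """Map SNPs, build the specific vs non-specific 2x2 table, and test it."""
    mapping = map_snps(snps, genes)
    universe = {g.gene_id for g in genes}
    table = enrichment_table(specific & universe, universe, mapping.per_gene)
    chi2_stat, p = chi_square(table, correction=correction)
    with np.errstate(invalid="ignore"):
        props = table[:, 0] / table.sum(axis=1)
    return (
        EnrichmentResult(
            table=table,
            row_proportions=(float(props[0]), float(props[1])),
            chi2_statistic=chi2_stat,
            p_value=p,
            per_category=mapping.per_category,
        ),
        mapping,
    )


def read_snps(path: str | Path) -> list[SNPRecord]:
    """Read a SNP TSV (chrom, pos_1based, id, optional gwas_p); positions are
    converted to 0-based on read."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    required = {"chrom", "pos", "id"}
    if not required <= set(df.columns):
        raise ValueError(f"SNP TSV missing columns {required - set(df.columns)}")
    has_p = "gwas_p" in df.columns
    return [
        SNPRecord(
            chrom=row.chrom,
            pos=int(row.pos) - 1,
            id=row.id,
            gwas_p=float(row.gwas_p) if has_p and pd.notna(row.gwas_p) else None,
        )
        for row in df.itertuples()
    ]


def write_snps(snps: Sequence[SNPRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos + 1 for s in snps],
            "id": [s.id for s in snps],
            "gwas_p": [s.gwas_p for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)
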