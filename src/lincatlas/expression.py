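"""Count-matrix construction, filtering, and normalization.

The substrate for tissue-specificity testing is a genes x samples matrix of
non-negative integer counts over known genes plus novel multi-exon lincRNAs.
Library-size scaling uses a trimmed-mean-of-log-ratios (TMM-style) factor with
geometric mean 1; expression thresholds are applied on log2 counts-per-million
with a pseudo-count, log2CPM = log2((y + prior) / (L*f + 2*prior) * 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval, _pairwise_overlap_bases


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids not unique")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_df(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids),
                           self.counts[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.sample_ids),
                           self.counts[idx, :])

    def write_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_df(df)


@dataclass(frozen=True)
class TissueDesign:
    """sample_id -> tissue label map."""

    labels: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s, t in self.labels.items() if t == tissue]

    def restrict(self, sample_ids: Iterable[str]) -> "TissueDesign":
        keep = set(sample_ids)
        return TissueDesign({s: t for s, t in self.labels.items() if s in keep})

    def validate_against(self, m: CountMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.labels), "tissue": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TissueDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample_id"], df["tissue"])))


class FragmentAssignment(NamedTuple):
    matrix: CountMatrix
    assigned: int
    ambiguous: int
    unassigned: int


def assign_fragments(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    loci: Sequence[GeneModel],
    min_overlap_frac: float = 0.5,
) -> FragmentAssignment:
    """Count fragments against gene union-exon models.

    A fragment is counted for a gene iff at least ``min_overlap_frac`` of its
    length overlaps that gene's union exons; fragments passing the bar for two
    or more genes are discarded as ambiguous, the rest as unassigned. The three
    tallies always sum to the number of input fragments.
    """
    from intervaltree import IntervalTree

    exon_index: dict[str, IntervalTree] = {}
    union_exons = {}
    for gi, g in enumerate(loci):
        union_exons[gi] = g.union_exons
        tree = exon_index.setdefault(g.chrom, IntervalTree())
        for s, e in union_exons[gi]:
            tree.addi(s, e, gi)

    gene_ids = [g.id for g in loci]
    sample_ids = sorted(fragments)
    counts = np.zeros((len(loci), len(sample_ids)), dtype=np.int64)
    n_assigned = n_ambig = n_unassigned = 0
    for sj, sample in enumerate(sample_ids):
        for frag in fragments[sample]:
            tree = exon_index.get(frag.chrom)
            cand = {iv.data for iv in tree.overlap(frag.start, frag.end)} if tree else set()
            hits = [
                gi
                for gi in cand
                if _pairwise_overlap_bases([(frag.start, frag.end)], union_exons[gi])
                >= min_overlap_frac * frag.length
            ]
            if len(hits) == 1:
                counts[hits[0], sj] += 1
                n_assigned += 1
            elif len(hits) > 1:
                n_ambig += 1
            else:
                n_unassigned += 1
    return FragmentAssignment(
        CountMatrix(gene_ids, sample_ids, counts), n_assigned, n_ambig, n_unassigned
    )


def expressed_filter(m: CountMatrix, min_count: int = 5) -> CountMatrix:
    """Keep genes with count strictly greater than ``min_count`` in at least
    one sample. Idempotent."""
    keep = (m.counts > min_count).any(axis=1)
    return CountMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k], list(m.sample_ids),
        m.counts[keep, :],
    )


@dataclass(frozen=True)
class NormFactors:
    """Per-sample library sizes and TMM-style scaling factors
    (geometric mean 1)."""

    lib_size: pd.Series
    factor: pd.Series

    def __post_init__(self) -> None:
        if (self.factor <= 0).any():
            raise ValueError("factors must be > 0")
        gm = np.exp(np.mean(np.log(self.factor)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"factor geometric mean {gm} != 1")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factor

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"lib_size": self.lib_size, "factor": self.factor}).rename_axis(
            "sample_id"
        ).to_csv(path, sep="\t")


def _tmm_factor(
    y: np.ndarray, lib: float, y_ref: np.ndarray, lib_ref: float,
    trim_m: float = 0.30, trim_a: float = 0.05,
) -> float:
    """Weighted trimmed mean of log2 ratios of one sample vs the reference,
    over genes positive in both; returns 2**(trimmed weighted mean M)."""
    ok = (y > 0) & (y_ref > 0)
    if not ok.any():
        return 1.0
    y, y_ref = y[ok].astype(float), y_ref[ok].astype(float)
    p, p_ref = y / lib, y_ref / lib_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # asymptotic (delta-method) precision weights, as in standard TMM
    w = 1.0 / ((lib - y) / (lib * y) + (lib_ref - y_ref) / (lib_ref * y_ref))
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def norm_factors(m: CountMatrix) -> NormFactors:
    """TMM-style scaling factors.

    The reference sample is the one whose 75th-percentile count fraction is
    the median across samples; each sample's factor is the weighted trimmed
    mean (30% tails by log-ratio, 5% by abundance) of gene-wise log2 ratios vs
    the reference, over genes positive in both; factors are renormalized to
    geometric mean 1.
    """
    lib = m.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = [s for s, l in zip(m.sample_ids, lib) if l == 0]
        raise ValueError(f"all-zero samples: {bad[:5]}")
    q75 = np.quantile(m.counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - np.median(q75))))
    y_ref, lib_ref = m.counts[:, ref_idx], lib[ref_idx]
    factors = np.array(
        [
            _tmm_factor(m.counts[:, j], lib[j], y_ref, lib_ref)
            for j in range(len(m.sample_ids))
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    idx = pd.Index(m.sample_ids, name="sample_id")
    return NormFactors(pd.Series(lib, index=idx), pd.Series(factors, index=idx))


def log2_cpm(
    m: CountMatrix, f: NormFactors | None = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million on the effective (TMM-scaled) library size with
    a pseudo-count: log2((y + prior) / (L_eff + 2*prior) * 1e6)."""
    if f is None:
        f = norm_factors(m)
    eff = f.effective_lib_size.loc[m.sample_ids].to_numpy()
    vals = np.log2((m.counts + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids)
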