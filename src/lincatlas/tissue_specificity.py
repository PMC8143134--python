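"""One-vs-rest negative-binomial tissue-specificity testing.

For each tissue, samples of that tissue (group A) are compared against all
remaining samples pooled (group B). Counts are modelled as negative binomial
with per-gene dispersion phi (variance mu + phi*mu^2), estimated by method of
moments within tissue groups and shrunk toward a trimmed-mean common value.
The per-gene p-value is a two-sided exact test on the group sums after scaling
each sample to the geometric-mean effective library size: conditional on the
pooled sum, all outcomes with probability not exceeding the observed one are
accumulated (double tail). In the phi -> 0 limit this reduces exactly to the
conditional binomial (Poisson) exact test.

Two selection tiers follow. Tier 1: mean log2 CPM > 0, BH FDR < 0.05, and
one-vs-rest log2 fold change > 2 (up-regulated only). Tier 2 (the dominance
criterion): additionally the tissue's one-vs-rest log2 FC must exceed the
maximum over all other tissues' one-vs-rest log2 FCs by a margin of 2 log2
units. Sub-organ contrasts (e.g. brain subregions) reuse the machinery within
the organ's samples with a relaxed fold-change threshold (log2 FC > 0.585,
i.e. 1.5-fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .expression import CountMatrix, NormFactors, TissueDesign, log2_cpm, norm_factors

_POISSON_PHI = 1e-8


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def subsample_design(
    design: TissueDesign, max_per_tissue: int = 100, seed: int = 0
) -> TissueDesign:
    """Cap each tissue at ``max_per_tissue`` samples, drawn without
    replacement; smaller tissues keep all samples. Deterministic under seed."""
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for tissue in design.tissues:
        samples = sorted(design.samples_for(tissue))
        if len(samples) > max_per_tissue:
            pick = rng.choice(len(samples), size=max_per_tissue, replace=False)
            samples = [samples[i] for i in sorted(pick)]
        kept.extend(samples)
    keep = set(kept)
    return TissueDesign({s: t for s, t in design.labels.items() if s in keep})


def estimate_dispersion(
    m: CountMatrix,
    design: TissueDesign,
    factors: NormFactors | None = None,
    n_prior: float = 10.0,
    trim: float = 0.25,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments.

    Counts are scaled to the geometric-mean effective library size; within each
    tissue group the moment estimate phi = (s^2 - mean)/mean^2 is formed and
    the group estimates pooled with df weights. The pooled estimate is shrunk
    toward the trimmed-mean common dispersion with weight
    w = n_prior / (n_prior + df).
    """
    design.validate_against(m)
    if factors is None:
        factors = norm_factors(m)
    eff = factors.effective_lib_size.loc[m.sample_ids].to_numpy()
    scale = np.exp(np.mean(np.log(eff))) / eff
    z = m.counts * scale  # depth-normalized counts

    num = np.zeros(len(m.gene_ids))
    df_total = 0
    sample_pos = {s: j for j, s in enumerate(m.sample_ids)}
    for tissue in design.tissues:
        cols = [sample_pos[s] for s in design.samples_for(tissue) if s in sample_pos]
        n = len(cols)
        if n < 2:
            raise ValueError(f"tissue {tissue!r} has fewer than 2 samples")
        zg = z[:, cols]
        mu = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(mu > 0, (s2 - mu) / mu**2, 0.0)
        num += (n - 1) * np.clip(phi, 0.0, None)
        df_total += n - 1
    phi_raw = num / df_total
    common = float(stats.trim_mean(phi_raw, trim)) if len(phi_raw) else 0.0
    w = n_prior / (n_prior + df_total)
    phi_hat = w * common + (1.0 - w) * phi_raw
    return pd.Series(np.clip(phi_hat, 0.0, None), index=pd.Index(m.gene_ids),
                     name="dispersion")


def _nb_logpmf(y, r, mu):
    """NB log pmf parameterized by size r and mean mu (r = 1/phi scale)."""
    p = r / (r + mu)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(p) + y * np.log1p(-p)
    )


def _double_tail_pvalue(s: int, y_a: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact double-tail p-value for one gene, conditioning on the pooled sum.

    Group sums are modelled as NB with sizes n_a/phi and n_b/phi and null means
    proportional to group size; all outcomes y in 0..s whose probability does
    not exceed the observed one (relative tolerance 1e-7) are accumulated and
    normalized by the total.
    """
    if s <= 0:
        return 1.0
    n = n_a + n_b
    y = np.arange(s + 1)
    m_a, m_b = s * n_a / n, s * n_b / n
    if phi < _POISSON_PHI:
        logp = stats.poisson.logpmf(y, m_a) + stats.poisson.logpmf(s - y, m_b)
    else:
        logp = _nb_logpmf(y, n_a / phi, m_a) + _nb_logpmf(s - y, n_b / phi, m_b)
    obs = logp[y_a]
    keep = logp <= obs + np.log1p(1e-7)
    mx = logp.max()
    num = np.exp(logp[keep] - mx).sum()
    den = np.exp(logp - mx).sum()
    return float(min(1.0, num / den))


def _exact_test_pvalues(
    sum_a: np.ndarray, sum_b: np.ndarray, n_a: int, n_b: int, phi: np.ndarray,
    chunk_support: int = 2_000_000,
) -> np.ndarray:
    """Vectorized double-tail exact test over genes.

    ``sum_a``/``sum_b`` are rounded scaled group sums. Support arrays for many
    genes are flattened into chunks and evaluated with one scipy call each.
    """
    s = np.round(sum_a + sum_b).astype(np.int64)
    y_obs = np.minimum(np.round(sum_a).astype(np.int64), s)
    pvals = np.ones(len(s))
    n = n_a + n_b

    order = np.argsort(s)
    chunks: list[list[int]] = []
    cur: list[int] = []
    cur_support = 0
    for gi in order:
        if s[gi] <= 0:
            continue
        if cur and cur_support + s[gi] + 1 > chunk_support:
            chunks.append(cur)
            cur, cur_support = [], 0
        cur.append(gi)
        cur_support += int(s[gi]) + 1
    if cur:
        chunks.append(cur)

    for genes in chunks:
        sizes = s[genes] + 1
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        total = int(sizes.sum())
        gene_of = np.repeat(np.arange(len(genes)), sizes)
        y = np.arange(total) - starts[gene_of]
        s_flat = s[genes][gene_of]
        m_a = s_flat * (n_a / n)
        m_b = s_flat * (n_b / n)
        phi_flat = phi[genes][gene_of]
        pois = phi_flat < _POISSON_PHI
        logp = np.empty(total)
        if pois.any():
            logp[pois] = stats.poisson.logpmf(y[pois], m_a[pois]) + stats.poisson.logpmf(
                s_flat[pois] - y[pois], m_b[pois]
            )
        nb = ~pois
        if nb.any():
            logp[nb] = _nb_logpmf(y[nb], n_a / phi_flat[nb], m_a[nb]) + _nb_logpmf(
                s_flat[nb] - y[nb], n_b / phi_flat[nb], m_b[nb]
            )
        obs = logp[starts + y_obs[genes]]
        mx = np.maximum.reduceat(logp, starts)
        w = np.exp(logp - mx[gene_of])
        den = np.add.reduceat(w, starts)
        keep = logp <= obs[gene_of] + np.log1p(1e-7)
        num = np.add.reduceat(np.where(keep, w, 0.0), starts)
        pvals[genes] = np.minimum(1.0, num / den)
    return pvals


@dataclass
class DEResult:
    """Per-gene one-vs-rest differential statistics for one tissue."""

    tissue: str
    table: pd.DataFrame  # columns: log2_fc, mean_log2_cpm, p_value, fdr

    def __post_init__(self) -> None:
        required = {"log2_fc", "mean_log2_cpm", "p_value", "fdr"}
        if not required <= set(self.table.columns):
            raise ValueError(f"DE table missing columns {required - set(self.table.columns)}")


def one_vs_rest_test(
    m: CountMatrix,
    design: TissueDesign,
    tissue: str,
    dispersion: pd.Series,
    factors: NormFactors | None = None,
    prior: float = 0.5,
) -> DEResult:
    """Test every gene for up/down-regulation in ``tissue`` vs all the rest.

    log2 FC is the difference of prior-augmented mean log2 CPM between the
    tissue and the rest; the p-value is the NB double-tail exact test on the
    depth-scaled group sums; FDR is BH within this contrast.
    """
    design.validate_against(m)
    samples_a = [s for s in m.sample_ids if design.labels[s] == tissue]
    samples_b = [s for s in m.sample_ids if design.labels[s] != tissue]
    if not samples_a or not samples_b:
        raise ValueError(f"empty group for tissue {tissue!r}")
    if factors is None:
        factors = norm_factors(m)
    phi = dispersion.loc[m.gene_ids].to_numpy()

    cpm = log2_cpm(m, factors, prior=prior)
    log2_fc = cpm[samples_a].mean(axis=1) - cpm[samples_b].mean(axis=1)
    mean_log2_cpm = cpm.mean(axis=1)

    eff = factors.effective_lib_size.loc[m.sample_ids].to_numpy()
    scale = np.exp(np.mean(np.log(eff))) / eff
    z = m.counts * scale
    pos = {s: j for j, s in enumerate(m.sample_ids)}
    ia = [pos[s] for s in samples_a]
    ib = [pos[s] for s in samples_b]
    sum_a = z[:, ia].sum(axis=1)
    sum_b = z[:, ib].sum(axis=1)
    p = _exact_test_pvalues(sum_a, sum_b, len(ia), len(ib), phi)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc.to_numpy(),
            "mean_log2_cpm": mean_log2_cpm.to_numpy(),
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    return DEResult(tissue=tissue, table=table)


def tier1_select(
    de: DEResult,
    min_log2fc: float = 2.0,
    max_fdr: float = 0.05,
    min_mean_log2cpm: float = 0.0,
) -> set[str]:
    """Tier-1 tissue-specific genes: expressed (mean log2 CPM above threshold),
    significant (FDR below threshold), and up-regulated more than
    ``min_log2fc`` log2 units (all strict inequalities)."""
    t = de.table
    keep = (
        (t["mean_log2_cpm"] > min_mean_log2cpm)
        & (t["fdr"] < max_fdr)
        & (t["log2_fc"] > min_log2fc)
    )
    return set(t.index[keep])


def tier2_select(
    logfc_matrix: pd.DataFrame,
    tier1: dict[str, set[str]],
    margin: float = 2.0,
) -> dict[str, set[str]]:
    """Dominance criterion: gene g is tier-2 for tissue t iff it is tier-1 for
    t and its one-vs-rest log2 FC in t is at least the maximum over all other
    tissues plus ``margin`` log2 units."""
    tissues = list(logfc_matrix.columns)
    if len(tissues) < 2:
        raise ValueError("tier-2 selection needs at least 2 tissues")
    out: dict[str, set[str]] = {}
    vals = logfc_matrix.to_numpy()
    for j, tissue in enumerate(tissues):
        others = np.delete(vals, j, axis=1).max(axis=1)
        dominant = set(logfc_matrix.index[vals[:, j] >= others + margin])
        out[tissue] = tier1.get(tissue, set()) & dominant
    return out


@dataclass
class SpecificityResult:
    """Full one-vs-rest analysis output across tissues."""

    de: dict[str, DEResult]
    tier1: dict[str, set[str]]
    tier2: dict[str, set[str]]
    logfc_matrix: pd.DataFrame
    dispersion: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for tissue, t2 in self.tier2.items():
            if not t2 <= self.tier1.get(tissue, set()):
                raise ValueError(f"tier2 not a subset of tier1 for {tissue!r}")


def specificity_analysis(
    m: CountMatrix,
    design: TissueDesign,
    max_per_tissue: int = 100,
    min_log2fc: float = 2.0,
    max_fdr: float = 0.05,
    min_mean_log2cpm: float = 0.0,
    margin: float = 2.0,
    seed: int = 0,
    n_prior: float = 10.0,
) -> SpecificityResult:
    """Run the full two-tier pipeline: subsample oversized tissues, estimate
    dispersion, test each tissue one-vs-rest, select tier-1 and tier-2 sets."""
    design = subsample_design(design, max_per_tissue=max_per_tissue, seed=seed)
    msub = m.subset_samples([s for s in m.sample_ids if s in design.labels])
    factors = norm_factors(msub)
    phi = estimate_dispersion(msub, design, factors=factors, n_prior=n_prior)
    de: dict[str, DEResult] = {}
    tier1: dict[str, set[str]] = {}
    for tissue in design.tissues:
        res = one_vs_rest_test(msub, design, tissue, phi, factors=factors)
        de[tissue] = res
        tier1[tissue] = tier1_select(
            res, min_log2fc=min_log2fc, max_fdr=max_fdr,
            min_mean_log2cpm=min_mean_log2cpm,
        )
    logfc = pd.DataFrame(
        {tissue: de[tissue].table["log2_fc"] for tissue in design.tissues}
    )
    tier2 = tier2_select(logfc, tier1, margin=margin) if len(design.tissues) >= 2 else {
        t: set() for t in design.tissues
    }
    return SpecificityResult(de=de, tier1=tier1, tier2=tier2, logfc_matrix=logfc,
                             dispersion=phi)


def subregion_specificity(
    m: CountMatrix,
    design: TissueDesign,
    min_log2fc: float = 0.585,
    max_fdr: float = 0.05,
    min_mean_log2cpm: float = 0.0,
    margin: float = 2.0,
    max_per_tissue: int = 100,
    seed: int = 0,
) -> SpecificityResult:
    """One-vs-rest analysis within one organ's subregions with a relaxed
    fold-change threshold (default log2 FC > 0.585, i.e. 1.5-fold). The design
    must already be restricted to the organ's samples."""
    if len(design.tissues) < 2:
        raise ValueError("subregion analysis needs >= 2 subregions")
    return specificity_analysis(
        m, design, max_per_tissue=max_per_tissue, min_log2fc=min_log2fc,
        max_fdr=max_fdr, min_mean_log2cpm=min_mean_log2cpm, margin=margin,
        seed=seed,
    )


def partition_by_membership(
    tier_sets: dict[str, set[str]],
) -> tuple[set[str], set[str]]:
    """Split genes called specific anywhere into (unique to one subregion,
    shared across 2+ subregions); a gene shared by several subregions counts
    once."""
    count: dict[str, int] = {}
    for genes in tier_sets.values():
        for g in genes:
            count[g] = count.get(g, 0) + 1
    unique = {g for g, c in count.items() if c == 1}
    shared = {g for g, c in count.items() if c >= 2}
    return unique, shared
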