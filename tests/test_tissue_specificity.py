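"""One-vs-rest NB testing: dispersion estimation, exact-test behavior,
BH adjustment, tier selection rules, and subregion contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincatlas.expression import CountMatrix, NormFactors, TissueDesign
from lincatlas.synthetic_data import SimulationConfig, make_design, simulate_counts
from lincatlas.tissue_specificity import (
    DEResult,
    _exact_test_pvalues,
    bh_adjust,
    estimate_dispersion,
    one_vs_rest_test,
    partition_by_membership,
    specificity_analysis,
    subregion_specificity,
    subsample_design,
    tier1_select,
    tier2_select,
)
from lincatlas.validation import brute_force_bh


def unit_factors(sample_ids, lib=1e6):
    idx = pd.Index(sample_ids, name="sample_id")
    return NormFactors(pd.Series(lib, index=idx), pd.Series(1.0, index=idx))


class TestSubsampleDesign:
    def test_small_tissue_kept_large_capped(self):
        labels = {f"a{i}": "A" for i in range(80)} | {f"b{i}": "B" for i in range(150)}
        d = subsample_design(TissueDesign(labels), max_per_tissue=100, seed=1)
        assert len(d.samples_for("A")) == 80
        assert len(d.samples_for("B")) == 100

    def test_deterministic_and_without_replacement(self):
        labels = {f"b{i}": "B" for i in range(150)}
        d1 = subsample_design(TissueDesign(labels), 100, seed=9)
        d2 = subsample_design(TissueDesign(labels), 100, seed=9)
        assert d1.labels == d2.labels
        assert len(set(d1.sample_ids)) == 100


class TestEstimateDispersion:
    def test_constant_gene_zero_dispersion(self):
        counts = np.full((1, 8), 42)
        m = CountMatrix(["g"], [f"s{i}" for i in range(8)], counts)
        d = TissueDesign({f"s{i}": "A" if i < 4 else "B" for i in range(8)})
        phi = estimate_dispersion(m, d, factors=unit_factors(m.sample_ids, 42.0),
                                  n_prior=0.0)
        assert phi["g"] == 0.0

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        """2000 Poisson genes: median estimated dispersion < 0.02."""
        mu = rng.uniform(20, 200, size=2000)
        counts = rng.poisson(mu[:, None], size=(2000, 40))
        m = CountMatrix([f"g{i}" for i in range(2000)],
                        [f"s{j}" for j in range(40)], counts)
        d = TissueDesign({f"s{j}": "A" if j < 20 else "B" for j in range(40)})
        phi = estimate_dispersion(m, d)
        assert np.median(phi) < 0.02

    def test_nb_dispersion_recovered(self, rng):
        """NB counts with phi=0.2 at n=50/group: mean estimate in [0.1, 0.3]."""
        phi_true, n = 0.2, 50
        mu = rng.uniform(50, 300, size=800)
        size = 1.0 / phi_true
        counts = rng.negative_binomial(
            size, size / (size + mu[:, None]), size=(800, 2 * n)
        )
        m = CountMatrix([f"g{i}" for i in range(800)],
                        [f"s{j}" for j in range(2 * n)], counts)
        d = TissueDesign({f"s{j}": "A" if j < n else "B" for j in range(2 * n)})
        phi = estimate_dispersion(m, d)
        assert 0.1 < phi.mean() < 0.3

    def test_single_sample_group_raises(self):
        m = CountMatrix(["g"], ["s1", "s2", "s3"], np.array([[1, 2, 3]]))
        d = TissueDesign({"s1": "A", "s2": "A", "s3": "B"})
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(m, d, factors=unit_factors(m.sample_ids))


class TestBHAdjust:
    def test_matches_brute_force_step_up(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=500)
        q = bh_adjust(p)
        assert (q <= 1).all() and (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestOneVsRestTest:
    def test_identical_groups_zero_logfc(self):
        counts = np.tile(np.array([[100], [7], [3000]]), (1, 10))
        m = CountMatrix(["a", "b", "c"], [f"s{j}" for j in range(10)], counts)
        d = TissueDesign({f"s{j}": "A" if j < 5 else "B" for j in range(10)})
        phi = pd.Series(0.1, index=pd.Index(m.gene_ids))
        res = one_vs_rest_test(m, d, "A", phi, factors=unit_factors(m.sample_ids, 3107.0))
        assert np.allclose(res.table["log2_fc"], 0.0, atol=1e-12)
        assert (res.table["p_value"] > 0.99).all()

    def test_empty_group_raises(self):
        m = CountMatrix(["g"], ["s1", "s2"], np.array([[1, 2]]))
        d = TissueDesign({"s1": "A", "s2": "A"})
        phi = pd.Series(0.1, index=pd.Index(["g"]))
        with pytest.raises(ValueError, match="empty group"):
            one_vs_rest_test(m, d, "B", phi, factors=unit_factors(m.sample_ids))

    def test_poisson_limit_matches_conditional_binomial(self, rng):
        """With dispersion -> 0 the double-tail NB p-value equals the
        two-sided conditional binomial exact test to 1e-6."""
        n_a, n_b = 5, 11
        sum_a = rng.integers(0, 300, 200).astype(float)
        sum_b = rng.integers(0, 600, 200).astype(float)
        p = _exact_test_pvalues(sum_a, sum_b, n_a, n_b, np.full(200, 1e-12))
        for i in range(200):
            s = int(round(sum_a[i] + sum_b[i]))
            if s == 0:
                assert p[i] == 1.0
                continue
            ref = stats.binomtest(
                int(round(sum_a[i])), s, n_a / (n_a + n_b)
            ).pvalue
            assert abs(p[i] - ref) < 1e-6

    def test_fdr_column_is_bh_of_pvalues(self, rng):
        cfg = SimulationConfig(seed=41, n_tissues=3, samples_per_tissue=5,
                               n_specific_genes_per_tissue=5)
        design = make_design(cfg)
        sim = simulate_counts([f"g{i}" for i in range(100)], design, cfg)
        phi = estimate_dispersion(sim.matrix, design)
        res = one_vs_rest_test(sim.matrix, design, "tissue01", phi)
        assert np.allclose(
            res.table["fdr"], bh_adjust(res.table["p_value"].to_numpy())
        )


class TestTierSelection:
    def _de(self, rows):
        return DEResult(
            "t",
            pd.DataFrame(
                rows, columns=["log2_fc", "mean_log2_cpm", "p_value", "fdr"],
                index=[f"g{i}" for i in range(len(rows))],
            ),
        )

    def test_tier1_boundaries_are_strict(self):
        de = self._de([
            (2.0, 1.0, 1e-9, 1e-8),   # log2fc exactly 2 -> excluded
            (2.1, 1.0, 1e-9, 1e-8),   # in
            (-3.0, 1.0, 1e-12, 1e-9), # down-regulated -> excluded
            (4.0, 0.0, 1e-9, 1e-8),   # mean CPM exactly 0 -> excluded
            (4.0, 1.0, 0.04, 0.05),   # fdr exactly 0.05 -> excluded
        ])
        assert tier1_select(de) == {"g1"}

    def test_tier2_dominance_margin(self):
        logfc = pd.DataFrame(
            {"t1": [5.0, 4.0], "t2": [2.5, 3.0], "t3": [0.0, 0.0]},
            index=["a", "b"],
        )
        tier1 = {"t1": {"a", "b"}, "t2": set(), "t3": set()}
        t2 = tier2_select(logfc, tier1, margin=2.0)
        assert t2["t1"] == {"a"}  # 5.0 >= 2.5+2; 4.0 < 3.0+2
        assert all(t2[t] <= tier1[t] for t in tier1)

    def test_tier2_needs_two_tissues(self):
        logfc = pd.DataFrame({"t1": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="2 tissues"):
            tier2_select(logfc, {"t1": {"a"}})


class TestSpecificityPipeline:
    def test_planted_genes_recovered(self):
        """Planted 16-fold tissue-specific genes are found with high
        sensitivity and the tier sets nest."""
        cfg = SimulationConfig(seed=51, n_tissues=4, samples_per_tissue=10,
                               n_specific_genes_per_tissue=10)
        design = make_design(cfg)
        sim = simulate_counts([f"g{i}" for i in range(400)], design, cfg)
        res = specificity_analysis(sim.matrix, design, seed=51)
        tp = planted = 0
        for tissue, genes in sim.specific_gene_map.items():
            tp += len(res.tier1[tissue] & genes)
            planted += len(genes)
            assert res.tier2[tissue] <= res.tier1[tissue]
        assert tp / planted >= 0.9

    def test_label_permutation_destroys_calls(self):
        """Permuting tissue labels leaves only null-rate tier-1 calls."""
        cfg = SimulationConfig(seed=52, n_tissues=4, samples_per_tissue=10,
                               n_specific_genes_per_tissue=10)
        design = make_design(cfg)
        sim = simulate_counts([f"g{i}" for i in range(400)], design, cfg)
        rng = np.random.default_rng(0)
        labels = list(design.labels.values())
        rng.shuffle(labels)
        permuted = TissueDesign(dict(zip(design.labels.keys(), labels)))
        res = specificity_analysis(sim.matrix, permuted, seed=52)
        n_calls = sum(len(v) for v in res.tier1.values())
        assert n_calls <= 0.01 * 400 * 4


class TestSubregionSpecificity:
    def test_relaxed_threshold_finds_moderate_markers(self):
        """A 2-fold subregion marker passes at log2 FC > 0.585 but would fail
        the 4-fold organ-level rule."""
        cfg = SimulationConfig(seed=61, n_tissues=2, samples_per_tissue=50,
                               n_specific_genes_per_tissue=20,
                               specific_log2fc=1.0)
        design = make_design(cfg)
        sim = simulate_counts([f"g{i}" for i in range(500)], design, cfg)
        res = subregion_specificity(sim.matrix, design, seed=61)
        recovered = sum(
            len(res.tier1[t] & sim.specific_gene_map[t]) for t in res.tier1
        )
        planted = sum(len(v) for v in sim.specific_gene_map.values())
        assert recovered / planted >= 0.8
        strict = specificity_analysis(sim.matrix, design, min_log2fc=2.0, seed=61)
        assert sum(len(v) for v in strict.tier1.values()) < recovered

    def test_needs_two_subregions(self):
        m = CountMatrix(["g"], ["s1", "s2"], np.array([[1, 2]]))
        d = TissueDesign({"s1": "A", "s2": "A"})
        with pytest.raises(ValueError, match="2 subregions"):
            subregion_specificity(m, d)

    def test_shared_gene_counted_once(self):
        unique, shared = partition_by_membership(
            {"r1": {"a", "b"}, "r2": {"b", "c"}, "r3": {"b"}}
        )
        assert unique == {"a", "c"}
        assert shared == {"b"}
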