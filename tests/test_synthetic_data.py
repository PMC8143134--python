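"""The synthetic study generator: determinism, construction guarantees, and
distributional sanity of the planted signals."""

import numpy as np
import pytest

from lincatlas.expression import TissueDesign
from lincatlas.genome_model import exonic_overlap_bases
from lincatlas.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    make_design,
    make_genome,
    simulate_assemblies,
    simulate_counts,
    simulate_snps,
)


class TestConfig:
    def test_rejects_invalid_probabilities_and_counts(self):
        with pytest.raises(ValueError):
            SimulationConfig(transcript_detection_prob=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_tissues=-1)
        with pytest.raises(ValueError):
            SimulationConfig(specific_log2fc=float("inf"))


class TestMakeGenome:
    def test_zero_novel_requested_gives_empty_truth(self):
        cfg = SimulationConfig(seed=5, n_true_novel_lincRNAs=0)
        _, truth = make_genome(cfg)
        assert truth.true_novel_loci == []

    def test_novel_loci_are_strictly_intergenic_and_long_enough(self):
        cfg = SimulationConfig(seed=6)
        catalog, truth = make_genome(cfg)
        assert len(truth.true_novel_loci) == cfg.n_true_novel_lincRNAs
        for t in truth.true_novel_loci:
            assert t.exonic_length > 200
            for g in catalog:
                assert exonic_overlap_bases(t, g) == 0
                assert not t.span.overlaps(g.span)

    def test_known_genes_do_not_overlap_each_other(self):
        catalog, _ = make_genome(SimulationConfig(seed=7))
        genes = sorted(catalog, key=lambda g: (g.chrom, g.span.start))
        for a, b in zip(genes, genes[1:]):
            if a.chrom == b.chrom:
                assert a.span.end <= b.span.start

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=9)
        cat1, tr1 = make_genome(cfg)
        cat2, tr2 = make_genome(cfg)
        assert [(g.id, g.biotype, g.union_exons) for g in cat1] == [
            (g.id, g.biotype, g.union_exons) for g in cat2
        ]
        assert [(t.id, t.exon_pairs()) for t in tr1.true_novel_loci] == [
            (t.id, t.exon_pairs()) for t in tr2.true_novel_loci
        ]

    def test_too_small_genome_raises(self):
        cfg = SimulationConfig(seed=1, chrom_length=10_000, n_coding_genes=200)
        with pytest.raises(ValueError, match="chrom_length"):
            make_genome(cfg)


class TestSimulateAssemblies:
    def test_perfect_detection_keeps_every_locus_intact(self):
        cfg = SimulationConfig(seed=3, transcript_detection_prob=1.0,
                               fragmentation_prob=0.0, n_tissues=2,
                               samples_per_tissue=3)
        catalog, truth = make_genome(cfg)
        asm = simulate_assemblies(catalog, truth, cfg)
        want = {(t.chrom, tuple(t.exon_pairs())) for t in truth.true_novel_loci}
        for per_sample in asm.values():
            for models in per_sample.values():
                got = {(m.chrom, tuple(m.exon_pairs())) for m in models}
                assert want <= got

    def test_full_fragmentation_leaves_no_multiexon_novel(self):
        cfg = SimulationConfig(seed=4, transcript_detection_prob=1.0,
                               fragmentation_prob=1.0, n_tissues=2,
                               samples_per_tissue=2)
        catalog, truth = make_genome(cfg)
        novel_chains = {tuple(t.exon_pairs()) for t in truth.true_novel_loci
                        if t.is_multi_exon}
        asm = simulate_assemblies(catalog, truth, cfg)
        for per_sample in asm.values():
            for models in per_sample.values():
                for m in models:
                    assert tuple(m.exon_pairs()) not in novel_chains

    def test_detection_rate_is_binomial(self):
        """With detection_prob=0.5 over 200 samples, per-locus detection
        counts stay within 3 sigma of Binomial(200, 0.5)."""
        cfg = SimulationConfig(seed=8, transcript_detection_prob=0.5,
                               fragmentation_prob=0.0, n_tissues=10,
                               samples_per_tissue=20, n_true_novel_lincRNAs=10)
        catalog, truth = make_genome(cfg)
        asm = simulate_assemblies(catalog, truth, cfg)
        n_samples = cfg.n_tissues * cfg.samples_per_tissue
        sigma = np.sqrt(n_samples * 0.25)
        for t in truth.true_novel_loci:
            chain = (t.chrom, tuple(t.exon_pairs()))
            hits = sum(
                1
                for per_sample in asm.values()
                for models in per_sample.values()
                if chain in {(m.chrom, tuple(m.exon_pairs())) for m in models}
            )
            assert abs(hits - n_samples * 0.5) < 3 * sigma

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=12, n_tissues=2, samples_per_tissue=2)
        catalog, truth = make_genome(cfg)
        a1 = simulate_assemblies(catalog, truth, cfg)
        a2 = simulate_assemblies(catalog, truth, cfg)
        flat = lambda a: [
            (t, s, m.id, m.exon_pairs())
            for t in a for s in a[t] for m in a[t][s]
        ]
        assert flat(a1) == flat(a2)


class TestSimulateCounts:
    def test_poisson_limit_moments(self):
        """With dispersion ~0 and mean 100, the sample mean of 10,000 draws
        is within 3 sigma of 100."""
        cfg = SimulationConfig(seed=21, nb_dispersion=0.0,
                               baseline_mean_count=100.0,
                               gene_abundance_sigma=0.0, libsize_sigma=0.0,
                               specific_log2fc=0.0)
        design = TissueDesign({f"s{i}": "t1" for i in range(10_000)})
        sim = simulate_counts(["g1"], design, cfg, specific_gene_map={})
        draws = sim.matrix.counts[0]
        assert abs(draws.mean() - 100.0) < 3 * np.sqrt(100.0 / len(draws))

    def test_nb_variance_exceeds_poisson(self):
        cfg = SimulationConfig(seed=22, nb_dispersion=0.5,
                               baseline_mean_count=100.0,
                               gene_abundance_sigma=0.0, libsize_sigma=0.0)
        design = TissueDesign({f"s{i}": "t1" for i in range(5_000)})
        sim = simulate_counts(["g1"], design, cfg, specific_gene_map={})
        draws = sim.matrix.counts[0].astype(float)
        mu, var = draws.mean(), draws.var()
        # expected var = mu + phi*mu^2 ~ 100 + 5000
        assert var > 10 * mu

    def test_planting_multiplies_means(self):
        cfg = SimulationConfig(seed=23, nb_dispersion=0.0, specific_log2fc=4.0,
                               gene_abundance_sigma=0.0, libsize_sigma=0.0,
                               baseline_mean_count=50.0)
        design = TissueDesign(
            {f"a{i}": "tA" for i in range(200)} | {f"b{i}": "tB" for i in range(200)}
        )
        sim = simulate_counts(["g1", "g2"], design, cfg,
                              specific_gene_map={"tA": {"g1"}})
        df = sim.matrix.df
        a_cols = [s for s in df.columns if s.startswith("a")]
        b_cols = [s for s in df.columns if s.startswith("b")]
        ratio = df.loc["g1", a_cols].mean() / df.loc["g1", b_cols].mean()
        assert 12 < ratio < 20  # 2**4 = 16 up to sampling noise
        flat = df.loc["g2", a_cols].mean() / df.loc["g2", b_cols].mean()
        assert 0.8 < flat < 1.2

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=24, n_tissues=2, samples_per_tissue=3,
                               n_specific_genes_per_tissue=2)
        design = make_design(cfg)
        g = [f"g{i}" for i in range(20)]
        s1 = simulate_counts(g, design, cfg)
        s2 = simulate_counts(g, design, cfg)
        assert (s1.matrix.counts == s2.matrix.counts).all()
        assert s1.specific_gene_map == s2.specific_gene_map


class TestSimulateSnps:
    def test_zero_snps_gives_empty_list(self):
        cfg = SimulationConfig(seed=31, n_snps=0)
        catalog, truth = make_genome(cfg)
        assert simulate_snps(catalog, truth, cfg) == []

    def test_positions_in_bounds_and_deterministic(self):
        cfg = SimulationConfig(seed=32, n_snps=500)
        catalog, truth = make_genome(cfg)
        snps = simulate_snps(catalog, truth, cfg)
        assert len(snps) == 500
        for s in snps:
            assert 0 <= s.pos < cfg.chrom_length
            assert s.gwas_p is None or 0 < s.gwas_p <= 1
        again = simulate_snps(catalog, truth, cfg)
        assert snps == again

    def test_neutral_odds_hit_rates_match_between_sets(self):
        """With snp_enrichment_odds=1 the per-base SNP density inside and
        outside the 'enriched' spans agrees within sampling error."""
        cfg = SimulationConfig(seed=33, n_snps=20_000, snp_enrichment_odds=1.0,
                               n_coding_genes=60, chrom_length=2_000_000)
        catalog, truth = make_genome(cfg)
        rng = np.random.default_rng(0)
        ids = [g.id for g in catalog]
        truth.enriched_gene_set = set(rng.choice(ids, 20, replace=False))
        snps = simulate_snps(catalog, truth, cfg)
        spans = [(g.chrom, g.span.start, g.span.end) for g in catalog
                 if g.id in truth.enriched_gene_set]
        len_in = sum(e - s for _, s, e in spans)
        genome = cfg.chrom_length * cfg.n_chroms
        n_in = sum(
            1 for s in snps
            if any(c == s.chrom and a <= s.pos < b for c, a, b in spans)
        )
        expect = cfg.n_snps * len_in / genome
        assert abs(n_in - expect) < 4 * np.sqrt(expect)

    def test_elevated_odds_concentrate_snps(self):
        cfg = SimulationConfig(seed=34, n_snps=5_000, snp_enrichment_odds=8.0,
                               n_coding_genes=60, chrom_length=2_000_000)
        catalog, truth = make_genome(cfg)
        ids = [g.id for g in catalog]
        truth.enriched_gene_set = set(ids[:20])
        snps = simulate_snps(catalog, truth, cfg)
        spans = [(g.chrom, g.span.start, g.span.end) for g in catalog
                 if g.id in truth.enriched_gene_set]
        len_in = sum(e - s for _, s, e in spans)
        genome = cfg.chrom_length * cfg.n_chroms
        n_in = sum(
            1 for s in snps
            if any(c == s.chrom and a <= s.pos < b for c, a, b in spans)
        )
        assert n_in > 2 * cfg.n_snps * len_in / genome
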