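#!/usr/bin/env python
"""Generate the synthetic multi-tissue study.

Writes the known-gene annotation, the planted novel lincRNA truth set, and
noisy per-sample assembly GTFs (detection dropouts plus single-exon
fragmentation artifacts) for each tissue, under results/analysis/data/.
"""

import argparse
from pathlib import Path

from lincatlas.genome_model import write_annotation_gtf, write_gtf
from lincatlas.synthetic_data import (
    SimulationConfig,
    make_design,
    make_genome,
    simulate_assemblies,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, n_tissues=4, samples_per_tissue=10,
                           n_coding_genes=120, n_known_lincRNAs=30,
                           n_specific_genes_per_tissue=15,
                           chrom_length=4_000_000, n_snps=800,
                           snp_enrichment_odds=8.0)
    data = args.out / "data"
    data.mkdir(parents=True, exist_ok=True)
    catalog, truth = make_genome(cfg)
    write_annotation_gtf(catalog, data / "annotation.gtf")
    write_gtf(truth.true_novel_loci, data / "truth_novel.gtf")
    assemblies = simulate_assemblies(catalog, truth, cfg)
    n_models = 0
    for tissue, per_sample in assemblies.items():
        tdir = data / "assemblies" / tissue
        tdir.mkdir(parents=True, exist_ok=True)
        for sample, models in per_sample.items():
            write_gtf(models, tdir / f"{sample}.gtf")
            n_models += len(models)
    make_design(cfg).write_tsv(data / "design.tsv")

    n_multi = sum(t.is_multi_exon for t in truth.true_novel_loci)
    print(f"genome: {len(catalog)} known genes on {cfg.n_chroms} chromosomes")
    print(f"planted: {len(truth.true_novel_loci)} novel lincRNA loci "
          f"({n_multi} multi-exon)")
    print(f"assemblies: {cfg.n_tissues} tissues x {cfg.samples_per_tissue} "
          f"samples, {n_models} transcript models "
          f"(detection prob {cfg.transcript_detection_prob}, "
          f"fragmentation prob {cfg.fragmentation_prob})")
    print(f"wrote {data}")


if __name__ == "__main__":
    main()
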