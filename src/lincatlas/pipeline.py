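"""Configuration-driven orchestration of the full analysis:
simulate -> merge -> classify -> count -> specificity -> enrich.

Every stage writes its artifact under the output directory and is recorded in
a run manifest (parameters, outputs, sha256 checksums). Reruns with the same
configuration reproduce byte-identical outputs. When a precomputed count
matrix and design are supplied, the simulate/merge/classify stages are skipped
and the manifest notes the skip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly_merge, expression, gwas_enrichment, lncrna_classify
from . import synthetic_data, tissue_specificity
from .genome_model import (
    AnnotationCatalog,
    read_gtf,
    write_annotation_gtf,
    write_bed6,
    write_gtf,
)


@dataclass
class PipelineConfig:
    """All stage parameters and input/output paths, with full defaults.

    Leave ``counts``/``design`` unset to simulate the study; set them to run
    the statistical stages on precomputed data.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    library: str = "unstranded"
    # optional precomputed inputs
    annotation: str | None = None
    counts: str | None = None
    design: str | None = None
    snps: str | None = None
    # simulation overrides (field name -> value on SimulationConfig)
    simulation: dict = field(default_factory=dict)
    # stage parameters
    min_samples: int = 2
    min_exonic_length: int = 201
    min_count: int = 5
    max_per_tissue: int = 100
    min_log2fc: float = 2.0
    max_fdr: float = 0.05
    margin: float = 2.0
    enrich_tissue: str | None = None
    genic_regions: str = "span"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def sim_config(self) -> synthetic_data.SimulationConfig:
        return synthetic_data.SimulationConfig(seed=self.seed, **self.simulation)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest (also written
    to <out_dir>/manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "stages": [],
        "complete": False,
    }

    def record(stage: str, outputs: list[Path], note: str = "") -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": [
                    {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                    for p in outputs
                ],
                "note": note,
            }
        )

    def write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    have_counts = cfg.counts is not None and cfg.design is not None
    sim = cfg.sim_config()
    catalog: AnnotationCatalog | None = None
    truth = synthetic_data.GroundTruth()
    novel_multi: list = []

    try:
        stage = "simulate"
        if have_counts:
            record(stage, [], note="skipped: precomputed counts supplied")
            if cfg.annotation:
                catalog = read_gtf(cfg.annotation, mode="known_annotation")
        else:
            catalog, truth = synthetic_data.make_genome(sim)
            assemblies = synthetic_data.simulate_assemblies(catalog, truth, sim)
            ann_path = out / "annotation.gtf"
            write_annotation_gtf(catalog, ann_path)
            truth_path = out / "truth_novel.gtf"
            write_gtf(truth.true_novel_loci, truth_path)
            asm_dir = out / "assemblies"
            asm_paths = []
            for tissue, per_sample in assemblies.items():
                tdir = asm_dir / tissue
                tdir.mkdir(parents=True, exist_ok=True)
                for sample, models in per_sample.items():
                    p = tdir / f"{sample}.gtf"
                    write_gtf(models, p)
                    asm_paths.append(p)
            record(stage, [ann_path, truth_path] + sorted(asm_paths))

        stage = "merge"
        if have_counts:
            record(stage, [], note="skipped: precomputed counts supplied")
            meta = []
        else:
            per_tissue = {}
            for tissue, per_sample in assemblies.items():
                models = [m for ms in per_sample.values() for m in ms]
                per_tissue[tissue] = assembly_merge.merge_transcripts(
                    models, min_samples=cfg.min_samples, tissue=tissue
                )
            meta = assembly_merge.meta_merge(per_tissue)
            meta_path = out / "meta_merged.gtf"
            write_gtf([ml.consensus for ml in meta], meta_path)
            support_path = out / "meta_support.tsv"
            pd.DataFrame(assembly_merge.support_table(meta)).to_csv(
                support_path, sep="\t", index=False
            )
            record(stage, [meta_path, support_path])

        stage = "classify"
        if have_counts:
            record(stage, [], note="skipped: precomputed counts supplied")
        else:
            novel = lncrna_classify.filter_novel_lincRNAs(
                meta, catalog, min_exonic_length=cfg.min_exonic_length,
                library=cfg.library,
            )
            novel_multi, novel_single = lncrna_classify.split_by_exon_status(novel)
            novel_gtf = out / "novel_lincRNAs.gtf"
            write_gtf(
                [n.locus.consensus for n in novel], novel_gtf,
                extra_attrs={
                    n.locus.consensus.id: {
                        "category": n.category, "exon_status": n.exon_status
                    }
                    for n in novel
                },
            )
            novel_bed = out / "novel_lincRNAs.bed"
            write_bed6([n.locus.consensus for n in novel], novel_bed)
            summary_path = out / "novel_category_summary.tsv"
            summary = lncrna_classify.category_summary(novel)
            pd.DataFrame(
                [{"category": k, "count": v} for k, v in summary.items()]
            ).to_csv(summary_path, sep="\t", index=False)
            record(stage, [novel_gtf, novel_bed, summary_path])

        stage = "count"
        if have_counts:
            matrix = expression.CountMatrix.read_tsv(cfg.counts)
            design = expression.TissueDesign.read_tsv(cfg.design)
        else:
            design = synthetic_data.make_design(sim)
            gene_ids = [g.id for g in catalog] + [
                n.locus.consensus.id for n in novel_multi
            ]
            csim = synthetic_data.simulate_counts(gene_ids, design, sim)
            matrix = csim.matrix
            truth.specific_gene_map = csim.specific_gene_map
        matrix = expression.expressed_filter(matrix, min_count=cfg.min_count)
        counts_path = out / "counts.tsv"
        matrix.write_tsv(counts_path)
        design_path = out / "design.tsv"
        design.write_tsv(design_path)
        factors = expression.norm_factors(matrix)
        factors_path = out / "norm_factors.tsv"
        factors.write_tsv(factors_path)
        record(stage, [counts_path, design_path, factors_path])

        stage = "specificity"
        spec = tissue_specificity.specificity_analysis(
            matrix, design, max_per_tissue=cfg.max_per_tissue,
            min_log2fc=cfg.min_log2fc, max_fdr=cfg.max_fdr, margin=cfg.margin,
            seed=cfg.seed,
        )
        outputs = []
        tier_rows = []
        for tissue in sorted(spec.tier1):
            de_path = out / f"de_{tissue}.tsv"
            spec.de[tissue].table.round(6).to_csv(de_path, sep="\t")
            outputs.append(de_path)
            for g in sorted(spec.tier1[tissue]):
                tier_rows.append(
                    {"tissue": tissue, "gene_id": g,
                     "tier": 2 if g in spec.tier2[tissue] else 1}
                )
        tiers_path = out / "tissue_specific_genes.tsv"
        pd.DataFrame(tier_rows, columns=["tissue", "gene_id", "tier"]).to_csv(
            tiers_path, sep="\t", index=False
        )
        logfc_path = out / "logfc_matrix.tsv"
        spec.logfc_matrix.round(6).rename_axis("gene_id").to_csv(
            logfc_path, sep="\t"
        )
        record(stage, outputs + [tiers_path, logfc_path])

        stage = "enrich"
        target = cfg.enrich_tissue or sorted(spec.tier1)[0]
        specific = spec.tier1.get(target, set())
        if cfg.snps is not None:
            snps = gwas_enrichment.read_snps(cfg.snps)
        else:
            truth.enriched_gene_set = (
                {g for g in specific if catalog is not None and
                 g in {x.id for x in catalog}}
                if catalog is not None else set()
            )
            snps = synthetic_data.simulate_snps(
                catalog if catalog is not None else AnnotationCatalog([]), truth, sim
            )
        regions = []
        if catalog is not None:
            regions += gwas_enrichment.regions_from_catalog(
                catalog, use=cfg.genic_regions
            )
        regions += gwas_enrichment.regions_from_novel(
            novel_multi, use=cfg.genic_regions
        )
        regions = [r for r in regions if r.gene_id in set(matrix.gene_ids)]
        result, mapping = gwas_enrichment.enrichment_analysis(
            snps, regions, specific & {r.gene_id for r in regions}
        )
        snp_path = out / "snps.tsv"
        gwas_enrichment.write_snps(snps, snp_path)
        assign_path = out / "snp_assignments.tsv"
        pd.DataFrame(
            {
                "snp_id": list(mapping.per_snp),
                "gene_ids": [",".join(v) for v in mapping.per_snp.values()],
            }
        ).to_csv(assign_path, sep="\t", index=False)
        table_path = out / "enrichment_table.tsv"
        pd.DataFrame(
            result.table,
            index=["specific", "non_specific"],
            columns=["with_snp", "without_snp"],
        ).rename_axis("gene_set").to_csv(table_path, sep="\t")
        summary_path = out / "enrichment_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(
                {
                    "target_tissue": target,
                    "chi2_statistic": result.chi2_statistic,
                    "p_value": result.p_value,
                    "proportion_specific_with_snp": result.row_proportions[0],
                    "proportion_nonspecific_with_snp": result.row_proportions[1],
                    "snps_total": mapping.total,
                    "snps_mapped": mapping.mapped,
                    "mapped_percent": mapping.mapped_percent,
                    "per_category_assignments": dict(
                        sorted(mapping.per_category.items())
                    ),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        record(stage, [snp_path, assign_path, table_path, summary_path])
    except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        write_manifest()
        raise PipelineError(stage, exc) from exc

    manifest["complete"] = True
    write_manifest()
    return manifest
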