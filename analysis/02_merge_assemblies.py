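#!/usr/bin/env python
"""Merge per-sample transcript models per tissue, then consolidate tissues.

Reads results/analysis/data/assemblies/, writes the tissue-level and
genome-wide (meta) merged GTFs plus a per-locus support table.
"""

import argparse
from pathlib import Path

import pandas as pd

from lincatlas.assembly_merge import merge_transcripts, meta_merge, support_table
from lincatlas.genome_model import read_gtf, write_gtf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--min-samples", type=int, default=2)
    args = ap.parse_args()

    data = args.out / "data"
    per_tissue = {}
    for tdir in sorted((data / "assemblies").iterdir()):
        models = []
        for gtf in sorted(tdir.glob("*.gtf")):
            models.extend(read_gtf(gtf, mode="assembly"))
        merged = merge_transcripts(models, min_samples=args.min_samples,
                                   tissue=tdir.name)
        per_tissue[tdir.name] = merged
        write_gtf([ml.consensus for ml in merged],
                  args.out / f"merged_{tdir.name}.gtf")
        print(f"{tdir.name}: {len(models)} transcripts -> {len(merged)} loci "
              f"(support >= {args.min_samples})")

    meta = meta_merge(per_tissue)
    write_gtf([ml.consensus for ml in meta], args.out / "meta_merged.gtf")
    pd.DataFrame(support_table(meta)).to_csv(
        args.out / "meta_support.tsv", sep="\t", index=False
    )
    shared = sum(1 for ml in meta if len(ml.source_tissues) >= 2)
    print(f"meta: {len(meta)} consolidated loci, {shared} found in >= 2 tissues")


if __name__ == "__main__":
    main()
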