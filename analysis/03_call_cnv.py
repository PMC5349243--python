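#!/usr/bin/env python
"""Normalize coverage and call CNVs with the panel-relative ratio rule.

Normalizes the panel counts (count × genome length / (library size × region
length)), calls deletion/duplication where a genotype's ratio to the panel
mean leaves the strict (0.5, 1.5) band, and summarizes the population
frequency spectrum of the calls. Writes results/normalized_coverage.tsv,
results/calls.tsv and results/cnv_frequency.tsv.
"""

import argparse
from pathlib import Path

from capcnv import regions_io
from capcnv.cnv_calling import call_cnv, cnv_frequency_spectrum
from capcnv.coverage_qc import normalize_coverage
from capcnv.pipeline import FLOAT_FORMAT

parser = argparse.ArgumentParser()
parser.add_argument("--panel", type=Path, default=Path("results/panel"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

regions = regions_io.read_regions(args.panel / "regions.bed",
                                  args.panel / "regions_annotation.tsv")
panel = regions_io.read_counts(args.panel / "counts.tsv", args.panel / "counts_meta.tsv")
labels = regions_io.read_morphotype_labels(args.panel / "morphotypes.tsv", panel)

norm = normalize_coverage(panel, regions)
calls = call_cnv(norm)
freq, fraction_rare = cnv_frequency_spectrum(calls, labels)

n_del = int((calls.calls == "deletion").sum().sum())
n_dup = int((calls.calls == "duplication").sum().sum())
n_nc = int((calls.calls == "no_call").sum().sum())
print(f"calls over {calls.calls.size} cells: {n_del} deletions, "
      f"{n_dup} duplications, {n_nc} no-call")
print(f"{len(freq)} distinct carried CNVs; "
      f"{100 * fraction_rare:.1f}% are rare (<10% of the panel)")

args.out_dir.mkdir(parents=True, exist_ok=True)
norm.matrix.to_csv(args.out_dir / "normalized_coverage.tsv", sep="\t",
                   float_format=FLOAT_FORMAT)
calls.to_symbols().to_csv(args.out_dir / "calls.tsv", sep="\t")
freq.to_csv(args.out_dir / "cnv_frequency.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT)
print(f"wrote normalized coverage, calls and frequency tables to {args.out_dir}/")
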