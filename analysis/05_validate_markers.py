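#!/usr/bin/env python
"""Validation stage: CNV marker recoding, filtering, and concordance.

Recodes the CNV calls into biallelic presence/absence markers, applies the
call-rate (>0.9), MAF (>0.01) and individual call-rate (>0.8) filters, and
demonstrates the cross-platform concordance computation by comparing the
marker set against a duplicate with a planted 7% discordance (standing in
for an independent genotyping platform). Writes results/cnv_markers_filtered.tsv
and results/concordance.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from capcnv import regions_io
from capcnv.cnv_calling import call_cnv
from capcnv.coverage_qc import normalize_coverage
from capcnv.pipeline import FLOAT_FORMAT
from capcnv.validation import (
    FilterThresholds,
    MarkerMatrix,
    concordance_rate,
    filter_markers,
    recode_cnv_markers,
)

parser = argparse.ArgumentParser()
parser.add_argument("--panel", type=Path, default=Path("results/panel"))
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--discordance", type=float, default=0.07)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

regions = regions_io.read_regions(args.panel / "regions.bed",
                                  args.panel / "regions_annotation.tsv")
panel = regions_io.read_counts(args.panel / "counts.tsv", args.panel / "counts_meta.tsv")
calls = call_cnv(normalize_coverage(panel, regions))

markers = recode_cnv_markers(calls)
thresholds = FilterThresholds()
filtered = filter_markers(markers, thresholds)
print(f"{len(markers.markers)} CNV markers from {calls.calls.shape[1]} regions; "
      f"{len(filtered.markers)} markers and {len(filtered.individuals)} individuals "
      f"survive the >{thresholds.marker_call_rate}/"
      f">{thresholds.minor_allele_frequency}/"
      f">{thresholds.individual_call_rate} filters")

# synthetic duplicate platform with planted discordance
rng = np.random.default_rng(args.seed)
vb = filtered.values.mask(rng.random(filtered.values.shape) < args.discordance,
                          1 - filtered.values)
other = MarkerMatrix(vb, filtered.alphabet)
pairing = [(m, m) for m in filtered.markers]
overall, per_pair = concordance_rate(filtered, other, pairing)
print(f"overall concordance vs duplicate platform with {100 * args.discordance:.0f}% "
      f"planted discordance: {overall:.1f}%")
worst = per_pair.head(5)
print("five least concordant markers:",
      ", ".join(f"{k.split('|')[0]} ({v:.0f}%)" for k, v in worst.items()))
kept = [p for p in pairing if f"{p[0]}|{p[1]}" not in worst.index]
overall_clean, _ = concordance_rate(filtered, other, kept)
print(f"after removing them: {overall_clean:.1f}%")

args.out_dir.mkdir(parents=True, exist_ok=True)
filtered.values.to_csv(args.out_dir / "cnv_markers_filtered.tsv", sep="\t",
                       float_format="%g")
per_pair.rename("concordance_pct").to_frame().to_csv(
    args.out_dir / "concordance.tsv", sep="\t", float_format=FLOAT_FORMAT)
print(f"wrote marker and concordance tables to {args.out_dir}/")
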