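"""Coverage normalization and target-enrichment quality metrics.

The central quantity is the normalized per-region coverage

    coverage_norm = (reads in region × genome length)
                    / (total aligned reads × region length)

which rescales each genotype's per-region read count by its library size and
the region's length, so that an unaltered single-copy region has the same
expected value for every genotype regardless of sequencing depth. The
remaining QC metrics summarize how well the capture worked: genome-wide and
on-target x-fold coverage, the enrichment factor (their ratio), the fraction
of sequenced reads on target (specificity) and the fraction of target bases
covered at a given depth (sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .regions_io import CoveragePanel, RegionTable

__all__ = [
    "NormalizedCoverageMatrix",
    "QCReport",
    "normalize_coverage",
    "genome_wide_coverage",
    "target_coverage",
    "enrichment_factor",
    "target_specificity",
    "target_sensitivity",
    "qc_report",
]


@dataclass(frozen=True)
class NormalizedCoverageMatrix:
    """Genotypes × regions normalized coverage, with provenance."""

    matrix: pd.DataFrame
    source: CoveragePanel

    @property
    def genotype_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def region_ids(self) -> pd.Index:
        return self.matrix.columns


@dataclass(frozen=True)
class QCReport:
    """Per-genotype enrichment QC, with panel and per-morphotype means.

    ``per_genotype`` columns: mean_genome_wide_coverage, mean_target_coverage,
    normalized_mean_target_coverage, enrichment_factor, target_specificity,
    and — when depth profiles were supplied — target_sensitivity and
    fraction_target_covered_gt_depth (both percent).
    """

    per_genotype: pd.DataFrame
    panel_mean: pd.Series
    per_morphotype: pd.DataFrame | None = None
    depth_threshold: int = 11


def normalize_coverage(panel: CoveragePanel, regions: RegionTable) -> NormalizedCoverageMatrix:
    """Normalize per-region counts to copy-comparable coverage.

    Each cell is ``count * genome_length / (total_aligned_reads * region
    length)``. Zero counts map to exactly zero; genotypes with non-positive
    library size are rejected by the panel invariants upstream.
    """
    lengths = regions.lengths.reindex(panel.region_ids)
    if lengths.isna().any():
        missing = panel.region_ids[lengths.isna()].tolist()
        raise ValueError(f"panel regions missing from region table: {missing}")
    totals = panel.total_aligned_reads.astype(float)
    mat = (
        panel.counts.astype(float)
        .mul(panel.genome_length)
        .div(totals, axis=0)
        .div(lengths.astype(float), axis=1)
    )
    return NormalizedCoverageMatrix(mat, panel)


def genome_wide_coverage(panel: CoveragePanel) -> pd.Series:
    """Per-genotype x-fold coverage over the whole assembly:
    total_aligned_reads × read_length / genome_length."""
    return panel.total_aligned_reads * panel.read_length / panel.genome_length


def target_coverage(panel: CoveragePanel, regions: RegionTable) -> pd.Series:
    """Per-genotype x-fold coverage over the target space:
    (Σ target counts × read_length) / Σ target lengths."""
    target_ids = regions.target_ids.intersection(panel.region_ids)
    if len(target_ids) == 0:
        raise ValueError("no target regions in panel")
    total_len = float(regions.lengths.loc[target_ids].sum())
    return panel.counts[target_ids].sum(axis=1) * panel.read_length / total_len


def enrichment_factor(panel: CoveragePanel, regions: RegionTable) -> pd.Series:
    """Mean target coverage over mean genome-wide coverage; the capture's
    fold-enrichment of the target space."""
    gw = genome_wide_coverage(panel)
    if (gw <= 0).any():
        bad = gw.index[gw <= 0].tolist()
        raise ValueError(f"zero genome-wide coverage for genotypes: {bad}")
    return target_coverage(panel, regions) / gw


def target_specificity(panel: CoveragePanel, regions: RegionTable) -> pd.Series:
    """Percent of aligned reads falling in target regions (a read counted in
    a target region is wholly on-target)."""
    target_ids = regions.target_ids.intersection(panel.region_ids)
    on_target = panel.counts[target_ids].sum(axis=1)
    return 100.0 * on_target / panel.total_aligned_reads


def target_sensitivity(
    profiles: Mapping[str, np.ndarray], regions: RegionTable, min_depth: int = 1
) -> float:
    """Percent of target bases covered by at least ``min_depth`` reads.

    ``min_depth=1`` is the covered-at-all variant; ``min_depth=11`` gives the
    fraction covered by more than 10 reads. Requires a profile for every
    target region.
    """
    target_ids = regions.target_ids
    missing = [rid for rid in target_ids if rid not in profiles]
    if missing:
        raise ValueError(f"missing depth profiles for target regions: {missing}")
    covered = 0
    total = 0
    for rid in target_ids:
        depths = np.asarray(profiles[rid])
        covered += int((depths >= min_depth).sum())
        total += len(depths)
    if total == 0:
        raise ValueError("target space is empty")
    return 100.0 * covered / total


def qc_report(
    panel: CoveragePanel,
    regions: RegionTable,
    profiles: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    labels: pd.Series | None = None,
    depth_threshold: int = 11,
) -> QCReport:
    """Assemble the per-genotype QC table plus panel and morphotype means.

    ``profiles``, when given, maps genotype_id → (region_id → depth vector)
    and adds the base-resolution sensitivity columns. ``labels`` (genotype →
    morphotype) adds per-group means over the labelled subset.
    """
    norm = normalize_coverage(panel, regions)
    target_ids = regions.target_ids.intersection(panel.region_ids)
    if len(target_ids) == 0:
        raise ValueError("no target regions in panel")
    report = pd.DataFrame(
        {
            "mean_genome_wide_coverage": genome_wide_coverage(panel),
            "mean_target_coverage": target_coverage(panel, regions),
            "normalized_mean_target_coverage": norm.matrix[target_ids].mean(axis=1),
            "enrichment_factor": enrichment_factor(panel, regions),
            "target_specificity": target_specificity(panel, regions),
        }
    )
    if profiles is not None:
        sens: dict[str, float] = {}
        sens_deep: dict[str, float] = {}
        for gid in panel.genotype_ids:
            if gid not in profiles:
                raise ValueError(f"missing depth profiles for genotype {gid!r}")
            sens[gid] = target_sensitivity(profiles[gid], regions, min_depth=1)
            sens_deep[gid] = target_sensitivity(
                profiles[gid], regions, min_depth=depth_threshold
            )
        report["target_sensitivity"] = pd.Series(sens).reindex(report.index)
        report["fraction_target_covered_gt_depth"] = pd.Series(sens_deep).reindex(
            report.index
        )
    panel_mean = report.mean(axis=0)
    per_morphotype = None
    if labels is not None:
        unknown = labels.index.difference(panel.genotype_ids)
        if len(unknown):
            raise ValueError(f"labels for unknown genotypes: {unknown.tolist()}")
        per_morphotype = report.loc[labels.index].groupby(labels).mean()
    return QCReport(report, panel_mean, per_morphotype, depth_threshold)
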