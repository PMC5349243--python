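"""Data model and file IO for capture-panel CNV analysis.

The pipeline's core containers are thin, validated wrappers around pandas
objects:

* :class:`RegionTable` — the captured regions (BED-derived intervals plus
  annotation: subgenome, target flag, gene label, annotation class).
* :class:`CoveragePanel` — genotypes × regions aligned-read counts together
  with per-genotype library sizes, read length and genome length.
* :class:`HomeologMap` — grouping of region ids into homeologous gene-copy
  groups spanning the A and C subgenomes.
* Depth profiles — per-base read depth for a region, as numpy vectors.
* Morphotype labels — genotype → crop-form group (winter, spring, ...).

All on-disk formats are plain text: BED (3+1 columns) for intervals, TSV for
everything else. Coordinates are 0-based half-open throughout; lengths are
always derived from start/end, never stored independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATION_CLASSES",
    "RegionTable",
    "HomeologMap",
    "CoveragePanel",
    "subgenome_of",
    "read_regions",
    "write_regions",
    "read_counts",
    "write_counts",
    "read_homeolog_map",
    "write_homeolog_map",
    "read_depth_profiles",
    "write_depth_profiles",
    "read_morphotype_labels",
    "write_morphotype_labels",
    "adapt_multicov_table",
]

ANNOTATION_CLASSES = (
    "target_gene",
    "target_promoter",
    "pseudogene",
    "non_target_gene",
    "non_target_other",
)

#: annotation classes counted as genic in subgenome summaries
GENIC_CLASSES = ("target_gene", "non_target_gene")


def subgenome_of(chrom: str) -> str:
    """Subgenome of a chromosome, from its name prefix.

    ``chrA*`` → A (B. rapa-derived), ``chrC*`` → C (B. oleracea-derived),
    anything else → other. Pure function of the name; unassembled scaffold
    bins like ``chrAnn_random`` keep their subgenome prefix.
    """
    if chrom.startswith("chrA"):
        return "A"
    if chrom.startswith("chrC"):
        return "C"
    return "other"


def _is_random_scaffold(chrom: str) -> bool:
    return "random" in chrom


@dataclass(frozen=True)
class RegionTable:
    """Annotated captured regions.

    ``df`` is indexed by unique region_id with columns ``chrom``, ``start``,
    ``end``, ``length``, ``subgenome``, ``is_target``, ``is_random_scaffold``,
    ``gene_label``, ``annotation_class``. Row order is file order.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {
            "chrom", "start", "end", "length", "subgenome",
            "is_target", "is_random_scaffold", "gene_label", "annotation_class",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"RegionTable missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate region_id: {dupes}")
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ValueError(f"empty interval (start >= end) for regions: {bad.tolist()}")
        if not (df["length"] == df["end"] - df["start"]).all():
            raise ValueError("length must equal end - start")
        unknown = set(df["annotation_class"]) - set(ANNOTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown annotation_class values: {sorted(unknown)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionTable":
        """Build a validated table, deriving length, subgenome and the
        random-scaffold flag from chrom/start/end."""
        df = df.copy()
        df["length"] = df["end"] - df["start"]
        df["subgenome"] = df["chrom"].map(subgenome_of)
        df["is_random_scaffold"] = df["chrom"].map(_is_random_scaffold)
        if "gene_label" not in df.columns:
            df["gene_label"] = ""
        df["gene_label"] = df["gene_label"].fillna("")
        if "is_target" not in df.columns:
            df["is_target"] = False
        if "annotation_class" not in df.columns:
            df["annotation_class"] = "non_target_other"
        return cls(df)

    @property
    def region_ids(self) -> pd.Index:
        return self.df.index

    @property
    def lengths(self) -> pd.Series:
        return self.df["length"]

    @property
    def target_ids(self) -> pd.Index:
        return self.df.index[self.df["is_target"]]

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class HomeologMap:
    """Homeologous gene-copy groups.

    ``groups`` maps group_id → tuple of member region_ids. Each region
    belongs to at most one group; every member must exist in the validating
    RegionTable.
    """

    groups: Mapping[str, tuple]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gid, members in self.groups.items():
            for rid in members:
                if rid in seen:
                    raise ValueError(
                        f"duplicate membership: region {rid!r} in groups "
                        f"{seen[rid]!r} and {gid!r}"
                    )
                seen[rid] = gid

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple], regions: RegionTable | None = None
    ) -> "HomeologMap":
        """Build from (group_id, region_id) rows, validating against a
        RegionTable when given."""
        groups: dict[str, list] = {}
        for gid, rid in pairs:
            if regions is not None and rid not in regions.df.index:
                raise ValueError(f"homeolog map references unknown region {rid!r}")
            groups.setdefault(str(gid), []).append(str(rid))
        return cls({g: tuple(m) for g, m in groups.items()})

    def group_of(self) -> dict:
        """region_id → group_id lookup."""
        return {rid: gid for gid, members in self.groups.items() for rid in members}

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class CoveragePanel:
    """Genotypes × regions aligned-read counts (duplicates removed).

    ``counts`` is an integer DataFrame, rows = genotypes, columns = regions.
    ``total_aligned_reads`` is the per-genotype library size (all aligned
    reads, on- and off-target). ``read_length`` (bp) and ``genome_length``
    (bp, reference assembly size) parameterize coverage arithmetic.
    Missing counts are not permitted: sequencing yields a count, possibly 0,
    for every region.
    """

    counts: pd.DataFrame
    total_aligned_reads: pd.Series
    read_length: int = 100
    genome_length: float = 8.5e8

    def __post_init__(self) -> None:
        counts = self.counts
        totals = self.total_aligned_reads
        if counts.isna().any().any():
            raise ValueError("missing counts are not permitted")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative count in coverage matrix")
        if not counts.index.equals(totals.index):
            raise ValueError("counts rows and total_aligned_reads must share genotype_ids")
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"non-positive total_aligned_reads for genotypes: {bad}")
        row_sums = counts.sum(axis=1)
        over = row_sums.index[row_sums > totals]
        if len(over):
            raise ValueError(
                f"counts exceed total_aligned_reads for genotypes: {over.tolist()}"
            )
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")

    @property
    def genotype_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def region_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genotypes(self) -> int:
        return len(self.counts.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_regions(path, annotation_path=None) -> RegionTable:
    """Read a BED-like file (chrom, start, end[, name]) plus an optional
    annotation TSV keyed by region_id with columns ``is_target``,
    ``gene_label``, ``annotation_class``.

    Regions without a name column get ``chrom:start-end`` ids. Malformed
    intervals and duplicate ids are rejected with the offending line/record.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval (start >= end)")
            name = parts[3] if len(parts) >= 4 else f"{chrom}:{start}-{end}"
            rows.append((name, chrom, start, end))
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])
    if df["region_id"].duplicated().any():
        dupes = df.loc[df["region_id"].duplicated(), "region_id"].tolist()
        raise ValueError(f"duplicate region_id in {path}: {dupes}")
    df = df.set_index("region_id")

    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype={"region_id": str}).set_index(
            "region_id"
        )
        unknown = ann.index.difference(df.index)
        if len(unknown):
            raise ValueError(f"annotation for unknown regions: {unknown.tolist()}")
        for col in ("is_target", "gene_label", "annotation_class"):
            if col in ann.columns:
                df[col] = ann[col].reindex(df.index)
        if "is_target" in df.columns:
            df["is_target"] = (
                df["is_target"].where(df["is_target"].notna(), False).astype(bool)
            )
        if "gene_label" in df.columns:
            df["gene_label"] = df["gene_label"].fillna("")
        if "annotation_class" in df.columns:
            df["annotation_class"] = df["annotation_class"].fillna("non_target_other")
    return RegionTable.from_frame(df)


def write_regions(regions: RegionTable, bed_path, annotation_path=None) -> None:
    """Write intervals as 4-column BED and (optionally) the annotation TSV."""
    with open(bed_path, "w") as fh:
        for rid, row in regions.df.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t{rid}\n")
    if annotation_path is not None:
        ann = regions.df[["is_target", "gene_label", "annotation_class"]].copy()
        ann.index.name = "region_id"
        ann.to_csv(annotation_path, sep="\t")


def read_counts(path, meta_path) -> CoveragePanel:
    """Read the counts TSV (header = region_ids, first column = genotype_id)
    and its metadata TSV (genotype_id, total_aligned_reads[, read_length,
    genome_length])."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = "genotype_id"
    counts.columns.name = "region_id"
    if counts.isna().any().any():
        raise ValueError(f"{path}: missing counts are not permitted")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError(f"{path}: negative count")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: counts must be integers")
    counts = counts.astype(np.int64)

    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"genotypes missing from metadata: {missing.tolist()}")
    totals = meta["total_aligned_reads"].reindex(counts.index).astype(np.int64)
    read_length = int(meta["read_length"].iloc[0]) if "read_length" in meta else 100
    genome_length = (
        float(meta["genome_length"].iloc[0]) if "genome_length" in meta else 8.5e8
    )
    return CoveragePanel(counts, totals, read_length, genome_length)


def write_counts(panel: CoveragePanel, path, meta_path) -> None:
    counts = panel.counts.copy()
    counts.index.name = "genotype_id"
    counts.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "total_aligned_reads": panel.total_aligned_reads,
            "read_length": panel.read_length,
            "genome_length": f"{panel.genome_length:.10g}",
        }
    )
    meta.index.name = "genotype_id"
    meta.to_csv(meta_path, sep="\t")


def read_homeolog_map(path, regions: RegionTable) -> HomeologMap:
    """Read a two-column TSV (group_id, region_id), validated against the
    region table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"group_id", "region_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns group_id, region_id")
    return HomeologMap.from_pairs(
        list(df[["group_id", "region_id"]].itertuples(index=False, name=None)), regions
    )


def write_homeolog_map(hmap: HomeologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tregion_id\n")
        for gid, members in hmap.groups.items():
            for rid in members:
                fh.write(f"{gid}\t{rid}\n")


def read_depth_profiles(path, regions: RegionTable | None = None) -> dict:
    """Read per-base depth profiles: TSV of region_id, comma-separated depths.

    When a RegionTable is given, each vector's length is checked against the
    region length.
    """
    profiles: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("region_id"):
            raise ValueError(f"{path}: expected header starting with region_id")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            rid, depth_s = line.split("\t", 1)
            depths = np.fromstring(depth_s, dtype=np.int64, sep=",")
            if (depths < 0).any():
                raise ValueError(f"{path}:{lineno}: negative depth")
            if regions is not None:
                if rid not in regions.df.index:
                    raise ValueError(f"{path}:{lineno}: unknown region {rid!r}")
                expected = int(regions.df.loc[rid, "length"])
                if len(depths) != expected:
                    raise ValueError(
                        f"{path}:{lineno}: profile length {len(depths)} != "
                        f"region length {expected}"
                    )
            profiles[rid] = depths
    return profiles


def write_depth_profiles(profiles: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tdepths\n")
        for rid, depths in profiles.items():
            fh.write(f"{rid}\t{','.join(map(str, np.asarray(depths, dtype=int)))}\n")


def read_morphotype_labels(path, panel: CoveragePanel | None = None) -> pd.Series:
    """Read genotype → morphotype labels (TSV: genotype_id, morphotype).

    Labels may cover a subset of the panel, but unknown genotypes are
    rejected when a panel is given.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("genotype_id")
    labels = df["morphotype"]
    if panel is not None:
        unknown = labels.index.difference(panel.genotype_ids)
        if len(unknown):
            raise ValueError(f"morphotype labels for unknown genotypes: {unknown.tolist()}")
    return labels


def write_morphotype_labels(labels: pd.Series, path) -> None:
    out = labels.rename("morphotype").to_frame()
    out.index.name = "genotype_id"
    out.to_csv(path, sep="\t")


def adapt_multicov_table(path, regions: RegionTable, genotype_ids: Sequence[str]):
    """Convert a ``bedtools multicov`` output table into a counts DataFrame.

    multicov emits the BED columns (chrom, start, end, name) followed by one
    count column per BAM, in the order the BAMs were given. ``genotype_ids``
    names those columns. This is a documented adapter for external
    preprocessing; BAM handling itself is out of scope.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    n_bed = 4
    if df.shape[1] != n_bed + len(genotype_ids):
        raise ValueError(
            f"expected {n_bed} BED columns + {len(genotype_ids)} count columns, "
            f"got {df.shape[1]}"
        )
    df.columns = ["chrom", "start", "end", "region_id"] + list(genotype_ids)
    df = df.set_index("region_id")
    unknown = df.index.difference(regions.df.index)
    if len(unknown):
        raise ValueError(f"multicov rows for unknown regions: {unknown.tolist()}")
    counts = df[list(genotype_ids)].T
    counts.index.name = "genotype_id"
    return counts.astype(np.int64)
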