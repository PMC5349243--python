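"""Classification of CNV calls into simple events and homeologous
non-reciprocal translocations (HNRTs).

In an allopolyploid, a duplication of one subgenome's gene copy coupled with
deletion of its homeolog on the other subgenome is the read-depth signature
of an HNRT: the donor copy has replaced its homeologous counterpart. Within
each genotype and homeolog group, duplicated copies on one subgenome are
paired with deleted copies on the other; each call is consumed at most once,
and what cannot be paired stays a simple duplication or deletion.

Event-table convention: one row per event. For an HNRT the row's region is
the duplicated (donor) copy, ``partner_region_id`` the deleted (acceptor)
copy, and the direction runs donor → acceptor (``A_to_C`` means the A copy
replaced the C copy). This makes call conservation exact: the number of
duplication calls equals simple_duplication rows plus hnrt rows, and
likewise for deletions.

Pairing is greedy in lexicographic region_id order, which makes the result
deterministic and independent of input row order for homeolog groups with
more than two members. Only cross-subgenome (A with C) pairings are
considered, and copies on unassembled ``*_random`` scaffolds are excluded
from pairing by default (their calls still yield simple events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnv_calling import CNVCallMatrix
from .regions_io import GENIC_CLASSES, HomeologMap, RegionTable

__all__ = [
    "EVENT_COLUMNS",
    "SubgenomeSummary",
    "HNRTLandscape",
    "classify_events",
    "classify_cell_events",
    "subgenome_event_counts",
    "deletion_duplication_correlation",
    "hnrt_landscape",
]

EVENT_COLUMNS = (
    "genotype_id",
    "region_id",
    "event_type",
    "partner_region_id",
    "direction",
    "subgenome",
)


@dataclass(frozen=True)
class SubgenomeSummary:
    """Simple-event counts per subgenome at three nested scopes (all
    captured regions ⊇ genic regions ⊇ target genes), plus HNRT counts by
    direction.

    ``simple_counts`` is indexed by (scope, subgenome) with columns
    ``deletions`` and ``duplications``; HNRTs contribute only to
    ``hnrt_by_direction``, never to the simple tallies.
    """

    simple_counts: pd.DataFrame
    hnrt_by_direction: dict

    @property
    def total_hnrt(self) -> int:
        return int(sum(self.hnrt_by_direction.values()))


@dataclass(frozen=True)
class HNRTLandscape:
    """HNRT counts per ordered donor→acceptor chromosome pair and simple
    event counts per region — the ingredients of a chromosome-map figure."""

    pair_counts: pd.DataFrame  # columns: donor_chrom, acceptor_chrom, count
    region_simple_counts: pd.DataFrame  # columns: region_id, simple_duplications, simple_deletions

    @property
    def total_hnrt(self) -> int:
        return int(self.pair_counts["count"].sum())


def classify_cell_events(
    cell_events: pd.DataFrame,
    hmap: HomeologMap,
    regions: RegionTable,
    exclude_random: bool = True,
) -> pd.DataFrame:
    """Classify a genotypes × regions matrix of cell-level events.

    ``cell_events`` holds "deletion", "duplication" or "" per cell. This is
    the classification core shared by :func:`classify_events` (which feeds
    it CNV calls) and by the simulator (which feeds it planted events to
    derive the ground-truth event table with identical pairing semantics).
    """
    unknown = [
        rid for members in hmap.groups.values() for rid in members
        if rid not in cell_events.columns
    ]
    if unknown:
        raise ValueError(f"homeolog map references regions absent from calls: {unknown}")

    subg = regions.df["subgenome"]
    random_flag = regions.df["is_random_scaffold"]
    # per group: lexicographically sorted pairable members split by subgenome
    group_sides: list[tuple[list, list]] = []
    for gid in sorted(hmap.groups):
        members = sorted(hmap.groups[gid])
        pairable = [m for m in members if not (exclude_random and random_flag.get(m, False))]
        a_side = [m for m in pairable if subg.get(m) == "A"]
        c_side = [m for m in pairable if subg.get(m) == "C"]
        if a_side and c_side:
            group_sides.append((a_side, c_side))

    mat = cell_events.to_numpy(dtype=object)
    col_of = {rid: j for j, rid in enumerate(cell_events.columns)}
    subg_arr = subg.reindex(cell_events.columns).fillna("other").to_numpy()

    rows: list[tuple] = []
    for i, gid in enumerate(cell_events.index):
        row = mat[i]
        consumed: set[int] = set()
        for a_side, c_side in group_sides:
            for donors, acceptors, direction in (
                (a_side, c_side, "A_to_C"),
                (c_side, a_side, "C_to_A"),
            ):
                dup_js = [
                    col_of[m] for m in donors
                    if row[col_of[m]] == "duplication" and col_of[m] not in consumed
                ]
                del_js = [
                    col_of[m] for m in acceptors
                    if row[col_of[m]] == "deletion" and col_of[m] not in consumed
                ]
                for dj, lj in zip(dup_js, del_js):
                    consumed.update((dj, lj))
                    rows.append(
                        (
                            gid,
                            cell_events.columns[dj],
                            "hnrt",
                            cell_events.columns[lj],
                            direction,
                            subg_arr[dj],
                        )
                    )
        for j in np.nonzero(row != "")[0]:
            if j in consumed:
                continue
            event = "simple_deletion" if row[j] == "deletion" else "simple_duplication"
            rows.append((gid, cell_events.columns[j], event, "", "none", subg_arr[j]))

    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return events.sort_values(["genotype_id", "region_id"], kind="stable").reset_index(
        drop=True
    )


def classify_events(
    calls: CNVCallMatrix,
    hmap: HomeologMap,
    regions: RegionTable,
    exclude_random: bool = True,
) -> pd.DataFrame:
    """Classify a CNV call matrix into simple and HNRT events.

    no_call cells contribute nothing. See the module docstring for pairing
    semantics and the one-row-per-event table convention.
    """
    arr = calls.calls.to_numpy(dtype=object).copy()
    arr[(arr == "normal") | (arr == "no_call")] = ""
    cell_events = pd.DataFrame(arr, index=calls.calls.index, columns=calls.calls.columns)
    return classify_cell_events(cell_events, hmap, regions, exclude_random)


def subgenome_event_counts(events: pd.DataFrame, regions: RegionTable) -> SubgenomeSummary:
    """Tally simple events per subgenome at the all / genic / target-gene
    scopes, and HNRTs by direction."""
    ann = regions.df["annotation_class"]
    scopes = {
        "all": pd.Series(True, index=regions.df.index),
        "genic": ann.isin(GENIC_CLASSES),
        "target": ann == "target_gene",
    }
    simple = events[events["event_type"] != "hnrt"]
    idx = pd.MultiIndex.from_product(
        [list(scopes), ["A", "C", "other"]], names=["scope", "subgenome"]
    )
    counts = pd.DataFrame(0, index=idx, columns=["deletions", "duplications"])
    for scope_name, mask in scopes.items():
        in_scope = simple[simple["region_id"].map(mask).fillna(False)]
        for etype, col in (
            ("simple_deletion", "deletions"),
            ("simple_duplication", "duplications"),
        ):
            tally = in_scope.loc[in_scope["event_type"] == etype, "subgenome"].value_counts()
            for sg, c in tally.items():
                counts.loc[(scope_name, sg), col] = int(c)
    hnrt = events[events["event_type"] == "hnrt"]
    by_dir = {
        "A_to_C": int((hnrt["direction"] == "A_to_C").sum()),
        "C_to_A": int((hnrt["direction"] == "C_to_A").sum()),
    }
    return SubgenomeSummary(counts, by_dir)


def deletion_duplication_correlation(
    events: pd.DataFrame,
    regions: RegionTable,
    subgenome: str,
    unit: str = "region",
) -> tuple[float, float]:
    """Pearson correlation between simple-deletion and simple-duplication
    counts on one subgenome's target-gene copies.

    ``unit="region"`` (default) correlates per-gene-copy carrier counts;
    ``unit="genotype"`` correlates per-genotype event counts instead. Needs
    at least 3 units and non-zero variance in both counts.
    """
    if subgenome not in ("A", "C"):
        raise ValueError(f"subgenome must be 'A' or 'C', got {subgenome!r}")
    if unit not in ("region", "genotype"):
        raise ValueError(f"unit must be 'region' or 'genotype', got {unit!r}")
    df = regions.df
    copy_ids = df.index[(df["annotation_class"] == "target_gene") & (df["subgenome"] == subgenome)]
    if len(copy_ids) < 3 and unit == "region":
        raise ValueError(f"need >= 3 target-gene copies on subgenome {subgenome}")
    simple = events[
        (events["event_type"] != "hnrt") & events["region_id"].isin(copy_ids)
    ]
    key = "region_id" if unit == "region" else "genotype_id"
    if unit == "region":
        units = pd.Index(copy_ids)
    else:
        units = pd.Index(sorted(events["genotype_id"].unique()))
        if len(units) < 3:
            raise ValueError("need >= 3 genotypes")
    x = (
        simple[simple["event_type"] == "simple_deletion"][key]
        .value_counts()
        .reindex(units, fill_value=0)
        .to_numpy(dtype=float)
    )
    y = (
        simple[simple["event_type"] == "simple_duplication"][key]
        .value_counts()
        .reindex(units, fill_value=0)
        .to_numpy(dtype=float)
    )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in deletion or duplication counts; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def hnrt_landscape(events: pd.DataFrame, regions: RegionTable) -> HNRTLandscape:
    """Summarize events for a chromosome-landscape view: HNRT counts per
    ordered donor→acceptor chromosome pair, and simple duplication/deletion
    counts per region."""
    chrom = regions.df["chrom"]
    hnrt = events[events["event_type"] == "hnrt"]
    if len(hnrt):
        pairs = (
            pd.DataFrame(
                {
                    "donor_chrom": hnrt["region_id"].map(chrom),
                    "acceptor_chrom": hnrt["partner_region_id"].map(chrom),
                }
            )
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["donor_chrom", "acceptor_chrom"], kind="stable")
            .reset_index(drop=True)
        )
    else:
        pairs = pd.DataFrame(columns=["donor_chrom", "acceptor_chrom", "count"])
    simple = events[events["event_type"] != "hnrt"]
    per_region = pd.DataFrame(
        {
            "simple_duplications": simple[simple["event_type"] == "simple_duplication"][
                "region_id"
            ].value_counts(),
            "simple_deletions": simple[simple["event_type"] == "simple_deletion"][
                "region_id"
            ].value_counts(),
        }
    ).fillna(0).astype(int)
    per_region.index.name = "region_id"
    per_region = per_region.sort_index().reset_index()
    return HNRTLandscape(pairs, per_region)
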