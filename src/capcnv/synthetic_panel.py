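"""Synthetic capture-coverage panels with planted CNV/HNRT truth.

Emulates the structure of a targeted-capture diversity panel of inbred
allopolyploid (AACC) lines: ~280 genotypes assayed over ~1,184 enriched
regions of which 231 are intended targets (homeologous flowering-gene
copies, promoter fragments and pseudogenes), sequenced to ~670x mean target
coverage with 100 bp single-end reads against an ~850 Mb reference.

Read-depth model
----------------
The expected read count of region r in genotype g factorizes as

    mu[g, r] = base[r] * capture_efficiency[r] * library_factor[g] * copy_ratio[g, r]

with ``base = mean_target_depth * length / read_length`` for target regions
(scaled down by ``off_target_depth_fraction`` for captured off-target
regions), a per-region gamma-distributed capture efficiency (mean 1), a
per-genotype log-normal library-size factor, and the planted copy ratio
(1 unaltered, 0 homozygous deletion, 2 one extra copy — the lines are
inbred, so events are homozygous by default). Counts are Poisson draws
around mu (the gamma efficiency makes the marginal a gamma–Poisson
mixture, i.e. overdispersed), or ``round(mu)`` in noiseless mode. Each
genotype's total aligned reads are set so that its on-target read fraction
matches ``on_target_fraction``, the remainder standing for reads aligned
outside any captured region.

Planted events
--------------
Per genotype, each homeolog group with pairable A and C copies carries an
HNRT with probability ``hnrt_prevalence`` (direction A→C with probability
``hnrt_direction_bias``): the donor copy gets the duplication ratio, the
acceptor the deletion ratio. Remaining cells carry independent simple
deletions/duplications with the per-region prevalences. The ground-truth
event table is derived from the planted cell events with the exact pairing
semantics of the classifier, so a coincidental duplication–deletion pair
across homeologs is ground-truth HNRT — by definition, that coupling *is*
the read-depth signature of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_classification import classify_cell_events
from .regions_io import CoveragePanel, HomeologMap, RegionTable

__all__ = ["SimulationConfig", "SimulatedPanel", "simulate_panel", "simulate_depth_profiles"]

#: homeologous chromosome numbering of the A and C subgenomes used for layout
_A_CHROMS = [f"chrA{i:02d}" for i in range(1, 11)]
_C_CHROMS = [f"chrC{i:02d}" for i in range(1, 10)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic panel.

    Panel shape: 280 genotypes, 1184 captured regions of which 231 targets;
    231 = target-gene copies (homeolog groups) + 33 promoter fragments + 12
    pseudogenes. Coverage: 670x mean target depth, 100 bp reads, 8.5e8 bp
    genome, 68% on-target read fraction. Event prevalences are per genotype:
    per homeolog group for HNRTs, per region for simple events; the defaults
    put the panel in the rare-CNV regime observed in diverse natural panels
    (most CNVs carried by <10% of genotypes). Direction bias is the fraction
    of HNRTs oriented A→C.
    """

    n_genotypes: int = 280
    n_regions: int = 1184
    n_target_regions: int = 231
    n_homeolog_groups: int = 80
    n_promoter_regions: int = 33
    n_pseudogene_regions: int = 12
    random_scaffold_group_fraction: float = 0.10
    random_scaffold_offtarget_fraction: float = 0.05
    mean_target_depth: float = 670.0
    read_length: int = 100
    genome_length: float = 8.5e8
    off_target_depth_fraction: float = 0.02
    on_target_fraction: float = 0.68
    deletion_ratio: float = 0.0
    duplication_ratio: float = 2.0
    deletion_prevalence: float = 0.011
    duplication_prevalence: float = 0.010
    hnrt_prevalence: float = 0.009
    hnrt_direction_bias: float = 0.82
    library_size_sd: float = 0.3
    capture_efficiency_shape: float = 20.0
    noise: str = "poisson"
    morphotype_counts: tuple = (("winter", 137), ("spring", 94), ("semi", 25), ("swede", 24))
    morphotype_prevalence_multipliers: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deletion_prevalence", "duplication_prevalence", "hnrt_prevalence",
                     "hnrt_direction_bias", "on_target_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.deletion_ratio < 0 or self.duplication_ratio < 0:
            raise ValueError("copy ratios must be >= 0")
        if self.deletion_ratio == 1.0 or self.duplication_ratio == 1.0:
            raise ValueError("event copy ratios must differ from 1 (the unaltered state)")
        if self.n_target_regions > self.n_regions:
            raise ValueError("n_target_regions cannot exceed n_regions")
        n_grouped = self.n_target_regions - self.n_promoter_regions - self.n_pseudogene_regions
        if n_grouped < 2 * self.n_homeolog_groups:
            raise ValueError(
                f"config demands {self.n_homeolog_groups} homeolog groups but only "
                f"{n_grouped} target-gene copies are available"
            )
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"noise must be 'poisson' or 'none', got {self.noise!r}")
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")

    @property
    def prevalence_multiplier_map(self) -> dict:
        return dict(self.morphotype_prevalence_multipliers)


@dataclass(frozen=True)
class SimulatedPanel:
    """A simulated panel and everything known about how it was made."""

    panel: CoveragePanel
    regions: RegionTable
    homeologs: HomeologMap
    truth: pd.DataFrame  # ground-truth event table (classifier schema)
    labels: pd.Series  # genotype -> morphotype
    copy_ratios: pd.DataFrame  # genotypes x regions latent copy ratios
    config: SimulationConfig

    def __iter__(self):
        # unpack like (panel, regions, homeologs, truth, labels)
        return iter((self.panel, self.regions, self.homeologs, self.truth, self.labels))


def _build_regions(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out the captured regions and the homeolog grouping.

    Target-gene copies come in homeolog pairs on matched A/C chromosomes; a
    fraction of groups carries an extra copy on an unassembled *_random
    scaffold. The 231-region target also includes promoter fragments and
    pseudogenes (ungrouped); the remaining regions are captured off-target
    genes and other loci.
    """
    rows = []  # (region_id, chrom, length, is_target, gene_label, annotation_class)
    group_pairs = []  # (group_id, region_id)

    gene_names = [f"G{i:03d}" for i in range(cfg.n_homeolog_groups)]
    n_random_groups = int(round(cfg.random_scaffold_group_fraction * cfg.n_homeolog_groups))
    random_group_idx = set(
        rng.choice(cfg.n_homeolog_groups, size=n_random_groups, replace=False).tolist()
    )
    for i, gene in enumerate(gene_names):
        k = int(rng.integers(0, len(_C_CHROMS)))  # matched homeologous chromosome pair
        a_chrom, c_chrom = _A_CHROMS[k], _C_CHROMS[k]
        length = int(rng.integers(1500, 4501))
        for chrom, sg in ((a_chrom, "A"), (c_chrom, "C")):
            rid = f"Bna.{gene}.{chrom[3:]}"
            rows.append((rid, chrom, length, True, rid, "target_gene"))
            group_pairs.append((gene, rid))
        if i in random_group_idx:
            sg_letter = "A" if rng.random() < 0.5 else "C"
            rid = f"Bna.{gene}.{sg_letter}nn_random"
            rows.append(
                (rid, f"chr{sg_letter}nn_random", int(rng.integers(1500, 4501)),
                 True, rid, "target_gene")
            )
            group_pairs.append((gene, rid))

    n_gene_copies = len(rows)
    n_extra_targets = cfg.n_target_regions - n_gene_copies
    n_promoters = min(cfg.n_promoter_regions, n_extra_targets)
    n_pseudo = n_extra_targets - n_promoters
    all_chroms = _A_CHROMS + _C_CHROMS
    for i in range(n_promoters):
        chrom = all_chroms[int(rng.integers(0, len(all_chroms)))]
        rows.append((f"prom{i:03d}.{chrom[3:]}", chrom, int(rng.integers(500, 1501)),
                     True, "", "target_promoter"))
    for i in range(n_pseudo):
        chrom = all_chroms[int(rng.integers(0, len(all_chroms)))]
        rows.append((f"pseudo{i:03d}.{chrom[3:]}", chrom, int(rng.integers(500, 2001)),
                     True, "", "pseudogene"))

    n_off = cfg.n_regions - cfg.n_target_regions
    n_off_genes = int(round(n_off * 0.475))  # captured non-target genes (~637 genic total)
    for i in range(n_off):
        if rng.random() < cfg.random_scaffold_offtarget_fraction:
            chrom = "chrAnn_random" if rng.random() < 0.5 else "chrCnn_random"
        else:
            chrom = all_chroms[int(rng.integers(0, len(all_chroms)))]
        cls = "non_target_gene" if i < n_off_genes else "non_target_other"
        rows.append((f"off{i:04d}.{chrom[3:]}", chrom, int(rng.integers(500, 3001)),
                     False, "", cls))

    # assign non-overlapping coordinates per chromosome, in region order
    cursor: dict[str, int] = {}
    recs = []
    for rid, chrom, length, is_target, label, cls in rows:
        start = cursor.get(chrom, 10_000)
        end = start + length
        cursor[chrom] = end + int(rng.integers(5_000, 50_000))
        recs.append((rid, chrom, start, end, is_target, label, cls))
    df = pd.DataFrame(
        recs,
        columns=["region_id", "chrom", "start", "end", "is_target", "gene_label",
                 "annotation_class"],
    ).set_index("region_id")
    regions = RegionTable.from_frame(df)
    hmap = HomeologMap.from_pairs(group_pairs, regions)
    return regions, hmap


def _plant_events(
    cfg: SimulationConfig,
    regions: RegionTable,
    hmap: HomeologMap,
    labels: pd.Series,
    genotype_ids: pd.Index,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plant HNRT and simple events; returns the genotypes × regions
    cell-event matrix with values in {"", "deletion", "duplication"}."""
    region_ids = regions.df.index
    cell = pd.DataFrame("", index=genotype_ids, columns=region_ids, dtype=object)
    mult_map = cfg.prevalence_multiplier_map
    mult = labels.map(lambda m: mult_map.get(m, 1.0)).reindex(genotype_ids).fillna(1.0)

    subg = regions.df["subgenome"]
    random_flag = regions.df["is_random_scaffold"]
    pairable_groups = []
    for gid in sorted(hmap.groups):
        members = sorted(hmap.groups[gid])
        a_side = [m for m in members if subg[m] == "A" and not random_flag[m]]
        c_side = [m for m in members if subg[m] == "C" and not random_flag[m]]
        if a_side and c_side:
            pairable_groups.append((a_side[0], c_side[0]))

    for g in genotype_ids:
        m = float(mult.loc[g])
        p_hnrt = min(1.0, cfg.hnrt_prevalence * m)
        for a_copy, c_copy in pairable_groups:
            if rng.random() >= p_hnrt:
                continue
            if rng.random() < cfg.hnrt_direction_bias:
                donor, acceptor = a_copy, c_copy
            else:
                donor, acceptor = c_copy, a_copy
            cell.loc[g, donor] = "duplication"
            cell.loc[g, acceptor] = "deletion"

    # independent simple events on still-unaltered cells
    u = rng.random(size=cell.shape)
    p_del = np.minimum(1.0, cfg.deletion_prevalence * mult.to_numpy())[:, None]
    p_dup = np.minimum(1.0, cfg.duplication_prevalence * mult.to_numpy())[:, None]
    arr = cell.to_numpy()
    free = arr == ""
    arr[free & (u < p_del)] = "deletion"
    arr[free & (u >= p_del) & (u < p_del + p_dup)] = "duplication"
    return pd.DataFrame(arr, index=genotype_ids, columns=region_ids)


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Simulate a coverage panel with known truth.

    Identical config (including seed) gives bit-identical outputs. The
    returned object unpacks as ``panel, regions, homeologs, truth, labels``
    and also carries the latent copy-ratio matrix and the config.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    regions, hmap = _build_regions(cfg, rng)

    genotype_ids = pd.Index([f"BnASSYST_{i + 1:03d}" for i in range(cfg.n_genotypes)],
                            name="genotype_id")
    label_pool: list[str] = []
    for name, count in cfg.morphotype_counts:
        label_pool.extend([name] * count)
    if len(label_pool) < cfg.n_genotypes:
        label_pool.extend([cfg.morphotype_counts[0][0]] * (cfg.n_genotypes - len(label_pool)))
    labels = pd.Series(label_pool[: cfg.n_genotypes], index=genotype_ids, name="morphotype")

    cell_events = _plant_events(cfg, regions, hmap, labels, genotype_ids, rng)

    ratios = pd.DataFrame(1.0, index=genotype_ids, columns=regions.df.index)
    arr = cell_events.to_numpy()
    rmat = ratios.to_numpy()
    rmat[arr == "deletion"] = cfg.deletion_ratio
    rmat[arr == "duplication"] = cfg.duplication_ratio

    lengths = regions.lengths.to_numpy(dtype=float)
    base = cfg.mean_target_depth * lengths / cfg.read_length
    base = np.where(regions.df["is_target"].to_numpy(), base,
                    base * cfg.off_target_depth_fraction)
    cap_eff = rng.gamma(cfg.capture_efficiency_shape,
                        1.0 / cfg.capture_efficiency_shape, size=len(lengths))
    lib = rng.lognormal(0.0, cfg.library_size_sd, size=cfg.n_genotypes)

    mu = rmat * base[None, :] * cap_eff[None, :] * lib[:, None]
    if cfg.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        counts = np.rint(mu).astype(np.int64)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genotype_ids,
                             columns=regions.df.index)

    target_mask = regions.df["is_target"].to_numpy()
    on_target = counts[:, target_mask].sum(axis=1)
    all_sum = counts.sum(axis=1)
    totals = np.maximum(np.ceil(on_target / cfg.on_target_fraction), all_sum).astype(np.int64)
    totals = np.maximum(totals, 1)
    panel = CoveragePanel(counts_df, pd.Series(totals, index=genotype_ids),
                          cfg.read_length, cfg.genome_length)

    truth = classify_cell_events(cell_events, hmap, regions, exclude_random=True)
    return SimulatedPanel(panel, regions, hmap, truth, labels, ratios_from(rmat, ratios), cfg)


def ratios_from(rmat: np.ndarray, template: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(rmat, index=template.index, columns=template.columns)


def simulate_depth_profiles(
    panel: CoveragePanel,
    regions: RegionTable,
    config: SimulationConfig,
    genotype_id: str | None = None,
    seed: int | None = None,
) -> dict:
    """Per-base depth profiles for the target regions of one genotype.

    Each of the genotype's counted reads gets a uniformly random start such
    that it lies inside the region when the region is at least one read
    long; regions shorter than the read are covered end-to-end by every
    read (the read is truncated at the region edges). Consequently the
    summed depth of a profile is count × read_length minus what truncation
    removed.
    """
    if genotype_id is None:
        genotype_id = str(panel.genotype_ids[0])
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rl = panel.read_length
    profiles: dict[str, np.ndarray] = {}
    for rid in regions.target_ids:
        length = int(regions.df.loc[rid, "length"])
        if length < 1:
            raise ValueError(f"region {rid!r} shorter than 1 base")
        count = int(panel.counts.loc[genotype_id, rid])
        depth = np.zeros(length, dtype=np.int64)
        if count > 0:
            if length <= rl:
                depth[:] = count
            else:
                starts = rng.integers(0, length - rl + 1, size=count)
                np.add.at(depth, starts, 1)
                ends = starts + rl
                np.add.at(depth, ends[ends < length], -1)
                depth = np.cumsum(depth)
        profiles[rid] = depth
    return profiles
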