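import numpy as np
import pandas as pd
import pytest

from capcnv.regions_io import CoveragePanel, HomeologMap, RegionTable
from capcnv.synthetic_panel import SimulationConfig, simulate_panel


@pytest.fixture
def tiny_regions() -> RegionTable:
    """Six hand-built regions: one homeolog pair + a random-scaffold copy,
    one ungrouped target, and two off-target regions."""
    df = pd.DataFrame(
        {
            "chrom": ["chrA03", "chrC03", "chrCnn_random", "chrA01", "chrC05", "chrUn"],
            "start": [1000, 2000, 0, 500, 100, 0],
            "end": [2200, 3200, 1200, 1500, 1100, 800],
            "is_target": [True, True, True, True, False, False],
            "gene_label": ["Bna.FRI.A03", "Bna.FRI.C03", "Bna.FRI.Cnn_random",
                           "Bna.FT.A01", "", ""],
            "annotation_class": ["target_gene", "target_gene", "target_gene",
                                 "target_gene", "non_target_gene", "non_target_other"],
        },
        index=pd.Index(
            ["Bna.FRI.A03", "Bna.FRI.C03", "Bna.FRI.Cnn_random", "Bna.FT.A01",
             "offgene.C05", "other.Un"],
            name="region_id",
        ),
    )
    return RegionTable.from_frame(df)


@pytest.fixture
def tiny_homeologs(tiny_regions) -> HomeologMap:
    return HomeologMap.from_pairs(
        [("FRI", "Bna.FRI.A03"), ("FRI", "Bna.FRI.C03"), ("FRI", "Bna.FRI.Cnn_random")],
        tiny_regions,
    )


@pytest.fixture
def tiny_panel(tiny_regions) -> CoveragePanel:
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(50, 200, size=(4, 6)),
        index=pd.Index([f"g{i}" for i in range(4)], name="genotype_id"),
        columns=tiny_regions.region_ids,
    )
    totals = counts.sum(axis=1) * 3
    return CoveragePanel(counts, totals, read_length=100, genome_length=8.5e8)


@pytest.fixture(scope="session")
def small_noiseless_sim():
    """A small noiseless panel with planted events, shared across tests."""
    cfg = SimulationConfig(
        n_genotypes=40,
        n_regions=120,
        n_target_regions=40,
        n_homeolog_groups=14,
        n_promoter_regions=6,
        n_pseudogene_regions=3,
        deletion_prevalence=0.04,
        duplication_prevalence=0.03,
        hnrt_prevalence=0.05,
        noise="none",
        seed=11,
    )
    return simulate_panel(cfg)
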