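"""HNRT pairing and event summaries: coupled-event semantics, greedy
multi-copy pairing, conservation identities, bias summaries, correlation."""

import numpy as np
import pandas as pd
import pytest

from capcnv.cnv_calling import CNVCallMatrix
from capcnv.event_classification import (
    classify_events,
    deletion_duplication_correlation,
    hnrt_landscape,
    subgenome_event_counts,
)
from capcnv.regions_io import HomeologMap


def make_calls(regions, states_by_genotype):
    """CNVCallMatrix from {genotype: {region: state}} over a RegionTable."""
    rids = regions.region_ids
    gids = pd.Index(sorted(states_by_genotype), name="genotype_id")
    arr = np.full((len(gids), len(rids)), "normal", dtype=object)
    for i, g in enumerate(gids):
        for rid, state in states_by_genotype[g].items():
            arr[i, list(rids).index(rid)] = state
    calls = pd.DataFrame(arr, index=gids, columns=rids)
    return CNVCallMatrix(calls, pd.DataFrame(1.0, index=gids, columns=rids))


class TestClassifyEvents:
    def test_coupled_dup_del_is_hnrt_a_to_c(self, tiny_regions, tiny_homeologs):
        calls = make_calls(
            tiny_regions,
            {"g0": {"Bna.FRI.A03": "duplication", "Bna.FRI.C03": "deletion"}},
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        assert len(events) == 1
        row = events.iloc[0]
        assert row["event_type"] == "hnrt"
        assert row["region_id"] == "Bna.FRI.A03"
        assert row["partner_region_id"] == "Bna.FRI.C03"
        assert row["direction"] == "A_to_C"
        assert row["subgenome"] == "A"

    def test_reverse_coupling_is_c_to_a(self, tiny_regions, tiny_homeologs):
        calls = make_calls(
            tiny_regions,
            {"g0": {"Bna.FRI.C03": "duplication", "Bna.FRI.A03": "deletion"}},
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        assert events.iloc[0]["direction"] == "C_to_A"
        assert events.iloc[0]["region_id"] == "Bna.FRI.C03"

    def test_unpaired_duplication_is_simple(self, tiny_regions, tiny_homeologs):
        calls = make_calls(tiny_regions, {"g0": {"Bna.FRI.A03": "duplication"}})
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        assert events.iloc[0]["event_type"] == "simple_duplication"
        assert events.iloc[0]["partner_region_id"] == ""
        assert events.iloc[0]["direction"] == "none"

    def test_deletion_without_homeolog_group_is_simple(self, tiny_regions, tiny_homeologs):
        calls = make_calls(tiny_regions, {"g0": {"Bna.FT.A01": "deletion"}})
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        assert events.iloc[0]["event_type"] == "simple_deletion"

    def test_random_scaffold_excluded_from_pairing(self, tiny_regions, tiny_homeologs):
        """A dup on the A copy with dels on both the C copy and the
        C*_random copy pairs with the assembled C copy only; the
        random-scaffold deletion stays simple."""
        calls = make_calls(
            tiny_regions,
            {
                "g0": {
                    "Bna.FRI.A03": "duplication",
                    "Bna.FRI.C03": "deletion",
                    "Bna.FRI.Cnn_random": "deletion",
                }
            },
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions, exclude_random=True)
        by_type = events.set_index("event_type")
        assert by_type.loc["hnrt", "partner_region_id"] == "Bna.FRI.C03"
        assert by_type.loc["simple_deletion", "region_id"] == "Bna.FRI.Cnn_random"

    def test_include_random_pairs_lexicographically(self, tiny_regions, tiny_homeologs):
        """With exclude_random off, the greedy rule pairs the dup with the
        lexicographically first deleted C copy (Bna.FRI.C03 < Bna.FRI.Cnn_random)."""
        calls = make_calls(
            tiny_regions,
            {
                "g0": {
                    "Bna.FRI.A03": "duplication",
                    "Bna.FRI.C03": "deletion",
                    "Bna.FRI.Cnn_random": "deletion",
                }
            },
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions, exclude_random=False)
        hnrt = events[events["event_type"] == "hnrt"].iloc[0]
        assert hnrt["partner_region_id"] == "Bna.FRI.C03"

    def test_same_subgenome_coupling_stays_simple(self, tiny_regions):
        """Coupled dup+del within one subgenome is never an HNRT."""
        hmap = HomeologMap.from_pairs(
            [("X", "Bna.FRI.A03"), ("X", "Bna.FT.A01")], tiny_regions
        )
        calls = make_calls(
            tiny_regions,
            {"g0": {"Bna.FRI.A03": "duplication", "Bna.FT.A01": "deletion"}},
        )
        events = classify_events(calls, hmap, tiny_regions)
        assert set(events["event_type"]) == {"simple_duplication", "simple_deletion"}

    def test_map_referencing_absent_region_rejected(self, tiny_regions, tiny_homeologs):
        calls = make_calls(tiny_regions, {"g0": {}})
        calls_sub = CNVCallMatrix(
            calls.calls.drop(columns=["Bna.FRI.C03"]),
            calls.ratios.drop(columns=["Bna.FRI.C03"]),
        )
        with pytest.raises(ValueError, match="absent from calls"):
            classify_events(calls_sub, tiny_homeologs, tiny_regions)

    def test_no_call_cells_contribute_nothing(self, tiny_regions, tiny_homeologs):
        calls = make_calls(tiny_regions, {"g0": {"Bna.FRI.A03": "no_call"}})
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        assert len(events) == 0

    def test_call_conservation(self, small_noiseless_sim):
        """Every deletion call becomes exactly one simple_deletion or hnrt
        row, and likewise for duplications."""
        from capcnv.cnv_calling import call_cnv
        from capcnv.coverage_qc import normalize_coverage

        sim = small_noiseless_sim
        norm = normalize_coverage(sim.panel, sim.regions)
        calls = call_cnv(norm)
        events = classify_events(calls, sim.homeologs, sim.regions)
        n_del_calls = int((calls.calls == "deletion").sum().sum())
        n_dup_calls = int((calls.calls == "duplication").sum().sum())
        n_hnrt = int((events["event_type"] == "hnrt").sum())
        assert n_del_calls == (events["event_type"] == "simple_deletion").sum() + n_hnrt
        assert n_dup_calls == (events["event_type"] == "simple_duplication").sum() + n_hnrt

    def test_direction_consistency(self, small_noiseless_sim):
        sim = small_noiseless_sim
        subg = sim.regions.df["subgenome"]
        hnrt = sim.truth[sim.truth["event_type"] == "hnrt"]
        for row in hnrt.itertuples(index=False):
            src, dst = row.direction.split("_to_")
            assert subg[row.region_id] == src != dst == subg[row.partner_region_id]

    def test_noiseless_recovery_equals_truth(self, small_noiseless_sim):
        from capcnv.cnv_calling import call_cnv
        from capcnv.coverage_qc import normalize_coverage

        sim = small_noiseless_sim
        calls = call_cnv(normalize_coverage(sim.panel, sim.regions))
        events = classify_events(calls, sim.homeologs, sim.regions)
        pd.testing.assert_frame_equal(
            events.reset_index(drop=True), sim.truth.reset_index(drop=True)
        )


class TestSubgenomeSummary:
    def test_empty_events_all_zero(self, tiny_regions):
        events = pd.DataFrame(
            columns=["genotype_id", "region_id", "event_type", "partner_region_id",
                     "direction", "subgenome"]
        )
        summary = subgenome_event_counts(events, tiny_regions)
        assert (summary.simple_counts.to_numpy() == 0).all()
        assert summary.total_hnrt == 0

    def test_target_scope_tally(self, tiny_regions, tiny_homeologs):
        states = {
            "g0": {"Bna.FRI.C03": "deletion", "Bna.FT.A01": "deletion"},
            "g1": {"Bna.FRI.C03": "deletion"},
            "g2": {"Bna.FRI.C03": "deletion"},
        }
        # break the would-be pairings: no duplications anywhere
        calls = make_calls(tiny_regions, states)
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        summary = subgenome_event_counts(events, tiny_regions)
        assert summary.simple_counts.loc[("target", "A"), "deletions"] == 1
        assert summary.simple_counts.loc[("target", "C"), "deletions"] == 3

    def test_hnrt_counts_direction_not_simple(self, tiny_regions, tiny_homeologs):
        calls = make_calls(
            tiny_regions,
            {"g0": {"Bna.FRI.A03": "duplication", "Bna.FRI.C03": "deletion"}},
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        summary = subgenome_event_counts(events, tiny_regions)
        assert summary.hnrt_by_direction == {"A_to_C": 1, "C_to_A": 0}
        assert (summary.simple_counts.to_numpy() == 0).all()

    def test_scopes_are_nested(self, small_noiseless_sim):
        sim = small_noiseless_sim
        summary = subgenome_event_counts(sim.truth, sim.regions)
        counts = summary.simple_counts
        for sg in ("A", "C", "other"):
            for col in ("deletions", "duplications"):
                assert (
                    counts.loc[("target", sg), col]
                    <= counts.loc[("genic", sg), col]
                    <= counts.loc[("all", sg), col]
                )


class TestCorrelation:
    def _events_from_counts(self, regions, del_counts, dup_counts):
        rows = []
        for rid, n in del_counts.items():
            for i in range(n):
                rows.append((f"g{i}", rid, "simple_deletion", "", "none",
                             regions.df.loc[rid, "subgenome"]))
        for rid, n in dup_counts.items():
            for i in range(n):
                rows.append((f"h{i}", rid, "simple_duplication", "", "none",
                             regions.df.loc[rid, "subgenome"]))
        return pd.DataFrame(
            rows, columns=["genotype_id", "region_id", "event_type",
                           "partner_region_id", "direction", "subgenome"]
        )

    def _c_regions(self):
        import pandas as pd

        from capcnv.regions_io import RegionTable

        n = 5
        return RegionTable.from_frame(
            pd.DataFrame(
                {
                    "chrom": ["chrC03"] * n,
                    "start": np.arange(n) * 1_000,
                    "end": np.arange(n) * 1_000 + 500,
                    "is_target": True,
                    "annotation_class": "target_gene",
                },
                index=pd.Index([f"c{i}" for i in range(n)], name="region_id"),
            )
        )

    def test_perfect_correlation(self):
        regions = self._c_regions()
        dels = {f"c{i}": i + 1 for i in range(5)}
        events = self._events_from_counts(regions, dels, dels)
        r, p = deletion_duplication_correlation(events, regions, "C")
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        regions = self._c_regions()
        dels = {f"c{i}": i for i in range(5)}
        dups = {f"c{i}": 4 - i for i in range(5)}
        events = self._events_from_counts(regions, dels, dups)
        r, _ = deletion_duplication_correlation(events, regions, "C")
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        regions = self._c_regions()
        dels = {"c0": 3, "c1": 0, "c2": 5, "c3": 2, "c4": 7}
        dups = {"c0": 1, "c1": 2, "c2": 4, "c3": 0, "c4": 6}
        events = self._events_from_counts(regions, dels, dups)
        r, _ = deletion_duplication_correlation(events, regions, "C")
        x = np.array([dels[f"c{i}"] for i in range(5)], dtype=float)
        y = np.array([dups[f"c{i}"] for i in range(5)], dtype=float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        regions = self._c_regions()
        events = self._events_from_counts(
            regions, {f"c{i}": 2 for i in range(5)}, {f"c{i}": i for i in range(5)}
        )
        with pytest.raises(ValueError, match="zero variance"):
            deletion_duplication_correlation(events, regions, "C")


class TestHNRTLandscape:
    def test_single_pair_counted(self, tiny_regions, tiny_homeologs):
        calls = make_calls(
            tiny_regions,
            {"g0": {"Bna.FRI.A03": "duplication", "Bna.FRI.C03": "deletion"}},
        )
        events = classify_events(calls, tiny_homeologs, tiny_regions)
        land = hnrt_landscape(events, tiny_regions)
        assert land.pair_counts.iloc[0].tolist() == ["chrA03", "chrC03", 1]

    def test_pair_counts_sum_to_total(self, small_noiseless_sim):
        sim = small_noiseless_sim
        land = hnrt_landscape(sim.truth, sim.regions)
        assert land.total_hnrt == (sim.truth["event_type"] == "hnrt").sum()

    def test_region_simple_counts_match_tally(self, small_noiseless_sim):
        sim = small_noiseless_sim
        land = hnrt_landscape(sim.truth, sim.regions)
        simple = sim.truth[sim.truth["event_type"] != "hnrt"]
        for row in land.region_simple_counts.itertuples(index=False):
            expected_dup = (
                (simple["region_id"] == row.region_id)
                & (simple["event_type"] == "simple_duplication")
            ).sum()
            expected_del = (
                (simple["region_id"] == row.region_id)
                & (simple["event_type"] == "simple_deletion")
            ).sum()
            assert row.simple_duplications == expected_dup
            assert row.simple_deletions == expected_del
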