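"""End-to-end orchestration: simulate/load → QC → normalize → call →
classify → summarize → recode, with a checksummed output manifest.

A run is driven by one :class:`AnalysisConfig`. Every stage writes plain TSV
(floats at 6 significant digits so checksums are platform-stable; full
precision is kept in memory), and the manifest records a SHA-256 per output
so that two runs with the same config and seed can be compared file by
file. Progress is logged to standard error with stage tags; stdout is never
used for outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coverage_qc, cnv_calling, event_classification, regions_io, validation
from .synthetic_panel import SimulationConfig, simulate_panel, simulate_depth_profiles

__all__ = ["AnalysisConfig", "run_analysis", "recovery_metrics"]

logger = logging.getLogger("capcnv")

FLOAT_FORMAT = "%.6g"


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (a synthetic panel is generated under
    ``seed``) or the four input paths point at an existing panel on disk.
    Thresholds mirror the analysis defaults: calling band 0.5/1.5, rare-CNV
    cutoff 10%, deep-coverage threshold 11 (= more than 10 reads), marker
    filters 0.9/0.01/0.8.
    """

    out_dir: str = "capcnv_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    counts_meta_path: str | None = None
    regions_path: str | None = None
    regions_annotation_path: str | None = None
    homeologs_path: str | None = None
    morphotypes_path: str | None = None
    lower: float = 0.5
    upper: float = 1.5
    rare_threshold: float = 0.10
    depth_threshold: int = 11
    exclude_random: bool = True
    filter_thresholds: validation.FilterThresholds = field(
        default_factory=validation.FilterThresholds
    )
    compute_profiles: bool = False
    n_profile_genotypes: int | None = 8
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        filt = raw.pop("filter_thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            if "seed" not in sim:
                sim["seed"] = cfg.seed
            if isinstance(sim.get("morphotype_counts"), list):
                sim["morphotype_counts"] = tuple(tuple(x) for x in sim["morphotype_counts"])
            cfg.simulation = SimulationConfig(**sim)
        if filt is not None:
            cfg.filter_thresholds = validation.FilterThresholds(**filt)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def recovery_metrics(truth: pd.DataFrame, events: pd.DataFrame, calls) -> dict:
    """Compare called events and calls against a planted truth table.

    Returns cell-level sensitivity (planted event cells called with the
    expected state), false-call rate (non-normal calls at unplanted cells,
    as a fraction of unplanted cells), event-level exact recovery, HNRT
    direction accuracy (planted HNRTs recovered with correct donor, partner
    and direction), and whether the two event tables agree exactly.
    """
    expected: dict[tuple, str] = {}
    for row in truth.itertuples(index=False):
        if row.event_type == "hnrt":
            expected[(row.genotype_id, row.region_id)] = "duplication"
            expected[(row.genotype_id, row.partner_region_id)] = "deletion"
        elif row.event_type == "simple_deletion":
            expected[(row.genotype_id, row.region_id)] = "deletion"
        else:
            expected[(row.genotype_id, row.region_id)] = "duplication"

    call_df = calls.calls
    hits = 0
    for (g, r), state in expected.items():
        if call_df.loc[g, r] == state:
            hits += 1
    n_truth_cells = len(expected)
    call_sensitivity = hits / n_truth_cells if n_truth_cells else float("nan")

    non_normal = call_df.isin(["deletion", "duplication"])
    n_false = int(non_normal.sum().sum()) - sum(
        1 for (g, r), s in expected.items() if call_df.loc[g, r] in ("deletion", "duplication")
    )
    n_cells = call_df.size
    n_unplanted = n_cells - n_truth_cells
    false_call_rate = n_false / n_unplanted if n_unplanted else float("nan")

    key_cols = ["genotype_id", "region_id", "event_type", "partner_region_id", "direction"]
    truth_keys = set(map(tuple, truth[key_cols].to_numpy()))
    event_keys = set(map(tuple, events[key_cols].to_numpy()))
    event_sensitivity = (
        len(truth_keys & event_keys) / len(truth_keys) if truth_keys else float("nan")
    )

    truth_hnrt = truth[truth["event_type"] == "hnrt"]
    hnrt_keys = set(
        map(tuple, events[events["event_type"] == "hnrt"][key_cols].to_numpy())
    )
    if len(truth_hnrt):
        ok = sum(1 for row in truth_hnrt[key_cols].to_numpy() if tuple(row) in hnrt_keys)
        hnrt_direction_accuracy = ok / len(truth_hnrt)
    else:
        hnrt_direction_accuracy = float("nan")

    return {
        "n_truth_events": int(len(truth)),
        "n_called_events": int(len(events)),
        "call_sensitivity": call_sensitivity,
        "false_call_rate": false_call_rate,
        "event_sensitivity": event_sensitivity,
        "hnrt_direction_accuracy": hnrt_direction_accuracy,
        "exact_match": bool(truth_keys == event_keys),
    }


def _configure_logging(verbosity: str) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[capcnv:%(stage)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline; returns the output manifest.

    The manifest lists every written file with its SHA-256 checksum, the
    seed, and headline numbers of the run. Identical config + seed produce
    identical checksums. Any stage failure is re-raised with the stage name.
    """
    _configure_logging(config.verbosity)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict = {}
    stage = "setup"
    try:
        truth = None
        sim = None
        if config.simulation is not None:
            stage = "simulate"
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg = SimulationConfig(**{**asdict_config(sim_cfg), "seed": config.seed})
            sim = simulate_panel(sim_cfg)
            panel, regions, hmap, truth, labels = sim
            _log(stage, f"simulated {panel.n_genotypes} genotypes x {len(regions)} regions, "
                        f"{len(truth)} planted events")
            regions_io.write_regions(regions, out / "regions.bed", out / "regions_annotation.tsv")
            regions_io.write_counts(panel, out / "counts.tsv", out / "counts_meta.tsv")
            regions_io.write_homeolog_map(hmap, out / "homeologs.tsv")
            regions_io.write_morphotype_labels(labels, out / "morphotypes.tsv")
            _write_tsv(truth, out / "truth.tsv", index=False)
            outputs.update({
                "regions.bed": out / "regions.bed",
                "regions_annotation.tsv": out / "regions_annotation.tsv",
                "counts.tsv": out / "counts.tsv",
                "counts_meta.tsv": out / "counts_meta.tsv",
                "homeologs.tsv": out / "homeologs.tsv",
                "morphotypes.tsv": out / "morphotypes.tsv",
                "truth.tsv": out / "truth.tsv",
            })
        else:
            stage = "load"
            if not (config.counts_path and config.counts_meta_path and config.regions_path):
                raise ValueError("need counts_path, counts_meta_path and regions_path "
                                 "when no simulation is configured")
            regions = regions_io.read_regions(config.regions_path,
                                              config.regions_annotation_path)
            panel = regions_io.read_counts(config.counts_path, config.counts_meta_path)
            hmap = (regions_io.read_homeolog_map(config.homeologs_path, regions)
                    if config.homeologs_path else regions_io.HomeologMap({}))
            labels = (regions_io.read_morphotype_labels(config.morphotypes_path, panel)
                      if config.morphotypes_path else None)
            _log(stage, f"loaded {panel.n_genotypes} genotypes x {len(regions)} regions")

        stage = "qc"
        profiles = None
        if config.compute_profiles:
            if config.simulation is None:
                raise ValueError("depth profiles can only be simulated for simulated panels")
            gids = list(panel.genotype_ids)
            if config.n_profile_genotypes is not None:
                gids = gids[: config.n_profile_genotypes]
            profiles = {
                g: simulate_depth_profiles(panel, regions, sim.config, genotype_id=g,
                                           seed=config.seed + 1000 + i)
                for i, g in enumerate(gids)
            }
            qc_panel = subset_panel(panel, gids)
            qc_labels = labels.loc[labels.index.intersection(gids)] if labels is not None else None
        else:
            qc_panel, qc_labels = panel, labels
        qc = coverage_qc.qc_report(qc_panel, regions, profiles, qc_labels,
                                   config.depth_threshold)
        qc_out = qc.per_genotype.copy()
        qc_out.loc["PANEL_MEAN"] = qc.panel_mean
        if qc.per_morphotype is not None:
            for m, row in qc.per_morphotype.iterrows():
                qc_out.loc[f"MEAN_{m}"] = row
        qc_out.index.name = "genotype_id"
        _write_tsv(qc_out, out / "qc_report.tsv")
        outputs["qc_report.tsv"] = out / "qc_report.tsv"
        summary["mean_target_coverage"] = float(qc.panel_mean["mean_target_coverage"])
        summary["enrichment_factor"] = float(qc.panel_mean["enrichment_factor"])
        summary["target_specificity_pct"] = float(qc.panel_mean["target_specificity"])
        _log(stage, f"mean target coverage {summary['mean_target_coverage']:.1f}x, "
                    f"enrichment factor {summary['enrichment_factor']:.0f}")

        stage = "normalize"
        norm = coverage_qc.normalize_coverage(panel, regions)
        _write_tsv(norm.matrix, out / "normalized_coverage.tsv")
        outputs["normalized_coverage.tsv"] = out / "normalized_coverage.tsv"

        stage = "call"
        calls = cnv_calling.call_cnv(norm, config.lower, config.upper)
        _write_tsv(calls.to_symbols(), out / "calls.tsv")
        _write_tsv(calls.ratios, out / "ratios.tsv")
        outputs["calls.tsv"] = out / "calls.tsv"
        outputs["ratios.tsv"] = out / "ratios.tsv"
        n_del = int((calls.calls == "deletion").sum().sum())
        n_dup = int((calls.calls == "duplication").sum().sum())
        summary["n_deletion_calls"] = n_del
        summary["n_duplication_calls"] = n_dup
        _log(stage, f"{n_del} deletion and {n_dup} duplication calls")

        stage = "frequency"
        freq, fraction_rare = cnv_calling.cnv_frequency_spectrum(
            calls, labels, config.rare_threshold
        )
        _write_tsv(freq, out / "cnv_frequency.tsv", index=False)
        outputs["cnv_frequency.tsv"] = out / "cnv_frequency.tsv"
        summary["fraction_rare_cnv"] = fraction_rare
        _log(stage, f"{len(freq)} carried CNVs, {100 * fraction_rare:.1f}% rare")

        stage = "classify"
        events = event_classification.classify_events(calls, hmap, regions,
                                                      config.exclude_random)
        _write_tsv(events, out / "events.tsv", index=False)
        outputs["events.tsv"] = out / "events.tsv"
        sg = event_classification.subgenome_event_counts(events, regions)
        _write_tsv(sg.simple_counts, out / "subgenome_summary.tsv")
        outputs["subgenome_summary.tsv"] = out / "subgenome_summary.tsv"
        land = event_classification.hnrt_landscape(events, regions)
        _write_tsv(land.pair_counts, out / "hnrt_pairs.tsv", index=False)
        _write_tsv(land.region_simple_counts, out / "region_simple_counts.tsv", index=False)
        outputs["hnrt_pairs.tsv"] = out / "hnrt_pairs.tsv"
        outputs["region_simple_counts.tsv"] = out / "region_simple_counts.tsv"
        summary["n_hnrt_events"] = sg.total_hnrt
        summary["hnrt_by_direction"] = sg.hnrt_by_direction
        _log(stage, f"{sg.total_hnrt} HNRT events "
                    f"({sg.hnrt_by_direction['A_to_C']} A->C, "
                    f"{sg.hnrt_by_direction['C_to_A']} C->A)")

        stage = "markers"
        markers = validation.recode_cnv_markers(calls)
        filtered = validation.filter_markers(markers, config.filter_thresholds)
        _write_tsv(filtered.values, out / "cnv_markers_filtered.tsv")
        outputs["cnv_markers_filtered.tsv"] = out / "cnv_markers_filtered.tsv"
        summary["n_cnv_markers"] = int(len(markers.markers))
        summary["n_cnv_markers_filtered"] = int(len(filtered.markers))
        _log(stage, f"{len(markers.markers)} CNV markers, "
                    f"{len(filtered.markers)} after filtering")

        if truth is not None:
            stage = "recovery"
            rec = recovery_metrics(truth, events, calls)
            pd.Series(rec).to_frame("value").to_csv(out / "recovery.tsv", sep="\t",
                                                    float_format=FLOAT_FORMAT)
            outputs["recovery.tsv"] = out / "recovery.tsv"
            summary["recovery"] = rec
            _log(stage, f"event sensitivity {100 * rec['event_sensitivity']:.2f}%, "
                        f"false-call rate {100 * rec['false_call_rate']:.3f}%")

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "thresholds": {
                "lower": config.lower,
                "upper": config.upper,
                "rare_threshold": config.rare_threshold,
                "depth_threshold": config.depth_threshold,
            },
            "summary": summary,
            "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        _log(stage, f"wrote {len(outputs)} outputs to {out}")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def asdict_config(cfg: SimulationConfig) -> dict:
    return asdict(cfg)


def subset_panel(panel, genotype_ids):
    from .regions_io import CoveragePanel

    return CoveragePanel(
        panel.counts.loc[genotype_ids],
        panel.total_aligned_reads.loc[genotype_ids],
        panel.read_length,
        panel.genome_length,
    )
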