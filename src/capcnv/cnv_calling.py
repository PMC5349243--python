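"""Panel-relative CNV calling from normalized coverage.

A region is called in a genotype by comparing its normalized coverage with
the panel mean for that region: ratio < 0.5 → deletion, ratio > 1.5 →
duplication, otherwise normal. The inequalities are strict, so a ratio of
exactly 0.5 or 1.5 is normal. The panel mean is the arithmetic mean over
all genotypes including the focal one; a consequence is that very common
CNVs shift the mean toward themselves and can partially self-mask —
documented behaviour, not corrected. Regions whose panel mean is zero give
``no_call`` for every genotype (the ratio is undefined there).

For inbred, effectively homozygous material the expected ratio is ~0 for a
homozygous deletion and ~2 for one extra copy, so the 0.5/1.5 band separates
the three states with a wide margin at high coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_qc import NormalizedCoverageMatrix

__all__ = [
    "CALL_STATES",
    "CALL_SYMBOLS",
    "CNVCallMatrix",
    "panel_mean",
    "call_cnv",
    "cnv_frequency_spectrum",
]

CALL_STATES = ("deletion", "normal", "duplication", "no_call")

#: compact symbols used in calls TSV files
CALL_SYMBOLS = {
    "deletion": "DEL",
    "normal": "NORM",
    "duplication": "DUP",
    "no_call": "NC",
}
SYMBOL_STATES = {v: k for k, v in CALL_SYMBOLS.items()}


@dataclass(frozen=True)
class CNVCallMatrix:
    """Genotypes × regions CNV calls with the ratios and thresholds behind
    them.

    ``calls`` holds state strings from :data:`CALL_STATES`; ``ratios`` holds
    the coverage ratio against the panel mean (NaN where no_call). The
    thresholds are recorded for provenance.
    """

    calls: pd.DataFrame
    ratios: pd.DataFrame
    lower: float = 0.5
    upper: float = 1.5

    @property
    def genotype_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def region_ids(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_genotypes(self) -> int:
        return len(self.calls.index)

    def to_symbols(self) -> pd.DataFrame:
        return self.calls.replace(CALL_SYMBOLS)

    @classmethod
    def from_symbols(
        cls, symbols: pd.DataFrame, ratios: pd.DataFrame | None = None,
        lower: float = 0.5, upper: float = 1.5,
    ) -> "CNVCallMatrix":
        unknown = set(np.unique(symbols.to_numpy())) - set(SYMBOL_STATES)
        if unknown:
            raise ValueError(f"unknown call symbols: {sorted(unknown)}")
        calls = symbols.replace(SYMBOL_STATES)
        if ratios is None:
            ratios = pd.DataFrame(
                np.nan, index=symbols.index, columns=symbols.columns
            )
        return cls(calls, ratios, lower, upper)


def panel_mean(norm: NormalizedCoverageMatrix) -> pd.Series:
    """Per-region arithmetic mean of normalized coverage over all genotypes.

    Needs at least two genotypes — the ratio of a genotype to a panel mean
    made only of itself is always 1 and carries no information.
    """
    if len(norm.genotype_ids) < 2:
        raise ValueError("panel mean requires at least 2 genotypes")
    return norm.matrix.mean(axis=0)


def call_cnv(
    norm: NormalizedCoverageMatrix, lower: float = 0.5, upper: float = 1.5
) -> CNVCallMatrix:
    """Call deletion/normal/duplication per cell by the strict ratio rule.

    ratio = cell / panel mean of the region; deletion iff ratio < lower,
    duplication iff ratio > upper, otherwise normal. Regions with zero panel
    mean are no_call for every genotype.
    """
    if not (0 <= lower < upper):
        raise ValueError(f"invalid thresholds: need 0 <= lower < upper, got {lower}, {upper}")
    means = panel_mean(norm)
    mat = norm.matrix.to_numpy(dtype=float)
    mean_arr = means.to_numpy(dtype=float)
    callable_cols = mean_arr > 0

    ratios = np.full_like(mat, np.nan)
    ratios[:, callable_cols] = mat[:, callable_cols] / mean_arr[callable_cols]

    calls = np.full(mat.shape, "normal", dtype=object)
    with np.errstate(invalid="ignore"):
        calls[ratios < lower] = "deletion"
        calls[ratios > upper] = "duplication"
    calls[:, ~callable_cols] = "no_call"

    idx, cols = norm.matrix.index, norm.matrix.columns
    return CNVCallMatrix(
        pd.DataFrame(calls, index=idx, columns=cols),
        pd.DataFrame(ratios, index=idx, columns=cols),
        lower,
        upper,
    )


def cnv_frequency_spectrum(
    calls: CNVCallMatrix,
    labels: pd.Series | None = None,
    rare_threshold: float = 0.10,
) -> tuple[pd.DataFrame, float]:
    """Population frequency of each carried CNV and the share that is rare.

    Returns a table with one row per (region, call type) that has at least
    one carrier — columns region_id, call_type, carriers, frequency, plus
    per-morphotype carrier counts when labels are given — and the fraction
    of those entries with frequency strictly below ``rare_threshold``.
    """
    if not (0 < rare_threshold <= 1):
        raise ValueError(f"rare_threshold must be in (0, 1], got {rare_threshold}")
    n = calls.n_genotypes
    rows = []
    for call_type in ("deletion", "duplication"):
        carrier = calls.calls == call_type
        counts = carrier.sum(axis=0)
        for rid, c in counts[counts > 0].items():
            row = {
                "region_id": rid,
                "call_type": call_type,
                "carriers": int(c),
                "frequency": c / n,
            }
            if labels is not None:
                for morpho, gids in labels.groupby(labels).groups.items():
                    row[f"carriers_{morpho}"] = int(carrier.loc[gids, rid].sum())
            rows.append(row)
    table = pd.DataFrame(
        rows, columns=["region_id", "call_type", "carriers", "frequency"]
        + ([f"carriers_{m}" for m in sorted(labels.unique())] if labels is not None else [])
    )
    if len(table):
        fraction_rare = float((table["frequency"] < rare_threshold).mean())
    else:
        fraction_rare = float("nan")
    return table, fraction_rare
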