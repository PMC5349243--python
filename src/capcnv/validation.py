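"""Cross-platform validation: marker recoding, filtering, concordance.

CNV calls (and externally supplied SNP/InDel genotypes) are recoded into a
common individuals × markers matrix so that call sets from different
platforms — capture sequencing, a SNP array, Sanger resequencing — can be
filtered with one rule set and compared marker by marker. Values are 0/1
(biallelic presence coding) or 0/1/2 (dosage), with NaN for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_calling import CNVCallMatrix

__all__ = [
    "MarkerMatrix",
    "FilterThresholds",
    "recode_cnv_markers",
    "filter_markers",
    "concordance_rate",
]


@dataclass(frozen=True)
class MarkerMatrix:
    """Individuals × markers matrix; NaN encodes missing.

    ``alphabet`` declares the legal non-missing values: (0, 1) for biallelic
    presence/absence coding, (0, 1, 2) for genotype dosage. The minor-allele
    frequency of a marker is computed on its non-missing calls, with values
    read as allele dosage out of ``max(alphabet)``.
    """

    values: pd.DataFrame
    alphabet: tuple = (0, 1)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        legal = np.isin(present, np.asarray(self.alphabet, dtype=float))
        if not legal.all():
            bad = sorted(set(present[~legal].tolist()))
            raise ValueError(f"marker values outside alphabet {self.alphabet}: {bad}")

    @property
    def individuals(self) -> pd.Index:
        return self.values.index

    @property
    def markers(self) -> pd.Index:
        return self.values.columns

    def call_rate_per_marker(self) -> pd.Series:
        return self.values.notna().mean(axis=0)

    def call_rate_per_individual(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker, over non-missing calls."""
        ploidy = float(max(self.alphabet))
        p = self.values.mean(axis=0, skipna=True) / ploidy
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class FilterThresholds:
    """Strict lower bounds for keeping markers/individuals: a marker needs
    non-missing fraction > marker_call_rate and MAF > minor_allele_frequency;
    an individual needs non-missing fraction > individual_call_rate on the
    surviving markers."""

    marker_call_rate: float = 0.9
    minor_allele_frequency: float = 0.01
    individual_call_rate: float = 0.8

    def __post_init__(self) -> None:
        for name in ("marker_call_rate", "minor_allele_frequency", "individual_call_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def recode_cnv_markers(calls: CNVCallMatrix) -> MarkerMatrix:
    """Recode CNV calls to biallelic markers.

    One marker per (region, event type) that has at least one carrier,
    named ``<region>:DEL`` / ``<region>:DUP``: carrier → 1, non-carrier → 0,
    no_call → missing.
    """
    cols = {}
    for call_type, suffix in (("deletion", "DEL"), ("duplication", "DUP")):
        carrier = calls.calls == call_type
        no_call = calls.calls == "no_call"
        for rid in calls.region_ids:
            if carrier[rid].any():
                col = carrier[rid].astype(float)
                col[no_call[rid]] = np.nan
                cols[f"{rid}:{suffix}"] = col
    values = pd.DataFrame(cols, index=calls.genotype_ids)
    return MarkerMatrix(values, alphabet=(0, 1))


def filter_markers(m: MarkerMatrix, t: FilterThresholds | None = None) -> MarkerMatrix:
    """Drop low-call-rate and low-MAF markers, then low-call-rate individuals.

    Markers first: keep those with non-missing fraction > marker_call_rate
    and MAF > minor_allele_frequency (MAF on non-missing calls). Then
    individuals, with call rate recomputed on the surviving markers. The
    operation is idempotent. An empty result is returned as such, not raised.
    """
    if t is None:
        t = FilterThresholds()
    keep_markers = (m.call_rate_per_marker() > t.marker_call_rate) & (
        m.maf() > t.minor_allele_frequency
    )
    vals = m.values.loc[:, keep_markers[keep_markers].index]
    if vals.shape[1] == 0:
        return MarkerMatrix(vals.iloc[0:0], m.alphabet)
    ind_rate = vals.notna().mean(axis=1)
    vals = vals.loc[ind_rate > t.individual_call_rate]
    return MarkerMatrix(vals, m.alphabet)


def concordance_rate(
    a: MarkerMatrix,
    b: MarkerMatrix,
    pairing: Sequence[tuple],
) -> tuple[float, pd.Series]:
    """Agreement between two call sets over paired markers.

    ``pairing`` lists (marker_in_a, marker_in_b) pairs. For each pair,
    concordance (%) is the fraction of shared individuals, non-missing in
    both, where the calls agree; the overall rate pools matches and
    comparisons across pairs. Pairs with zero comparisons get NaN and do
    not enter the overall rate. The per-pair series, sorted ascending,
    ranks markers for removal of poorly concordant ones.
    """
    if len(pairing) == 0:
        raise ValueError("empty marker pairing")
    shared = a.individuals.intersection(b.individuals)
    if len(shared) == 0:
        raise ValueError("no shared individuals between marker sets")
    total_matches = 0
    total_comparisons = 0
    per_pair = {}
    for ma, mb in pairing:
        if ma not in a.values.columns:
            raise ValueError(f"marker {ma!r} absent from first set")
        if mb not in b.values.columns:
            raise ValueError(f"marker {mb!r} absent from second set")
        xa = a.values.loc[shared, ma]
        xb = b.values.loc[shared, mb]
        both = xa.notna() & xb.notna()
        n = int(both.sum())
        if n == 0:
            per_pair[f"{ma}|{mb}"] = np.nan
            continue
        matches = int((xa[both] == xb[both]).sum())
        per_pair[f"{ma}|{mb}"] = 100.0 * matches / n
        total_matches += matches
        total_comparisons += n
    if total_comparisons == 0:
        raise ValueError("no comparable calls in any marker pair")
    overall = 100.0 * total_matches / total_comparisons
    return overall, pd.Series(per_pair).sort_values()
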