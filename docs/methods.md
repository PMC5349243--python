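# Methods

## Read-depth model and its assumptions

The analysis rests on the standard read-depth assumption for capture
sequencing: conditional on library size and capture efficiency, aligned
reads fall on a region in proportion to its copy number, so coverage
deviations indicate deletions or duplications. Normalization

    cov_norm[g, r] = n[g, r] · G / (N[g] · L[r])

removes library size `N[g]` and region length `L[r]`; the genome length `G`
is a fixed scale factor (default 8.5×10⁸ bp, the approximate size of the
*B. napus* reference assembly; it cancels in all ratio-based calls and is
configurable because published capture studies rarely print the exact value
used). The caller compares each genotype with the arithmetic panel mean of
the same region, so it detects variation *relative to the panel consensus*,
not absolute copy number: a CNV shared by the whole panel is invisible, and
a CNV carried by a large fraction of the panel drags the mean toward itself
(self-masking). Both are inherent to the panel-relative design and are
documented rather than corrected; with per-region carrier fractions under
~20% and copy ratios 0/2, the ratio margins remain wide.

Boundary semantics are deliberate and tested: ratios of exactly 0.5 or 1.5
are *normal* (strict inequalities), and a region whose panel mean is zero
yields `no_call` for every genotype — a ratio against zero is undefined,
and forcing deletions there would mislabel capture failures.

## HNRT classification

An HNRT's read-depth signature is a duplication of one subgenome's copy
coupled with deletion of its homeolog in the same genotype. Classification
therefore works per genotype and homeolog group: duplicated A copies are
paired with deleted C copies (direction `A_to_C`, the A copy replaced the
C copy) and vice versa. Pairing is greedy in lexicographic region-id order,
which is deterministic and independent of input row order; groups with more
than two members (e.g. an extra copy on an unassembled scaffold) consume
each call at most once. Copies on `*_random` scaffolds are excluded from
pairing by default — their placement is unreliable, so a coupled signal
involving them is not credible evidence of an exchange — but their calls
still surface as simple events. Only cross-subgenome (A↔C) couplings count:
a dup+del pair within one subgenome stays two simple events.

The event table carries one row per event; for an HNRT the row's region is
the duplicated donor copy and `partner_region_id` the deleted acceptor.
This makes the conservation identity exact (deletion calls =
simple-deletion rows + HNRT rows; likewise duplications), which the tests
assert on every simulated run. Cell-level data cannot distinguish a true
exchange from an independent co-occurring duplication and deletion of
homeologs; like the source analyses in this field, the classification is
"putative" by construction, and the simulator's ground truth uses the same
pairing semantics so that the distinction is well defined.

## Synthetic panel

The generator emulates a species-wide diversity panel of inbred (≥5
generations selfed, hence effectively homozygous) allopolyploid lines:

| parameter | default | meaning |
|---|---|---|
| n_genotypes | 280 | panel size |
| n_regions / n_target_regions | 1184 / 231 | captured regions / intended targets |
| n_homeolog_groups | 80 | A/C target-gene groups (2 copies each; ~10% carry a third copy on a `*_random` scaffold) |
| n_promoter_regions / n_pseudogene_regions | 33 / 12 | ungrouped target promoter fragments / pseudogenes |
| mean_target_depth | 670x | expected target coverage |
| read_length / genome_length | 100 bp / 8.5×10⁸ bp | sequencing and reference scale |
| on_target_fraction | 0.68 | share of aligned reads on target (sets library size) |
| off_target_depth_fraction | 0.02 | off-target regions' expected depth relative to targets (~13x, keeping captured off-target regions above the >10-read threshold typical of enriched-region lists; no published value exists for this, so it is a free parameter) |
| deletion_ratio / duplication_ratio | 0 / 2 | homozygous loss / one extra copy; heterozygous 0.5/1.5 available for threshold-sensitivity studies |
| deletion/duplication/hnrt prevalence | 0.011 / 0.010 / 0.009 | per genotype per region (simple) or per homeolog group (HNRT); chosen so a 280-line panel carries a few hundred simple events and ~200 HNRTs on target genes, the regime reported for natural diversity panels |
| hnrt_direction_bias | 0.82 | fraction of HNRTs oriented A→C, matching the strong A-replaces-C bias of natural *B. napus* |
| library_size_sd | 0.3 | lognormal sigma of per-genotype library factors |
| capture_efficiency_shape | 20 | gamma shape of per-region efficiency (mean 1, CV ≈ 22%) |

Counts are Poisson around `base · efficiency · library · copy_ratio`, where
`base = depth · L / read_length`; the gamma efficiency factor makes the
marginal count distribution an overdispersed gamma–Poisson mixture, but the
factor is shared by all genotypes of a region and so cancels in the
panel-relative ratio — exactly the property that makes the ratio caller
robust in real capture data. Library size is set from the realized
on-target reads so that the on-target fraction is controllable. Morphotype
labels (137 winter / 94 spring / 25 semi / 24 swede by default) allow
per-group event-prevalence multipliers to emulate morphotype-enriched CNVs.

What the generator does **not** model: GC and mappability bias, reference
errors, mapping ambiguity between homeologs, duplicate reads, segmental
events spanning multiple regions, heterozygosity (beyond optional 0.5/1.5
ratios), and linkage between events in related lines. Passing recovery
tests therefore demonstrates correctness of the computational chain under
the stated read-depth model, not calling accuracy on real alignments, where
homeolog cross-mapping is the dominant error source.

Depth profiles for base-resolution QC place each counted read uniformly at
random within its region (reads covering the whole region when the region
is shorter than a read), so summed depth equals reads × read length up to
edge truncation; they are generated per genotype on demand rather than
materialized for the full panel.

## QC metrics

Enrichment factor = mean target coverage / mean genome-wide coverage;
specificity = 100 × on-target reads / total aligned reads (computed on
reads — a read counted in a region is wholly on-target — which coincides
with the base-level definition whenever reads lie inside regions);
sensitivity = % of target bases at depth ≥ d, with d = 11 for the
"more than 10 reads" variant (strict reading). "Normalized mean target
coverage" is the target-region mean of `cov_norm`. The normalization obeys
an exact mass identity, Σ_r cov_norm·L/G = on-target read fraction, used as
a numerical check at 10⁻¹².

## Validation stage

CNV calls are recoded to biallelic markers (one per region × event type
with ≥1 carrier; carrier = 1, no-call = missing), filtered with strict
thresholds as printed (> 0.9 marker call rate, > 0.01 MAF on non-missing
calls, > 0.8 individual call rate), markers before individuals — the order
is the common convention; the thresholds' source does not state one — and
compared across platforms by per-marker and pooled concordance over
individuals non-missing in both sets. The per-marker ranking supports
removing poorly concordant markers either by rank or by threshold; both are
left to the caller since published workflows have removed such markers by
inspection.

## Numerical and design choices

- Thresholds 0.5/1.5 and all filter cut-offs are parameters with the
  published defaults; the call matrix records the thresholds used.
- The panel mean includes the focal genotype ("all genotypes" read
  literally); excluding it is a one-line change but alters boundary cases,
  so the literal reading is kept and tested.
- The deletion–duplication correlation is computed per target-gene copy
  (x = deletion carriers, y = duplication carriers per region) via Pearson;
  a per-genotype alternative is exposed as an option because the unit of
  analysis is ambiguous in the field's reports.
- Pipeline outputs print floats at 6 significant digits so that manifest
  SHA-256 checksums are platform-stable; full precision is kept in memory.
- Simulation sizes in the test suite: module tests use 12–40 genotype
  panels; the acceptance properties run the full 280 × 1184 panel
  (noiseless once, Poisson × 10 seeds), which completes in well under a
  minute — chosen as the smallest scales at which the respective properties
  are meaningfully exercised.

## Known limitations

- No segmentation or HMM smoothing across adjacent regions; each region is
  called independently (by design — regions are discrete capture targets).
- No integer copy-number estimation; calls are three-state.
- Panel-relative calling cannot see panel-fixed CNVs and can self-mask very
  common ones (documented above).
- HNRT calls are putative: read depth alone cannot rule out independent
  co-occurring events, and breakpoints are not localized.
- The simulator's independence assumptions (events independent across
  genotypes and regions) understate the block structure of real
  homeologous exchanges.
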