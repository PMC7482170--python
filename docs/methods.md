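# Methods

This note documents the models and procedures implemented in `radmut`,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical decisions taken where the
design was genuinely open.

## Study design being modelled

Dry seeds are acutely gamma-irradiated; surviving M1 plants are selfed;
one M2 plant per M1 individual is whole-genome resequenced. A mutation
induced in the (effectively single-cell) dormant embryo genome is
heterozygous in M1 and segregates 1:2:1 in M2 — homozygous mutant with
probability 1/4, heterozygous 1/2, absent 1/4 — so among *detected*
mutations the homozygous:heterozygous ratio is expected at 0.5. The
analysis treats detected mutations identically regardless of zygosity
when counting events.

## Call filtering

Thresholds (config keys, defaults): `af_exclusion_max = 0.25` (calls
with AF ≤ 25% discarded), `het_hom_boundary = 0.80` (AF ≥ 80% is
homozygous, the boundary inclusive on the homozygous side; 25% < AF <
80% heterozygous), `other_sample_max = 0.05` (any other sample with AF ≥
5% at the site rejects the call), `shared_site_max_samples = 2` (a site
called in more than two distinct samples is excluded as an artifact).
"More than two" is implemented literally as > 2; a site shared by
exactly two samples survives this filter, though each copy is then
typically rejected by the 5% cross-sample rule. Every candidate call
ends in exactly one of five bins (two retained, three excluded), so
stage counts are conserved and logged. The cross-sample exclusion is
applied uniformly to all variant classes, and manual read-level review
(IGV-style) from the original workflow is replaced by these automated
rules — both choices are exposed in the config.

## Variant representation and normalization

Internal coordinates are 1-based inclusive; the VCF anchor-base
convention exists only at the I/O boundary. Anchor removal trims the
shared prefix first, preserving the caller's reported placement;
left-alignment (shifting indels to the leftmost placement that yields
the same derived sequence) is a separate explicit step, verified in the
tests against an oracle that enumerates every equivalent placement.
Multi-base substitutions are decomposed into per-base SBS calls;
length-changing replacements become a deletion plus insertion at the
same spot. Both decompositions are reassembled by the merge step, so a
clustered change is classified once, as one complex event.

## Event merging and the seven categories

Two variants are linked when fewer than 10 intervening reference bases
separate their spans (`merge_window_bp = 10`); insertions occupy a
zero-length span between two bases, so the intervening count is always
`start_b − end_a − 1`. Events are the connected components of this
linkage; the implementation sweeps sorted spans and is tested against a
brute-force union–find oracle. A cluster of ≥ 2 variants is complex:
single-member events classify by class and length (SBS, −1, +1,
Del ≥2 bp, Ins ≥2 bp); inversions and translocations are SVs, are never
merged with small variants, and always count as their own events.
"More than two mutations" in the verbal definition of complex events is
read as "two or more", since two-SBS complex events are explicitly part
of the reported composition counts. Within a complex event, maximal runs
of ≥ 2 reference-matching bases (`spacer_min_match = 2`) delimit change
blocks and a single matching base is absorbed into one block.
Mixed-zygosity clusters keep the majority label (ties → heterozygous)
and carry a flag rather than being dropped.

## Junction microhomology

For a deletion of length ≥ 2 the apparent microhomology is defined as
placement ambiguity: the number of distinct equal-length deletions
producing the identical derived chromosome, minus one. This equals
`mh_left + mh_right`, the maximal flank identities of the deleted
sequence against the right and left junction sides, extended base by
base so tandem-repeat deletions may exceed the deletion length (no cap
is applied; matching truncates only at chromosome ends). Junctions with
N in the deleted segment or in a flank window of one deletion length per
side are reported as undefined and excluded from distributions but
counted. Bin edges {0, 1, 2, 3–4, 5–9, ≥10} follow the named peaks of
the underlying comparison (2 bp in wild type, 3–4 bp in NHEJ-deficient
mutants) and are configurable. Only simple Del ≥2 bp events feed the
microhomology analysis by default; deletions inside complex clusters do
not, since junction assignment there is ambiguous.

## Rates, spectra and tests

Per-plant event counts divide by the haploid golden-path length
119,146,348 bp (per-bp rates, reported ×10⁻⁸) and additionally by the
dose in Gy (×10⁻¹⁰). Standard errors are sample SD / √n across plants;
n = 1 reports SE 0 with a flag. The published rate table is embedded as
input data (`reference_tables`) for consistency checks and for
parameterizing the simulator; note its upper block reads both as
events/plant and as rates ×10⁻⁸/bp, an ambiguity inherited from the
source — the simulator uses the per-plant-count reading. SBS spectra use
the six strand-collapsed classes; complex events contribute once to
event counts and are excluded from SBS/InDel tallies by default. InDel
length bins are {1, 2–10, 11–30, 31–100, >100}. Group comparisons use
Welch's t-test; no multiple-testing correction is applied, mirroring the
per-type testing of the original analysis. The zygosity ratio is tested
with an exact two-sided binomial test of the homozygous count against
expected fraction 1/3 of detected events.

## Single-hit multitarget survival model

`S(D) = 1 − (1 − e^(−D/D0))^n` with D0 > 0 (mean lethal dose per target)
and n ≥ 1 continuous (extrapolation number); `Dq = D0·ln n` is the
shoulder width, 0 exactly when n = 1. Fitting is least squares on the
linear fraction scale with equal weights, multi-started from a fixed
log-spaced grid (D0 ∈ [10, 5000] Gy × 10 points, n ∈ {1 … 40} × 8
points), ties broken by lowest residual then lowest n — the surface is
non-convex in n and a single start is unreliable. Parameter standard
errors come from the Gauss–Newton covariance (JᵀJ)⁻¹·s², Dq's by the
delta method. Fractions must lie in (0, 1]; zero survival is floored at
1/(2·total plants sown at that dose) when building from raw counts.
Normalization to the 0-Gy control is available but off by default, since
whether the original curves were control-normalized is not stated; both
modes are provided. Noise-free forward-simulated curves are recovered to
within 1–2% in (D0, n, Dq); across binomial assays (3 replicates × 30
plants) the median relative Dq error stays under 15%.

## Synthetic-data generator

The generator defines the testing conditions; its defaults are the study
conditions wherever these are stated, and fixed realistic choices where
they are not:

* **Reference**: i.i.d. random sequence, default 1 Mb, GC 0.36
  (Arabidopsis-like). Events are placed at the published *per-plant*
  counts (e.g. ≈ 49 events/plant for the 1000-Gy wild type, ≈ 11 for the
  100-Gy mutants), not at per-bp rates, keeping desk-scale runs fast
  while preserving every per-plant statistic.
* **Per-strain profiles**: per-type Poisson means from the embedded rate
  table; complex-event composition weights from the reported
  compositions (SBS-only in 20/23 wild-type vs 4/27 mutant events). The
  SBS-class, InDel-length and microhomology-bin weights are not printed
  numerically in the source, so they were chosen once to match its
  qualitative statements (transitions and A/T→T/A slightly elevated;
  wild-type InDels shortest-first vs mutant peak at 11–30 bp; wild-type
  microhomology peaked at 2 bp with 24% zero-mh vs mutant peaks at
  3–4 bp with 12%/4% zero-mh) and are not revisited.
* **Deletion placement** is rejection-sampled (≤ 1000 tries) toward the
  target microhomology bin. The ≥10 bp bin is given weight 0: an i.i.d.
  genome contains essentially no ≥10 bp flank identity to sample, a
  structural difference from real genomes whose long-microhomology
  junctions arise from repeat families. Consequently, passing tests
  demonstrate correctness of the scoring and the sampling bias, not the
  absolute tail of real microhomology distributions.
* **Zygosity** is drawn at the detected-M2 Mendelian odds (1/3
  homozygous); `simulate_m2` exposes the full 1:2:1 draw including
  absent mutations.
* **Caller emulation**: per-site depth Poisson around the mean (default
  50, within the reported 24–75× coverage range), mutant reads binomial
  at the true allele fraction; `depth=None` gives noise-free AFs.
  Low-AF noise calls and multi-sample artifact sites are injected at
  configurable rates so each filter has something to remove. Alignment
  artifacts, mapping bias and read-level errors are *not* modelled —
  recovery results say nothing about mapping quality on real data.
* **Survival assays**: binomial survivors per replicate (default 3 × 30
  plants, the reported assay design) from the multitarget curve.

Events are spaced ≥ 30 bp apart (beyond the merge window plus
left-alignment drift) unless deliberately clustered, so ground-truth
events are exactly the connected components the merger should find;
end-to-end recovery on noise-free data is then required to be exact in
category and zygosity.

## Problem sizes and degenerate inputs

Default desk-scale runs use a 1 Mb genome with 3–10 plants per strain
and complete in seconds; the survival property suite fits 100 simulated
assays. Empty call sets produce all-zero summaries, not errors; empty
junction sets produce empty distributions; a WT rate of zero makes a
fold change undefined (NaN) rather than raising. All randomness flows
through explicit integer seeds, generator metadata records them, and
pipeline reruns are byte-identical.

## Known limitations

* The microhomology definition (summed two-sided placement ambiguity,
  uncapped in tandem repeats) is one of several in use; one-sided or
  capped definitions would shift the 3–4/5–9 bins on repeat-rich
  junctions.
* The cross-sample filters assume the candidate tables list every
  sample's AF evidence at a site; absent evidence is treated as AF 0.
* SV handling is breakpoint bookkeeping only; no breakpoint-sequence
  assembly or SV-junction microhomology.
* The printed quasi-threshold doses of the motivating experiment
  (2045/222/193 Gy) derive from assay points not available in text form,
  so the survival fitter is validated by forward simulation at those
  shoulder scales rather than against the original data.
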