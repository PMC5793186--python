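# Methods

## Data model and coordinate conventions

Transcripts are exon chains on a named chromosome and strand. Internally all
intervals are 0-based half-open, which makes overlap and distance arithmetic
exact; GTF input/output uses the standard 1-based inclusive convention, and
the two conversions are tested as an identity round trip. A transcript's
**length** always means mature (spliced) length — the sum of exon lengths —
because the >200-bp lncRNA size criterion and the length comparisons between
lncRNAs and mRNAs are statements about transcripts, not genomic footprints.
The genomic span (first exon start to last exon end) is a separate quantity
used for locus-level overlap and distance.

Expression is an FPKM matrix (transcripts × samples) with a sample design
(stage, replicate). FPKM from counts follows the standard definition
count·10⁹/(length·library size). The default design is four stages
(A0/A1/A3/A5) × three replicates; nothing in the code assumes those names
beyond the simulator and the default comparison list, both configurable.

## lncRNA identification

The cascade applies, in order: mature length strictly > 200 bp; exon count
≥ 2; expression (FPKM ≥ `min_fpkm` in at least one sample by default — see
"declared conventions"); exclusion of candidates overlapping known coding
genes; exclusion of candidates with exonic overlap (either strand) with
pseudogene or housekeeping small-RNA loci; and the four coding-potential
thresholds. Filters are conjunctive, so the retained set is independent of
order (a tested invariant), and the audit records every filter's verdict
even after the first failure, so a rejected transcript's full profile is
inspectable.

Coding-gene overlap is resolved so that the surviving set partitions cleanly
into the two lncRNA classes: a candidate is excluded when it has same-strand
exonic overlap with a coding transcript, **or** when its span overlaps a
coding locus without any opposite-strand exonic contact (e.g. a transcript
contained in an intron). What survives is either clear of coding loci on
both strands (lincRNA) or in exon-level antisense contact (antisense). The
classifier re-derives this and raises on any record that fits neither —
that would indicate a cascade bug, and the condition is cross-checked
against a per-base brute-force oracle in the tests.

Novelty against a known-lncRNA reference uses same-strand exonic overlap:
a candidate is "annotated" when some single known transcript covers at
least `min_overlap_fraction` (default 0.5) of the candidate's mature length
(and at least 1 bp). Coordinate overlap replaces sequence search here: on a
shared assembly the two agree wherever a BLAST match would be colinear, and
coordinate overlap is exactly testable against planted truth.

### Declared conventions where the field's usage varies

- **Expression filter**: default FPKM ≥ 0.5 in ≥ 1 sample. Both the cutoff
  (e.g. 5) and the rule (`all_samples`) are configurable; published
  descriptions of such cascades vary and sometimes garble this clause, so
  the choice is a visible parameter rather than a buried constant.
- **Score-threshold sides**: each coding-potential threshold carries an
  explicit retained side. Defaults follow the tools' own conventions —
  noncoding means CNCI < 0, CPC < 0, Pfam E-value > 0.001, PhyloCSF < −20.
  `FilterThresholds.as_printed()` switches CNCI/CPC/PhyloCSF to
  "retained when above", the sign convention sometimes quoted in papers.
- **Missing score rows** fail the cascade by default (conservative);
  `missing_score_fails=False` passes them through.

## Target prediction

**cis**: a coding gene (union span of its transcripts) is a cis candidate
for an lncRNA when the closest distance between their spans is ≤ 10 kb
(inclusive), same chromosome, either strand. Span-to-span distance, not
TSS-to-TSS, is the weakest assumption consistent with "neighbouring within
10 kb" and is what the brute-force oracle recomputes. Relative position
(upstream/downstream) is reported with respect to the gene's strand.

**trans**: Pearson correlation across all 12 samples (a 4-point stage-mean
mode exists for designs where replicate-level pairing is not meaningful).
The two-sided p-value uses the exact t transform with n − 2 df; it is
verified against numerical quadrature of the t density to 1e-6. Edges
require |r| > 0.95 **and** p < 0.05 strictly; at n = 12 the r cutoff
dominates (|r| > 0.95 already gives p ≈ 2·10⁻⁶), which is asserted as a
sanity property. Raw p-values are used (no multiple-testing correction) to
match the conventional definition of such networks; a BH mode can be
applied downstream via the returned edge table. Zero-variance rows are
skipped and counted rather than erroring the whole run.

## Differential expression

The test is a deliberate, documented stand-in for assembly-suite tools
(e.g. Cuffdiff's negative-binomial model): Welch's t on log2(FPKM+1)
replicate values, BH adjustment per comparison, log₂FC from stage-mean FPKM
with pseudocount ε = 1 (bounded fold changes at zero expression;
configurable). Calls require |log₂FC| > 1 and q < 0.05. The interface is a
plain per-feature table, so externally computed p-values can be slotted in.
Numerical edge cases: groups with identical replicate values get p = 1
(p = 0 if the group means differ in the noise-free limit); the all-equal
test is exact rather than variance-based because the standard deviation of
identical floats can round away from zero.

Calibration is tested, not assumed: on planted-null features with lognormal
replicate noise the raw p < 0.05 rate must sit inside the binomial 99%
interval around 0.05, and with planted |log₂FC| = 2 at noise sd 0.1 the
procedure must reach power ≥ 0.95 with empirical FDR ≤ 0.1 at BH 0.05.

## K-means archetypes

DE-feature stage-mean profiles are z-scored per feature (clustering shapes,
not magnitudes; `zscore=False` disables this), then clustered with Lloyd's
K-means, Euclidean metric, 10 restarts, fixed seed. For k = 4 the centroids
are mapped to named archetypes:

- **K1** = most negative Spearman trend against stage order (decreasing);
- **K4** = of the rest, the centroid with the largest second-stage excess
  over all other stages (peaked at 24 h);
- **K2/K3** = the remaining two, split by the weighted centre of their
  positive increments — later rise = K2, earlier rise = K3.

Ambiguities (flat centroids, ties) resolve deterministically to the lower
cluster index with a warning. Cluster indices depend on the seed, but the
partition is stable under feature permutation (tested via ARI = 1).

## Enrichment and qPCR

Over-representation is the upper-tail hypergeometric probability of the
observed overlap between a selection and each gene set, both intersected
with the declared universe, BH-adjusted across terms. It is verified against
the closed-form combinatorial tail and, for a tiny universe, against full
enumeration of all draws. This is a database-agnostic replacement for web
enrichment services; term databases are supplied as GMT files.

qPCR: ΔCt = Ct(target) − mean Ct(references) per sample (two references
combined by arithmetic mean of Ct, i.e. geometric mean on the linear scale);
ΔΔCt subtracts the calibrator sample; relative expression is 2^−ΔΔCt, so the
calibrator is exactly 1 and the result is invariant to any global Ct shift.
Agreement with RNA-seq is Spearman's rho (Pearson on tie-averaged ranks)
between per-stage relative expression and per-stage FPKM.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:
4 stages × 3 replicates; by default 120 coding genes, 60 lincRNAs, 12
antisense lncRNAs, 6 pseudogene and 6 small-RNA loci on 3 chromosomes of
3 Mb. Proportion-type defaults mirror the magnitudes reported for this
experimental system: archetype mix (0.325, 0.100, 0.398, 0.177), 60% of
lincRNAs given a cis neighbour, 74% of planted trans pairs positive, 30% of
expressed features differentially expressed with planted |log₂FC| = 2, and
half of the planted lncRNAs present in the known-lncRNA reference. Feature
counts are desk-scale: every guarantee the tests rely on is structural
(placement constraints, threshold sides), not count-dependent.

Placement is sequential per chromosome with ≥ 12 kb spacing between
unrelated features, which guarantees that non-cis lincRNAs sit outside
every 10-kb window and that each cis-designated lincRNA has exactly its
designated neighbour within the window (gap drawn in 0.3–9 kb, either
side). Antisense transcripts are built directly on a host gene's first
exon, opposite strand. Pseudogene and small-RNA loci get an assembled
two-exon fragment overlapping them, so the noncoding-exclusion filter has
real work to do. Expression is multiplicative lognormal noise around planted
stage means — the pipeline consumes FPKM, so count-level simulation would
add realism the thresholds never see. Trans pairs share a latent stage
profile (proportional for positive pairs, arithmetically mirrored for
negative ones), giving |r| = 1 in the noise-free limit and |r| ≳ 0.95 at
the default noise. Scores are drawn on the correct side of every threshold
with seeded margins. All randomness flows from one seed through named
generator streams; a fixed config reproduces byte-identical files (tested).

What the simulation does **not** emulate: realistic sequence content (the
optional genome is uniform-random, so ORF statistics on it reflect length,
not coding bias), read-level sampling noise and its mean–variance
relationship, partially-overlapping isoforms, and annotation errors.
Passing tests therefore demonstrate that the implementation computes its
definitions correctly and recovers structure it is designed to detect —
not that those thresholds are optimal on real data.

Known behavioural consequences of the defaults worth knowing: with the four
archetype shapes, no feature exceeds the fold-change threshold in *all*
four stage comparisons, so the "common to all comparisons" Venn region is
typically empty on synthetic data; and qPCR rank agreement for archetypes
with tied extremes (e.g. K4's equal first/last stages) can drop to 0.8 on
4 points from a single rank flip, which is why the per-target rho is
reported rather than asserted.

## Problem sizes

Default test and acceptance runs use ~200 transcripts, 12 samples,
200-feature calibration matrices and 200 archetype profiles; the full suite
runs in a few seconds and the acceptance script in under ten on one CPU.
These sizes were chosen so that exact brute-force oracles (per-base overlap,
all-pairs correlation, subset enumeration) remain feasible cross-checks.
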