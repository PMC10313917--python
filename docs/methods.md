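# Methods

This note records the models implemented in `cnith`, the decisions taken
where the procedures admit more than one reading, the defaults and their
rationale, and what the synthetic-data generator does and does not emulate.

## Input model

The pipeline consumes allele-specific segmented copy-number profiles of the
kind ASCAT emits from SNP-array data: per sample, ordered non-overlapping
segments with integer major/minor allele copies, plus per-sample purity
("aberrant cell fraction") and ploidy.  Coordinates are 1-based inclusive
throughout (converters to 0-based half-open exist at the boundary only).
Profiles are validated on load — overlaps, negative copies, unknown
chromosomes and out-of-range coordinates are hard errors — and coalesced
(adjacent equal-state zero-gap segments merged) before any distance or scar
computation, since both counts are otherwise representation-dependent.

Chromosome X is accepted but excluded by default from distances and scar
scoring (configurable); Y is ignored.  The cohort this pipeline targets is
all-female and X allele states from arrays are ambiguous, so autosome-only is
the conservative default.  Total-CN-only input is accepted; allele-dependent
operations refuse it with an explicit error rather than guessing a split.
Missing purity/ploidy are allowed on load; operations that filter on them
treat missing as failing the filter and log the exclusion.

## CN-event distance

The distance between two samples collates the breakpoints of both profiles,
maps each sample's total CN onto the merged segmentation, and counts merged
segments with unequal totals.  Allele-specific information is deliberately
ignored by default (the comparison is of total-CN profiles); a switch counts
(major, minor) state mismatches instead.  Profiles covering different
chromosome sets or different bases within a chromosome are a hard error by
default — silent intersection hides data loss — with an `intersect=True`
escape hatch that restricts to the shared footprint and logs a warning.

The count is an estimate of the number of CN events separating the samples
from a common ancestor.  It is symmetric, non-negative, zero iff the
coalesced profiles agree, and invariant to splitting segments into
equal-state pieces; it is **not** asserted to satisfy the triangle inequality
(each pair is evaluated on its own segmentation), and the test suite
documents this with a counterexample search rather than a metricity claim.

Hierarchical clustering is agglomerative with complete linkage.  The
agglomeration is implemented directly (cross-checked against
`scipy.cluster.hierarchy` on tie-free inputs) so that ties in merge order can
be broken deterministically by the smallest lexicographic pair of cluster
indices — dendrograms are then reproducible byte-for-byte.  Newick export
assigns each branch the difference between parent and child merge heights, so
every root-to-leaf path sums to the root height.

## Clone calling

The threshold is fitted cohort-wide: every unordered pair of samples is
labelled intra- or inter-patient, and a univariate logistic regression of
P(inter | distance) is fitted by penalized maximum likelihood — mean
cross-entropy plus a ridge penalty (default 1e-4) on the slope of the
standardized covariate, intercept unpenalized.  The penalty exists because
well-separated cohorts completely separate the two labels, where the
unpenalized MLE diverges; with it, the decision boundary stays finite and
falls strictly inside the gap.  The clone threshold is the closed-form 0.5
crossing, −intercept/slope.  A likelihood-ratio test of the slope guards the
no-signal case: slope ≤ 0 or LR p above `signal_alpha` (default 0.05) raises
an explicit "distance does not discriminate patients" error instead of
returning a meaningless boundary.

Relapse samples are excluded from the threshold fit by default (the threshold
is meant to describe the primary disease; a flag includes them).  Clones are
assigned by cutting each patient's complete-linkage dendrogram at the
threshold: merges at height ≤ threshold join, so any two samples in different
clones were merged only above it.  Because linkage heights are maximal
within-group distances, this is the closest operational reading of "as
divergent as deposits from different patients".  A pairwise single-linkage
alternative (`assign_clones_pairwise`) is provided for sensitivity analysis;
when the two disagree, both can be reported.

Topology is classified structurally on the binary merge tree: sympodial iff
every internal node has at least one leaf child (ladder), dichotomous iff
some internal node has two internal children.  The two cases are
complementary for binary trees, so trees with ≥ 4 leaves always classify;
trees with < 4 leaves (the shapes coincide) and trees whose merge heights are
all tied (shape is an artifact of tie-breaking) return indeterminate.
"Equal branches" is read structurally, not by branch length, because the
exemplar shapes differ in structure.

Relapse patterns require pooling a patient's primary and relapse samples in
one clustering.  Type 3 iff some relapse sample's clone contains no primary
sample; otherwise type 1 iff the primary samples form one clone, else
type 2.  The classification is invariant to clone relabelling.

## HRD scar scores

The three components follow the standard genomic-scar conventions; every
size threshold is a keyword with these defaults:

* **HRD-LOH** — maximal runs of adjacent LOH segments (minor allele 0, at
  least one copy retained) longer than 15 Mb that do not span the whole
  chromosome.
* **LST** — per chromosome arm (arms delimited by the centromere interval):
  clip to the arm, coalesce, drop segments < 3 Mb, re-join equal-state
  neighbours within a 3 Mb gap, then count breakpoints whose flanking
  segments are both ≥ 10 Mb, differ in allele-specific state, and are ≤ 3 Mb
  apart.
* **ntAI** — maximal allelic-imbalance runs (major ≠ minor) that reach a
  chromosome end, do not cross the centromere interval, and do not span the
  whole chromosome.  No minimum length by default (a config key exists).

"Chromosome end" means the first/last base covered by the sample's
segmentation, not the literal telomere — array segmentations rarely reach
telomeric coordinates.  All three scores are invariant to segment splitting
(property-tested), a fully heterozygous diploid genome scores (0, 0, 0), and
ploidy plays no role in scar scoring (it is carried for gene-level calls
only).

A sample is HRD iff ntAI + LST + HRD-LOH ≥ 42, else HRP.  Scorability
filters: purity < 0.3 excluded; purity exactly 1 with all three components 0
excluded (a provisional scoring pass implements this); missing purity fails
the filter.  Every exclusion is logged with its reason.

Patient status is all_HRD / all_HRP / mixed (both calls present).  The
ambiguity model regresses, per scored sample, the indicator "some same-patient
sample lies strictly on the opposite side of 42" on |HRD sum − 42|.  The
covariate choice is interpretive: the probability of a contradictory call
peaks *at* the cut, which no monotone-in-score logistic can represent, so the
distance from the cut is the natural single covariate.  A raw-score fit is
computed alongside and reported in the results object; a log message notes
when the two disagree qualitatively.

## Gene-level CN and feature summaries

Gene-level total CN is the overlap-length-weighted mean of covering segments'
totals.  This stands in for probe-level averaging: with per-probe copy
numbers unavailable, segment-overlap weighting is the closest
segment-resolution equivalent, and the two can differ for genes straddling a
breakpoint — documented, not reconciled.  Genes with no covering segment are
missing with a warning.

COSMIC gain/loss calls relative to ploidy: for ploidy ≤ 2.7, gain iff
CN ≥ 5, loss iff CN = 0; for ploidy > 2.7, gain iff CN ≥ 9, loss iff
CN < ploidy − 2.7; else neutral.  Comparisons are exact (no tolerance), so
calls are stable under perturbations away from the boundaries.

Signature-exposure heterogeneity per patient is the mean over unordered
sample pairs of the sum of squared differences of the 7-long exposure
vectors.  "Euclidean (sum-squared)" is ambiguous, so both modes exist;
sum-squared is the default and the pipeline's cohort summary reports both.
MAD is unscaled by default (plain median absolute deviation; a flag applies
the 1.4826 normal-consistency factor).  Ki67 bins treat the bounds as real
intervals: low ≤ 20 < moderate ≤ 60 < high, so fractional scores between 20
and 21 are moderate.

## Spatial analysis

IMO cells map to integer (column, row) coordinates; the anatomical distance
is Euclidean on those coordinates (Manhattan by flag).  The grid metric and
the treatment of same-cell pairs (distance 0) are choices of this package and
are flagged in output metadata.

The Mantel test correlates upper-triangle entries and permutes the sample
labels of one matrix; p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm) with
n_perm = 999 by default, one-sided "greater" (the working hypothesis is
positive correlation; two-sided by flag), seeded and recorded in every
report.  An exact mode enumerates all n! relabellings for small n.  Under
the null the test is calibrated: rejection at α = 0.05 occurs at rate 0.05
(verified by simulation).  Note that grid symmetries (e.g. four deposits on
a square) create permutations that exactly reproduce r, so small or highly
symmetric layouts have coarse attainable p-values.

Cohort aggregation reports a one-sample t-test of |r| against a configurable
null mean (default 0).  Testing |r| against 0 is degenerate under the null
of no correlation — |r| is positive-biased — so the output carries an
explicit caveat field and a Kolmogorov–Smirnov comparison of the observed
Mantel p-values against Uniform(0,1) is emitted alongside as the cleaner
null check.

## Synthetic cohorts

The generator is first-class, tested code: it is the ground truth against
which clone recovery, topology and relapse classification, and the spatial
power properties are validated.

Per patient: a binary clone tree over k clones (caterpillar for a sympodial
target, maximally balanced for dichotomous, uniform over rooted labelled
topologies otherwise); truncal events at the root; clone-private events per
edge; each sample inherits its clone's profile plus private noise events.
Events are interval CN changes on one parental allele — length log-uniform
on 1–50 Mb, ±1 (80%) or ±2 (20%) copies, a configurable fraction LOH (half
of those copy-neutral), composing additively and clipped at zero — so the
generative event count is the analogue of the CN-event distance the pipeline
estimates.  A fraction of events (default 0.4) is anchored at a chromosome
end: HGSOC copy-number profiles are rich in terminal and arm-level changes,
and without terminal events telomeric allelic imbalance would be
structurally impossible, leaving the ntAI scorer unexercised.

Two deliberate calibrations of the divergence budget:

* Clone-edge event counts (default 40 per level) dominate the truncal load
  (default 10).  Distinct clones within a patient are *defined* as deposits
  as divergent as different patients' deposits; if truncal events dominated,
  every between-clone distance would sit below the fitted inter-patient
  threshold and no patient could ever be called polyclonal.
* Edge counts scale with the drop in "divergence level" (tree height) from
  parent to child, making the clone metric ultrametric-like.  With equal
  per-edge counts a caterpillar tree produces tied complete-linkage merges
  that collapse the ladder, so the generating topology would be
  unrecoverable by *any* clustering — the scaling encodes that in a
  sympodial tumor the persisting trunk keeps accumulating events after each
  clone stops diverging.

Relapse scenarios: type 1 forces a monoclonal patient and draws relapse
samples from the single clone; type 2 draws them from existing primary
clones (requires k ≥ 2, otherwise the config is rejected as infeasible);
type 3 branches a fresh clone off a random existing clone with two edges'
worth of private events (the divergence of sibling clones) and draws relapse
samples from it.

Each clone gets a home IMO cell (distinct cells per patient); a sample lands
in its clone's home cell with probability ρ (`spatial_concordance`, default
0.5 — a moderate concordance consistent with a weakly positive cohort-level
spatial-genomic signal) and uniformly otherwise.  Exposure vectors are
Dirichlet draws around clone-specific means (concentration 100).  Purity is
drawn uniformly on (0.35, 0.95) and recorded in the metadata, but does not
dilute the integer clonal states — the pipeline consumes ASCAT-style clonal
integer profiles; a `dilute_and_round` flag mixes in a diploid normal
component and re-rounds, for robustness testing only.  All randomness flows
from the single config seed; identical config + seed give byte-identical
output files.

**What the generator does not emulate.**  Whole-genome doubling, signature-
process-specific event spectra, subclonal mixtures within a deposit,
array noise and segmentation error, and genome-scale scar burdens on the
default reduced genome.  The default genome is three chromosomes
(100/150/200 Mb) for desk-scale speed; `grch37_genome()` provides the full
autosome table.  On the reduced genome scar sums rarely approach the
clinical cut of 42 — there is simply not enough chromosome to accumulate
forty large scars — so HRD/HRP boundary behaviour is validated on
constructed profiles and synthetic score tables rather than on simulated
cohorts.  Passing recovery tests therefore demonstrate correctness of the
algorithms under the generative model, not performance on array data.

## Problem sizes and numerical choices

The validation suite runs cohorts of 15–20 patients with 4–8 samples each
(20 seeds for clone recovery and topology, 10 per relapse scenario), 1000
null simulations for Mantel calibration, 250 random profile pairs against
the brute-force grid oracle, and 500 random-splitting trials for scar-score
invariance.  Topology-recovery cohorts use the GRCh37 autosome table: on the
reduced genome, deep clone trees saturate the breakpoint space and the
compressed distances distort the tree metric.

Tie-breaks and tolerances: clustering ties break on the smallest
lexicographic cluster-index pair; Mantel permutation comparisons use a 1e-12
slack on r to absorb floating-point noise; the logistic fits run BFGS to a
1e-10 gradient tolerance from a zero start; distances are reported as
integers but treated as reals downstream.  Degenerate inputs raise typed
errors (`ValidationError`, `NoSignalError`, `DegenerateOutcomeError`) rather
than returning silent defaults.

## Known limitations

* The clone threshold depends on cohort composition (class imbalance between
  intra- and inter-patient pairs shifts the logistic boundary); it is a
  cohort-level construct, not a biological constant.
* The CN-event distance is not a metric and dendrogram heights inherit that.
* Scar-score definitions follow the cited conventions but the upstream
  method's internal re-segmentation is not reproduced; counts on identical
  input may differ near its smoothing edge cases.
* Gene-level CN via segment overlap can differ from probe-level averaging at
  breakpoints.
* The cohort-level |r| t-test inherits its anti-conservative null; prefer
  the KS-vs-uniform output for inference.
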