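# Methods

This note documents the models behind `rarepc`, the defaults that matter,
the choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real data.

## Rare-cell classification

**Positivity thresholds.** On an enrichment-free slide the cell population
is ~99.9% common leukocytes, which dictates opposite calibration logic per
channel. For CD138 and CD56 the bulk defines the *negative* distribution,
so the cutoff is the upper robust fence, median + k·MAD of log1p
intensity (default k = 5, ≈ 3.4 robust standard deviations; the rare
positives cannot move a median/MAD estimate). CD45 marks essentially every
plated cell, so its bulk is *positive* and the negativity cutoff is the
lower fence, median − k·MAD. Positivity is a strict `>` comparison; a
zero-MAD (constant) channel falls back to an epsilon above the median so
the constant bulk is never called positive. Thresholds are reported on the
original intensity scale. Because the fences are defined in robust
quantile terms of the log intensities, multiplying every intensity in a
sample by a constant gain leaves classifications unchanged (exactly so for
intensities ≫ 1, where log1p ≈ log).

**Subtypes.** Every DAPI+ cell receives exactly one of eleven classes: the
eight myeloma CTC / bone-marrow PC candidate subtypes (the four CD138+
marker combinations with CD56/CD45; CD138− candidate PC; apoptotic PC; PC
cluster; binucleated PC) plus CD56+ non-PC, common WBC and "other rare".
The morphology-defined categories overlap the marker combinations, so
enumeration (which needs a partition) applies the precedence
apoptotic > cluster > binucleated > marker combination; the positivity
triple is recorded alongside, so no information is lost. "Larger than
surrounding WBCs" is operationalised as area above the 95th percentile of
the same sample's CD45+CD138− cells (no size cutoff is standard in the
field); nuclear-eccentricity cutoff 0.6 and apoptosis-score cutoff 0.7 are
configurable `ClassifierParams`. The PC-cluster rule (≥ 2 CD138+ cells
sharing a cluster id) requires sample context; the single-record
`classify_cell` therefore takes a precomputed cluster size.

**Outlier scores** are mean distances to the k nearest neighbours
(default k = 10) in robust-z feature space. They rank candidates for
manual review — the workflow this replaces has a technician confirm every
call — and never override the marker rules. Scores are not invariant under
duplicating the dataset (each point acquires a zero-distance twin), but
twins score identically and genuine outliers keep the top ranks.

**Enumeration** divides subtype counts by the sample's blood-volume
equivalent (mL); the union of CD138-positive subtypes is reported as
"total CD138+", and a sample is labelled myeloma-like iff that rate
strictly exceeds 3 cells/mL.

## Single-cell copy-number calling

Input is one count per genome bin per cell (defaults: 5,000 bins over an
hg19-proportioned genome, ~500,000 reads, i.e. ~100 reads/bin — the regime
in which whole-chromosome copy-number states are resolvable in single
cells).

**Normalisation.** Counts are divided by bin width; a lowess fit
(frac = 0.3, zero robustifying iterations so the operator stays linear in
the counts) of rate against GC fraction is divided out; ratios are scaled
to genome mean 1. The GC curve is estimated on *detrended* rates (each
chromosome divided by its median): fitting it on raw rates lets a
chromosome-scale aberration leak into the GC curve and imprint spurious
within-chromosome structure on the corrected ratios. Correction is skipped
when GC has no variation.

**Segmentation.** Per-chromosome binary segmentation minimises
within-segment squared error; a breakpoint is accepted when it reduces the
error by more than a BIC-like penalty 2·log(n)·σ̂², two parameters
(location and level) per changepoint. σ̂² is estimated robustly from
successive differences *per chromosome*: read-depth noise scales with the
local copy number, and a single global estimate under-penalises splits
inside gained chromosomes. Minimum segment length is 5 bins; segments
never cross chromosome boundaries. The implementation is a dependency-free
prefix-sum binary segmentation chosen for determinism; the interface
accepts an explicit penalty so an alternative segmenter can be swapped in.

**Integer ploidy fit.** A scale s on the grid [1.5, 6.0] step 0.05 (covers
diploid through pentaploid-plus with margin) maps segment mean ratios to
copy numbers; the objective is the segment-length-weighted mean squared
distance of s·mean to the nearest integer, with three robustness
refinements, each of which reduces to the plain objective on clean input:

1. *s²-normalisation.* Noise in a segment mean inflates the distances in
   proportion to s, so objectives at different scales are compared per
   implied segment-mean error (objective / s²). Multiples of a
   well-fitting scale then tie instead of out-competing it.
2. *Trimming.* The worst-fitting 2% of bin weight is excluded per scale,
   so one aberrant segment (usually a segmentation artifact) cannot veto
   an otherwise consistent scale. A genuinely wrong scale misfits far more
   weight than the trim absorbs (≥ 12% under the study architectures).
3. *Smallest-consistent-scale rule.* Among scales whose normalised
   objective is within a factor 2.2 of the minimum, the smallest wins —
   the lowest ploidy consistent with the data. Integer divisors of the
   minimiser get a wider band (8×): a divisor describes the same profile
   with every copy number divided by k, and if it were wrong it would put
   half-integer states on most of the genome (objective ratio > 10), so
   accepting it within 8× is safe and eliminates spurious
   whole-genome-doubled calls. On noise-free input all bands collapse to
   exact ties, resolved toward the smallest scale (a flat profile is
   called diploid and flagged `degenerate`).

Segments shorter than 10 bins are excluded from the scale objective (their
means are noise-dominated); they still receive copy numbers. Sex
chromosomes are excluded from the fit and from altered-calling by default
because patient sex is not modelled; an unmatched X/Y dose would
masquerade as an aberration. Baseline ploidy is the bin-weighted modal
autosomal copy number, ties toward the smaller value.

A known identifiability limit: a pentaploid cell whose only aberration is
one mid-size chromosome at CN 4 (~5% of the genome) cannot be separated
from a tetraploid interpretation at negative-binomial dispersion 0.1 — the
misfit of the 4/5 scale is within noise. At Poisson noise the call is
exact. Real pentaploid myeloma genomes carry events at several levels,
which is what the recovery study simulates.

**Altered call.** A cell is altered iff its baseline ploidy differs from 2
or any run of bins at CN ≠ 2 within a chromosome spans at least
`min_event_bins` (default 10 — roughly arm scale at 5,000 bins; the
minimum discernable event size is a free parameter in this field and is
exposed as such). Runs are measured on the bin-level profile so an event
split across adjacent segments counts once.

**Clone grouping.** Altered cells are clustered by average linkage on the
distance "fraction of autosomal bins with differing integer CN", cut at
1 − similarity_threshold (default 0.95). Two cells differing by one
whole large chromosome (~8% of bins) are separate clones at 0.95 and merge
at 0.90; differences smaller than 5% of bins (chr13-sized events) merge at
the default — the threshold trades subclone resolution against noise
tolerance. Clone consensus is the per-bin modal CN; unaltered cells carry
the reserved label "normal"; per-clone compartment counts make clones
shared between blood and marrow visible.

## FISH-panel concordance

The default panel hardcodes hg19-approximate arm/band intervals for the
nine copy-number probes (CKS1B/1q21 gain, CDKN2C/1p32 loss, FGFR3/4p16
gain, CCND1/11q13 gain, RB1/13q14 loss, 13q34 loss, IGH/14q32 gain,
TP53/17p13 loss, CEP17 gain) and the three IGH translocations t(4;14),
t(11;14), t(14;16). Clinical probes are named, not published as
coordinates, so the BED-like panel file is the override mechanism.

Observed CN at a locus is the bin-length-weighted *median* integer CN over
overlapping bins (medians resist boundary bins; an exact half split takes
the lower value, a deterministic tie rule that matters when comparing
against 2). A gain is present iff observed CN > 2 absolute copies and a
loss iff < 2, matching interphase-FISH copy counting (a clinical report of
"three copies" is positive regardless of the cell's overall ploidy); a
`relative_to_ploidy` mode is available but off by default — note that
under it a uniformly triploid cell shows *no* gains. Translocations cannot
be detected from low-pass copy number and are always `not_evaluable`;
discordance reports exclude them from both directions. Event calls are a
pure function of the integer profile, so re-calling is idempotent;
aggregation conserves counts across patient/compartment/cohort margins by
construction.

## Statistics

Group comparisons use the exact Wilcoxon rank-sum (Mann–Whitney) test with
midranks for ties: the two-sided p is the probability, over all
C(n₁+n₂, n₁) assignments of the ranks, of a rank sum at least as far from
its mean as observed. Totals ≤ 12 are fully enumerated; larger inputs use
seeded Monte-Carlo permutation (default 10⁵ draws, observed assignment
included so p > 0). At 4-vs-4 with complete separation p = 2/70 ≈ 0.029
exactly. The test is applied to independent groups; the paired signed-rank
variant would require a pairing that does not exist between patient and
donor cohorts.

Percentages are rounded half-away-from-zero to one decimal throughout
(`round_half_away`), the convention consistent with the worked fractions
the tables reproduce; percentage rows sum to 100 within 0.2 after
rounding.

## Synthetic data: what it emulates, and what it does not

The generators are the package's study conditions, not tuning knobs:
50,000 cells per slide (a scaled-down slide; real slides carry ~3 million
cells), rare-subtype frequencies of order 10⁻⁴ to 10⁻³ summing below 1%,
log-normal channel intensities with 10× negative-to-positive separation
and log-scale spread 0.3 (≈30% CV — a validated high-separation assay in
which single-channel misclassification is a sub-10⁻³ tail event), plasma
cells ~2.5× the area of WBCs with eccentric nuclei, 500,000 reads over
5,000 bins, negative-binomial count noise with one genome-wide dispersion
parameter (default 0.1; Poisson at 0) and a multiplicative quadratic GC
curve normalised to mean 1, clone mixtures specified as integer-CN
architectures, and a 20% clinical positivity cutoff for the derived FISH
panel. Sex chromosomes are simulated at CN 2 (female-like) so they cannot
confound ploidy fitting. All generators are deterministic given their
seeds.

Passing recovery tests on these inputs shows the pipeline's inference is
correct *under its own noise model*. It does not demonstrate robustness to
what real slides and real WGA add: segmentation/staining artifacts,
autofluorescence, batch-varying gains, locus-specific amplification
dropout, waviness correlated with replication timing, mappability gaps, or
translocation detection (out of scope by design). The manual-review step
of the laboratory workflow is replaced by the ranked outlier score and
exported review tables; no human is in the loop in tests.

## Problem sizes

Test-suite and acceptance-script simulation sizes are chosen to estimate
each rate with adequate precision while keeping runs short: 100 cells per
ploidy class (binomial SE < 2.2 points at 95% recovery), 100 cells × 20
diploid autosomes for event precision, 40 cells for clone grouping, one
50,000-cell slide per classifier check, 60 cells for the end-to-end
discordance study. The full suite runs in well under a minute on one CPU.
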