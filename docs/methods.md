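# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limitations of `gbsmedip`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All coordinates are 1-based and inclusive on both ends, so a region
printed as `chr1:61077901-61078200` has width 300 = end − start + 1 —
the convention of the tabular DMR reports. BED files are 0-based
half-open on disk only; the shift happens at the I/O boundary. Interval
files naming chromosomes absent from the genome model are rejected
rather than silently dropped, because the chromosomal expectancy
statistics require a closed universe.

## Reduced representation and QC

In-silico digestion places a cut after offset 5 of each CTGCAG
occurrence (PstI's documented CTGCA^G cleavage); fragments are the
inter-cut spans on the forward strand, so fragment widths per chromosome
sum to the chromosome length and k sites yield k + 1 fragments. Size
selection keeps widths in [lo, hi], both ends inclusive (default
200–600 bp, the library-compatible range).

Two CpG enrichment scores are computed for a region set and for the
genome, and reported as region/genome ratios: **relH** (CpG dinucleotides
per 100 bp) and **GoGe** (observed/expected CpG, `n_CpG·n_bp/(n_C·n_G)`).
Both are standard immunoprecipitation QC scores; values above 1 indicate
CpG-enriched capture. The package reports both because QC conventions
differ on which to headline; `GoGe` is used in the pipeline manifest.

Per-chromosome expectancy: expected counts are `total · length_c / L`.
The headline p-value is the multinomial chi-square goodness-of-fit
(conditioning on the total), which is calibrated — simulated Poisson
counts proportional to length reject at ~5 % at α = 0.05 (verified in
the test suite). A one-sample t-test of the relative deviations against
zero is also reported for descriptive continuity, but because the
expectation is estimated from the same total the deviations are
sum-constrained and that t-test is strongly conservative (its statistic
has roughly half the nominal spread); it should not be used for
inference.

Coverage summaries follow the breadth convention: bp sequenced =
Σ(count × fragment width), depth = bp over covered bases, breadth = bp
sequenced / depth, percent covered = breadth / genome length × 100.

## Window counts and normalization

Fixed windows tile each chromosome from base 1; a trailing partial
window is kept so the windows exactly partition the genome. A fragment's
count is split across the windows it overlaps in proportion to the
overlapped share of the fragment, accumulated in floating point and
rounded half-up once at the end (total mass conserved to within half a
count per fragment). Row filtering keeps windows with count sum across
all samples ≥ `minRowSum`; the threshold scales with relative coverage
(`round(base × coverage_ratio)`, e.g. 10 → 35 at a 3.5× wider library)
so comparably many windows are tested in populations of different
breadth. Library sizes are frozen at matrix construction so filtering
does not change the normalization denominator.

TMM normalization: the reference sample is the one whose 75th-percentile
count fraction is closest to the mean of those; M (log2 ratio of count
fractions) and A (mean log2 abundance) are formed over windows nonzero
in both sample and reference; the extreme 30 % of M and 5 % of A (split
over both tails) are trimmed; the factor is 2 to the precision-weighted
mean of the surviving M values (weights: inverse binomial asymptotic
variances), and factors are rescaled to geometric mean 1.

Common NB dispersion is estimated by method of moments per window
(`φ_w = (s² − m)/m²` from pooled within-group variance and grand
within-group mean on normalized counts) and summarized by the median
with a chi-square median-bias correction: the pooled variance's median
lies below its mean by the factor `qchisq(0.5, df)/df`, so the raw
median underestimates φ (0.184 recovered for a true 0.2 at n = 14) and
makes the exact test anti-conservative; the corrected estimator recovers
0.196 and restores type-I calibration, and it is floored at 0 so Poisson
data yield φ ≈ 0. A single common dispersion (not tagwise) is a
deliberate simplification: it keeps the conditional test closed-form and
oracle-checkable by enumeration.

## The exact test

Counts are rescaled to the geometric-mean effective library size
(rounded half-up), summed within groups, and the S-group sum is tested
conditionally on the total with the beta-binomial form given in the
README (`r_S = n_S/φ`, `r_C = n_C/φ`; binomial limit at φ = 0). The pmf
is evaluated by the ratio recurrence from x = 0 and renormalized, which
keeps agreement with 40-digit enumeration below 1e-12 even at totals of
several hundred (a direct log-gamma evaluation loses ~1e-12 to
cancellation). Ties in the two-sided summation use a 1e-12 relative
tolerance. A window with total 0 gets p = 1 and is flagged untestable;
untestable regions are excluded from the BH denominator so structurally
empty regions do not dilute the FDR.

Per-window log2FC uses a 0.5 pseudo-count on the normalized group means,
keeping fold-changes finite for zero groups. Merging of significant
adjacent windows requires zero gap and the same direction; the merged
record carries the minimum component p (reports print one p per DMR and
component rows are not repeated), the count-weighted mean log2FC and the
summed CpG count. BH is applied within each analysis (route ×
population) separately. The `% of CpG` column is CpG count / width ×
100.

## Peak preselection (ROI route)

Pooled group tracks are spread over fine genome bins (mass-conserving,
proportional to overlap). The control track is scaled to the treatment
total; the local rate is `max(λ_genome, λ_1kb, λ_5kb, λ_10kb)` from
centred moving averages of the scaled control (edge-truncated), the
MACS-style guard against local biases. Bin p-values are Poisson upper
tails, BH-corrected; bins at q ≤ 0.1 merge within a 100-bp gap and peaks
shorter than 50 bp are dropped. Calling runs in both directions (S over
C and C over S) and the union forms the ROI set, because hypomethylated
regions must be discoverable too; an all-zero control falls back to one
pseudo-count per bin, logged. The `binned_coverage` default bin is 10 bp,
but the pipeline runs the caller at 50 bp: with mass-split fragment
counts a 10-bp bin holds roughly one count at realistic simulated
depths, leaving no per-bin Poisson power, while 50 bp keeps the
resolution below the 100-bp window scale. Bin size, merge gap and
minimum width are all configurable.

## Genomic context

The randomization null draws window lengths from
Normal(mean, sd) truncated to [1, mean + 4·sd] — the truncation avoids
nonpositive lengths when only a mean ± sd is available (the pipeline
uses the DMR set's own width mean and sd) — picks chromosomes with
probability proportional to length (chromosomes shorter than the
truncation cap are excluded with a notice) and uniform starts over valid
placements. Fold enrichment is (observed fraction)/(expected fraction)
per chromosome. Inter-DMR distances are nearest-neighbour edge-to-edge
gaps on the same chromosome (0 when overlapping; a running maximum of
preceding ends handles contained intervals), binned by leading digit ×
power of ten. TSS distances are signed from the DMR midpoint — a single
symmetric point per DMR — multiplied by −1 on minus-strand genes so
negative always means upstream; the nearest TSS is chosen by absolute
distance with ties broken toward the larger coordinate for determinism;
the default histogram uses 5-kb bins over ±100 kb with out-of-range
values clipped into the edge bins so counts always sum to n. Mode
detection smooths with a 3-bin moving average and reports strict local
maxima (plateaus from single-bin spikes count once, anchored at their
highest raw bin; a fully flat histogram has no modes) with mass fraction
≥ 0.05. Note that a 3-bin average cannot separate modes only two bins
apart; resolving peaks at −10 kb and 0 requires bins finer than 5 kb.
Annotation precedence is coding sequence > 5′ UTR > 3′ UTR > intron >
upstream (within a strand-aware flank, default 5,000 bp, of the TSS) >
downstream (within the flank of the 3′ end) > intergenic; a DMR spanning
a boundary gets a compound per-gene label ("coding sequence, intron")
and multiple qualifying genes are all listed. The flank is configurable
because annotator conventions differ (3-kb and 5-kb defaults are both
common).

## Overlap permutation test and motifs

Two intervals overlap at gap tolerance g when their edge-to-edge gap is
≤ g; overlap events are counted as connected components of the union of
both sets that contain members of each (runs of mutually close DMRs
collapse to one event), alongside the raw pair count. The permutation
scheme re-places each interval of the second set uniformly within its
own chromosome, preserving lengths and chromosomal composition — the
composition is preserved deliberately, since DMR density varies strongly
by chromosome class and a genome-wide shuffle would confound the test.
No mutual-exclusion constraint is applied among placed intervals. The
empirical p is (k + 1)/(N + 1), never 0, valid at N = 100.

PWM columns are normalized to frequencies; scoring is log2 odds against
a background composition (default uniform) with a 0.01 pseudo-count, on
both strands, with N scoring 0. The selection criterion is two-part:
(a) every DMR longer than 100 bp has at least one hit at any score above
the motif's floor (default 0 log-odds — "a hit at all"), vacuously true
and flagged when no DMR is that long; (b) at least 50 % (inclusive) of
all DMRs have a hit at or above the motif's own significance threshold,
which the user supplies per motif (an operating point such as maximum
precision from an external source).

## Synthetic data: what it emulates, what it does not

The generator controls CpG and PstI densities exactly by construction:
the background sequence is scrubbed of CG dinucleotides and CTG
trinucleotides (so it can contain neither CpG nor CTGCAG), then CG and
CTGCAG are planted at the configured densities (collisions dropped;
accuracy within a few percent). Genes are non-overlapping, on both
strands, with 1–4 exons and UTR stubs. Fragment capture is
`(1 − ε)·min(1, c/c_sat) + ε` with ε = 0.05 background and c_sat the
90th-percentile fragment CpG count — a saturating stand-in for antibody
capture chosen to put the simulated GoGe enrichment in the 1.5–3 range
typical of such libraries, not a kinetic model; its parameters are
configuration, not claims. Counts are NB (gamma-Poisson) with dispersion
φ = 0.2 by default, per-sample log-normal library factors (sd 0.2), and
the planted effect is applied symmetrically (S × 2^{+e/2}, C × 2^{−e/2})
so the planted log2FC is exactly e and recovery tests are unbiased. The
input channel ignores methylation and applies the planted CNV fold to
S-group samples. Two presets mirror a two-cohort design: a 16 v 16
higher-breadth/lower-depth population with inputs and a 8 v 6
lower-breadth/higher-depth population without.

Simulation is per fragment, not per read: there are no read positions,
no sequencing errors, no mapping ambiguity, no biological covariates
(age, family structure), and window counts derive from fragment counts
by deterministic mass splitting. Two consequences matter for
interpreting green tests. First, windows of one fragment share a single
NB draw, so window counts are correlated along the genome and marginally
sub-Poisson — the dispersion estimator correctly returns φ ≈ 0 there,
and the per-window test remains calibrated marginally, but passing
calibration on this structure does not demonstrate calibration on real
read data. Second, planted DMRs coincide with single fragments; real
DMRs can straddle fragment boundaries and be diluted.

## Problem sizes and known limitations

The shipped tests and the acceptance script use desk-scale problem
sizes: genomes of 2–6 Mb across four chromosomes, ~2,500–5,000
size-selected fragments, 10,000-window null calibrations, 20 planted
DMRs, 20-replicate FDR checks, and two-population pipelines of a few
hundred kb per chromosome. These sizes were chosen so the whole suite
runs in minutes while every statistic still has enough data to be
informative; all of them are configuration, and the machinery is
size-agnostic.

At a p ≤ 0.005 window threshold with ~19,000 tested windows, the
multiple-testing α budget alone admits on the order of 90 calls when
only 20 planted effects exist, so precision at that threshold is
intrinsically low (~20–25 %) even though sensitivity exceeds 80 % and
the test is correctly calibrated; the stringent 0.0005 threshold is
where calls become precision-dominated (the corresponding check in the
validation suite documents this gap deliberately). Other known
limitations: the common-dispersion exact test does not reproduce
quantile-adjusted or tagwise dispersion estimates of mature count
packages (by design — those are cross-checks, not the implementation);
the peak caller is not a read-model caller (no fragment-size estimation
or shifting); and the annotation taxonomy is gene-relative only, with no
regulatory-feature classes.
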