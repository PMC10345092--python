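# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, the synthetic-data model and
what it does and does not emulate, and the numerical conventions.

## Expression scale and prevalence filter

All analyses run on `log10(CPM + 1)`, where CPM divides a gene's reads by the
cell's total mapped reads and scales to one million.  CPM removes per-cell
depth; the +1 log transform compresses the heavy right tail while mapping
zero counts to exactly 0.  The per-cell sum of CPM over the full gene universe
is 1e6 by construction (checked to 1e-6 relative tolerance in tests).

The zero-prevalence filter excludes a gene when it has zero expression in
strictly more than a threshold fraction (default 0.95) of a designated
reference population.  "Strictly more" matters at the boundary: with 276
reference cells, a gene zero in 263 cells (263 > 262.2) is excluded while 262
is retained.  The reference population is configurable because a small,
deeply characterized cohort can serve as the prevalence reference even when
scoring a much larger survey matrix; the default is all cells of the matrix.
Zeroness is tested on the stored value regardless of normalization state —
0 counts, 0 CPM and 0 log10(CPM+1) coincide, so no epsilon is needed.

Gene-set scores are the arithmetic mean of `log10(CPM+1)` over the retained
set genes, computed per cell.  The mean is taken on the log scale (not logged
afterwards); a cell in which every retained gene is zero scores 0, not
missing.  Gene symbols match case-sensitively after whitespace trimming; a
case-folding option exists but is off by default because silent case-folding
can merge distinct symbols.

## FREM3 depth split

FREM3 cells spanning L2/L3 are split at relative cortical depth 0.3 (fraction
of the L2/L3 band, pia side = 0): depth > 0.3 is "L3 FREM3", depth < 0.3 is
"L2 FREM3".  The boundary value itself goes to L2 because L3 is defined by a
strict inequality; both the boundary and the labels are configurable.  FREM3
cells without a recorded depth are a hard error rather than silently dropped.

## Group statistics

Cell-level comparisons use the Kruskal–Wallis test with average ranks for
ties and the standard tie correction; when every observation is identical the
statistic is defined as 0 with p = 1 (no rank separation).  Post-hoc pairwise
comparisons use Dunn's z,

    z_ab = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T)(1/n_a + 1/n_b)),
    T    = sum_t (t^3 - t) / (12 (N - 1)),

with two-sided normal p values and Holm step-down adjustment.  The adjustment
family is all k(k−1)/2 pairs by default; a `reference_groups` option restricts
it to pairs containing a named reference type, the design used when only
contrasts against particular types are of interest.  All-pairs is the more
conservative default.

Donor-level analysis collapses each (donor, condition) cell population to its
median and applies the Friedman test to the complete donors x conditions
block: within-donor average ranks, chi-square statistic
`12/(n k (k+1)) sum R_j^2 - 3 n (k+1)` with the standard tie correction, and
an asymptotic chi-square p on k−1 df.  Donors missing any condition are
dropped with a warning, never imputed: an incomplete block would change the
null distribution.  For very small designs an exact permutation p (all
within-donor orderings) is available; at n = 3 donors and k = 3 conditions
the maximum attainable statistic is 6.0 with exact p = 6/216 ≈ 0.028, which
is why small donor panels can at best reach that significance.

## Phenotype screen and FDR

For each retained gene, expression is regressed on the phenotype by ordinary
least squares with expression as the dependent variable; the choice of
dependent variable only affects the slope's units because the zero-slope t
test is symmetric and identical to the Pearson correlation t test with n−2
df.  Cells lacking the phenotype are excluded from that screen only (the
morphology and electrophysiology subsets of a Patch-seq cohort differ).
Genes with zero expression variance across the screened cells are dropped and
reported, not tested.

Benjamini–Hochberg runs as the classic step-up: sort p ascending, find the
largest i with `p_(i) <= i q / m`; that `p_(i)` is the critical p (0 when
nothing passes) and every gene with `p <= critical_p` is flagged.  The
critical p is reported alongside the flags because it is the interpretable
per-screen threshold.  `<=` rather than `<` at the critical value follows from
the step-up definition itself and only matters at exact ties.

Heatmap bundles z-score each significant gene across the screened cells
(population SD), order columns by ascending phenotype with cell-id
tie-breaks, order rows by ascending raw p, and split panels by correlation
sign — the display construction for expression-gradient figures.

## Overlap enrichment and ORA

The overlap enrichment asks whether the phenotype-correlated members of a
GWAS set are enriched for membership in a reference set.  The 2x2 table rows
split the set into correlated vs non-correlated members, columns by reference
membership, and the one-sided Fisher p (alternative: greater) is the exact
hypergeometric upper tail.  This table construction is the only 2x2 that
reproduces percentage pairs of the form "X% of correlated genes vs Y% of the
whole set" with a one-sided test.  The odds ratio is the unconditional sample
OR, infinite when a margin cell is zero.  Correlated genes are pooled across
both phenotype screens (union) before restricting to the set under test.

The genes-of-interest rule keeps screen hits (either phenotype) that belong
to at least two of the three input sets — membership in both a
cognition-associated set and the HAR set being the motivating case.

ORA tests each annotation term by `P(X >= k)` for X hypergeometric with
universe N, term size K and foreground size n after universe intersection;
this equals the one-sided Fisher test (verified exhaustively in tests).  Two
backgrounds are supported: the catalog's annotated universe, and an explicit
restricted background (e.g. brain-expressed genes), under which N, K and n
are all re-intersected.  A term is called over-represented only when p, the
BH-adjusted p and the q value are all below 0.05.  The q value is a
Storey-style positive-FDR estimate with pi0 estimated at lambda = 0.5; with
fewer than 20 terms pi0 is fixed at 1, making q equal the BH-adjusted p.
This is a documented, reproducible stand-in for external q-value software
whose exact estimator is rarely stated.  No term-size filters are applied by
default (configurable).

## AP rise speed

A sweep is a uniformly sampled voltage trace (mV) with a known sampling rate.
APs are detected at upward crossings of a dV/dt threshold (default 10 V/s)
followed by a voltage peak of at least −10 mV within 5 ms; crossings within a
1 ms refractory window merge.  These detector constants are not dictated by
the underlying measurement definition — rise speed is insensitive to detector
details for clean spikes — and are fully configurable.  The rise speed is the
maximum of the central finite-difference derivative between the threshold
crossing and the voltage peak, in V/s (1 mV/ms = 1 V/s); no smoothing is
applied by default.  The per-cell summary is the mean rise speed of the first
AP of each suprathreshold step, so later, often slower APs within a train do
not dilute the measure.  On generated waveforms with closed-form maximum
derivative, the extracted value is within 1% at 50 kHz sampling and 5% at
10 kHz (tested).

## Synthetic-data model

Each cell carries a latent size factor `z = shift(t-type) + N(0,1)`.  The
defaults place six t-types (25 cells each, 150 total, three donors) with the
two deep-L3-like types at the largest shifts, so the generated data reproduce
the qualitative pattern the pipeline is meant to detect: the same latent
factor elevates total dendritic length `TDL = 4500 exp(0.35 z)(1 + eps)` µm
(multiplicative noise SD 0.15, clipped at −0.9 to keep TDL positive), AP rise
speed `AP = 300 + 60 z + N(0, 30)` V/s, and the planted gene module.  These
magnitudes give TDL in the several-thousand-µm range with ~2–3x spread
between extreme types and AP rise speeds of roughly 150–450 V/s, realistic
for L2/L3 pyramidal neurons, with phenotype noise low enough that a
latent–phenotype correlation of ~0.9 remains.

Counts are negative binomial with common dispersion 0.5, per-cell library
sizes lognormal around 5e5 reads (sigma 0.35), and per-gene baseline
fractions lognormal with a wide spread (sigma 3 in natural log), which
naturally produces a minority of genes with >95% zeros and thereby exercises
the prevalence filter without a zero-inflation component.  Planted genes sit
at a fixed ~100 CPM baseline and receive a multiplicative effect
`exp(beta z)`, mean-preserving via the lognormal correction.  `beta` is
calibrated by an internal pilot simulation (fixed internal seed, independent
of the dataset seed, cached per configuration): the target Pearson r against
the AP phenotype is first converted to a required expression–latent
correlation through `rho(z, AP) = d / sqrt(d^2 + sigma^2)`, then beta is
found by scanning and bisecting the rising branch of the simulated
correlation curve (the curve peaks and falls at extreme beta because
mean-preserving scaling drives most counts to zero).  Infeasible targets
raise an error stating the attainable bound.  Empirically the planted |r|
lands within 0.1 of the target at the default scale.

Non-planted members of the gene sets receive a small additive t-type shift on
log expression (0.25 natural-log units per unit latent shift, mean-preserved)
so that whole-set scores — not only the planted module — are elevated in the
large-type cells, as in real data.  When a strictly null complement is needed
(FDR calibration), this coupling is set to 0.

Gene sets are built from disjoint region counts so realized pairwise overlaps
equal `round(fraction x size of the first-named set)` exactly; defaults give
14% IQ–HAR and 19% EA–HAR baseline overlaps with a small triple region.  A
`planted_overlap_bias` weight plants genes preferentially among members
shared with the HAR-like set, producing the enrichment signature downstream.

Randomness flows from a single seed through fixed-purpose substreams
(structure, sets, latent factors, libraries, counts, phenotypes), so the gene
universe and set memberships are independent of the cell count, and the same
seed reproduces bit-identical datasets.

What the generator does *not* emulate: per-donor batch effects beyond the
block structure, gene–gene correlation beyond the shared latent factor,
zero-inflation beyond what the NB with low means produces, realistic
transcriptome-wide mean–variance trends, and any spatial or temporal
structure.  Passing tests therefore demonstrate the pipeline's correctness
and calibration under this model, not robustness to every failure mode of
real Patch-seq data.

Spike traces are Gaussian bumps `A exp(-(t - t0)^2 / (2 sigma^2))` above a
−70 mV baseline (default A = 100 mV, sigma = 0.3 ms, 50 kHz), whose maximum
derivative `A exp(-1/2) / sigma` ≈ 202 V/s is recorded as ground truth;
spikes closer than 8 sigma are rejected as overlapping.

## Problem sizes and calibration checks

The statistical validation suite checks every primitive against a
from-first-principles implementation (explicit ranking, exhaustive tail
summation, threshold scanning) on 500 random instances each, and
hypergeometric tails exhaustively for all parameter combinations up to
N = 30.  Screen calibration uses datasets of 1000 genes x 150 cells: 600
all-null replicates for the familywise error of the BH screen (a binary
per-replicate outcome whose estimate needs that replication for a
sub-percent standard error; the measured rate is ~0.04 against the 0.05
nominal), 100 replicates for sensitivity at planted r = 0.6 (≈1.0 observed),
and 200 replicates at planted r = 0.5 for the headline mean false-discovery
proportion reported by `scripts/acceptance.py` (0.054 with seed 1; BH's
guarantee under these conditions is q·m0/m = 0.049).

## Numerical conventions and degenerate inputs

Floats serialize with 10 significant digits; delimited outputs use `\n` line
endings and UTF-8.  Decimal points only (no locale parsing); scientific
notation accepted.  Ties: average ranks everywhere; heatmap column ties break
by cell id; Holm and BH adjustments enforce monotonicity explicitly.
Degenerate inputs fail loudly: cells with zero total counts, constant
phenotypes, empty gene-set/matrix intersections, incomplete donor blocks,
non-uniform sweep sampling, and infeasible overlap or correlation targets all
raise errors naming the offending entities rather than producing silently
wrong output.

## Known limitations

* The screen has no donor covariate by default (associations are pooled
  across cells); a donor-adjusted variant would require a mixed model, out of
  scope.
* The Storey q value is one specific pi0 estimator; external q-value packages
  may differ slightly near the significance boundary.
* The exact Friedman permutation test is limited to designs with at most 1e6
  within-donor orderings.
* ORA treats the annotation catalog as flat; no GO-graph propagation or
  redundancy trimming is performed.
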