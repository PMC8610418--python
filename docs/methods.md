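# Methods

## Scope and model of the data

The pipeline analyzes mutation-accumulation experiments in which yeast
clones are chronically passaged on an alkylating agent (MMS) and whole-genome
sequenced.  Each clone yields a catalog of differences from the reference
genome; the analysis asks how many mutations accumulated, of what classes,
and whether they are asymmetrically distributed between DNA strands with
respect to transcription and replication — the readouts that distinguish
double-stranded-DNA lesions (3meA, 7meG) from single-strand-specific ones
(3meC, 1meA).  Companion modules handle the two non-sequencing measurements
used in such studies: CAN1 fluctuation assays (mutation rates) and
equilibrium anisotropy titrations (protein–DNA affinity).

## Call filtering and event clustering

Whole-genome calls are kept when covered by **≥ 10 reads** with an
alternate-allele fraction **in [0.45, 0.55] inclusive**.  Mutations arise
mid-passaging, so true calls sit near 50% of reads in the sequenced colony;
the window removes both noise and fixed differences.  Both boundaries are
exercised by tests at depth 9/10 and support 0.44/0.45/0.55/0.56.  Calls
with identical (chrom, pos, ref, alt) in two or more clones are removed from
*all* clones as inherited polymorphisms or recurrent artifacts; keying on
the full allele (not position alone) keeps independent mutations that happen
to hit one site.  Recurrence screening is applied after the depth/support
filter; the order is a configuration choice of the pipeline, not forced by
the data model.

Nearby calls are chained into events by single linkage on start-position
distance: consecutive calls ≤ 10 bp apart join one event, so runs of nearby
mutations collapse transitively.  Events with ≥ 2 records are *complex*
(the signature of one error-prone bypass tract); singletons classify as
substitution, insertion or deletion by allele lengths.  An equal-length
multi-nucleotide block substitution is itself ≥ 2 changed bases within its
span and is classed complex.  Clustering is verified against a brute-force
transitive-closure oracle on random instances.

Reporter-gene (CAN1 amplicon) calls use the looser screen appropriate to
deep amplicon sequencing: ≥ 2 supporting reads comprising **strictly more
than 30%** of reads for the isolate.

## Spectra and burdens

Substitutions are keyed to the purine reference base, giving six classes
that describe the mutated base *pair*; this makes spectra invariant to which
strand the call was reported on.  Per-genome burden counts *events* — a
complex event counts once — matching how event-class plots treat complex
mutations as a category (raw record counting is available by flag).  Fold
change is the ratio of group medians, robust to the heavy right tail of
per-clone counts.  Group comparisons delegate to scipy: Mann–Whitney
(burdens and rates), t-test (per-class counts), chi-square homogeneity on
the six-category event table; the asymptotic chi-square p-value is checked
against a label-permutation null in the tests.  CAN1 class frequencies are
reconstructed as (class proportion among sequenced resistant isolates) ×
(fluctuation-derived total rate), the natural decomposition when only
resistant clones are sequenced; the per-class frequencies sum back to the
total rate by construction.

## Strand-asymmetry profiles

Transcripts are divided into five body bins of 0.2 of transcript length
(fractional coordinates measured from the TSS in transcript orientation)
plus three 500-bp bins upstream of the TSS and three downstream of the TTS,
with bin −1/+1 abutting the TSS/TTS.  The *non-transcribed* strand is the
coding (mRNA-like) strand — the top strand of a plus-strand transcript.
Density is opportunity-normalized: mutated A (or C) bases on a strand in a
bin divided by the number of A (or C) bases on that strand in that bin,
counted from the reference genome.  Every A:T pair carries exactly one A and
every G:C pair one C, so naming the strand that carries the mutated base
fully resolves the event's strand.  Mutations inside overlapping transcripts
count once per transcript frame (an exclusion flag is provided); bins with
zero opportunity are flagged NaN, never imputed.

Replication profiles use the interval between neighboring origin midpoints,
split into ten 0.1-fractional bins.  A position at an origin belongs to bin
0 of the rightward interval; positions outside the first/last origin of a
chromosome are outside the analyzed domain.  Per bin, the fraction of A (or
C) mutations on the top vs bottom strand is computed (complementary by
construction), and an OLS line of fraction against bin-center fractional
coordinate summarizes the gradient; complementarity forces the top and
bottom slopes to be equal in magnitude and opposite in sign.  The OLS slope
standard error provides the 95% CI used in recovery tests.  A flat profile
(constant fractions) short-circuits to slope 0 to avoid a degenerate
regression.

Bin-boundary arithmetic uses ceilings of fractional positions, so body bins
partition the transcript exactly; the mirror symmetry between a transcript
and its strand-flipped twin is exact when the length is divisible by the
body-bin count (tested at such lengths) and off by at most one base
otherwise.

## Fluctuation assays

Mutant frequency is `f = canr / (sc × dilution)`, with duplicate plates
averaged per culture before the division.  Rates use the Lea–Coulson method
of the median: solve `r̃/m − ln m = 1.24` for the expected mutation events
per culture `m` (Brent's method on the log scale; the relation is strictly
monotone), then `μ = m / N` with `N` the final cells per culture.  The
published source for the study's frequency→rate conversion is a citation
without a printed formula, so this standard estimator is the default and a
plain median-frequency mode is provided; the estimator name is recorded in
every output.  Confidence limits use the log-normal approximation
`σ_ln m = 1.225·m^(−0.315)/√C` over `C` cultures.  A zero median returns a
flagged upper bound (`m ≤ −ln 0.05 / C`, the Poisson bound from observing
mostly-zero cultures) rather than a point estimate.  The median-based
estimator carries a known ~10–15% downward bias at `m ≈ 10` with 24
cultures; the tests therefore assert recovery within 25%, which the
simulations meet with margin.

## Luria–Delbrück generator

Cultures grow by binary fission from one cell to `n_final`.  Counting
generations back from the end, generation `j` contains `n_final/2^j`
divisions; mutation events there are Poisson with mean `μ·n_final/2^j` and
each expands clonally to `2^(j−1)` cells.  This reproduces the jackpot-skewed
resistant-count distribution with total expected events `m = μ·n_final` (to
within `2^-g`).  For `n_final` not a power of two the `⌈log₂ n_final⌉`
generation grid is an approximation; the generator is validated against an
independent simulator that explicitly tracks wild-type and mutant
populations generation by generation, at a dyadic culture size where both
follow the identical law.  Viable (permissive-plate) counts are Poisson
around `n_final / dilution`.

## Quadratic binding model

With probe (labeled substrate) concentration `D` comparable to `Kd`, free
and total titrant concentrations differ materially and the hyperbolic
isotherm is wrong; the exact single-site solution is

    Y(x) = M·((x + D + Kd) − √((x + D + Kd)² − 4·D·x)) / (2·D)

with `Y(0) = 0`, monotone saturation at `M`, and convergence to
`M·x/(x + Kd)` as `D → 0` (the relative deviation is of order
`D·Kd/(x + D + Kd)²`, so 10⁻⁶ agreement requires `D ≲ 10⁻⁶·Kd`).  The
discriminant is algebraically positive for valid inputs and only guarded
against floating-point rounding.  Fits are nonlinear least squares per
replicate with positivity bounds and no weighting (per-point errors are not
available); initial guesses are `M₀ = max(Y)` and `Kd₀ = x` at half-max.
Replicate fits are summarized as mean ± SD, matching the
independent-protein-preparation design; a pooled mode concatenates points
into one fit, and a free-offset mode accommodates raw (non-baseline-
subtracted) anisotropy.  Kd is invariant to uniform rescaling of `Y`
(absorbed by `M`).

## Synthetic-data generator

The generator emulates the structure the analyses read out, not sequencing
physics.  Defaults are the study-like conditions used throughout the tests
and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 200 kb, 38% GC | yeast-like composition at desk scale |
| transcripts | 40 of 2–4 kb, strand-random, non-overlapping incl. 1500-bp flanks | ~30% occupancy gives both strands ample opportunity |
| origins | 4 per chromosome, jittered even spacing | ≥ 2 needed to define inter-origin bins |
| event mix | 95% substitution / 3% indel / 2% complex | substitutions dominate chronic-MMS catalogs |
| class weights | A>G+A>T ≈ 0.67 of substitutions | 3meA-driven A:T-pair bias of MMS spectra |
| depth, allele fraction | Poisson(40); N(0.50, 0.03) truncated to [0,1] | ~90% of records pass the 45–55% window, so the filter sees both outcomes |
| cohort sizes (drivers/acceptance) | 75 wild-type, 22 mutant clones; burden 20 vs 254 per genome | study clone counts and 12.7-fold ratio at toy-genome scale |
| fluctuation | μ = 10⁻⁷, N = 10⁸, 24 cultures, 10⁴ dilution | typical CAN1 assay regime |
| titrations | D = 5 nM, M = 0.2, 21 points to 1600 nM, noise SD 0.004 | titration range and replicate noise of the anisotropy design |

Substitutions at A:T pairs land uniformly on A/T sites.  G:C-pair ("C")
mutations are drawn by per-site Bernoulli thinning with inclusion
probability proportional to a weight `w = w_tx · w_rep`, where `w_tx` is the
transcriptional bias (sites whose C lies on the non-transcribed strand get
weight `tx_bias_C` inside transcripts) and `w_rep` implements a linear
top-strand probability `p_top(f) = 0.5 + rep_gradient_C·(f − 0.5)` along the
fractional inter-origin coordinate `f` (clipped to [0.02, 0.98]).  Thinning,
rather than fixed-count weighted sampling without replacement, keeps
realized per-site rates exactly proportional to the weights at any mutation
density; the realized count fluctuates around its target, as it would in a
real mutagenesis experiment.  Complex events are generated minimally as two
substitutions 1–10 bp apart.  Positions never repeat within a sample.  All
generators are bit-reproducible for a fixed seed.

What the generator does *not* emulate — sequencing reads and mapping
artifacts, real yeast chromosome structure, replication timing beyond the
linear inter-origin coordinate, selection during passaging, context
(trinucleotide) preferences — bounds what passing tests show: they
demonstrate that the estimators recover what the generator injected, under
the stated noise, not that the filters are optimal for any particular real
pipeline's error modes.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 400-kb genomes, 10–20 k
mutations for asymmetry recovery (giving ~3–4% standard error on the
density ratio and ~0.018 standard error on the regression slope), 100
replicate fluctuation experiments, and 200 titration fits.  Statistical
recovery tests use fixed seeds and tolerances set from the analytic
sampling error of the corresponding estimator (binomial/multinomial bounds,
OLS slope CIs, Monte-Carlo error for permutation comparisons).  Ties,
degenerate inputs (zero-variance groups, all-zero cultures, empty bins,
constant regressions) are either handled with a defined, flagged result or
rejected with a specific error — never silently imputed.

## Known limitations

* The recurrence screen cannot distinguish a genuine independent recurrent
  mutation from a shared polymorphism; at study scale this loses a
  negligible number of true calls (14 of ~7,000 in the default run).
* The Lea–Coulson estimator assumes constant μ, no mutant fitness cost and
  full plating; partial-plating corrections and maximum-likelihood
  estimators are out of scope (the estimator interface accepts
  alternatives).
* Transcription profiles attribute a mutation to every overlapping
  transcript frame; with heavily nested annotations the optional exclusion
  flag is the safer choice.
* The sub-bin localization of asymmetry boundaries (e.g. how far upstream of
  a TSS an asymmetry extends) is not implemented beyond per-bin densities.
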