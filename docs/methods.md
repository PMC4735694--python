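# Methods

This note documents the models and numerical choices behind `denovotrio`:
what the synthetic cohort generator emulates, how the filter cascades,
phasing, interval arithmetic and statistics are defined, and where design
decisions were genuinely open.

## The problem

A germline de novo single-nucleotide mutation (DNM) is a variant present in
a child but in neither parent. Trio whole-genome sequencing detects DNMs by
comparing the child's genotype to both parents, but the raw candidate list
is dominated by artifacts, so production pipelines apply long cascades of
read-evidence and positional filters. Once a call set exists, the
scientific questions are statistical: how does the number of DNMs per child
depend on each parent's age at conception, which parent contributed each
mutation, and what is the per-base per-generation mutation rate after
correcting for the pipeline's sensitivity, precision, and the fraction of
the genome that is confidently callable?

The real cohorts behind such studies are access-controlled, so this package
pairs every analysis stage with a synthetic cohort generator that carries
ground truth. All end-to-end claims are parameter-recovery claims: simulate
at a documented operating point, run the estimators, and verify that the
generative values come back.

## Synthetic cohort generator

The packaged operating point (`data/paper_cohort.yaml`) encodes a published
693-trio cohort: father/mother mean ages 33.4 / 31.2 years with Pearson
r = 0.70 and ranges 17–63 / 17–43; DNM counts with intercept 6.61 and
slopes 0.64 / 0.35 DNMs per year of paternal / maternal age; an ART
(assisted reproduction) offset of +4.25 DNMs; 78% paternal origin with 30%
of DNMs phaseable; CpG transition/transversion enrichments of 13.1x / 2.4x
over a 29.04 Mb CpG / 1.59 Gb non-CpG effective-base partition; detection
sensitivity 0.75 and precision 0.87.

* **Ages** are drawn from a bivariate normal truncated by rejection to the
  configured bounds. The published source gives no age standard deviations;
  the defaults (5.5 y father, 4.5 y mother) were chosen once so the
  simulated count s.d. approximates the published 8.77. Truncation
  attenuates the realized correlation slightly (empirical r ~ 0.66 for a
  configured 0.70) and shifts the mean ages down by ~0.2 y; both effects
  are visible in, and tolerated by, the calibration tests.
* **Counts** are Poisson around the linear predictor (with optional
  centered maternal quadratic term). The source fits Gaussian OLS; Poisson
  counts are the natural generative model, OLS still recovers the slopes,
  and the induced count s.d. (~7.9 at the packaged point) is close to the
  published 8.77 without an extra dispersion knob.
* **Sites**: each true DNM gets a uniform position over 22
  pseudo-autosomes whose lengths are proportional to the hg19 autosomes and
  sum to the configured effective genome. Context (CpG / non-CpG) and class
  (transition / transversion) are drawn with probabilities proportional to
  `bases_context x multiplier`, so per-base rate ratios equal the
  configured multipliers by construction. Strength classes (strong G:C vs
  weak A:T) respect the constraint that CpG reference bases are strong: the
  non-CpG strong-to-weak share is solved so the cohort-level
  strong-to-weak : weak-to-strong intensity ratio equals the configured
  value (1.69 at the packaged point).
* **Detection channel**: each true DNM is detected with probability equal
  to the sensitivity; false positives are injected per trio as Poisson with
  intensity `detected_i * (1 - q) / q` (q = precision), plus optional
  additive per-software-version batch offsets. Making the false-positive
  intensity proportional to the trio's own detected load (rather than a
  cohort constant) is a deliberate choice: it makes the precision factor in
  the downstream slope adjustment exactly self-consistent, so the
  adjusted-slope estimator is unbiased under the generator's own
  assumptions. With a constant intensity the same adjustment would
  overcorrect slopes by the precision factor.
* **Evidence**: every emitted site carries all three read-evidence channels
  (CGI-style quality class / refScore / allele depths, Strelka-style
  tier1/tier2 tallies, GATK-style PL triplets and transmission
  probability), generated from one latent Poisson(60) depth draw per member
  per site and clipped so a clean true call passes all three cascades.
  Injected clustered artifacts (pairs within a small window) carry clean
  evidence but are removed by the cluster rule; injected false positives
  deliberately survive filtering — they model the residual false-positive
  load that the precision correction is for.

What the generator does **not** emulate: read-level sequence context,
alignment error, indels, multi-allelic sites, X-chromosome dosage, or
realistic no-call spatial structure (no-call masks are uniform random
intervals). Passing recovery tests therefore demonstrates the correctness
and calibration of the estimators under the stated model, not robustness
to real-data pathologies such as mapping bias or batch-correlated error
modes.

## Filter cascades

Three cascades are implemented as ordered, named rule lists; every input
site receives a trace with its verdict and first failed rule.

* **CGI-style** (autosomes): cohort biallelic with call rate >= 0.99,
  variant private to one proband across the whole cohort, proband quality
  HIGH, both parents' refScore > 0, proband alt fraction >= 0.3; then the
  positional filters; finally >= 5 reads on each allele and <= 5%
  third-allele reads. The chrX variant for male probands replaces the final
  step with depth >= 5 and reference-allele fraction < 5%.
* **Strelka-style**: depth >= 10 in all members, filtered basecalls < 20%
  of tier-1 depth, <= 1 spanning deletion, parental reference purity (>=
  90% reference reads, zero alt reads, tier1 >= 80% of tier2), proband
  genotype-read fraction >= 90% with tier-ratio checks on both alleles,
  minor-allele fraction >= 30%; then clusters / masks / known variants.
* **GATK-style**: transmission probability >= 30, depth in [10, 100] for
  all members, parents' hom-ref PL = 0 and proband het PL = 0, zero
  parental alt reads, >= 5 reads per proband allele, minor-allele fraction
  >= 30%; then clusters / masks / known variants.

Conventions (declared, since the stated rules leave them open): the
alt-fraction rules use tier-1 counts over tier-1 depth; cluster removal
drops *both* members of a close pair (the conservative symmetric reading)
and is idempotent; rules are evaluated in their listed order; the
biallelic/private test counts carriers among all cohort members. Masks are
0-based half-open BED; VCF positions are converted by `pos - 1` at the
boundary. refScore is modeled only as "positive means confident homozygous
reference" (its native semantics are proprietary).

## Parent-of-origin

Transmission phasing applies Mendelian logic at a nearby heterozygous child
site: if only one assignment of the child's alleles to parents is
consistent, that site is phase-informative (triple-het sites are ambiguous;
impossible configurations are flagged as Mendelian violations). Read-backed
phasing is modeled on proband fragments: sites co-observed on a fragment
join a haplotype block, with relative phase decided by majority vote over
fragments and ties splitting the block. A DNM is assigned paternal
(maternal) origin iff its allele shares a haplotype with at least one
paternally (maternally) transmitted allele within +/-20 kb and no opposing
allele in the same block; opposition is a conflict and the origin is
undetermined. The +/-20 kb window gates informative-site eligibility, not
block extent. Per-trio origin counts are normalized by the trio's phased
fraction; trios with zero phased DNMs are excluded and reported.

The fragment model stands in for BAM-level read-backed phasing (out of
scope); blocks are built by greedy majority vote rather than likelihood-
based assembly, which is exact on error-free fragments and degrades
gracefully under conflict.

## Callable-genome arithmetic

Intervals are 0-based half-open, per chromosome, normalized (sorted,
merged) on construction. Subtraction, intersection and three-way trio
intersection are sweep-line merges; `common_callable` drops every base
no-called in at least `ceil(f * n)` of n individuals ("at least 1%" is
implemented literally as the ceiling) and returns the complement within the
genome extent. CpG partitioning intersects the effective region with a CpG
track that marks both the C and G of each dinucleotide. All four operations
are property-tested against per-base bitmap oracles (up to 1e6 bp) and
`bedtools subtract` on random inputs. The published effective-base totals
(1.62 Gb effective, 2.21 Gb commonly callable, 29.04 Mb CpG) are carried as
configuration constants, not recomputed — reproducing them would require
the real no-call and repeat tracks.

## Regression suite

* **MLR / exponential / per-chromosome**: statsmodels OLS. The exponential
  model is OLS on log counts (R^2 reported on the log scale, one of two
  readings of an underspecified original; zero counts raise with advice to
  offset). The per-chromosome model regresses each chromosome's counts on
  father's age and the mother-minus-father age difference and classifies
  significance at 0.05 (raw, no multiplicity correction, replicating the
  original analysis).
* **Outliers**: externally studentized residuals, two-sided t with
  n - k - 2 df, Bonferroni-corrected by n, threshold 0.05.
* **Permutation test** for the maternal effect: shuffle the per-family age
  differences d_i = M_i - F_i, set M*_i = F_i + d_perm(i) (father marginal
  and the difference multiset preserved exactly), refit, record the
  maternal t; p is the upper-tail fraction. The 10,000-replicate loop is a
  closed-form batched 3x3 normal-equations solve (two dot products per
  replicate), so it runs in seconds.
* **Bootstrap**: trio resampling, percentile CIs, batched normal-equations
  solves; rank-deficient resamples are redrawn and counted. Coverage is
  verified at >= 90% for nominal 95% over 100 simulation repeats.
* **Median split**: ties at the median go to the lower half (declared
  convention).
* **GAM**: additive penalized cubic B-spline smooths (10 uniform-knot basis
  functions per age term, second-difference penalty — the standard P-spline
  setup, under which an infinite penalty reduces a smooth exactly to a
  straight line). Penalties are selected by GCV over a two-dimensional
  log-spaced grid with a degrees-of-freedom inflation factor gamma = 1.4,
  the usual guard against GCV undersmoothing. Per-term edf is the trace of
  the term's block of the influence matrix; term F statistics compare
  penalized fits with and without the term. The centered partition-of-unity
  basis leaves one exact null direction per term, resolved with a
  pseudoinverse. GCV remains a noisy criterion at n ~ 700: on purely linear
  truth the selected edf is usually 1.0 but occasionally jumps for one
  term; R's mgcv shows the same behavior on the same draws, and a test
  cross-checks the two implementations' maternal edf and fitted surfaces.
* **Batch models**: the two-age model augmented with, in turn,
  software-version dummies, the fully-called genome fraction, and the gross
  mapping yield. Single-level categorical columns are dropped with a
  warning.
* **Cluster-robustness scan**: re-applies cluster removal at windows from
  10 bp to 1e8 bp, recounts and refits. Note that an arbitrarily large
  window still keeps sites that are alone on their chromosome for their
  proband, so counts shrink sharply but not to zero.

## Rate adjustment

The published rate formulas are not printed in recoverable form, so the
package defines them explicitly and validates by recovery:

    rate      = (n_dnm * precision / sensitivity) / (2 * effective_bases * n_trios)
    slope_adj = slope_obs * precision / sensitivity / genome_proportion
    (phased slopes further divided by the mean phased fraction)

`observed * precision / sensitivity` is the standard recall/false-discovery
correction of a count; the denominator counts diploid base-generations.
Applied to the published inputs (26,939 DNMs, accuracy 0.75/0.87, 1.62e9
bases, 693 trios) this yields 1.39e-8, not the published 1.05e-8 — no
formula assembled from the printed constants reproduces that value, so the
published rate is treated as a generative constant and verified by
recovery through the detection channel instead. "Specificity 87%" is
interpreted as precision (fraction of calls that are true), which is how a
call-set Venn overlap measures it; a genome-scale true-negative specificity
would be ~1 and uninformative.

Context-specific rates divide each (context, class) count by the context's
own base total; all reported ratios are invariant to accuracy and trio
count, which cancel.

## Concordance

Call sets are compared on exact (trio, chrom, pos, ref, alt) keys with no
position tolerance (SNVs only). The truth set is the union of pairwise
intersections of the three pipelines ("called by at least two");
sensitivity and precision restrict calls and truth symmetrically to the
commonly callable region. Twin concordance drops the twin id from the key;
under independent detection at sensitivity s from a shared truth the
expected shared fraction of the union is s^2 / (2s - s^2), which the
estimator reproduces.

## Problem sizes

The bundled checks use the cohort sizes of the study they model (693 trios;
719 for the ART model) and scale site-level analyses to >= 1e5 simulated
DNMs (a few thousand trios) — ample for 1–3% Monte-Carlo error on every
ratio while keeping the whole suite and the acceptance script each under a
minute of compute. Slope-type acceptance quantities are reported as the
mean fitted coefficient over replicate cohorts (25–150 replicates,
documented in `scripts/acceptance.py`), which estimates the same quantity
with smaller Monte-Carlo error than a single draw.

## Known limitations

* The generator's evidence channels are idealized: clean calls pass all
  cascades by construction, so cascade *discrimination* is exercised by the
  rule-level unit fixtures, not by the cohort simulation.
* Phasing instances carry at most one informative site per DNM; multi-site
  blocks and fragment errors appear only in unit fixtures.
* The GAM's GCV surface is evaluated on a fixed grid; edf values between
  grid-implied optima are not interpolated.
* The published effective-base totals are constants here; interval
  arithmetic is validated on synthetic tracks only.
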