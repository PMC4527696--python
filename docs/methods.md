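# Methods

This note documents the models, parameter choices and numerical decisions
behind `cagtrace`, in the order the pipeline runs.

## Fragment data model

A sample is a peak table: fragment sizes (bp) with heights in arbitrary
fluorescence units.  Size maps to repeat count linearly,
`repeats = (size_bp − flank_bp) / unit_bp` with `unit_bp = 3` for a CAG
tract.  The flanking length of the amplicon is assay-specific and cannot be
derived from primer sequences alone, so `flank_bp` is an explicit parameter
everywhere; the synthetic assay uses 100 bp.  Conversion is exact and
invertible; rounding to integer repeats uses nearest-integer
(half away from zero — ties cannot occur for exact 3 bp spacing).

**Peak calling threshold.** `peaks_to_distribution` discards peaks below
`min_rel_height × max height`, default 0.05 — a conventional relative floor
for instrument noise.  The cohort-level pipeline (`quantify_cohort`) lowers
this to 0.01: rendered synthetic tables carry no baseline noise peaks, and a
5% floor measurably clips real low-frequency classes in the right tail of
strongly expanded samples (≈ −0.05 to −0.1 repeat bias on low-mean strata).

**Stutter correction.** PCR stutter is modelled as a geometric ladder:
satellites at −1 and −2 repeat units with relative heights `d` and `d²`
(default d = 0.35) and a +1 satellite (default 0.10).  Correction solves the
ladder convolution `S f = h` by nonnegative least squares, which inverts the
ladder exactly for noiseless input and degrades gracefully under
multiplicative trace noise.  Correction is OFF by default when reading raw
peak tables (instrument exports are typically used as called) and ON inside
the cohort pipeline, where the rendering parameters are known.

## Gaussian allele-peak fitting

The measured repeat distribution of an inherited allele is modelled as a
Gaussian sampled at integer repeats.  Fitting is separable ("variable
projection"): midpoints and widths are the nonlinear parameters, optimized
by bounded trust-region least squares (`scipy.optimize.least_squares`,
iteration cap 200, tolerances 1e-12); at every iterate the heights are
profiled out by nonnegative least squares.  Initialization: midpoints at the
highest well-separated local maxima (minimum separation 3 repeats), width at
the weighted SD of the distribution (clipped to [0.5, 5]); widths are
bounded below at 0.25 repeats.  Fitting is deterministic given the input.

**Two-peak model selection.**  For homozygotes a two-peak fit is attempted
and then audited against the single-peak fit.  The pair is declared
*coincident* — and the single fit used — when any of: the fitted separation
is below 0.5× the mean width; a component carries < 0.1% of the mass; the
single-peak RSS is already at numerical floor (< 1e-6 × Σy²); or the second
component removes less than 90% of the single-peak residual.  The last rule
is deliberately conservative: splitting a genuinely single noisy peak into
two spurious components shifts the Δ reference and biases pooled means,
whereas treating a barely-resolved pair as one peak only adds symmetric
spread (verified unbiased in the test suite).  Accepted pairs are classified
*separated* when separation > 4× mean width, else *partially overlapping* —
the thresholds are recorded with the fits so they are auditable.

## Inherited-allele normalization

Somatic change is `Δ = repeats − round(inherited midpoint)`, with
round-half-even on the reference: coincident homozygote references sit at
half-integers whenever the allele sum is odd, and half-away rounding would
bias pooled Δ means by ≈ −0.25 repeats; half-even is unbiased across
animals.  Contractions (negative Δ) are retained in all summaries.

For two resolved references the default method deconvolves the two-spike
reference mixture by nonnegative least squares: both alleles of a homozygote
acquire changes from the same tissue law, so the aged distribution is that
law convolved with the inherited pair, and inverting the convolution stays
unbiased however much the components overlap.  A hard nearest-midpoint
assignment (ties to the lower allele) is available as `method="nearest"`;
it is exact for well-separated pairs but loses ≈ 0.5 repeats per animal on
partially overlapping ones, which is why it is not the default.

Whether the original procedure subtracted a full reference distribution or
its midpoint is ambiguous; we subtract the (rounded) midpoint, and the
deconvolution route is the natural full-distribution generalization for
resolved pairs.

## Pooling and quantile cells

Global distributions weight animals equally (not molecules/peaks), so
high-signal samples cannot dominate; pooling is associative under
n-weighted combination.  When both HD zygosities enter one comparison the
pooled law is the equal-weight average of the per-zygosity pools
("combined, adjusted for zygosity").

Percentile values use the weighted nearest-rank convention — the smallest
support value whose cumulative frequency reaches p/100 — keeping cells on
the integer Δ grid.  Cell differences get SEs and two-sided p-values from an
animal-level bootstrap (default 2000 resamples, fixed seed, resampling
within stratum when stratified): the SE is the bootstrap SD, the p-value the
add-one-corrected bootstrap sign probability (so the smallest attainable p
at 2000 resamples is ≈ 0.001).  Animal-level resampling respects the
clustering of repeats within animals.  Significance codes: `*` P≤0.05,
`†` P≤0.01, `‡` P≤0.005.

The two-sample statistic is `Z = (m₁ − m₂)/√(se₁² + se₂²)`.  Applied to the
published 10-week striatal values (4.89±1.41 vs 2.04±1.13) this gives
Z = 1.58, not the Z = 4.50 printed alongside them; no standard two-sample
formula reproduces that value from those numbers (the ± quantities may be
SDs with an unstated n), so the package implements the documented formula
and leaves the discrepancy flagged rather than tuned away.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are the published
values wherever one is printed.

**Inherited alleles.**  Rounded Gaussian, mean 117, SD 12 repeats (so ±2SD
spans 48 repeats), minimum 1.  A homozygote's second allele is the first
plus round(N(0, 1.5)) — both knock-in alleles descend from one founder, so
within-animal pairs are near-identical (and typically fit as coincident,
matching how real homozygous traces present), while the across-animal law
stays N(117, 12).  Truly independent allele pairs would put the two
references ~13 repeats apart and make per-class reference assignment the
dominant error source, which no published trace shows.

**Somatic Δ law.**  Floored gamma (shape default 1.5 — right-skewed, skew
2/√k), negated with contraction probability 0.05.  The continuous gamma mean
is solved numerically (brentq) so the final signed integer law has *exactly*
the configured mean, discretization and contractions included.  Per-animal
biological heterogeneity enters as a lognormal factor on the stratum mean
(CV 0.3, mean 1), giving between-animal SDs of the order implied by the
published per-arm SEs.  Each sample's absolute repeat distribution is the
allele (or equal-weight allele pair) plus the Δ law, broadened by a
discretized Gaussian of SD 1.5 repeats — the "single narrow Gaussian" a
birth/tail sample shows, and the width the allele fitter estimates.

**Calibration of the default Δ means.**  Per-zygosity pooled-brain means by
age window reproduce the published age summary exactly (heterozygote values
are 2×combined − homozygote, so combined means are exact too); windows past
40 weeks follow the published narrative that the knockout difference
disappears and can reverse.  Tissue allocation uses per-OGG1-status
multipliers (mean 1) chosen to reproduce the striatal 10-week homozygote
means (4.89 / 2.04) and the hippocampal and cerebellar knockout differences
(2.20, 2.10 repeats, averaged over the ≤40-week windows); the cortical
multiplier is then fixed by mass balance.  The printed regional differences
sum to slightly more than the pooled window means allow, so the cortical
difference absorbs the residual; and because the knockout's late-window
pooled means are large (the printed 31–40-week homozygote means already
reverse), the knockout striatum overtakes the wild-type one past ~30 weeks
under this allocation.

**Trace rendering.**  Each repeat class emits its stutter ladder; heights
are scaled (10⁴) and multiplied by lognormal noise of CV 0.05 (mean 1),
typical fragment-analysis values.  Peak positions are exact
(`flank + 3·repeats`); no per-scanline electropherogram simulation.

**Phenotype model.**  Expected score = 91.9 s, +7.7 s female, +11 s
OGG1-null, −23.7 s HD-homozygous, with a post-onset decline for Q150/Q150
genotypes: onset weeks 12 (ogg1+/+) and 42 (ogg1−/−) — inside the onset
groups the box-plot analysis identifies — at 6 s/week down to a 25 s floor
(the worst-quartile value the 11–20-week group already reaches).  Attempt
times are `clip(N(c, 20), 0, 120)`; the centre `c` is solved per animal so
that the expected best-of-3/5-day score equals the structural mean exactly,
ceiling truncation included — the generator's contract is on the expected
*score*, which is what the regression recovers.  Grip: per-day fail
probability from a logistic in age with genotype-specific intercepts,
calibrated so the overall fail rate (all five days failed) of 40-week
Q150/Q150·ogg1+/+ animals is 0.909⁵ ≈ 62%; an animal passes if any day
passes.  The baseline age effect is 0; age structure enters only through
the onset terms.

**Reproducibility.**  One `numpy` Generator seeded from the config drives
every draw in a fixed order; identical configs give byte-identical cohorts.
Sexes alternate within each stratum (balanced within 1) unless a male
fraction is configured.

## Onset detection

Onset is operationalized as the earliest age group whose *baseline-aligned*
median deficit against the wild-type reference exceeds a margin, sustained
into the next group (vacuously at the last group).  Deficits are aligned at
the first shared age group so that a genotype offset present from the
youngest age — which the structural phenotype model has — does not register
as decline; with no baseline offset the rule reduces to "median below the
reference band".  The default margin is the Tukey IQR of the pooled
reference scores; it is a parameter, and reported with the result.  Under
the default generator the homozygous arms are detected at 11–20 and 41–60
weeks (group midpoints 15.5 and 50.5), a 35-week delay.

## Phenotype analyses

Scores are plain least squares despite the 120 s ceiling, matching the
original analysis choice; truncation behaviour is characterized in tests
rather than switched to a censored model.  The association grid regresses
score on each animal's Δ value at a percentile *of its own distribution*,
adjusted for the four covariates (HD genotype, OGG1 genotype, age, sex),
with no multiple-testing correction (the grid reports unadjusted P).  A
significant negative slope is labelled "fewer-repeats-better" in the lower
half of the distribution and "more-repeats-worse" in the upper tail,
mirroring how such grids are annotated.  Box summaries use Tukey hinges
(median of halves, halves sharing the median for odd n).

## What the generator does not emulate

Real electropherograms (per-scanline fluorescence, pull-up, off-ladder
artifacts); allele dropout and amplification bias between long and short
alleles; within-tissue spatial heterogeneity (tissue is an atomic label);
learning or fatigue effects in motor testing (each age group is an
independent cohort, as in the study design); breeding structure, survival
and body-weight covariates.  Passing tests therefore demonstrate that the
pipeline recovers known parameters under a faithful statistical abstraction
of fragment-analysis data, not that it is robust to every instrument
artifact of real capillary traces.

## Problem sizes

The acceptance script uses the cohort sizes stated with each analysis:
20,000 birth samples for the inherited-allele recovery, 20 animals per arm
or stratum for the expansion summaries (32/arm for the hippocampal
difference), 600 animals for the regression, and 20 animals per age group
for onset detection — the same order as the real design (16–24 per group).
Calibration properties (type-I error of the interaction, inherited-length
and association-grid tests) use 200–500 replicate null cohorts.
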