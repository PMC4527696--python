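# cagtrace

Quantification of age-dependent somatic CAG-repeat expansion from
fragment-analysis peak tables, with the genotype–phenotype analyses used to
link somatic expansion to disease onset — plus a synthetic cohort generator
that makes every stage testable without animal data.

## The scientific problem

Huntington's disease is caused by inheriting one expanded CAG tract in *HTT*,
but the tract keeps expanding *somatically* with age, tissue by tissue.
Whether that ongoing somatic expansion adds to toxicity — and whether
suppressing it (e.g. by knocking out the DNA glycosylase OGG1, whose
base-excision repair of oxidized guanines drives expansion) delays disease —
is a quantitative question: you must measure small (~1–5 repeat) shifts of
broad, right-skewed repeat-length distributions in many animals, and relate
them to motor phenotypes.

`cagtrace` implements that measurement pipeline for capillary-electrophoresis
fragment data (GeneScan/GeneMapper-style peak tables):

1. **fragment IO** — parse peak tables (fragment size in bp, height), convert
   sizes to repeat counts via the linear calibration
   `repeats = (size − flank) / 3`, build normalized repeat distributions, and
   optionally deconvolve the geometric PCR-stutter ladder (nonnegative least
   squares).
2. **allele-peak deconvolution** — fit one or two Gaussian peaks to a repeat
   distribution with a separable (variable-projection) scheme: peak position
   and width are nonlinear parameters optimized iteratively, peak heights are
   linear and solved by nonnegative least squares at each iterate.
   Homozygous allele pairs are classified *coincident* (refit as one peak),
   *partially overlapping*, or *separated* from the fitted separation `s`
   and mean width `w` (`s < 0.5w`, `s > 4w`).
3. **inherited-allele normalization** — subtract the birth (tail) reference
   from each aged tissue sample to get the signed somatic-change
   distribution Δ; for resolved homozygote pairs the two-spike reference
   mixture is deconvolved so both alleles share one Δ law.
4. **instability statistics** — animal-equal-weight pooling into global Δ
   distributions; nearest-rank quantile "cells" (1st…99th percentile)
   compared between genotypes with animal-level bootstrap SEs and
   significance codes (`*` P≤0.05, `†` P≤0.01, `‡` P≤0.005); age-window
   summaries (mean ± SE); zygosity × OGG1 interaction and
   inherited-length-independence regressions; two-sample
   `Z = (m₁ − m₂)/√(se₁² + se₂²)`.
5. **motor phenotype** — rotarod protocol summaries (best of 3 attempts/day,
   5 days, 120 s ceiling), Tukey box summaries, least-squares regression of
   score on sex/OGG1/HD-zygosity/age, a percentile-wise association grid
   between performance and somatic repeat length, grip pass rates, and
   operational onset-of-decline detection against a wild-type reference.
6. **synthetic cohorts** — virtual `Hdh(Q150) × ogg1` mice with inherited
   alleles ~ round(N(117, 12²)), calibrated right-skewed Δ laws per
   (genotype, tissue, age window), stuttered noisy trace rendering, and
   phenotype records with configurable effect sizes and post-onset decline.

## Worked example

`examples/02_quantify_expansion.py` simulates two 20-animal homozygous arms
at 10 weeks and runs the full pipeline (trace → stutter correction → allele
fit → normalization → pooling) on the striatum samples:

```
ogg1(+/+): pooled mean somatic change =  4.66 ± 0.35 repeats (n = 20 animals)
ogg1(-/-): pooled mean somatic change =  2.01 ± 0.11 repeats (n = 20 animals)

Two-sample Z = 7.22
```

The pooled mean change is how many CAG units the average striatal repeat
tract gained between birth and 10 weeks; the knockout arm gains less than
half as much, which is the suppression signal the downstream phenotype
analyses build on.  The other example scripts cover cohort simulation,
quantile-cell tables, the rotarod analyses with onset detection, and a
pharmacologically treated arm.

A thin CLI mirrors the stages:

```bash
cagtrace simulate --out run/ --seed 1
cagtrace deconvolve --peaks run/peaks --metadata run/metadata.csv --out run/dists
cagtrace instability --distributions run/dists --metadata run/metadata.csv --out run/stats
cagtrace phenotype --performance run/performance.csv --metadata run/metadata.csv --out run/motor
```

## Layout

```
src/cagtrace/
  cohort.py       synthetic cohort generator (animals, traces, phenotypes)
  fragments.py    peak-table IO, bp↔repeat conversion, stutter correction
  peakfit.py      separable Gaussian allele fits, Δ normalization
  instability.py  pooling, quantile cells, window summaries, Z/interaction
  motor.py        rotarod/grip summaries, regression, onset detection
  pipeline.py     end-to-end quantification over a cohort
  cli.py          thin command-line interface
docs/methods.md   model, parameter and calibration notes
examples/         one narrative script per capability
```
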