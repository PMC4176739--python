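# Methods

`origingwas` implements a subspecies-origin-aware association scan for
populations formed from two deeply diverged source populations (referred to
throughout as *taurus* and *indicus*, after the cattle system that motivates
the design) plus recently admixed composites. This note records the models,
the defaults and why they were chosen, the generative assumptions of the
synthetic-data module, and the numerical conventions.

## Local ancestry from segment haplotype frequencies

Each chromosome is partitioned into non-overlapping segments of 30 or 31
consecutive SNPs. For the haplotype string a given chromosome copy carries
in a segment, the probability of indicine origin is

    b = pBi / (pBi + pBt)

where `pBt` and `pBi` are the frequencies of that exact string among the
taurine and indicine reference haplotypes. Matching is exact; a string seen
in neither panel has undefined `b`. Because admixture is recent, true
ancestry tracts span many segments, so a centered rolling average of `b`
over seven segments (truncated at chromosome ends, missing values skipped)
pools information along the chromosome. A segment is labelled indicine when
the smoothed `b` strictly exceeds 0.6, taurine otherwise; the boundary value
0.6 resolves to taurine. A window that is entirely missing yields 0.5 and
therefore a taurine label. Combining the label with the A/B allele carried
at each SNP gives the four allele classes taurine A, taurine B, indicine A,
indicine B.

Remainder handling in segmentation: when the SNP count is not a multiple of
30, the excess is spread over the final segments (sizes 30/31); on short
chromosomes a terminal remainder of at least 15 SNPs stands alone, a smaller
one is merged into the previous segment, and a chromosome under 15 SNPs
becomes one undersized segment with a warning. Smoothing is per haplotype,
not per animal, and reference haplotype frequencies are not re-estimated
leave-one-out.

## Contrast coding and the three scans

Each single allele is coded by seven 0/1 variables: x1 (B allele), x2
(indicine origin), x3 (indicine B, the interaction), and the one-hot classes
x4 (taurine A), x5 (indicine A), x6 (taurine B), x7 (indicine B), so that
x1 = x6 + x7, x2 = x5 + x7 and x3 = x7. Paternal and maternal codings are
summed to per-animal 0/1/2 counts.

Three per-SNP models are fitted:

- **conventional** — x1 alone: the ordinary allele-count regression;
- **interaction** — {x1, x2, x3} jointly, equivalently re-parameterised as
  {x2, x6, x7} (origin, allele within taurus, allele within indicus); the
  two blocks are linear bijections of one another and their 3-df joint
  statistics are identical at full rank;
- **best variable** — each of x1, x2, x4, x5, x6, x7 alone (x3 duplicates
  x7); the minimum-p variable is reported, with ties broken by the fixed
  order x1 < x2 < x4 < x5 < x6 < x7. A winning within-origin variable
  implicates that origin's allele as the one tracking the causal mutation.

## Mixed model and testing

The trait model is `y = Xβ + z + g + e` with `z` the SNP term, a polygenic
animal effect `g ~ N(0, σg² G)` for a VanRaden centred-scaled GRM `G`
(missing dosages mean-imputed for `G` only, no leave-one-chromosome-out),
and residual `e ~ N(0, σe² I)`. Variance components are estimated once per
trait/subset by REML under the no-SNP null — profile restricted likelihood
over h² on a 40-point grid refined by bounded Brent search, after rotating
into the GRM eigenbasis — and reused for every SNP (two-stage, EMMAX-style).
Per SNP, generalized least squares in the rotated-whitened basis gives
coefficient estimates; marginal tests are Wald chi-square tests of each
coefficient in the joint fit (i.e. conditional on the other terms), and the
SNP block gets a joint Wald chi-square with degrees of freedom equal to the
number of testable columns. The null-model variance is treated as known, so
with σg² = 0 the estimates coincide exactly with OLS and the p-values with
its large-sample normal approximation. Constant or collinear SNP columns
are dropped with the joint df reduced and flagged, never raised as errors.
SNPs with missing genotypes leave the vectorized path and are fitted by
exact per-SNP GLS with animal-wise deletion (Cholesky of the retained
covariance submatrix when a GRM is active).

Default covariates are an intercept plus breed-group indicators. Degenerate
inputs: zero-variance phenotypes and non-PSD GRMs are rejected; a subset
with no animals is an error; a genome-wide monomorphic SNP is an untestable
result.

## Reporting

The FDR among SNPs declared significant at threshold `P` out of `T` tested
is the expected-by-chance count over the observed count,
`floor(100·P·T/A)` percent, capped at 100 and undefined when `A = 0`. A
refined variant `P(1−A/T)/((A/T)(1−P))` is available behind a flag and
differs negligibly at genome scale. Per-subset `T` is the number of
testable SNPs in that subset. Significant SNPs are labelled by which of the
three re-parameterised contrasts drive them (origin O, allele within taurus
T, allele within indicus I — patterns `OTI` … `---`); SNPs significant
within both origins are checked for sign agreement of b6 and b7. Per
trait-by-chromosome, the single most significant best-variable SNP passing
the threshold is retained (position breaks ties), and the winning variable
maps to a mutant-allele descriptor: x4..x7 implicate a specific origin and
allele letter, whose within-origin frequency and signed t-value (estimate
over SE) are reported; x1/x2 winners are indeterminate, x2 being the
fixed-difference candidate pattern.

## Synthetic populations

The generator produces the statistical structure the analysis assumes,
together with truth labels for recovery tests.

- **Founder divergence.** Per-SNP B-allele frequencies for the two pools
  follow the Balding–Nichols construction around a Uniform(0.05, 0.95)
  ancestral frequency: `Beta(p(1−F)/F, (1−p)(1−F)/F)` per pool, so the
  expected Hudson-type differentiation equals the single parameter `F`
  (default 0.3). A configurable fraction of SNPs (default 2%) is fixed for
  alternate alleles outright.
- **Within-pool LD.** Haplotypes are mosaics of a small pool of template
  haplotypes (default 20 per pool), switching templates with probability
  0.02 per inter-SNP step. This makes 30-SNP segment haplotypes recur at
  estimable frequencies — the role pedigree structure plays in real data.
  The template count is a knob because the realistic haplotype diversity at
  30-SNP scale is not independently constrained here.
- **Composites.** Each composite chromosome is a tract mosaic: tract
  genetic lengths are exponential with mean `1/admix_generations` Morgan
  (renewal approximation to recombination since admixture, default 8
  generations), each tract's pool is drawn with the configured indicine
  proportion (default 0.5), and its alleles are copied from one uniformly
  chosen pool haplotype. Tracts are recorded in 0-based half-open bp.
- **Map.** Uniform 1 cM/Mb equivalence, 1e8 bp per Morgan. The default map
  (900 SNPs per 0.25-Morgan chromosome) keeps a 30-SNP segment about 15×
  shorter than a typical tract, the dense-chip regime the smoothing window
  assumes. The analytic identity that 1e5 generations of divergence leave
  ~1e-5 Morgan = 1 kb shared segments is exposed as
  `expected_ibd_tract_bp`.
- **QTL.** A planted locus lives at a SNP and is identified by allele
  letter *and* true ancestry: modes `taurus_only`, `indicus_only`,
  `shared_same_phase`, `shared_reversed_phase` (mutant on B in taurus, on A
  in indicus) and `fixed_difference` (causal lineage split between pools).
  For one-subspecies modes only the segregating pool's frequency is pinned;
  the tag SNP's frequency in the other pool stays as drawn, since its
  alleles there are a different, effect-free lineage. This is what makes
  origin-by-allele interaction signal real rather than a coding artifact.
- **Phenotypes.** `y` = group offset (defaults 0 / 0.4 / 0.2 SD for
  taurus / indicus / composite) + Σ causal dosages × effects + polygenic
  value + residual. Polygenic values are drawn with covariance proportional
  to the GRM and rescaled so their realised variance equals the configured
  h²; the residual takes the remainder of unit phenotypic variance, and a
  configuration whose QTL-plus-polygenic variance reaches 1 is rejected.

Everything is driven by one seed through `numpy` `SeedSequence` spawning
and is bit-reproducible. What the generator does **not** emulate: real LD
decay from pedigree and mutation history, genotyping and imputation error
beyond injected missingness, phasing switch errors, multi-breed structure
within each pool, and trait-specific fixed-effect nesting. Passing recovery
tests therefore demonstrates correctness of the method's logic under its
own assumptions, not field performance on array data.

## Experiment sizes

The canned studies in `origingwas.experiments` fix the conditions used by
the test suite and the results script: ancestry accuracy at Fst 0.3 with
250 reference animals per side and 200 composites over three 900-SNP
chromosomes; power at 100 phase-reversed 0.3-SD tag SNPs (10 per replicate
× 10 replicates, 3000 composites, h² 0.3); pattern recovery over 50
single-QTL replicates per mode (0.5 SD, n = 3000, no polygenic term — with
an effect that size the background only rescales all six candidate tests);
null calibration on 5000 SNPs, n = 2000, h² 0.3; heritability recovery over
20 phenotype redraws on one n = 2000 panel. Association experiments use the
generator's true ancestry labels so that each study isolates the property
it measures; the end-to-end pipeline wires inferred ancestry into the scans
and is exercised separately.

## Known limitations

- Wald chi-square approximations rather than exact F-tests; denominator-df
  effects at small n are not modelled.
- Two-stage variance-component reuse (no per-SNP REML), no
  leave-one-chromosome-out GRM; proximal contamination is negligible at the
  simulated scales but would matter on dense real data.
- Exact string matching of segment haplotypes: genotyping error or rare
  recombinant strings fall back to the missing-`b` path.
- The FDR estimator is the expected-by-chance ratio, not a permutation or
  empirical-Bayes estimate.
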