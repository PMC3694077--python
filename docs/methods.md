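# Methods

This note documents the models, the defaults and the reasoning behind the
design choices, in the package's own words. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Phenotype derivation

**ADG** (average daily gain, kg/day) is the ordinary least-squares slope
of biweekly body weights on days on test; it needs at least two distinct
weigh days.

**ADFI** (average daily feed intake, kg/day) fits each animal's daily
intakes with a quadratic in day by least squares and returns the mean of
the fitted curve over the integer days of the animal's own on-test to
off-test window. The quadratic absorbs the rise-then-plateau shape of
intake curves; averaging the fit rather than the raw records makes ADFI
robust to missing feeder days. A population-level random-regression
formulation would pool curvature across animals; the per-animal fit was
chosen because it needs no variance components and converges for every
animal with ≥ 3 distinct days.

**RFI** (residual feed intake, kg/day) is ADFI minus its prediction from
growth, body composition and nuisance effects under a single-trait animal
model:

    ADFI = cells(generation×line) + group + sex
           + Σ_c b_{c,cell} · covariate_c
           + animal + dam + pen(group) + e

with covariates onwt−40, age at on-test−90, offwt−115, metamidwt
(mean on-test weight^0.75), adga (ADG linearly adjusted to the 90–180 day
reference window) and offbfa (backfat linearly adjusted to 115 kg
off-test weight), each with its own slope per generation-by-line cell.
The adga/offbfa pre-adjustments use pooled within-group regression slopes
estimated from the data — the exact functional form is a design choice
recorded here and in the output metadata.

Three level-identifiability decisions matter:

1. **Covariates are mean-centred before fitting**, so their contributions
   carry no arbitrary baseline into RFI.
2. **RFI keeps the genetic deviation.** Only the nuisance prediction
   (group, sex, covariate terms) is subtracted; the animal/dam/pen
   predictions are not (flag `subtract_random` reverses this). A selected
   line realizes its response *in* RFI — removing the animal effect would
   define the response away.
3. **RFI keeps the within-generation line contrast.** On-test group is
   nested within generation, so the generation-level intercept is
   confounded between group effects and generation-by-line cells; the
   solver's minimum-norm solution splits it arbitrarily. The package
   subtracts the (confounded) generation level with the nuisance and keeps
   only the identifiable line contrast of the cell intercepts. With
   `subtract_line=True` the cell intercepts are subtracted entirely, which
   makes RFI exactly mean-zero and covariate-orthogonal within every cell
   — useful for checking the fit, wrong for measuring selection response.

**Mixed-model machinery.** A⁻¹ is assembled by Henderson's rules with
Mendelian-sampling variances 0.5−0.25(F_s+F_d) (one/no parent known:
0.75−0.25F_p / 1), inbreeding coefficients from memoised recursive
kinship (Meuwissen–Luo values). The MME are solved densely; variance
ratios are supplied as λ = σ²ₑ/σ²ᵤ per random effect (0/None drops the
effect, so an all-zero configuration is OLS), with a simple EM-REML
option for estimating them. Rank deficiency is handled by corner
constraints (first level of each factor is the reference) plus a
minimum-norm SVD fallback when the normal equations are ill-conditioned;
fitted values are invariant to that fallback.

## Divergence scan

Allele_b frequencies per line at the focal generation (default 8) give a
signed difference d = f_HIGH − f_LOW per SNP. Because drift moves rare
alleles relatively further, SNPs are stratified by their generation-0
minor-allele frequency into bins [0,0.1), [0.1,0.2), [0.2,0.3),
[0.3,0.4), [0.4,0.5] (half-open left edges, 0.5 in the top bin) and each
SNP is scored z = (d − mean_bin)/sd_bin with population-formula moments,
so within-bin z has mean 0 and SD 1 by construction and the scan is
exactly antisymmetric under swapping line labels. P values are two-sided
normal; Benjamini–Hochberg FDR runs over the scored SNPs only (bins with
< 2 SNPs or zero SD are flagged, not scored). Z-scoring the *differences*
(not the per-line frequencies) is the only construction that yields one
Z per SNP; the published FDR column for this scan cannot be reproduced
from the printed P values by standard BH, so standard BH is reported
without adjustment. The scan defaults to all animals of the focal
generation; a founders-only HWE subset mask is available in QC because
pooled diverged lines violate HWE by construction.

## BayesB whole-genome regression

Model: y = Xb + Σⱼ zⱼaⱼδⱼ + e with zⱼ the −10/0/10-coded marker
(missing genotypes mean-imputed, preserving allele-frequency
expectations), P(δⱼ=0) = π (default 0.995), aⱼ | σ²ⱼ ~ N(0, σ²ⱼ),
σ²ⱼ ~ scaled-inv-χ²(ν_a = 4, S_a), e ~ N(0, Iσ²ₑ),
σ²ₑ ~ scaled-inv-χ²(ν_e = 10, S_e).

Sampler (single-site Gibbs, numba-compiled, O(n) per marker per
iteration via running residual updates):

- fixed effects from their normal full conditionals (flat prior);
- per marker, σ²ⱼ is refreshed from the prior when the marker is excluded
  and from its full conditional (ν_a+1 df) when included — a valid Gibbs
  step on the augmented (δ, σ²ⱼ, a) space that avoids the reducibility of
  conditioning δ on a = 0;
- δⱼ from the likelihood ratio with aⱼ integrated out, then aⱼ from its
  normal full conditional when included;
- σ²ₑ from its scaled-inv-χ² full conditional.

Prior scales: S_a is solved so the prior-mean genetic variance matches
`expected_h2 · var(y)` given π and the mean coded-column variance (the
standard construction when software-internal scales are unpublished);
S_e targets (1−expected_h2)·var(y). Both can be overridden explicitly.
Defaults run 51,050 iterations with 1,000 burn-in and output frequency
50, i.e. ⌊(51,050−1,000)/50⌋ = 1,001 saved states; the test suite uses
shorter chains (≤ 11,000 iterations) at desk scale. `method="bayesc"`
swaps the locus-specific variances for one common effect variance.

**Windows.** Markers map to non-overlapping windows keyed by
(chrom, ⌊(pos−1)/10⁶⌋); unassigned/unmapped markers (chromosome U etc.)
are excluded. Per saved state, a window's genetic contribution is the
variance across individuals of Σ_{j∈window} zⱼaⱼδⱼ, expressed as a share
of that state's total genetic variance (0/0 counts as 0); the reported
percentage is 100× the posterior mean of the share, and PPA is the
fraction of states with positive window variance. Because windows
covary, the percentages need not sum to 100 and are not forced to. A
window is a candidate QTL when its percentage reaches 5× the uniform
expectation 100%/n_windows (0.04% → 0.2% at the 2,815-window pig map).
Genomic heritability is the posterior mean of var(g)/(var(g)+σ²ₑ) with g
the empirical genetic values of the analysed individuals.

## Single-SNP association

Phenotypes are adjusted by OLS for sex, pen-by-group and an
age-at-on-test covariate with a separate slope per line-by-parity cell
(cells with < 2 animals merge into the nearest parity with a warning);
each SNP is then tested by simple regression of the adjusted phenotype
on allele count, t with n−2 df, converted to a 1-df χ² through the
standard-normal quantile of the P value. Genomic control divides all χ²
by λ = median(χ²)/0.4549364 when λ > 1 (never below 1, which would be
anti-conservative), and BH FDR runs on the corrected P values.
Significance is flagged both at GC-corrected P < 0.01 and at q < 0.05.
The two-step adjusted-phenotype design mirrors the standard
PLINK-with-pre-adjustment workflow rather than a joint mixed-model fit.
Stratification diagnostics: IBS(i,j) = mean shared alleles / 2 over
pairwise-complete SNPs, classical Torgerson scaling of D = 1 − IBS
(double-centred −D²/2, eigendecomposition, top-k coordinates scaled by
root eigenvalues), and Q-Q points with expected quantiles −log10((i−½)/m).
GC restores calibration exactly when structure inflates statistics
scale-like (drift-style random per-SNP divergence); under strong
fixed differentiation of every SNP the inflation is non-central and GC
over-corrects the tail — a known property, not a defect.

## Synthetic-data generator

The generator emulates the two-line design: founders drawn in linkage
equilibrium with MAF uniform on [0.05, 0.5] across 18 autosome-like
chromosomes (sex chromosomes simulated as autosomal, flagged in
metadata); 9 generations (G0–G8); the LOW line truncation-selected
(best 20–30% within each sex) on the simulated RFI *phenotype* every
generation; the HIGH line random-mated until generation 5, then selected
upward. Gametes recombine with Poisson crossover counts per chromosome
(default 10⁻⁸/bp), so LD accrues from drift and selection with no
coalescent backstory. A fraction of SNPs (default 0.5%, matching a
mixture fraction π = 0.995) are QTL; effects are scaled so founder
genetic variance equals `h2_target` (default 0.4–0.5 in the tests) on a
unit-phenotypic-variance scale, and companion traits (ADG, BF, LMA) get
correlated effect vectors (genetic correlations 0.2/0.35/−0.15 with
RFI). Breeding values are reported as deviations from the founder mean.
Records: biweekly weights on an individual growth line (intercept ≈ 40 kg,
slope = true ADG, measurement SD 0.8 kg), daily intakes on a gentle
quadratic whose window mean is the animal's true ADFI (carrying the RFI
breeding value plus sex, pen-by-group and dam effects; daily SD 0.35 kg),
off-test ultrasound traits, and per-SNP quality scores with a
configurable failure fraction.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: genotyping error beyond missingness, realistic
pig linkage maps and mutation, feeder-malfunction artefacts in intake
records, selection on estimated (rather than phenotypic) breeding values,
and maternal/common-litter environmental covariance structures richer
than a single dam effect. Selection on phenotype rather than EBV slightly
understates realized response per generation; no acceptance check depends
on the response magnitude.

## Scale of the checks

Desk-scale defaults (hundreds of SNPs and animals per test, 2,000 SNPs ×
1,000 individuals with an 11,000-iteration chain for the largest BayesB
recovery check, 20 replicate seeds for scan calibration) keep the whole
suite around two minutes while exercising every code path; the full
50k-SNP scale is supported by the same code but not used by the tests.

## Numerical conventions

- Coordinates are 1-based (PLINK MAP); window bins use ⌊(pos−1)/width⌋.
- Allele orientation is fixed at load: allele_b = dataset minor allele,
  ties broken lexicographically; monomorphic SNPs pass HWE (P = 1) but
  are flagged.
- QC thresholds are strict inequalities.
- HWE uses the 1-df χ² goodness-of-fit test; at α = 10⁻⁴ and these sample
  sizes it is practically equivalent to the exact test.
- Chains, simulations and the pipeline are exactly reproducible from
  integer seeds; the pipeline fans one global seed into per-stage seeds
  via `SeedSequence([seed, stage_index])`.
- The MME solver's corner constraint and minimum-norm fallback make
  solutions reproducible; only identifiable contrasts are interpreted.
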