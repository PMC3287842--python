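# Methods

## The statistical model

Every test in `rarepool` is a weighted burden regression. For a gene with
variant minor-allele counts x_i (columns of the samples × variants matrix)
and weights w_i, the per-sample burden is C_j = Σ_i w_i x_ji and the fitted
model is the ordinary linear regression y = β₀ + β₁ C + ε. Inference is by
the standardized score statistic of β₁,

    z = Σ_j C_j (y_j − ȳ) / ( sd(y) · √Σ_j (C_j − C̄)² ),

where sd(y) is the divide-by-n standard deviation. Two properties drive the
implementation:

1. z is scale-invariant in the weights, so any positive rescaling of w leaves
   every p-value unchanged (in particular the sample-size factor in the
   weighted-sum weights cancels);
2. ȳ and sd(y) are invariant under permutation of y, so each permuted
   statistic is a single dot product of the permuted phenotype with the
   centered burden columns. The whole permutation loop is a chunked
   matrix–matrix product, which is what makes re-optimizing the variable
   threshold inside every permutation affordable at 10³–10⁵ permutations.

Whether the divide-by-n or divide-by-(n−1) convention enters sd(y) is
irrelevant to inference: the factor is permutation-invariant and cancels in
the rank comparison. We use divide-by-n.

Binary phenotypes are analyzed through the identical linear score path — no
logistic model anywhere — and covariate-adjusted binary traits are their
linear residuals. This keeps all traits on one code path and mirrors standard
practice for permutation-based burden testing, where only the ordering of
statistics matters.

### The four tests

- **Fixed threshold (T1, T5, fixed(T))**: w_i = 1 iff maf_i < T, strictly.
  A gene with no qualifying variant is *not testable* at that threshold and
  is excluded from the test's gene universe rather than given a p-value.
- **Weighted sum (WS)**: w_i = 1/√(n p_i (1 − p_i)) with p_i the full-sample
  minor-allele frequency. Monomorphic variants (p_i = 0) are dropped before
  weighting — they carry no information and would make the weight infinite.
- **Variable threshold (VT)**: candidate thresholds are the distinct observed
  MAFs of the gene's polymorphic variants; variant i enters the burden at
  threshold t iff maf_i ≤ t (inclusive, so every variant enters at its own
  MAF; note the deliberate asymmetry with the strict `<` of the fixed tests,
  whose cutoffs are external round numbers rather than observed values). The
  statistic is z_max = max_t z(t); ties take the smallest threshold, which
  prefers the rarer-variant explanation and is deterministic. Under
  permutation the maximization is re-run on each permuted phenotype, so the
  permuted optimum may sit at a different threshold — omitting this step
  would anti-conservatively anchor the null distribution at the observed
  optimum.

### Permutation p-values

p = (1 + #{z_k ≥ z_obs}) / (1 + P), the add-one estimator, which never
returns 0 and has lower bound 1/(P+1). Default sidedness is one-sided-greater
(higher burden, higher phenotype), matching the one-directional max-z
construction; a two-sided |z| option exists for protective effects. Monte
Carlo permutation (default P = 100,000; desk-scale runs use 999) shuffles the
phenotype with a per-gene generator seeded from SHA-256 of
`(master seed, replicate, gene name)`, so results are independent of gene
processing order, reruns are bit-identical, and all tests of one gene share
one permutation stream (paired comparisons between tests are therefore less
noisy). Exhaustive mode enumerates all n! orderings and is capped at n = 8.

Tie counting uses a 1e-12 relative guard: permutations that merely re-pair
identical values are exact ties mathematically but can differ from the
observed statistic in the last floating-point ulp; without the guard, exact
agreement with enumeration oracles (and between chunk sizes) would be
unstable.

Degenerate inputs: a constant burden column gives z = 0 (neutral, not an
error); a constant phenotype is an error; a gene whose polymorphic variants
all miss a fixed threshold is flagged not-testable.

## Covariate adjustment

Adjustment is two-stage: regress each trait on an intercept plus the chosen
covariates (OLS), keep the residuals as the adjusted phenotype, then test as
usual. It is an orthogonal projection — idempotent, residuals orthogonal to
the covariates — and is refit within each phenotype replicate, since each
replicate is an independent realization. With an empty covariate list the
trait is still mean-centered; centering changes no permutation p-value but
keeps adjusted and unadjusted analyses on one code path. Rank-deficient
designs are rejected with the collinear columns named. Freedman–Lane-style
adjustment inside the permutation scheme is deliberately out of scope: the
procedure modeled here is plain residualize-then-test.

Why this works against stratification: if the trait depends on subpopulation
only through Age (linearly), residualizing on Age removes the entire pathway
from genotype to trait, and the permutation test is calibrated again.

## The synthetic-data generator

The generator emulates the *structure* of an exome-panel benchmark of
unrelated individuals (default 697 samples, 200 phenotype replicates over one
fixed genotype draw): genes are disjoint coordinate blocks; each gene carries
6–14 SNPs; MAFs follow a two-component law (beta(0.8, 15)·0.05 rare bulk plus
a 10% uniform-on-[0.05, 0.5] common admixture, so ~90% of variants are rare);
genotypes are binomial(2, maf) under Hardy–Weinberg.

Trait architectures (defaults chosen once, as what a simulation study in this
field would call moderate effects — power in the 30–80% band at α = 0.05,
where test differences are visible):

- **Q1-like** — 4 rare causal variants per causal gene, MAF ∈ (0.001, 0.035),
  +0.25 trait units per copy, plus Age (0.05/yr) and Smoking (0.5) effects,
  noise sd 1. Every causal variant sits below the 5% threshold.
- **Q2-like** — per causal gene one rare causal variant (MAF 0.4–1%, effect
  0.5) and one common causal variant (MAF fixed at 0.17, effect 0.2), no
  covariate influence at all, noise sd 1. The common variant carries most of
  the association information but is invisible to the 1%/5% cutoffs.
- **Q4-like** — Age and Smoking effects plus noise, zero genotype effect: the
  null trait for type-I-error estimation.
- **Binary** — liability = 0.6·(genetic trait) + 0.6·(Q4-like trait) + noise,
  thresholded at the empirical 70% quantile (≈30% prevalence, a config knob;
  the liability construction is this package's interpretation of a
  noise-contaminated disease model and is labeled as such).

Covariates and noise are redrawn per replicate; genotypes are fixed.

`make_confounded_null` builds the stratified null: two subpopulations (fixed
membership), per-variant allele frequencies diverged around the base draw by
a Balding–Nichols model (F = 0.05), Age means 20 years apart, and a trait
equal to 0.05·Age + noise with no genotype term. Genotype and trait are then
marginally dependent through subpopulation, so unadjusted tests reject far
above nominal — the common-variant-heavy WS and VT tests most, T1 least —
while Age-residualized tests are calibrated. Setting F = 0 and a zero Age
shift degenerates to an ordinary null.

What the generator does **not** emulate: linkage disequilibrium (variants are
independent given their MAFs), mutation/demography, related individuals,
genotyping error, and any real gene map. Consequences: calibration and
power-ordering results here demonstrate the *mechanisms* (threshold choice
vs. architecture; confounding via a covariate) and are expected to transfer
qualitatively, but absolute power numbers and the behavior of tests under
strong LD are not validated by this suite.

## Evaluation

Each test has a gene universe: fixed-threshold tests cover genes with ≥ 1
polymorphic variant strictly under their cutoff; WS and VT cover genes with
≥ 1 polymorphic variant. Universes satisfy T1 ⊆ T5 ⊆ WS = VT. Type I error,
TPP and FPP are rejection proportions of I(p ≤ α) over (gene, replicate)
units — over all testable genes of a null dataset, over causal genes S_g, and
over the complement, respectively. A causal gene outside a test's universe is
excluded from the TPP denominator and the exclusion counted, keeping the
proportion well-defined. Not-testable entries are excluded from numerator and
denominator everywhere.

ROC curves sweep α over a 200-point logarithmic grid on [10⁻⁵, 1] (the curve
is thresholded on the p-value, which is how TPP/FPP are defined — not on raw
statistics), extend the polyline to (0,0) and (1,1), and integrate by the
trapezoid rule for AUC. TPP at a matched FPP is linear interpolation along
the polyline. `bonferroni_threshold(n, fwer) = fwer/n` supplies the
genome-wide significance line.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so each property has comfortable statistical resolution: null
calibration on 100 genes × 20 replicates (2,000 units, n = 200, 999
permutations, 3-binomial-SE bands); the confounding demonstration on 125
genes × 20 replicates at n = 697; the power orderings on the presets' 50
causal + 200 null genes × 20 replicates at n = 697, compared by TPP at
FPP = 0.05 with paired seeds and shared permutation streams. Exhaustive-mode
agreement with a brute-force enumerator is exact at n = 6 (720 permutations).

## Known limitations

- No variance-component (SKAT-style) tests, no asymptotic or exact
  small-sample p-values — permutation only.
- MAFs are always estimated from the full loaded sample, cases and controls
  pooled; there is no reference-panel option.
- Missing genotypes must be resolved at load (reject by default, or
  impute-as-zero, the conservative burden choice; the policy is logged).
  Multi-allelic sites are rejected.
- Gene regions are 1-based inclusive intervals; a variant in two overlapping
  regions is tested in both.
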