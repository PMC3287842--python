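# rarepool

Gene-based pooled association testing for rare variants, plus the machinery
to evaluate when each test wins.

Single rare variants carry too little information to test individually, so
gene-level ("burden") tests collapse the minor-allele counts x_i of a gene's
variants into one per-sample score C_j = Σᵢ wᵢ x_ji and regress the phenotype
on it. The choice of weights wᵢ — really, the choice of which variants count
as "rare" — is the whole game, and `rarepool` implements the three classic
answers side by side:

- **T1 / T5 (fixed threshold)** — wᵢ = 1 if MAFᵢ < 1% (or 5%), else 0.
- **WS (weighted sum)** — wᵢ = 1/√(n pᵢ(1−pᵢ)), the inverse square root of the
  expected genotype variance, so rarer variants weigh more.
- **VT (variable threshold)** — compute the score statistic

  z(T) = Σⱼ Cⱼ(T)(yⱼ − ȳ) / ( sd(y) · √Σⱼ(Cⱼ(T) − C̄(T))² )

  at every candidate threshold T (the distinct observed MAFs) and take
  z_max = max_T z(T). Significance comes from phenotype permutation in which
  the threshold is re-optimized inside **every** permutation, which is what
  keeps the maximization honest.

All four tests use the same linear score path for every phenotype — including
binary traits — and all p-values are add-one permutation estimates
p = (1 + #{z_k ≥ z_obs}) / (1 + P).

Around the tests sit:

- two-stage covariate adjustment (`adjust_table`): OLS residuals of each trait
  on Age/Smoking become the adjusted phenotypes, which removes the type-I-error
  inflation that confounders such as population stratification otherwise
  induce;
- an exome-like simulator (`simulate_dataset`, `make_confounded_null`) with a
  known causal answer key: one fixed cohort of unrelated samples, many
  phenotype replicates, a rare-skewed MAF spectrum, and named trait
  architectures (Q1-like, Q2-like, Q4-like null, a liability-threshold binary
  trait);
- evaluation (`run_evaluation`): per-test gene universes
  (T1 ⊆ T5 ⊆ WS = VT), type I error, true-/false-positive proportions over an
  α sweep, ROC curves, trapezoid AUC, Bonferroni thresholds.

The headline finding this package lets you reproduce on your desk: **there is
no uniformly most powerful pooled test.** When every causal variant is rare
(MAF < 5%), T5 beats VT; when a gene mixes a rare and a common (~17% MAF)
causal variant, VT wins decisively — and Age adjustment removes
stratification-induced false positives entirely.

## Worked example

```python
import rarepool as rp

# one rare + one common causal variant per causal gene (5 causal, 20 null)
cfg = rp.q2like_config(n_causal_genes=5, n_null_genes=20, n_replicates=2, seed=1)
ds = rp.simulate_dataset(cfg)
reps = rp.run_association(ds.genotypes, ds.variants, ds.gene_index,
                          ds.phenotype_frame(), "Q2",
                          plan=rp.PermutationPlan(n_perm=999, seed=1))
res = rp.run_evaluation(rp.results_to_frames(reps), ds.truth,
                        ds.variants, ds.gene_index)
print(res.summary.to_string(index=False))
```

prints

```
test     auc  universe_size  causal_in_universe
  T1 0.52750             25                   5
  T5 0.56875             25                   5
  WS 0.73500             25                   5
  VT 0.93625             25                   5
```

Each row is one test over the 25-gene universe: `auc` is the area under the
ROC curve built by sweeping the significance level and plotting the rejection
rate over the 5 causal genes (TPP) against the rejection rate over the 20
null genes (FPP). Even at this toy scale the variable-threshold test is far
ahead, because only it can reach up to the 17%-MAF causal variant that the
1%/5% cutoffs discard.

The same analysis runs from the shell:

```bash
rarepool full --preset q2like --out-dir runs/q2 --seed 1 --n-replicates 2
```

which writes the dataset, per-replicate result tables, the evaluation report
and a manifest recording the seed and options.

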