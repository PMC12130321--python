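# pgsnn

How much nonlinearity — gene–gene (G×G) and gene–environment (G×E)
interaction — can a neural network actually exploit when predicting a
polygenic trait, and how much of an apparent nonlinear advantage is just
linkage disequilibrium (LD) in disguise?

`pgsnn` is a simulation and evaluation pipeline for that question,
aimed at statistical geneticists working on polygenic scores (PGS). It
provides:

- **Genotype simulation** — hard-call diploid dosage panels
  ({0, 1, 2}) under Hardy–Weinberg equilibrium with controllable block
  LD, via a latent-Gaussian copula.
- **Phenotype simulation** — continuous traits composed as

  ```
  Y = G + E + G'×E' + G'×G' + E'×E' + ε
  ```

  with additive effects on standardized causal dosages, 4-way
  multiplicative epistasis, environmental main effects and
  interactions, variance-calibrated so that var(G)/var(Y) hits a target
  heritability (h² = 0.5 by default); plus additive:epistatic blends
  (2:1, 1:2), liability-threshold binarization and 6:2:2
  train/validation/test splits.
- **The joint-tagging confound** — causal SNPs tagged by ≥ 2 other
  panel SNPs at r² > 0.25 are randomly removed (up to 50%) from the
  observed panel, so that their signal is only *jointly* inferable from
  variants in LD with them. This manufactures statistical epistasis
  with a purely additive generative model.
- **Additive baselines** — vectorized per-SNP GWAS, greedy LD clumping
  (r² > 0.5 within 500 kb) and distance filtering (≥ 500 kb apart), an
  LD-aware shrinkage PGS built by windowed ridge regression on summary
  statistics, PGS-Catalog scoring-file I/O, PLINK-style scoring, and a
  PGS + covariates regression baseline with p < 0.05 covariate
  retention.
- **Matched linear/nonlinear networks** — three-hidden-layer
  perceptrons (large: 100-50-25, small: 24-12-6; batch 32, dropout 0.3,
  lr 0.001, batch norm, softplus, plain SGD, early stopping with
  12-epoch patience, 50:50 case oversampling for binary traits),
  trained from scratch **with and without activation functions**. An
  activation-free stack collapses algebraically to a single linear map,

  ```
  Y = (((X W₁) W₂) … W_k) = X (W₁ W₂ … W_k) = X W_all ,
  ```

  so the performance difference between the two variants estimates the
  nonlinearity the activated network exploited. `collapse_to_linear`
  performs the reduction explicitly (folding batch-norm into its
  inference-time affine form) and is verified against the network's own
  forward pass.
- **Evaluation** — test-set r² between observed and predicted
  phenotype, expressed relative to the additive PGS baseline:
  `gap% = 100 · (r²_nonlinear − r²_linear) / r²_baseline`, with a
  two-sided paired t-test across replicates, and the result-QC filter
  (drop results 500% from the mean or with any model at p ≥ 0.05).

The mitigation of interest is **SNP-dosage weighting**: multiplying the
network's dosage inputs by LD-aware per-SNP PGS weights, which hands
both network variants the additive LD solution so that any remaining
nonlinear-vs-linear gap reflects genuine epistasis rather than joint
tagging.

## Worked example

```python
from pgsnn import run_scenario, test_scale_config

# pure 4-way epistatic trait, no mitigation, 10 replicates
cfg = test_scale_config(scenario="epistatic", mitigation="none", base_seed=1)
result = run_scenario(cfg)
s = result.summarize()
print(f"mean gap {s.mean_gap:.1f}% of baseline r^2, paired-t p={s.p_value:.2g}")
print(f"mean r^2: nonlinear {sum(result.r2_nonlinear)/10:.3f}, "
      f"linear {sum(result.r2_linear)/10:.3f}, baseline {sum(result.r2_baseline)/10:.3f}")
```

prints (≈ 90 s on one CPU):

```
mean gap 95.7% of baseline r^2, paired-t p=3.9e-06
mean r^2: nonlinear 0.224, linear 0.116, baseline 0.119
```

Read: on a trait whose genetic variance comes entirely from 4-way
interactions, the additive PGS baseline and the linear network capture
only the additive projection of the epistatic variance (r² ≈ 0.12 of a
possible 0.5), while the activated network finds roughly twice that —
a large, significant gap. Running the same preset with
`scenario="additive", joint_tagging=True` instead gives a gap near zero,
and applying `mitigation="snp_dosage_weighting"` shrinks the LD-driven
component of the gap further — the signature that separates genuine
epistasis from joint tagging.

The same machinery runs on user data (PLINK-style `.raw` dosages, a
phenotype/covariate TSV, and a PGS-Catalog scoring file) through
`run_real_data` or the CLI:

```bash
pgsnn simulate      --config cfg.yaml --seed 1 --out sim/
pgsnn run-scenario  --config cfg.yaml --seed 1 --out out/
pgsnn run-real      --genotypes g.raw --snp-metadata snps.tsv \
                    --phenotypes pheno.tsv --scoring-file pgs.txt \
                    --covariates cov.tsv --out real/
pgsnn report        --results out/
```

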