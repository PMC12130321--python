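# Methods

## The question and the estimator

Statistical epistasis and linkage disequilibrium (LD) are both defined
by the co-occurrence of alleles, and they can masquerade as one
another. In particular, when two genotyped SNPs each imperfectly tag an
*ungenotyped* causal variant, their joint haplotype can tag it better
than either does alone; a flexible model then shows an apparent
interaction between the two tags — a *joint tagging effect* — even
though the generative model is purely additive. Any claim that a neural
network "found epistasis" because it beat an additive model must
discount this artefact.

The estimator of exploitable nonlinearity used throughout is the
matched-network gap. Two multilayer perceptrons of identical
architecture and training protocol are trained from scratch on the same
input; one applies a softplus activation between layers, the other
applies none. Without activations the stack is algebraically a single
affine map (`collapse_to_linear` computes it explicitly and the test
suite verifies predictions equal `X @ W_all + c` to 1e-5), so the
activated network's advantage on held-out data,

    gap% = 100 · (r²_nonlinear − r²_linear) / r²_baseline ,

measures nonlinearity the activated model exploited, in units of the
additive PGS baseline's performance. Replicated simulations give a
paired t-test on per-replicate gaps.

Two mitigations address the joint-tagging confound:

- **SNP-dosage weighting** — network inputs are per-SNP weights times
  dosages, where the weights come from an LD-aware additive PGS. Both
  network variants then receive the additive LD solution in their
  input, so joint-tagging information no longer differentiates them;
  a surviving gap indicates genuine epistasis.
- **LD clumping + distance filtering** — keep one variant per clump
  (r² > 0.5, 500 kb window), then enforce ≥ 500 kb between kept
  variants (retaining the lower p-value on conflicts). This removes the
  possibility of joint tagging by construction, at the cost of most of
  the signal; it is a point of reference, not a usable PGS method.

## Simulators

**Genotypes.** Diploid hard calls in {0,1,2}. Per LD block, two haploid
latent vectors per sample are drawn from an equicorrelated Gaussian
(one-factor construction, correlation ρ within the block, blocks
independent) and thresholded at Φ⁻¹(MAF); the two indicators sum to the
dosage. Marginally every SNP is in Hardy–Weinberg equilibrium at its
MAF; ρ controls tagging strength. The ρ→dosage-r² map has no convenient
closed form, so tests compare against a Monte-Carlo oracle of the same
copula at 10× the sample size. Chromosome labels and base-pair
positions are synthetic (fixed spacing, a new chromosome every k
blocks) so distance-based operations are exercisable. Monomorphic
columns (possible at small n) trigger a bounded per-block redraw with
resampled MAFs, then a hard error.

**Joint-tagging reduction.** A causal SNP is *eligible* when ≥ 2 other
panel SNPs tag it at r² > 0.25 (tags need not be causal). Each eligible
SNP is removed independently with probability 0.5 ("up to 50%"), with a
seeded truncation to the hard cap ⌊0.5 × eligible⌋ so the report
invariant (removed ≤ half of eligible) always holds. Removal affects
only the observed panel; the phenotype keeps the removed SNPs'
contributions — that asymmetry is what creates the confound.

**Phenotypes.** Additive effects are i.i.d. standard-normal weights on
*standardized* causal dosages (so rarer alleles carry larger per-allele
effects; the effect-frequency coupling is a modelling choice, stated
here because nothing in the data constrains it). Epistasis is the
centered product of the four **raw** {0,1,2} dosages in each disjoint
4-tuple, with standard-normal group weights. The raw-dosage product is
deliberate: expanding ∏(μⱼ+σⱼzⱼ) shows such a trait carries a large
additive projection (roughly half its variance at common allele
frequencies), so a GWAS sees it and an additive PGS gains traction —
the trait *appears* to have ordinary narrow-sense heritability even
though its generative model is purely epistatic. This matches the
observation that epistatic variance is substantially captured by
additive models, and it keeps baseline-relative units well-defined. The
fully standardized product (zero additive projection under HWE and
linkage equilibrium) remains available as
`epistasis_form="standardized_product"`; with it the additive baseline
r² is ≈ 0 on pure-epistasis traits and baseline-relative metrics
degenerate.

After composing the genetic terms, the genetic component is rescaled so
its empirical variance equals `target_h2` (default 0.5) on a unit total
variance scale; environmental terms keep the variance their weights
imply; i.i.d. Gaussian noise fills the remainder. With `target_h2 = 1`
the trait equals its genetic component exactly. Components are stored
separately and always sum to the phenotype (tested to 1e-10). Mixed
architectures standardize two phenotypes to unit variance and average
them with parts (2:1 or 1:2); blends are not re-calibrated after
mixing, so their realized genetic fraction is the ratio-weighted
combination.

**Binary traits** threshold the continuous trait at the empirical
(1 − prevalence) quantile. **Splits** are a seeded 6:2:2 shuffle.
**Outlier filtering** masks values > 4 SD from the mean, both moments
computed once before any removal.

## Additive baselines

GWAS is per-SNP simple linear regression (closed-form, vectorized;
intercept included, no covariates — the simulated panels have no
population structure). The LD-aware PGS solves, within contiguous
genomic windows (default 250 kb), the summary-statistic ridge system
(R + λI)·w = r, with R the training-sample dosage correlation matrix
and r the marginal correlations; λ is picked from a small grid by
validation-set score r². This windowed ridge is the package's own
additive shrinkage baseline — simple, deterministic, and tuned on the
same validation split the networks use; its provenance string is
stamped into every weight set it produces. Scoring is Σ w·dosage (sum
mode; with complete hard calls this differs from allele-averaging by a
constant factor, which cancels in r²). Effect-allele mismatches flip
the contribution to w·(2 − dosage). The covariate baseline fits
y ~ PGS + all expanded covariates, then refits keeping PGS plus
covariate columns with full-model p < 0.05; the retained list is
forwarded to the matching network input. In the regression (unlike the
network input) factor dummies drop a reference level to keep the design
identifiable.

## Networks and training

Three fully-connected hidden layers; large (100, 50, 25) and small
(24, 12, 6) variants, the final model chosen by validation r² (exact
tie → small). Protocol: batch size 32, dropout 0.3, learning rate
0.001, batch normalisation, softplus, plain SGD, mean-squared-error
loss (cross-entropy for binary traits), early stopping when validation
r² has not improved for 12 epochs with best-epoch weight restore, and a
single from-scratch retrain at half the learning rate when the best
epoch was the first. Binary traits may oversample so each batch slot is
a fair coin between the case and control pools (with replacement),
giving a 50:50 expected presentation; the realized per-epoch case
fraction is logged. The linear variant keeps dropout and batch norm —
batch norm is affine at inference and dropout is inactive, so linearity
is preserved while regularisation stays matched; only the activations
differ between variants, and both are always trained from scratch.

The implementation is numpy with hand-written backpropagation
(finite-difference-checked in the test suite), plus a numba-compiled
epoch kernel for the three-hidden-layer case. All randomness — batch
order, oversampling draws, dropout masks — is drawn from a single
seeded numpy Generator and passed into the kernel, so the compiled and
pure-numpy paths consume the identical random stream and training is
bit-reproducible on one machine.

Validation and selection use r² between predictions and observations
for both continuous and binary traits (for binary, predicted
probability vs label), keeping one criterion across trait types. The
nominal significance of a model's predictions is a Pearson correlation
test on the test split; the regression baseline also carries its own
F/likelihood-ratio p-value.

## Study scales

Three presets, identical in structure and differing only in size:

| preset | n | SNPs | causal | replicates | networks |
|---|---|---|---|---|---|
| `full_scale_config` | 125,000 | 500,000 | 2,000 (500 groups) | 20 | large + small |
| `desk_scale_config` | 8,000 | 2,000 | 200 (50 groups) | 10 | large + small |
| `test_scale_config` | 6,000 | 96 | 16 (4 groups) | 10 | small |

The full-scale preset states the reference design; it is expressible in
config but not intended for a single workstation. The desk preset is
the default for interactive use. The test preset is what the automated
end-to-end checks run: 4 four-way groups in a 96-SNP panel (blocks of
4, latent ρ = 0.85, MAF 0.2–0.5) keep each interaction group's variance
share large enough (~12.5% of the trait) for a small network to find.

One scaling rule matters: the optimizer protocol is fixed per *update*,
not per epoch. At full scale an epoch is ~2,300 gradient updates; at
test scale it is ~113. The test preset therefore uses learning rate
0.008 with patience 60 epochs (max 400), keeping the optimization and
early-stopping budgets comparable in updates while `NnConfig` defaults
remain the printed protocol (0.001 / 12). Without this rescaling the
activated network is stopped on its pre-interaction plateau and the
epistasis signal is never found — an instance of the general point that
network results are strongly sample- and budget-dependent.

## What the scaled-down runs do and do not show

They reproduce the qualitative structure of the full design: a large
positive nonlinear-vs-linear gap on pure-epistasis traits; a gap near
zero on additive traits with joint-tagging confounds, shrunk further
toward zero by SNP-dosage weighting; and a monotone increase of the gap
across additive → 2:1 → 1:2 → pure-epistatic architectures under
weighting. Magnitudes are not comparable to biobank-scale results: with
a 96-SNP panel and 16 causal variants, baseline r² on pure-epistasis
traits is ~0.12 rather than a realistic small value, and gaps reach
tens of percent of baseline rather than ~10%. Two effects visible at
full scale do not manifest at n = 6,000: the nonlinear network cannot
convert joint tagging into a prediction *gain* (its gap on the
additive+joint-tagging scenario is slightly negative — small networks
at this sample size pay a variance cost that outweighs the tiny
joint-tagging bonus), so the mitigation check is stated on the gap's
magnitude rather than its signed value; and LD-exploitation advantages
of nonlinear networks on fully additive traits are likewise absent.
Synthetic panels also lack realistic human LD (no hotspots, no
long-range structure, exchangeable block positions), dosage
uncertainty, ancestry structure, or relatedness; conclusions about real
cohorts require the real-data path.

## Numerical and design choices

- Equal GWAS p-values are broken by (position, snp_id) in clumping and
  distance filtering, making both deterministic across platforms; both
  are fuzz-tested against brute-force enumeration oracles.
- Ridge windows that remain singular despite λ escalate λ tenfold up to
  six times, then fail loudly.
- One-hot covariate encoding keeps all levels (networks are
  regularized; the regression baseline drops a reference level
  instead). Missing numerics impute to the training mean; missing
  factor values become an explicit level.
- The halved-learning-rate retrain does not recurse: one retrain only.
- `r_squared` reports 0 (with a warning) for constant predictions;
  a constant *observed* vector is an error.
- The "500% from the mean" outlier rule is |x − mean| > 5·|mean| on the
  relative-metric scale, mean computed once before removal; both the
  percentage and the α = 0.05 significance screen are configurable.
- Replicate seeds derive affinely from the base seed and stay below
  2³¹; every output directory carries the config hash and per-replicate
  seeds, and any replicate can be re-run in isolation.

## Known limitations

- The windowed-ridge PGS is intentionally simpler than full Bayesian
  shrinkage; absolute baseline performance on real data will differ
  from catalogue-grade scores.
- Binary-trait discrimination uses r² on probabilities rather than AUC
  or liability-scale measures; adequate for matched comparisons, not
  for absolute calibration claims.
- The epistatic functional form is one choice among many (multiplicative,
  raw-dosage); thresholding or pathway-style epistasis would project
  differently onto additive models.
- Only hard-call dosages are simulated; imputation uncertainty is out
  of scope.
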