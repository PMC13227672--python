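# Methods

`omicsblup` implements phenotype prediction for pigs (or any cohort
with a company/batch/pen/litter structure) from genomic and blood
multi-omics similarity, via multi-kernel linear mixed models. This
note records the models, the numerical choices, and what the synthetic
cohort generator does and does not emulate.

## The model

For a trait `y` measured on `n` animals,

    y = 1*mu + X b + Z_pen p + Z_litter l + sum_k u_k + e

with fixed effects `b` (entry age, and batch where identifiable),
random pen-within-batch effects `p ~ N(0, I s2_p)`, random litter
effects `l ~ N(0, I s2_l)`, residual `e ~ N(0, I s2_e)`, and one random
animal effect per relationship kernel, `u_k ~ N(0, K_k s2_k)`. Effects
of different kernels are assumed uncorrelated. Binary traits
(mortality) are fitted with the same linear model on 0/1 records.

Kernels:

* **G** (genomic): VanRaden method 1 computed separately within each
  source company using within-company allele frequencies, assembled
  block-diagonally with cross-company entries exactly zero. The
  block-diagonal form restricts genomic relationships to
  within-company comparisons and yields pooled within-company variance
  components. SNPs monomorphic within a company drop out of that
  block's denominator.
* **T / P / M** (transcriptome / proteome / metabolome):
  `K = M M' / p`, where `M` is the animals x features matrix of
  residual feature values standardized per feature to mean 0,
  variance 1 (population variance, ddof=0 — this makes the mean
  diagonal of `K` exactly 1).
* **Combined**: the unweighted elementwise mean of selected kernels,
  fitted as a single random effect; a parsimonious alternative that
  halves the number of components to estimate for large subsets.

The variance share attributed to the omics kernels is

    h2_omics_total = sum_k s2_k / (s2_p + s2_l + sum_k s2_k + s2_e)

with per-kernel shares defined analogously. With four layers, the
model grid is the 15 nonempty kernel subsets plus 11 combined-mean
variants of the subsets of size >= 2: 26 specifications.

## REML solver

Variance components are estimated by average-information (AI) REML on
the covariance structures `V = sum_i s2_i V_i + s2_e I`, where `V_i` is
a kernel or `Z Z'` for a grouped (pen, litter) effect. Details:

* initialization: equal split of the ordinary-least-squares residual
  variance across all components;
* each iteration proposes an AI step; proposals that leave the
  feasible region or decrease the restricted likelihood are halved (up
  to 20 times) and, failing that, replaced by an EM-style fixed-point
  step `s2_i <- s2_i * (y'P V_i P y) / tr(P V_i)`. The accepted
  restricted-log-likelihood trace is therefore non-decreasing;
* non-negativity by an active set: a component pushed to the boundary
  with a non-positive score is pinned at zero and released if its
  score turns positive. Proposals that would jump past zero decay
  geometrically instead (factor 10 per step). The residual component
  keeps a small positive floor;
* convergence: |change in restricted log-likelihood| < 1e-6 AND max
  relative component change < 1e-4, within 200 iterations. If no
  improving step exists within line-search resolution the iterate is
  accepted as a maximum within tolerance. If the iteration budget runs
  out the fit is returned with `converged=False` rather than raising —
  downstream code treats such fits as the protocol's "NA" cells;
* BLUPs: `u_hat_k = s2_k V_k P y`; fixed effects by GLS at the final
  components. Aliased fixed-effect columns (e.g. batch confounded
  with company) are dropped trailing-first before fitting.

These tolerances are package decisions; the reference software the
field uses for such models does not publish its internal settings.

Two independent oracles pin the solver down in the test suite: a 1-D
profiled restricted-likelihood grid search for single-kernel models,
and the GBLUP/SNP-BLUP identity (kernel BLUPs must equal ridge SNP
effects mapped through centered dosages, to 1e-6). Both comparisons
need an interior optimum: a full-rank kernel at small `n` can
legitimately drive the residual to the boundary, where different
solvers stop at indistinguishable likelihoods but different parameter
splits.

## Preprocessing

**Transcriptome.** Counts are TMM-normalized (log-ratio trim 0.30,
absolute-intensity trim 0.05, precision-weighted — the canonical
published defaults), converted to counts per million on effective
library sizes, and transformed as `log2(CPM + 1)`. The reference
sample is the animal whose library size is closest to the 75th
percentile of library sizes. During development the factors were
checked against the standard Bioconductor implementation (agreement to
1e-15 with a shared reference); the shipped tests use a pure-Python
re-derivation so the suite is hermetic.

**Metabolome.** Metabolites with >= 20% generic missing values or
below-limit-of-detection status in > 20% of samples are excluded (note
the two different comparators); remaining missing cells are imputed
with the metabolite-specific median of observed values, then values
are log2-transformed.

**Proteome.** Abundances are log2-transformed, then missing-at-random
cells are imputed feature-wise by K-nearest neighbors: the k=10
features nearest by RMS difference of z-scored values over co-observed
animals, with each neighbor aligned to the target's observed mean/SD
before unweighted averaging. Distances are computed on z-scores
because raw abundances differ by orders of magnitude across proteins;
the unweighted mean (rather than distance weighting) was chosen for
simplicity and is stated here as a package decision, as is k=10.
Imputation quality is validated by masking: per repeat, 100 randomly
chosen proteins have half of their observed cells set to missing, the
matrix is re-imputed, and the Pearson correlation between original and
imputed values at the masked cells is recorded; features with mean
correlation > 0.4 over repeats are retained. Half of the cells are
masked (rather than all of a protein's values) so the neighbor search
uses only the retained cells and is evaluated strictly out of sample —
masking an entire column would either make feature-wise neighbor
search impossible or force it to peek at the values being predicted,
which inflates the apparent accuracy of uninformative features.

**Residualization (all layers).** Each feature is adjusted by a
mixed model with layer-specific fixed effects (transcriptome: batch,
enrichment-toy status, entry age, RNA integrity number; proteome and
metabolome: batch, entry age) and a random pen-within-batch effect.
The pen-to-residual variance ratio is profiled out by REML on a
bounded grid (`{0} + logspace(-3, 6, 91)`), evaluated for all features
simultaneously through a shared spectral decomposition of `Z Z'`;
conditional residuals (pen BLUP subtracted) are centered and scaled to
unit population variance. Features whose residual variance collapses
(exact linear functions of the design) are flagged and dropped.
Conditional rather than marginal residuals are a package decision.

**Genotype QC.** SNP call rate > 0.90, individual call rate > 0.90,
minor allele frequency > 0.05, applied in that order in one pass; all
thresholds strict. Both call rates are computed on the input matrix
(an animal's rate over all input SNPs), MAF on the call-rate-filtered
matrix; surviving missing calls are mean-imputed per SNP (twice the
allele frequency), which is standard practice ahead of relationship-
matrix construction.

## Leave-one-batch-out validation

Within each company contributing at least three batches, each batch is
held out once; the remaining batches of the same company train the
model. Accuracy therefore measures the ability to predict a *new
batch of the same company*. Protocol details:

* phenotypes are pre-adjusted with a kernel-free baseline model (same
  fixed effects, random pen and litter); the corrected phenotype is
  the conditional residual, which is exactly orthogonal to the fixed
  design;
* adjustment is estimated per training fold, and validation animals
  are corrected with the training-fold fixed-effect estimates
  (pen/litter levels of a held-out batch are unseen, so their BLUPs
  are zero). A `global` mode that adjusts once on all data is
  available behind a flag; per-fold is the default because it cannot
  leak validation information;
* batch is excluded from fold-level fixed effects — the validation
  batch is unseen in training by construction, so its adjustment falls
  to the intercept (Pearson correlations are invariant to the
  resulting constant offset);
* validation scores are the sum of predicted random animal effects,
  `u_val = K[val,train] (K[train,train] + 1e-8 I)^-1 u_train` per
  fitted kernel — identical (to the ridge) to solving the mixed-model
  equations with validation records absent;
* per-fold accuracy is the Pearson correlation between scores and
  adjusted phenotypes; the trait/model accuracy is the
  sample-size-weighted mean over folds. Folds whose REML fit does not
  converge, or whose scores have zero variance, are excluded and
  logged;
* for binary traits a pooled AUC is computed on the concatenated
  out-of-sample scores (each animal contributes exactly once), with
  ties counted one half; batch-level AUCs are often undefined because
  a batch can contain only controls.

## Synthetic cohort generator

No public data accompany the study design this package targets, so the
generator is a first-class module. Its default layout
(`table1_config`) mirrors the enrolment structure of a natural-
disease-challenge cohort: 836 animals in 15 batches from 6 companies
(2, 4, 1, 3, 3 and 2 batches; batch sizes 34-71), five pens and ten
litters per batch, so exactly three companies are eligible for
leave-one-batch-out validation. Per-trait genomic and litter variance
shares follow the cohort's published genomic-model estimates for the
21 traits; pen share is 0.03; omics shares are set larger for
quarantine-nursery traits (T 0.08, P 0.03, M 0.08) than for later
traits (T 0.03, P 0.01, M 0.02), mirroring the stage-specific signal
blood profiles are expected to carry. Mortality traits are generated
by thresholding the latent liability at the normal quantile of their
observed prevalence.

Generative mechanics:

* genotypes: unlinked SNPs, per-SNP base frequency uniform on the
  configured range, per-company frequency jitter (SD 0.03) so the
  block-diagonal G construction is non-trivially exercised; dosages
  binomial(2, p). Defaults: 5,000 SNPs (enough for stable kernels;
  array-scale marker counts add nothing at these sample sizes);
* omics features: each feature's core signal is a genetically
  anchored SNP score (share `genetic_anchor` of its variance; 10 SNPs
  per feature) plus non-genetic variation with co-expression-module
  structure — features belong to one of ~p/25 modules sharing a
  latent factor that carries 60% of the non-genetic variance. The
  module structure emulates co-regulation and is what gives
  nearest-neighbor imputation something to recover; batch (SD 0.5)
  and pen (SD 0.3) shifts are added on top and are what the
  residualization step removes;
* raw scales: transcript counts are negative-binomial (dispersion 10)
  around exponentiated Gaussian means; protein abundances and
  metabolite concentrations are 2^(base + signal) with
  missing-at-random and lowest-value (limit-of-detection) masking
  respectively;
* phenotypes: kernel effects are drawn as `u_k ~ N(0, K_k s2_k)` using
  kernels built from the shift-free core signals (and the
  block-diagonal G); pen, litter and residual effects are normal.
  Continuous traits add modest management effects — batch means
  contribute ~4% and entry age ~1% of the configured phenotypic
  variance — so a trait's sample variance stays close to its component
  total; binary liabilities carry no fixed-effect shifts, so
  prevalence follows the normal-threshold expectation exactly;
* one master seed drives independent substreams for design, genotypes,
  layers, phenotypes and missingness, so every cohort is bitwise
  reproducible.

What the generator does **not** emulate: linkage disequilibrium and
pedigree structure (kernels, not mapping, are under test), pathogen
exposure dynamics, platform-specific noise (lane effects, isotope
interference, spectral overlap), repeated sampling, and trait-specific
fixed-effect lists beyond entry age and batch (the real lists are not
public). Passing tests therefore certify the estimation and
validation machinery under the stated generative model, not the
field-data performance of any particular omics platform.

## Verification problem sizes

The acceptance checks run at deliberately modest sizes chosen to make
each property sharp: the grid-search comparison at n=50 with a
rank-25 kernel; the GBLUP/SNP-BLUP identity at 30 animals x 200 SNPs;
variance-share recovery at n=800 (4 batches x 200) over 20 replicate
cohorts; the prediction-protocol identity at 40 training / 10
validation animals; null calibration and signal-ordering at 20
replicate one-company cohorts of 180 animals. `scripts/acceptance.py`
recomputes all of these from scratch for any seed.

## Numerical choices and degenerate inputs

* kernels are stabilized by adding `epsilon - min_eig` to the diagonal
  when the minimum eigenvalue falls below `epsilon = 1e-8` (recorded
  in `ridge_applied`); the same ridge backs the validation-prediction
  solve;
* zero-variance phenotypes, single-class AUC sets, folds with fewer
  than three scored animals, empty kernel lists, and rate-1
  missingness requests raise named errors; zero-variance prediction
  folds are flagged NaN and excluded from the weighted mean;
* TMM with a single animal, a zero library, or negative counts is
  rejected; features with fewer than two observed values cannot be
  mean/SD-aligned and are rejected by the imputer.

## Known limitations

* The per-feature residualization grid bounds the pen-to-residual
  ratio at 1e6 and resolves it to ~0.1 dex; features at the boundary
  fall back to fixed-effects-only residuals.
* Binary traits use the linear model on 0/1 records; no threshold
  (probit) model is fitted, matching the analysis protocol this
  package reimplements.
* The combined-kernel mean is unweighted; data-driven kernel weights
  are out of scope.
* Cross-company prediction is deliberately impossible: the genomic
  kernel has zero cross-company entries and fold planning never mixes
  companies.
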