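# Methods

## Model

Orion is a variational auto-encoder for sparse count data with two input
arms and two supervised objectives. The generative model for oncRNA counts
is zero-inflated negative binomial (ZINB): feature *j* of sample *i* is
zero with probability φᵢⱼ and otherwise NB with mean μᵢⱼ = ρᵢⱼ·e^ℓᵢ and
inverse dispersion θⱼ, where ρᵢ lies on the d-simplex (softmax decoder
output), ℓᵢ is a latent log library size, and θ is a free per-feature
parameter (softplus of an unconstrained vector). The NB uses the
Gamma–Poisson parameterization, Var = μ + μ²/θ.

Posteriors are diagonal Gaussians. q(z|x) has a standard-normal prior.
q(ℓ|r) has a log-normal prior whose log-mean and log-SD are the mean and
population SD of log row sums of the endogenous matrix within each
mini-batch, floored at 1e-3 so a batch of identical depths keeps a proper
prior. The library encoder predicts a *correction* added to the observed
log endogenous total (a skip connection); this makes q(ℓ|r) start near its
prior and removes a large transient in the ℓ-KL during the first epochs.
Encoders take log1p-transformed counts.

All likelihood and KL computation is in log space; the ZINB zero-mass
log(φ + (1−φ)·NB(0)) is computed by log-sum-exp of the two branches with
φ handled through its logit. Posterior log-SDs are clipped to [−6, 4].

### Losses and weights

The objective is λ₁·KL_z + λ₂·KL_ℓ + λ₃·NLL + λ₄·TML + λ₅·CE, with
defaults λ = (1, 1, 1, 25, 50). The NLL sums over thousands of features
while CE and TML are per-sample scalars, so the supervised terms must be
up-weighted to register at all: with λ₅ = 1 the classifier does not train
within a practical epoch budget, and with λ₄ = 1 the triplet term
measurably converges but has no detectable effect on supplier leakage.
λ₄ = 25 is the smallest round weight at which the ablation experiment
(below) shows a consistent effect; raising it to 100 changes little
because the hinge saturates once its margins are met.

The triplet margin loss follows the stated sampling scheme: per anchor and
per confounder column (supplier, experiment ID), ω = 16 positives with the
same label but a different confounder value and ω negatives with a
different label, hinge on squared Euclidean distances with margin α = 1,
normalized by 1/(ω·c) and averaged over anchors. Triplets are resampled
inside every mini-batch at every epoch, so distances always refer to
current embeddings. When an anchor has no same-label sample from another
confounder stratum, the constraint is dropped for that anchor with a
warning rather than silently skipping the stratum. The loss is applied to
the posterior means rather than the reparameterized draws: the hinge is a
comparison of two distances, and draw noise flips its active/inactive
state stochastically, diluting an already small gradient.

### Generative sampling

During training the classifier head receives η = 100 reparameterized draws
of (z, ℓ) per data point and the cross-entropy is averaged over draws (an
unbiased estimate of E_q[CE]; averaging probabilities instead would
estimate a different, Jensen-biased quantity). The head input z·ℓ is
batch-normalized using the statistics of the *posterior means*, not of the
draw cloud: the draws then act as augmentation around a test-consistent
scale. Normalizing by the draw statistics instead systematically shrinks
test-time logits (means have smaller spread than draws) and erases the
benefit of sampling. At test time predictions use posterior means only, so
scores are deterministic and independent of η.

### Optimization

Adam (lr 1e-3, β = 0.9/0.999), batch size 128, 30 epochs by default;
dropout p = 0.5 on encoder hidden layers; decoupled weight decay 2.0 on
encoder/decoder weight matrices (classifier weights are exempt — the CE
path is already the weakest gradient). All parameters are float64 and all
randomness flows from one seeded generator, so a fixed seed reproduces
training bit-for-bit on the same platform. Divergence (non-finite loss)
aborts with a diagnostic rather than continuing.

## Synthetic cohorts

The simulator emulates the data regime the model is built for, not any
particular real dataset:

* 600 samples, 2000 oncRNA features, 30 endogenous features by default;
* per-feature base rates log-normal (median 0.08 counts at unit depth);
  with θ = 2 and zero-inflation 0.7 the observed sparsity is ≈ 95%;
* library sizes log-normal (SD 0.5 in log space); endogenous means are
  100–1000× oncRNA means so row sums of r are a usable depth proxy;
* 100 signal features carry a 1.5 log-fold rate increase in cancer
  samples. Signal features are drawn from the upper half of base rates:
  marker panels in practice consist of detectable species (candidate
  oncRNAs are pre-filtered for prevalence in tissue before ever reaching
  serum models), and an undetectable marker is unrecoverable by any
  method;
* each supplier multiplies a random 20% of *non-signal* features by
  e^1.0. Keeping technical shifts off the signal features makes supplier
  identity a removable shortcut (correlated with the label only through
  cohort composition) rather than part of the disease signal itself;
* cohort composition is vendor-confounded: 65% of cancer but only 40% of
  control patients come from supplier 0 — the same direction as real
  multi-vendor serum cohorts, softened because the simulated per-feature
  batch shift is stronger than typical real vendor effects;
* patients may contribute replicate samples; replicates share the
  patient's rate vector (which includes a per-patient log-normal jitter,
  SD 0.5) and differ only in counting noise and library size.

What the simulator does *not* model: read-level chemistry and UMIs, depth-
dependent zero inflation, correlated feature blocks (pathways), drift
between experiments within one supplier, or age/sex/BMI covariates.
Passing tests therefore demonstrate that the implementation realizes the
intended mechanisms under the assumed generative process, not clinical
performance on real serum data.

## Evaluation protocol

Splits are patient-grouped throughout: 20% of patients held out,
stratified jointly on label and supplier (strata with fewer than two
patients are merged with a warning); the rest divided into patient-grouped
stratified folds; replicates always travel with their patient. Five models
per fold with different seeds; tuning-set scores average the fold's seeds;
held-out scores average all folds × seeds. One deterministic
representative sample per patient (first by sample ID) enters reported
metrics.

The operating cutoff is the midpoint between the bracketing control scores
achieving a target specificity on cross-validated training scores, then
frozen. AUROC uses the Mann–Whitney tie convention; F1 and MCC are
computed at the frozen cutoff only. Bootstrap CIs resample patients with
replacement (percentile, 1000 draws by default; degenerate single-class
resamples are redrawn); paired ΔAUC uses identical resamples for both
scorers.

Feature selection is re-run inside each training fold: presence in ≥ 2% of
samples of every supplier (inclusive boundary), presence/absence log odds
ratio > 0 for cancer within every supplier (Haldane–Anscombe +0.5 on
tables with a zero cell), then 8 rounds of gradient-boosted-tree
classification in which every feature with non-zero gain importance is set
aside and removed from the pool. The round models use xgboost defaults —
the rounds are a screening device, not a tuned learner.

In silico dilution downsamples the pooled (x, r) counts of a sample by a
multivariate hypergeometric draw (exact without-replacement semantics at
count resolution) and adds complementary fractions of a cancer and a
control sample from the same supplier; 10 top-scoring cancer × 10
bottom-scoring control samples per supplier (after excluding the depth
deciles below the 10th and above the 90th percentile) × 4 ratios × 2
suppliers = 800 mixtures, scored without retraining.

Feature attribution averages gradient×input (on the log1p input, along the
deterministic prediction path) over samples and over fold models; the
backend is pluggable — any callable with the same signature, e.g. a
Shapley-value estimator, can be substituted. An always-zero feature gets
exactly zero attribution under this scheme.

## Experiment problem sizes

The replicated experiments in `oncvae.experiments` use a reduced
architecture (k = 16, hidden 128, η = 100) on cohorts of 400–600 samples
and 600–2000 features so a full replicate set completes in minutes on one
CPU:

* batch-effect removal: 5 replicates × {triplet, ablated} on the default
  confounded cohort, 30 epochs; supplier AUROC of control scores compared
  by distance from 0.5;
* generative sampling: 5 replicates × {η-draws, expected-only} at 150
  training samples, 60 epochs, on the weaker-signal cohort
  (effect 1.0 log-fold) — the data-limited regime this mechanism targets;
  at 30 epochs both variants are still underfit and the comparison is
  uninformative;
* cutoff transfer: 5 replicates of 3-fold × 2-seed cross-validation
  (n = 400, d = 600, selection with 2 tree rounds), cutoff frozen at 90%
  CV specificity, specificity measured on the held-out 20%;
* dilution/perturbation: one 2-model ensemble (n = 400, d = 600); 800
  mixtures; top-50 attributed features ablated or permuted;
* selection recovery: 10 planted signal features among 2000, full
  8-round selection.

## Known limitations

* The numpy autodiff tape is single-threaded apart from BLAS matmuls;
  the default full-size architecture (hidden 1500, k 50) trains, but the
  reduced architecture is the practical choice for experimentation.
* The smooth-L1 regression head is wired but disabled by default; none of
  the bundled experiments exercise it.
* Batch-effect removal by the triplet margin loss is margin-limited: once
  every triplet satisfies its margin the gradient vanishes, so residual
  supplier information below the margin persists in the embedding. The
  ablation experiment measures a consistent *reduction* of leakage, not
  its elimination.
* Bit-level reproducibility holds per platform/BLAS build; across
  different BLAS libraries results match only to floating-point tolerance.
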