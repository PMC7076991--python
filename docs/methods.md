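# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the known limits of what the test suite shows.
It states no result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Data model

A `MethylationArray` is a samples × CpGs matrix of beta values (the
estimated fraction of methylated DNA copies at a locus, bounded in
[0, 1]) with a phenotype table aligned row-for-row on sample id.
Validation enforces finite betas in [0, 1], unique ids, and an exact
keyed join between matrix and phenotype. Betas of exactly 0 or 1 are
accepted in stored data and clamped to [1e-6, 1 − 1e-6] only when a
Bernoulli-style loss is evaluated.

**Splitting.** `train_test_val_split` uses a two-stage ceiling
convention: the test set takes ⌈test_frac · n⌉ samples, the validation
set then takes ⌈val_frac/(1 − test_frac) · remainder⌉, and the training
set keeps the rest. On 719 samples at 70/20/10 this gives 503/144/72.
Stratified mode applies the same convention within each stratum (each
needs ≥ 3 samples); the unstratified mode is the reference.

**Feature selection.** "Most variable CpGs" is implemented literally as
the mean absolute deviation about the per-CpG mean, `stat="median"`
switching to the median absolute deviation. Ties break by input CpG
order and selection preserves the original CpG order.

**I/O.** Delimited text (beta CSV/TSV + pheno CSV/TSV) or a single-file
HDF5 container (beta stored float64 so a round trip is exact to 1e-12;
id string arrays; pheno column-wise; attribute `format_version`).

## VAE feature extractor

Encoder: ReLU stack with configurable hidden widths, then linear maps to
μ and log σ². Decoder mirrors the encoder widths in reverse with a
sigmoid output layer, so decoded values live strictly in (0, 1).
Training draws z = μ + ε·σ (reparameterisation) and minimises soft-
Bernoulli cross-entropy reconstruction (betas treated as continuous
Bernoulli targets; MSE available via `recon_loss="mse"`) plus
β_kl-weighted KL to N(0, I). Choices worth knowing:

* **Validation loss** is the same β_kl-weighted objective, evaluated
  deterministically with z = μ; it drives early stopping (`patience`
  epochs without improvement), best-epoch snapshotting, and scan
  ranking. With β_kl = 0 training reduces exactly to a plain
  auto-encoder (the KL term contributes no gradient).
* **Inference is deterministic**: embeddings are posterior means, never
  samples; `sample_latent` decodes N(0, I) draws for synthesis.
* **Optimisation**: Adam, minibatches shuffled per epoch from the run
  seed; the seed fully determines initialisation, shuffling and
  reparameterisation noise, so runs are bit-reproducible at a fixed
  thread count. Schedulers: none (default), cosine, step (halving
  every 10 epochs).
* **Initialisation**: He for ReLU stacks, Xavier for the μ/log σ²/output
  projections, with the log σ² head scaled by 0.1 so early posteriors
  stay near-deterministic.

Networks are implemented in a compact numpy engine with hand-written
backpropagation (`nn.py`); it also exposes input gradients, which the
expected-gradients attribution estimator needs.

## Transfer-learning prediction

`build_finetune_model` deep-copies a trained VAE's encoder (hidden stack
+ μ projection) into a prediction network — mutating the fine-tuned model
never touches the source — and appends a freshly initialised ReLU head.
All layers are trainable from epoch 0. Output layer weights start at
0.01 × N(0, 1) so a fresh classifier predicts near-uniform probabilities
(initial cross-entropy ≈ ln k, a useful sanity bound). Losses: softmax
cross-entropy (classification), MSE (regression; targets z-scored from
the training set and un-scored at prediction, which changes the scale of
logged losses but not of predictions), and MSE on softmax outputs for
simplex-constrained multi-output regression, the default for cell-type
proportions (an unconstrained linear head is available). Early stopping
and best-validation-epoch snapshotting are identical to VAE training.
`train_mlp_baseline` trains the same architecture from random
initialisation — the no-pretraining comparison.

## Hyperparameter scan

Trials sample a learning rate (and for embedding a KL weight and
scheduler) from grids, and a topology from depth/width/latent ranges.
`complexity_weight` w mixes two uniform draws: with probability 1 − w
the low half of each range, with probability w the high half — so w = 0
is uniform over the low end, w = 1 over the high end, linear in between.
Trial i is seeded `scan_seed + i`; results are independent of execution
order and the whole log is determined by (scan_seed, space, data).
Divergent trials (non-finite loss) are recorded with infinite loss
rather than aborting. Logs are JSON-lines; `select_best` takes the
minimum validation loss, ties to the earliest trial id.

## Shapley attribution

All three estimators target the interventional value function
v(S) = E_b[f(x_S, b_{S̄})] over a seeded background subsample of the
training split (default 100 rows):

* **exact** — full 2^p coalition enumeration, refused above 20 features;
* **kernel** — the weighted least-squares approximation on coalition
  indicators; all 2^p − 2 proper coalitions are enumerated when that is
  within budget (then the solution matches exact enumeration to solver
  precision), otherwise coalitions are drawn from the Shapley kernel
  size law; the efficiency constraint is enforced by elimination;
* **gradient** — expected gradients, E[(x − b) · ∇f(b + α(x − b))] over
  (background, α ~ U(0,1)) draws; exact on multilinear models,
  approximate elsewhere.

For classifiers the attributed output is the predicted class's
pre-softmax logit, per sample (per-class attributions are available by
calling the estimators with a fixed output). Downstream: condition
means (first-appearance group order), top-k overlap against reference
CpG sets (signed-descending ranking by default, |score| optional; the
k = 1000 default is an arbitrary but conventional cutoff), average-
linkage dendrograms on 1 − Pearson r between condition profiles
(zero-variance rows sit at the maximum distance 2, with a warning), and
rank concordance: ranks of per-CpG mean |score| (ties averaged) against
an external ranking, Pearson r plus the two-sided non-correlation test,
restricted to the shared CpGs (≥ 3 required).

## Embedding evaluation

Group cosine distances are means of pairwise 1 − cos over cross-group
pairs; the diagonal holds the within-group mean over distinct pairs
(0 for singletons). Superclassing cuts an average-linkage tree built
from the off-diagonal entries only; when the superclass count is not
given, a maximum-curvature (second-difference) knee detector on the
merge heights chooses it — a standard substitute where no specific
detector is prescribed. The v-measure uses natural-log entropies;
a conditional ratio with zero unconditional entropy is taken as
perfectly homogeneous/complete, so two single-class labelings score 1.
Bootstrap CIs are percentile (2.5/97.5) over `n_boot` resamples of
sample indices; resamples on which a metric is undefined are skipped and
counted. CpG feature grouping transposes the beta matrix, embeds CpGs
with UMAP (default 6 dims), partitions with k-means (default 25), and
drops clusters whose embedding variance (trace of the per-cluster
covariance) exceeds the cutoff, leaving their CpGs unassigned.

## Synthetic generators

All generators draw per-CpG baselines in logit space from a bimodal
mixture (45% near logit(0.1), 45% near logit(0.9), 10% intermediate),
add effects and N(0, noise_sd) noise on the logit scale, and map through
the sigmoid — so betas are strictly inside (0, 1) and the noise model is
logit-normal, matching the bounded, bimodal look of array-wide beta
distributions. Classes and exposures are balanced by default. Defaults
(the conditions the recovery tests run at): cluster — 3 classes,
effect 4 logit units on 60 of 500 CpGs, noise 0.5; age — uniform ages on
15–95 y, 50 informative CpGs with |slope| ∈ [0.02, 0.05]/y, noise 0.3;
exposure — geometrically decaying effects e_r = 3.0 · 0.9^(r−1) over 50
CpGs, noise 0.5.

The mixture generator builds reference methylomes by recursive
perturbation along a binary tree: the split below a level-L node adds
N(0, (divergence · level_decay^L)²) logit offsets per child. With
level_decay < 1 divergence shrinks toward the leaves, mirroring
haematopoietic methylomes where the major lineage split (lymphoid vs
myeloid) dwarfs terminal splits (CD4T and CD8T are nearly identical
genome-wide). Default level_decay = 0.3. Bulk samples mix reference
betas by Dirichlet(α) proportions and add beta-scale noise, clipped to
the open unit interval.

**The lineage-recovery experiment** (attribution dendrograms grouping
sibling cell types) runs at level_decay = 0.1: sibling linkage of
condition-mean attributions is a property of the regime where siblings
are nearly unresolvable, as they are in real blood. When siblings are
clearly separable, a well-trained deconvolution model concentrates
attribution mass on sibling-discriminative CpGs, whose signs oppose
between siblings, and the linkage inverts; averaging signed attributions
across compositionally heterogeneous samples also cancels shared-family
signal. At level_decay = 0.1 the readout is stable across training
lengths and seeds; this is documented here precisely because it is a
regime statement, not a universal property of attributions.

**EWAS-style concordance** is reported as the median over three dataset
seeds (the same convention as the other recovery metrics): a single
realisation varies noticeably with the generator draw because planted
effects live in logit units while attributions live on the beta scale —
sigmoid saturation at extreme baselines compresses tail effects, so the
recoverable ranking depends on where informative CpGs land.

## What the tests do and do not show

Problem sizes are desk-scale by design: hundreds of samples and
hundreds of CpGs per experiment, networks of one or two hidden layers.
The suite demonstrates that the implementation recovers planted
structure through the full pipeline (generate → split → embed → scan →
fine-tune → attribute → evaluate) and that the estimators satisfy their
contracts (loss decomposition, snapshot rules, Shapley axioms, simplex
outputs, CI behaviour). It does not demonstrate performance on real
arrays: the generators have no batch effects, probe chemistry, missing
values, correlated CpG blocks beyond the planted ones, or 450K/EPIC
platform differences, and real phenotype signal is far sparser relative
to 300k+ CpGs than in these fixtures. Numbers printed by the acceptance
script quantify recovery under the stated synthetic conditions only.

## Known limitations

* Exact Shapley is limited to ≤ 20 features; kernel at full array width
  relies on coalition sampling and is slow — expected gradients is the
  intended estimator for real-width arrays.
* Expected gradients equals the Shapley value only on multilinear
  models; on deep networks it is an approximation (tested at 5%
  agreement on toy models, not bounded in general).
* The scan runs trials sequentially; a process-parallel mode would need
  its seeds re-verified against the sequential contract.
* Percentile bootstrap CIs are first-order; no BCa correction.
* Training determinism assumes a fixed BLAS thread configuration;
  bit-level reproducibility across different BLAS builds is not
  guaranteed.
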