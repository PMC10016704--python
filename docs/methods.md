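# Methods

This note documents the model, the synthetic data, and the numerical and
design choices behind `scemila`. It is written for readers who want to know
what the package computes and why, and what its tests do and do not
demonstrate about real cytomorphology data.

## Problem setting

A peripheral-blood smear is digitized into a few hundred single white-cell
images per patient. The diagnostic label (a genetic AML subtype — PML::RARA,
NPM1, CBFB::MYH11, RUNX1::RUNX1T1 — or healthy control) exists only at the
patient level; no per-cell labels are available. This is the classic multiple
instance learning (MIL) setting: a patient is a *bag* B = {x_1, …, x_N} of
instance feature vectors, supervised by one bag label y. Diagnostically, a
smear's label can rest on a small sub-population of pathognomonic cells (for
example faggot cells in APL), so a useful model must both classify the bag
and say *which* cells carried the decision.

## Model

Instances enter as fixed-length feature vectors x_k ∈ R^d extracted from a
supervised single-cell classifier (below). The bag model is

    h_k   = f_emb(x_k; γ)                  instance embedding, ReLU MLP
    e_ik  = w_i^T tanh(V_i h_k)            raw attention score, class i
    α_ik  = exp(e_ik) / Σ_j exp(e_ij)      softmax over the bag, per class
    z_i   = Σ_k α_ik h_k                   class-wise attention pooling
    s_i   = u_i^T z_i + c_i                per-class logit
    p     = softmax(s)

The distinctive element is the *class-wise* attention matrix A = (α_ik):
every class owns a full attention distribution over the bag's instances, and
rows are normalized independently. Consequently attention values never
compete across classes — perturbing class i's attention parameters (V_i, w_i)
provably leaves every other row of A unchanged — and the attention row of the
predicted class, α = A_ŷ, is the per-cell explanation that the rest of the
package analyses. The model is permutation invariant in the instance order.

Because a bag of size one has α = [1] and z_i = h_1, the same fitted
parameters define a single-cell classifier: passing each cell through the
model as a bag of one ("deconvolution") is algebraically a linear head on the
embedded cell, and the package computes it that way.

Training minimizes the bag-level categorical cross-entropy with Adam, one
optimizer step per bag, shuffling bag order and permuting within-bag instance
order every epoch. Early stopping monitors validation loss with zero minimum
delta; the best-validation weights are restored (earliest epoch on ties).

### Resolved ambiguities

* The attention raw score is e_ik = w_i^T tanh(V_i h_k), normalized over
  instances j within class i — the only reading of the formula that is a
  per-class softmax over instances.
* The training loss is cross-entropy of the predicted distribution against
  the true one-hot label (the only computable direction).
* f_emb is a single hidden ReLU layer d → L_emb by default (`embed_depth`
  raises the depth); the smallest architecture that "further analyses" the
  input features. Whether the original operates on the flattened feature
  vector or the unflattened convolutional map is unknowable from the text;
  the flat-vector reading is implemented.
* f_cls is a per-class linear head applied to that class's own pooled vector,
  preserving the class-wise decoupling; a shared-weight head is available
  behind `shared_head=True`.
* The bag-level optimizer is not named in the source recipe (only the
  learning rate 5e-5); Adam is used and recorded in the configuration.
* Argmax ties resolve to the lowest class index; validation-loss ties keep
  the earliest epoch.
* All softmaxes subtract the row maximum before exponentiation.

### Initialization

Embedding and head weights use He/Xavier-style scaled Gaussian draws. The
attention vectors w_i start at **zero**, so every attention row is exactly
uniform at initialization and the first epochs fit a mean-pooled bag
classifier; attention sharpens only where it reduces the loss. This choice
removes an initialization-luck failure mode observed during development,
where randomly initialized attention occasionally locked onto noise
directions and individual fold models lost 1–2 bags' accuracy. An optional
decoupled weight-decay term (`weight_decay`, default 0) is available.

### Configuration scales

`MILConfig` defaults are the full-scale recipe (L_emb = 500, L_att = 128,
lr 5e-5, patience 20, max 150 epochs) appropriate for d = 12,800 features.
`desk_scale_config()` returns the reduced configuration used by this
package's tests and acceptance runs — L_emb = 128, L_att = 64, embed depth 2,
lr 1e-3, patience 5, max 30 epochs — sized so a full 5-fold cross-validation
of the default synthetic cohort (200 patients, d = 64) runs in a few minutes
on one CPU core. These problem sizes are the package's own choice of
desk-scale experiment. Training also supports validation-selected random
restarts (`n_restarts`, default 1).

## Feature extraction

The instance features are the flattened pre-pooling activations of a
supervised single-cell classifier trained with categorical cross-entropy.
Two backbones satisfy the contract:

* **resnet34** — the full-scale recipe: ImageNet-initializable 34-layer
  residual network, SGD at 5e-4, patience 10, flip/rotation/translation/
  rescale/random-erasing augmentation, inverse-frequency probabilistic
  oversampling, 21 cell-type classes (23 annotated minus two excluded for
  class size, expressed as a configurable exclusion list). At 144×144 input
  the final convolutional stage is 512×5×5, so d = 12,800. The numpy
  implementation here is forward-only: training a ResNet at corpus scale is
  out of reach without a deep-learning framework and an annotated corpus of
  hundreds of thousands of cells, so `train_extractor` raises for this
  backbone. The d = 12,800 contract is verified by an actual forward pass.
* **tiny_cnn** — three stride-2 convolution stages (8/16/8 channels) with a
  global-average-pool + linear head. It trains on a CPU in seconds-to-minutes
  and is the tested training path on synthetic cell images. Its feature
  length is 8·⌈s/8⌉² at input size s (72 at 24 px).

The feature dimension is a pure function of backbone and input size;
extraction is augmentation-free and deterministic. Features are stored
float32 (bag files half the size; downstream training is tested at 1e-5/1e-6
tolerances, which float32 inputs satisfy since all arithmetic is float64).

"Probabilistic oversampling" is implemented as sampling with replacement
with per-sample probability inversely proportional to class frequency, which
makes the expected class distribution of a training epoch uniform; the
expectation is what the tests check.

## Quality control

The cleaning cascade runs in the order blur → low-blast → manual, with a
consort-style report accounting for every exclusion.

* **Blur filter.** Each image is converted to grayscale (luma weights
  0.299/0.587/0.114) and Canny edge detection is applied (scikit-image).
  The *edge sum* is the sum of the binary edge map valued 255 per edge pixel;
  an image is excluded iff its edge sum is strictly below 5×10⁴ (≈196 edge
  pixels). A `count` mode interprets the threshold as a raw edge-pixel count
  instead — both readings of "sum of all edges" are defensible, and the
  configuration is persisted in the report since the threshold is only
  meaningful jointly with the Canny parameters. Hysteresis thresholds are
  configured in 8-bit Sobel-gradient units (defaults 100/200) and divided by
  1020 — the maximum per-axis response of a 3×3 Sobel operator on 8-bit
  data — to reach scikit-image's unit-intensity gradient scale, where they
  land at (0.098, 0.196). Exact replication of the original pipeline's
  image-level exclusion counts is not attempted (its exact Canny parameters
  and grayscale convention are unknown).
* **Blast filter.** An AML patient is excluded iff the routine
  differential-count percentages of myeloblasts + promyelocytes + myelocytes
  sum strictly below 20% — the conventional WHO blast threshold. Controls
  are exempt (the criterion is defined on AML samples). The percentages come
  from the manifest's differential count, not from the images.
* **Manual hook.** Ingests a list of expert-excluded patient ids; unknown
  ids warn and are skipped. The expert assessment itself is out of scope.

The cascade is idempotent, each stage partitions its input exactly, and
stage counts are monotone non-increasing.

## Synthetic data

The feature-bag generator emulates the statistical core of the problem: a
patient bag mixes a *background* population shared across all classes with a
minority *planted* population carrying a class signature. Background
instances are N(0, σ²I); planted instances add a class mean μ_c of norm equal
to `signature_separation` along mutually orthogonal canonical axes (one per
AML class; the control class has no signature and its bags contain zero
planted instances). Which instances are planted is Bernoulli per instance.
Defaults: 5 classes × 40 bags, bag sizes uniform on [99, 500] (the observed
per-patient image-count range; the within-class size distribution is not
documented, so uniform is a choice, not an inference), d = 64,
planted fraction 0.2 per AML class (a "rare" preset at 0.05 exists for
needle-in-haystack tests), separation 4σ with σ = 1.

The image generator renders crude stained-smear cells — elliptical cytoplasm
on a pink background, one to three nuclear lobes, optional azurophilic
speckle — with class-dependent radius/lobedness/granularity, at 144×144 RGB
by default. A deterministic count round(blur_fraction·n) of images is
Gaussian-blurred (σ = 10) to near-featurelessness so the blur filter has
exact, constructed true positives. Synthesized differential counts tie the
blast percentage to the planted fraction (100·f + 12 ± 3, clipped), push
designated low-blast patients into 8–16%, and controls into 0–5%, so the
blast filter is exercised end-to-end.

What passing on these fixtures does **not** show: real smears have
correlated, non-Gaussian features, class overlap, staining variation and
artifacts; the planted/background dichotomy is cleaner than real
pathognomonic-vs-unremarkable cell distinctions. Tests on this generator
demonstrate algorithmic correctness and the *mechanism* of attention
recovery, not clinical performance.

## Explainability analyses

* **Deconvolution** — every cell classified as a bag of one; output order is
  bag order.
* **Attention ranking** — stable ascending sort by the predicted class's
  attention row; ties keep bag order.
* **Quartile concordance** — ranked cells are cut into four *rank-based*
  quartiles (equal counts, sizes differing by at most one; the lower
  quartiles take the extra cells). Rank-based quartiles keep the top-quartile
  summaries well defined when the attention distribution is heavily skewed,
  which it typically is; value-based quartiles would often be nearly empty at
  the top. Per quartile, the composition over annotation relevance groups is
  reported; the relevance vocabulary is user-supplied data (annotations TSV
  plus a group→relevant mapping), not package constants. Unannotated cells
  are excluded from fractions and counted separately.
* **Representative cells** — per class and fold, the k = 2 cells with the
  highest single-cell output activation for that class, pooled across folds
  (10 per class at k = 5 folds); ties break by (patient id, cell id).
* **Subsample robustness** — per patient and subset size s (default ladder
  1, 2, 5, 10, 20, 50, 100, 200, 500, clipped per patient, plus the full
  bag), repeated draws without replacement are passed through the model;
  reported are mean accuracy over patients and mean true-class activation
  per patient, with a "random cell from the dataset" baseline that ignores
  patient ground truth. At s = N the subsample is the full bag, so the
  full-size entry reproduces full-bag accuracy exactly.

## Cross-validation protocol

Splitting is at patient level and class-stratified: each class's patients
are shuffled once and cut into k = 5 chunks via largest-remainder sizing;
fold i tests on chunk i, validates on the next chunk, trains on the rest
(60/20/20 at k = 5). Every patient appears in exactly one test set, so
pooling the folds' test predictions counts every patient once in the final
confusion matrix. Reported metrics: per-class F1 mean ± s.d. *across folds*,
pooled confusion matrix, pooled one-vs-rest ROC-AUC and PR-AUC per class,
pooled macro-F1, and the collapsed AML-vs-control binary accuracy. One
master seed fans out (via `SeedSequence`) to the split and the per-fold
training streams; all derived seeds stay below 2³¹.

## The 2-D embedding

UMAP is fitted on one fold's cell features (≥10 cells required; degenerate
all-identical input is rejected) with a fixed seed, and other folds' cells
are projected with `transform` without refitting. Neighborhood parameters
are library defaults, recorded in the provenance block: the embedding is a
visualization stage, not a quantitative claim, and no coordinate
post-scaling is applied.

## Known limitations

* The numpy backbones are CPU-sized: ResNet34 is inference-only, and the
  trainable CNN is deliberately tiny.
* The MIL trainer is sequential (one bag per step) and single-threaded
  beyond BLAS; full-scale defaults (L_emb = 500, d = 12,800) train slowly
  on CPU.
* Attention explains the bag decision; it is not pixel-level saliency, and
  no pixel-level attribution is provided.
* The synthetic generator's independence assumptions understate real-data
  difficulty (see above); performance numbers on it are mechanism checks,
  not clinical estimates.
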