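# Methods

This note documents the models, the synthetic worlds they are validated on,
and the numerical and design choices that were genuinely open.

## 1. Stage 1 — multimodal severity assessment

### Model

Let a patient have n numeric and m categorical laboratory fields and a set of
precomputed image feature vectors. The table encoder follows the
feature-tokenizer pattern: numeric field j becomes the token x_j·w_j + b_j
(learned d-vectors), each categorical level has a learned d-vector, and a
learned CLS token is appended, giving an (n+m+1)×d token matrix. Fields are an
unordered set, so there are no positional encodings; consequently the CLS
output is invariant to permuting field tokens (asserted in tests). L pre-norm
transformer layers (self-attention + GELU feed-forward, residuals) produce
E_Table as the CLS row. Image vectors are averaged per patient and linearly
projected to width d, giving E_Image.

Fusion is single-query cross-attention (table queries, image keys/values)
scaled by √d, followed by a residual connection from the query path and layer
normalisation. Auxiliary linear heads on E_Image and E_Table give unimodal
cross-entropy losses; their gradient L2 norms — each taken over that
modality's own encoder+head parameters, once per batch, and detached —
feed a three-layer projection network (linear → ReLU → linear → sigmoid →
linear → softmax) producing w_image + w_table = 1, and a two-layer softplus
network producing w_fusion > 0. The composite loss is

    L = w_image·L_image + w_table·L_table + w_fusion·L_multimodal + L_gradnorm,
    L_gradnorm = ‖∇L_image‖₂ + ‖∇L_table‖₂.

The weight networks receive gradients through the weighted loss terms; the
gradient statistics themselves are inputs, not differentiable paths (no
second-order terms).

### What drives the learned weights

Because w_image + w_table = 1, the gradient on the weight-network parameters
is (L_image − L_table)·∂w_image/∂θ: training moves weight toward the modality
whose unimodal loss is currently lower. The weights are therefore a trained
readout of relative modality usefulness, and they need enough optimizer steps
for the slower (transformer) path to express its signal — at desk scale we use
≥150 steps before reading the trajectory.

### Numerical choices

* **ReZero gate on the fusion branch.** The attention branch is multiplied by
  a learned scalar initialised at 0, so fusion starts exactly at the table
  residual. Without it, Adam's per-parameter normalisation regrows the value
  projection from pure-noise gradients, and a zero-signal image modality costs
  the fused classifier ~0.05 AUROC against the table-only model; with the
  gate, a noise modality cannot push the scalar away from 0 (zero-mean
  gradients) while an informative one grows it quickly. The printed attention
  formula is unchanged; only the residual combination is gated.
* Numeric fields are z-scored with development-split statistics.
* Defaults: d = 64, 2 layers, 4 heads, Adam 1e-3, 50 epochs, batch 32. The
  chain and acceptance runs use d = 32 and 12–16 epochs to fit a 1-CPU,
  minutes-scale budget; this is a compute reduction, not a different model.
* Cross-entropy is used for all classification losses (the loss family was
  unspecified); the multi-head count of the table encoder is configurable,
  while the cross-attention fusion is single-head as printed.
* Missing image modality: configurable between refusing (default) and
  zero-vector imputation.

### Ablation switches

The trainer exposes image-only, table-only, fixed-weight (w = 0.5/0.5,
w_fusion = 1, no gradient-norm term) and simple-fusion (elementwise addition
instead of cross-attention) controls, giving the five-row grid
MI / TD / MI+TD / +GNW / +GNW+CA reported by `run_ablation`.

## 2. Stage 2 — medication-combination efficacy

### Features

Each medication contributes three views, concatenated into the node feature
h = [F_macro; F_micro; F_ppi]:

* **F_macro** — the four pharmacology attribute texts (meridian, property,
  flavours, side effects) are embedded by a pluggable text embedder and fused
  by a self-attention layer, mean-pooled over attribute tokens. Empty texts
  give flagged zero vectors.
* **F_micro** — target-protein sequences embedded by a pluggable sequence
  embedder, mean-aggregated over the medication's targets (flagged zero
  vector when no targets).
* **F_ppi** — DeepWalk over the protein interaction network: uniform-neighbour
  random walks (length 10, 10 per node) fed to a NumPy skip-gram with negative
  sampling (window 4, unigram^0.75 negatives); a medication's F_ppi is the
  mean over its targets. Isolated nodes map to zero vectors.

The shipped embedders are deterministic stand-ins for the pre-trained language
models a production deployment would plug in: a seeded SHA-256-keyed Gaussian
projection per string for text, and k-mer counts (k = 2) with a fixed random
projection for amino-acid sequences. They are contracts, not approximations of
any particular pre-trained model.

### Graph model

A regimen is a complete graph over its medications. Edge weights come from the
prescription co-occurrence prior w_ij = count(i,j)/max count ∈ (0,1]; pairs
absent from the prior get a fallback of 1/max count. Two graph-transformer
layers update nodes by attention over neighbours with the scalar edge weight
broadcast-added to the key vector:

    α_ij = softmax_{j∈N(i)} ( (h_i W_Q)·(h_j W_K + w_ij)ᵀ / √d_k ),
    h_i' = σ( Σ_j α_ij h_j W_V ),    σ = ReLU.

Isolated nodes fall back to a self-loop with weight 0. A per-node VAE then
maps features to (μ, σ), samples z = μ + σ⊙ε (seeded; z = μ at inference),
and a masked mean pool over z gives the regimen embedding E_medication used
both by the classifier head and by stage 3. The loss is

    L_total = L_KL + L_focal,    L_KL = ½ Σ_dims (μ² + σ² − log σ² − 1)

averaged over nodes, with focal loss −α_t(1−p_t)^γ log p_t (γ = 2).

### Numerical and design choices

* **Posterior-at-prior initialisation.** The VAE encoder weights are scaled by
  0.01 at init so μ ≈ 0, σ ≈ 1 at step 0. Otherwise the initial KL gradient
  dwarfs the focal-loss gradient (whose (1−p_t)^γ factor shrinks
  classification gradients by roughly an order of magnitude) and collapses the
  latent before it learns anything: on the planted benchmark this is the
  difference between test AUROC ≈ 0.59 and ≈ 0.82, with the stated loss
  untouched.
* **α_t is a batch-constant scalar, default 1.0.** The focal formula prints a
  single α_t. With a batch-constant α its only effect is to rescale L_focal
  against L_KL in the total; 0.25 (the common default) starves the classifier
  here (minority F1 0.23 vs 0.61). A per-class α mapping was tried and
  rejected: weighting the minority at 0.25 simply suppresses minority
  predictions.
* The VAE decoder reconstructs the graph-transformer output; a reconstruction
  term is exposed (`recon_weight`, default 0) but the default total is exactly
  L_KL + L_focal. With the weight at 0 the decoder is untrained scaffolding;
  the KL term alone regularises the latent.
* VAE placement: between the graph-transformer output and the readout (the
  alignment site was under-specified; this is the single site shipped).
* Readout: masked mean pooling (the readout was never named).
* Pairwise ranking scores every unordered pair as a 2-node regimen by the
  positive-class probability, keeps the top fraction (ceiling convention,
  default 15%), and breaks ties lexicographically by id pair.

## 3. Stage 3 — patient-regimen matching

Patient and regimen embeddings pass through separate two-layer ReLU MLPs into
a shared space. Training minimises the hinged bidirectional margin loss

    L_dir = 1/(2N) Σ_i max(0, s(a_i, neg_i) − s(a_i, pos_i) + α),
    L = ½ (L_regimen→patient + L_patient→medication),

with cosine similarity s, margin α = 0.2, and in-batch negatives (each
anchor's negative is another pair's partner, cyclic shift drawn per batch).
The as-printed unhinged form — which, minimised literally, would drive
positive similarity down — is available behind `literal=True`; the hinged
triplet reading matches the surrounding intent ("separation strength") and is
the default. Normalisation is by anchor count with the ½ factor.

Ranking is cosine confidence, descending, ties broken lexicographically by
regimen id; recommendation defaults to k = 5 and evaluation to HIT@10.
Cosine of a zero vector is defined as 0 with a warning.

## 4. Synthetic worlds

The generator is a pure function of (config, seed) and emulates the structure
of a multimodal chronic-disease cohort. It does **not** attempt realistic
clinical marginals, disease-specific laboratory panels, real pharmacology
text, or real protein families — a green test establishes that the planted
statistical structure is recovered, not clinical validity.

* **Patients.** Severity labels are drawn first (balanced). Numeric fields get
  a class-conditional mean shift of total size β_table along a fixed random
  unit direction plus unit Gaussian noise; categorical fields get
  class-dependent Dirichlet frequencies; image embeddings get a class-aligned
  direction of size β_image plus unit noise, 1–3 vectors per patient. Either β
  can be zeroed to make that modality pure noise. A 2% missingness rate and 1%
  out-of-range outlier rate exercise the cleaning rules. Default n = 600,
  75/25 development/test.
* **Medications, PPI, regimens.** 60 proteins in a 2-block stochastic block
  model (p_within 0.3, p_between 0.02); 30 medications, each targeting 1–3
  proteins from one block, with block-biased amino-acid compositions and
  block-tagged attribute texts. 400 regimens of 2–4 medications; the outcome
  score sums per-medication effects (N(0, 0.5)), **symmetric pairwise
  synergy** (+2 for same-block pairs, −2 for cross-block pairs) and N(0, 0.5)
  noise, thresholded at a configurable quantile (0.5 → balanced, 0.9 → 1:9
  imbalance). The symmetry matters: a same-block-only bonus makes the outcome
  predictable from regimen size alone (a shuffled-label control then scores
  ≈0.7 AUROC); with the symmetric rule the signal is irreducibly pairwise and
  the shuffled null sits at chance.
* **Matching.** Each matched patient/regimen pair shares a latent factor
  (dim 8); both observables are fixed linear maps of it plus N(0, 0.1) noise.
  This world is the stage-3 benchmark. The full chain instead feeds stage-1
  and stage-2 embeddings to stage 3, and in the default world those share no
  planted factor — the chain's matching header is therefore near chance by
  construction, and demonstrates plumbing, determinism and leak-guarding
  rather than retrieval quality.

## 5. Pipeline, metrics, leak guard

Metrics: AUROC (rank statistic), AUPRC (precision-recall step integration),
F1 and precision at the 0.5 threshold (binary) or macro over argmax
(multiclass), all via scikit-learn. Cross-validation is stratified and
deterministic; random oversampling of minority classes happens inside each
training fold only, and the test split always keeps its original distribution.
Test-split severity labels are held in a vault that counts every access before
the evaluation phase; `run_chain` reports that count (0 in a correct run).
Reports are serialised with sorted keys and fixed rounding, making reruns
byte-identical.

## 6. Known limitations

* The neural core is a minimal NumPy autodiff: float64, single-CPU,
  mini-batch; adequate at desk scale, not for image encoders or large
  formularies.
* Text and sequence embedders are synthetic contracts; conclusions about real
  pharmacology text or protein sequences require plugging in real encoders.
* The gradient-norm weighting readout is a relative-loss signal; with
  modalities of very different convergence speed it needs enough steps per
  epoch before the trajectory is meaningful.
* Stage-2 supervision is the regimen outcome label; supervising on the paired
  patient's severity instead is structurally supported (labels are caller
  supplied) but not separately benchmarked.
* Out-of-range laboratory values are blanked and imputed rather than dropping
  the patient; whether removal should drop the record was left open upstream.
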