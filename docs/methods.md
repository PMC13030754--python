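# Methods

## Problem and model

The package classifies endoscopy frames into adenoma, hyperplastic polyp, or
normal mucosa with a dual-encoder vision–language model. An image backbone
maps a frame to a unit vector `v ∈ R^D`; a text backbone maps each class's
clinical prompt to a unit anchor `t_y`. Classification (default rule) is the
argmax of `cos(v, t_y)` over classes, with ties broken deterministically to
the lowest class index; an alternative rule uses the linear identity head
trained alongside. Both rules are exposed because a fine-tuned system of this
kind can legitimately read out either way, and they agree when training has
converged.

Training couples two objectives at a shared temperature `τ = 0.02`:

- **Label-aware cross-modal projection matching.** For each direction
  (image→text and text→image) the model's compatibility distribution
  `p_{ij} = softmax_j(v_i · t_j / τ)` is pulled toward the normalized
  ground-truth match distribution `q_{ij} = [y_i = y_j] / n_same(i)` by
  `KL(p ‖ q + ε)` with stabilizer `ε = 1e−8`; the two directions are
  averaged. Rows of `q` always sum to one because a sample matches itself.
  An `instance_softmax` mode replaces `q` with the identity (diagonal
  positives, per-direction softmax cross-entropy, averaged); it is the
  printed form of the loss, coincides with symmetric InfoNCE, and serves as
  the ablation bridge.
- **Identity loss.** Mean softmax cross-entropy of a linear head
  `W^T v + b` against the class labels. The head sees image embeddings only;
  the text branch is frozen. The loss is normalized by batch size so that a
  zero-weight head scores `ln C` regardless of `N` (the unnormalized sum is
  an equivalent objective up to a constant factor at fixed batch size).

The total objective is the unweighted sum of the two; weights are exposed in
the run config and validated non-negative.

### A note on the two CMPM readings

With all-distinct labels `q` collapses to the identity, and the KL objective
and the instance-softmax objective share the same minimizer (probability
mass concentrated on the diagonal). Their *values* differ, however: the
forward KL with a one-hot `q` pays `≈ −log ε` per unit of off-diagonal mass,
so the two modes are not numerically interchangeable even on distinct-label
batches. Tests therefore assert the structural relationship (the collapse of
`q` and the shared optimum direction), not value equality.

## Encoders

The framework is backbone-agnostic: plugins register under string
identifiers, and a large pretrained dual encoder can be mounted behind the
same contract (unit-normalized rows, a controllable number of trainable
blocks, frozen text by default). The bundled backbones are deliberately
small:

- **`tiny_cnn`** — a patch-embedding network: the frame is cut into an 8×8
  grid of patches (a stride-equals-kernel convolution written as reshape +
  matmul), each patch is contrast-standardized per channel, embedded
  linearly, passed through ReLU, mean-pooled over patches, and projected to
  `R^D`. Per-patch standardization (local contrast normalization) makes the
  texture features largely invariant to illumination gain/bias — the same
  family of perturbations the photometric augmentation applies — while the
  per-patch channel means and standard deviations are appended as explicit
  color/contrast features. Without this front end, training under
  photometric augmentation is visibly unstable (the color cue and the
  dithering ranges overlap); with it the recipe converges smoothly. Two
  blocks; `image_trainable_depth` freezes from the bottom up.
- **`class_embedding_table`** — a bag-of-tokens random-feature text encoder:
  every whitespace token maps to a fixed Gaussian vector (seeded by the
  table seed and a hash of the token), and a prompt embeds as the normalized
  token mean. Identical strings give identical rows. Prompts sharing
  boilerplate ("A photo of …") therefore produce correlated anchors, while
  prompts rich in distinct clinical vocabulary produce near-orthogonal ones.
  This gives prompt *content* a real geometric effect — the mechanism by
  which structured clinical templates out-separate generic class names here —
  without pretending to model language semantics.

Gradients flow through a small bundled reverse-mode autodiff core
(`_autodiff.py`: broadcasting arithmetic, matmul, exp/log/relu/sqrt,
reductions, reshape, float64 accumulation). The test suite checks every loss
and the normalization chain against central finite differences at 1e−4
relative tolerance.

## Prompts

A class prompt is `entity ⊕ quantification ⊕ context`, realized as three
sentences joined by single spaces; the bundled registry stores the
three-class clinical templates as UTF-8 JSON package data (typographic
apostrophes preserved verbatim). New labels can be registered at run time;
fragments must be non-empty and end with terminal punctuation.

The entropy diagnostic `H(·)` is operationalized as the Shannon entropy (in
bits) of the pooled whitespace-token frequency distribution — the
distribution underlying the stated information-density inequality is never
defined formally, so one defensible choice is made and kept as a diagnostic
only (it never enters training). Under this operationalization the
subadditivity `H(P) ≤ H(E) + H(Q) + H(C)` holds with wide margins for any
multi-word fragments, which is what the property tests draw; it can fail
only in the degenerate case where every fragment is a repetition of a single
token (component entropies 0, pooled entropy positive).

## Augmentation

Geometry: similarity transform about the image center — the only reading
consistent with the requirement that constrained rotation retain the central
pathological structure — with bilinear interpolation and nearest-edge
replication fill (black corners would be an artificial cue absent from real
endoscopy). An optional mode crops the largest always-valid central square
and resizes back; default off. Photometry: per-channel gain/bias, clipped to
[0, 1]. Order is geometric first, then photometric, so clipped values are
interpolated only once. Angles are accepted in degrees at the API surface
and stored in radians; both translation axes are bounded by 0.1 × width.
Augmentation runs on training batches only; evaluation never perturbs an
image, and tests assert this with a spy.

## Synthetic corpus

The generator emulates the shape of a single-center polyp corpus: by default
30 patients per class with 5 frames each at 64×64 (a study-shaped variant
reproduces 154/147/88 images over 39/36/16 patients). Appearance latents
(lesion position, size, texture phase and orientation, hue) are drawn once
per patient and shared across that patient's frames; per-frame jitter is
small (≈3° tilt, ≈2% lesion shift, ±8% illumination), so frames of one
patient are near-duplicates while patients differ substantially — the regime
in which patient-level splitting matters and augmentation has a real job.

Class textures are procedural and spectrally separated: adenomas carry
low-frequency lobulated bumps (2.5–4 cycles/image) plus faint surface
granularity (~7.5 cycles), hyperplastic polyps carry high-frequency
serrated triangular-wave ridges (12–16 cycles), normal mucosa is smooth.
Lesion classes are raised and tinted the way they present endoscopically
(adenomas redder, hyperplastic polyps paler). All classes share an
endoscopic vignette, 1–3 specular highlights, and sensor noise. The
corpus is verified separable by construction: a 5-nearest-neighbour
classifier on 8×8 thumbnails exceeds 70% on a patient-disjoint split, and
the high-band spectral energies order hyperplasia > adenoma > normal.

What passing on this corpus does **not** show: robustness to real
endoscopic nuisance (motion blur, fluid, debris, occlusion, camera
auto-exposure), to inter-observer label noise, or to the far richer
within-class variability of real lesions. The synthetic task is a
correctness and mechanism harness, not a clinical benchmark; the headline
numbers reported on clinical data by full-scale fine-tuning of a large
pretrained backbone are out of scope here and not comparable.

## Training recipe and scaled defaults

The optimizer and schedule follow the fine-tuning recipe: AdamW with
`β1 = 0.9`, `β2 = 0.98`, `ε = 1e−8`, weight decay 5e−4; linear warm-up
reaching the base rate at iteration 5 (decay iterations are counted after
warm-up); halving every 1000 iterations; batch size 8; `τ = 0.02`. Package
defaults scale the recipe to the bundled tiny backbone and 64×64 corpus:
learning rate 1e−3, 30 epochs. `RunConfig.paper_scale()` restores the
full-scale settings (learning rate 1e−5, 60 epochs, 224×224) for use with a
mounted pretrained backbone. Gradient norms are clipped globally at 1.0; at
`τ = 0.02` the softmax saturates sharply and occasional spiky batches
otherwise destabilize the late phase of training. Batches are drawn by
uniform per-epoch shuffling without class balancing. Three named RNG streams
(data order, augmentation, initialization) derive from the run seed, so
ablation variants see identical data order; runs are bit-reproducible per
seed.

Cross-validation partitions *patients*, stratified by their (single) class,
into folds whose sizes differ by at most one within each class stratum —
each patient carries one class, matching how such corpora are labeled. Both
a five-fold CV protocol and a single holdout split (fold 0 of the same plan)
are provided; the ablation harness defaults to the holdout protocol. The
study-shaped 91-patient corpus yields test folds of 19/18/18/18/18 patients.

## Numerical conventions and degenerate inputs

- Zero-denominator metrics: precision/recall are 0 when their denominator is
  0; F1 is 0 when precision + recall = 0. Macro averages are unweighted.
- Embedding batches validate unit row norms to 1e−6; `from_raw` normalizes.
- Temperature, learning rates, and loss weights are validated positive /
  non-negative; unknown labels, missing files, and train/test patient
  overlap raise immediately with the offending row or ids named.
- The optimizer skips parameters that received no gradient, so a zero-weight
  objective leaves parameters bit-identical (no stray weight decay).
- KL values can dip below zero by at most the `ε` perturbation; tests bound
  losses below by −1e−6.

## Known limitations

- The bundled text encoder is a random-feature device: it makes prompt
  vocabulary geometrically meaningful but carries no semantics; two
  synonymous prompts embed unrelatedly.
- On the default corpus the full recipe and several ablations saturate near
  perfect accuracy, so the component comparison there shows direction mainly
  through ties; the reduced corpus in the examples separates the variants
  more visibly.
- The entropy diagnostic depends on whitespace tokenization; punctuation
  attached to words counts as part of the token.
- Patient stratification assumes one class per patient; corpora with
  mixed-lesion patients fall back to the majority class for stratification.
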