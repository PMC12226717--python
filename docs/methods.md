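# Methods

## The three tiers

**Tier 1 — screening.** A binary classifier over the five features (age,
gender in {female→0, male→1}, BCVA, IOP, CDR). BCVA is accepted as a raw
numeric value; no decimal↔logMAR conversion is applied — document the
scale of your source table. Four families are available (`knn`, `svm`,
`lr`, `xgb`); all but XGBoost sit behind a standardization pipeline, and
SVM probabilities come from Platt-style sigmoid calibration. Hyperparameters
are tuned by Bayesian optimisation: a Gaussian-process (Matérn ν=2.5)
surrogate over a unit-box parameterisation of each family's search space
(xgb: max_depth 2–8, learning_rate 0.01–0.5 log, n_estimators 50–400;
lr: C 1e−3–100 log; svm: C 1e−2–100 log, γ 1e−3–10 log; knn: k 3–50,
uniform/distance weights), objective = mean stratified-CV AUC, acquisition
= expected improvement over 256 random candidates after a random warm-up;
default budget 50 evaluations. Class imbalance is unweighted by default
(`class_weight="balanced"` is available).

Operating points are exact: the candidate grid is every midpoint between
consecutive sorted unique scores plus one threshold below the minimum and
one above the maximum, so the selected threshold provably maximizes
specificity among thresholds meeting the sensitivity target (ties → higher
threshold), and symmetrically for specificity targets. Unattainable
targets return the extreme threshold flagged `saturated`.

Shapley attribution is exact in both paths: XGBoost uses its internal
TreeSHAP (margin space); the other families use interventional Shapley
values computed by full enumeration of the 2⁵ feature subsets against a
background sample (probability space). Both satisfy the efficiency
(additivity) axiom to numerical precision, which the tests assert.

**Tier 2 — Freeze-Missing.** Each image branch is a 7×7 stride-2
convolution, 2×2 max-pool, and three Se-Conv blocks (a residual block with
a squeeze-and-excitation gate on the residual path:
`out = shortcut(F) + SE(conv-bn-relu-conv-bn(F))`). Image feature maps are
fused by one of four schemes — `mean`, `concat`, `seconv_mean`,
`seconv_concat` (default) — then globally pooled, concatenated with the
numerical-branch feature (a small MLP over the standardized five features)
and mapped to a sigmoid probability of the *serious* class.

Missing-modality mechanism: an absent branch is (a) zero-substituted on
the input side, (b) forced to an exactly-zero feature map before fusion,
and (c) frozen — its parameters receive exactly zero gradient from that
sample. Mechanically each branch processes only the samples that carry its
modality (gather) and the outputs are scattered into a zero tensor through
a constant selection matrix, so all three properties hold by construction
rather than by masking after the fact; batch-norm statistics are likewise
never updated from zero-substituted passes. Mean fusion under missingness
averages over the *present* branches only (renormalized). With all images
absent the model degrades gracefully to the numerical branch.

**Tier 3 — M³-VF.** Image branches: 7×7 stride-2 conv → batch-norm →
ReLU → 2×2 max-pool → nine CBAM-residual blocks (stride 2 at blocks 1 and
4, widths stepping through the configured triple) → 1×1 conv. CBAM applies
channel attention (shared two-layer bottleneck over average- and
max-pooled descriptors, sigmoid) then spatial attention (7×7 conv over the
channel-pooled 2-plane stack, sigmoid), sequentially. Each branch's pooled
map becomes one modality token; the numerical branch contributes a fourth.
Tokens are fused by a post-norm transformer encoder (multi-head scaled
dot-product attention + FFN, 1 layer by default) and an MLP softmax head
over the four stages. Ablations: `use_cbam=False`, `use_transformer=False`
(concatenation fusion), and single-stream variants (`global_only`,
`focused_only`, `rnfl_only`). This tier requires complete modalities and
raises an error directing incomplete samples to the pre-diagnosis tier.

Defaults for both networks: widths 32→64→128, SE/CBAM reduction r=8,
embedding D=128, 4 heads, 1 encoder layer, Adam lr 1e−4, batch 16, early
stopping on validation loss with patience 10, numerical features
standardized by train-split statistics. Every width is config-exposed; the
desk-scale settings used in the tests and the acceptance script are widths
(4,6,8), D=16, 2 heads, lr 1e−3, images 24–32 px, ≤10 epochs — sizes at
which a full training run takes seconds to tens of seconds on one CPU.

## The numpy autodiff engine

No GPU framework is assumed: `multiglau.nn` is a compact reverse-mode
autodiff on numpy arrays implementing exactly the operator set the
networks need (broadcast arithmetic, batched matmul, im2col convolution,
max-pooling, ReLU/sigmoid/exp/log, reductions, slicing, concatenation).
Gradients are validated against central finite differences (relative error
~1e−10 on every primitive) and the attention blocks against naive
re-implementations. `guided_relu_mode()` switches every ReLU's backward
rule to the guided-backpropagation variant.

## Staging

`stage_from_md` partitions the real line: early `md ≥ −6`, moderate
`[−12, −6)`, advanced `(−20, −12)`, severe `md ≤ −20`. The boundary at
−12 dB is assigned to moderate and −20 dB to severe: the explicit `≥ −6`
and `≤ −20` rules take priority at their boundaries, and the interval
conventions are documented rather than inferred. The binary pre-diagnosis
target collapses moderate/advanced/severe to *serious*, which equals
thresholding MD at −6 dB.

## Synthetic data: what it emulates and what it does not

One sample is one eye-visit. Glaucomatous samples draw a stage from the
class prior (proportional to 1198/655/535/1157), then MD uniformly inside
the stage's interval (severe truncated at −35 dB), so stage labels are
always derivable from MD. Age and IOP are Gaussians around the per-stage
means (58.0/62.5/62.4/61.4 y, sd 8; 18.64/20.88/22.71/25.79 mmHg, sd 2.5);
CDR rises (0.55/0.65/0.75/0.85, sd 0.07) and BCVA falls
(0.70/0.55/0.40/0.25, sd 0.12) with stage; the severe group's female
fraction is 0.4486 vs 0.55 elsewhere. Healthy samples (for the screening
task; default fraction 0.5, a balanced screening cohort) have lower
CDR/IOP and carry no MD. Within-stage MD is uniform because only group
means are known; the sd values are plausible clinical spreads chosen once.

Images are geometric phantoms: a textured background with a disc ellipse
and a cup whose diameter ratio equals the record's CDR (±0.01 noise); the
"focused" view is the polar transform of the global phantom about the disc
centre; the RNFL map is a banded image whose mean intensity falls linearly
with severity level, scaled by `signal_strength` (0 ⇒ no image signal).
Only these monotone relations are contractual — the phantoms share no
texture statistics with real fundus photographs or OCT maps, so passing
tests demonstrate that the *mechanisms* (fusion, freezing, attention,
staging) work, not that the architectures reach clinical accuracy on real
data.

Image missingness is MCAR: one Bernoulli(rate) draw per sample removes all
three modalities jointly (default, matching the clinical story of a site
lacking imaging equipment altogether); independent per-modality drop is
available via `joint_image_drop=False` since the mechanism is ambiguous.

## Preprocessing

The image stack is order-fixed: Lanczos resample (default 256×256, output
clipped to the input's value range to suppress ringing) → CLAHE (clip
limit expressed as a multiple of the mean histogram bin height, default
2.0, tiles 8×8) → polar transform for the focused flow → min-max
normalization to [0, 1]. CLAHE precedes the polar transform for the
focused flow; the order is a documented package choice. A constant image
min-max-normalizes to zeros (with a warning) rather than erroring, so
degenerate synthetic tiles survive.

The polar transform samples ring r, angle a at
`center + (r/rings)·radius·(cos θ_a, sin θ_a)`, θ_a = 2πa/angles, angle 0
along +col, counter-clockwise, bilinear, out-of-bounds → 0. The disc
centre and radius come from configuration — the synthetic generator knows
them exactly; real use must supply them (disc localization is out of
scope). An explicit inverse transform exists as the round-trip oracle
(in-disc mean absolute error < 3% of range on smooth images).

Tabular imputation: iterative per-column LightGBM regressions (missing
cells initialized at column means, swept until max change < 1e−4 or 10
sweeps), repeated 5 rounds with different stochastic seeds, final value =
round mean. Observed cells are never altered; a fully missing column is an
error naming the column.

## Evaluation

Accuracy (TP+TN)/n, sensitivity TP/(TP+FN), specificity TN/(TN+FP); a
zero denominator reports NaN, never 0. The four-class task reports
exact-match accuracy and macro (unweighted one-vs-rest) sensitivity/
specificity; multiclass AUC is the unweighted mean of one-vs-rest AUCs —
macro averaging is the package's documented choice where a single
multiclass number is needed. Binary positive class = *serious*. ROC/AUC
uses the rank (Mann–Whitney) tie convention and is tested against an
O(n²) pairwise oracle. Calibration uses 10 equal-width bins over [0, 1].
Net benefit at threshold t is TP/n − FP/n·t/(1−t) with treat-none (≡0)
and treat-all (π − (1−π)·t/(1−t)) references. The CV harness uses
stratified folds, reports per-fold/mean/sd, and selects the best fold by
accuracy.

## Saliency

GradCAM++ channel weights use the first/second/third-order gradient terms
(α = g²/(2g² + ΣA·g³), w_c = Σ α·relu(g)); the weighted activation sum is
ReLU-ed, bilinearly upsampled and min-max normalized. The default target
layer is the last convolution of the attributed branch. Guided backprop
propagates only where both the forward activation and the incoming
gradient are positive; non-ReLU activations (sigmoid gates) backpropagate
normally. The overlay is the normalized elementwise product of the region
and pixel maps.

## Numerical choices and degenerate inputs

- BCE/CE losses are clamped at 1e−9 inside the log.
- Max reductions send gradient to the first argmax on ties.
- Training is fully deterministic given the seed (numpy RNG only); the
  end-to-end pipeline derives every stage seed from one top-level seed.
- n-fold CV of the screening objective shrinks the fold count to the
  minority-class count when necessary and skips degenerate folds.
- All-zero saliency (constant-output head) normalizes to the zero map.

## Known limitations

- Phantom images are not photorealistic; nothing here validates clinical
  accuracy on real fundus/OCT data, and the private-cohort performance
  figures of the original clinical system are out of scope.
- Optic-disc localization, EMR/ICD-10 extraction, DICOM support, reader
  studies, and deployment tooling are out of scope.
- Whether two eyes of one patient should be treated as independent samples
  is unresolved; the package models one eye-visit per row.
- The screening tier's probability calibration to a real prevalence is not
  attempted.
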