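# Methods

This note documents the model conventions, the parameters that matter, the
synthetic data the experiments run on, and the limits of what desk-scale
results can show.

## Predictive-coding engine

**State.** A strictly sequential chain of L layers; layer i holds an
activation node `v_i`, a prediction `v̂_i = f_i(v_{i−1}; θ_i)` and an error
node `e_i = v̂_i − v_i` (error = prediction − actual throughout; every
objective coupling is sign-aligned to this convention).  A layer is either
an affine map (flatten → Wx+b → ReLU/identity → optional dropout) or a
convolution block (3×3 same-padding convolution → optional batch norm →
ReLU → 2×2 max-pool) treated as a single unit with one error node at its
output.

**Free energy.** `F = ½ Σ‖e_i‖²`, averaged over the minibatch.  The ½
factor is a deliberate convention: it makes the equilibrium PC update equal
the gradient of the standard ½-squared-error (and mean-cross-entropy) loss
with no factor-of-two mismatch.  Some presentations write the energy
without the ½; only the scale of `η_v`/`η_θ` changes.

**Inference (backward phase).** All unclamped activations take simultaneous
gradient steps `Δv_i = η_v(e_i − J_{i+1}ᵀe_{i+1})`, after which errors are
refreshed.  The input is always clamped; the output is either
value-clamped to the target (squared error) or error-clamped to the
objective's logit gradient (all other objectives).  Two modes:

* *Fixed predictions* (default): predictions, layer caches and Jacobians
  stay at their feedforward values; only `e_i = v̂_i − v_i` is refreshed.
  Iterated to convergence, the equilibrium errors are exactly the
  backpropagation deltas, so the local updates equal BP gradients — the
  equivalence the acceptance suite checks at 1e−6 relative error.
  Convergence is geometric with per-iteration factor (1−η_v); η_v = 1
  converges in L steps on a linear chain.
* *Re-evaluated predictions*: `v̂_i` is recomputed at the current
  activations each step (dropout masks and batch-norm statistics stay
  frozen at their forward-phase draws, so inference is deterministic given
  the forward pass).  This mode is true gradient descent on F, and F is
  non-increasing provided η_v is below the local curvature limit.  At
  η_v = 0.1 on random ReLU networks a few instances per hundred show
  ~1e−3 single-step increases when a step crosses a ReLU kink; at
  η_v = 0.05 descent is monotone on all tested instances.  The descent
  experiment therefore defaults to η_v = 0.05.

**Learning phase.** `dθ_i = −e_i · ∂f_i(v_{i−1}; θ_i)/∂θ_i`, computed from
layer-local quantities only and averaged over the batch; updates are
`θ ← θ + η_θ dθ` with optional multiplicative weight decay on the weight
matrices.  ReLU'(0) := 0.  Batch-norm running statistics are buffers, not
trained parameters.

**Defaults and their provenance.** 20 inference iterations per minibatch
(fixed-iteration convergence); η_v = 0.1 (not stated by the experimental
protocol this package follows; exposed in every config); incremental
training uses η_θ = 0.1 (PC) vs 0.05 (BP) with batch 64; long-tailed
training uses η_θ = 0.002 with weight decay 2e−4 and batch 128 for 100
epochs; few-shot training uses lr 1e−3 stepped ×0.1 every 20 epochs.  The
long-tailed protocol's "learning rate 0.002 + weight decay" and "weight
learning rate 0.1" cannot both be the weight update rate of a single
optimizer; this package reads 0.002 (+decay) as η_θ for that pipeline and
0.1 as η_v, which is consistent with η_v = 0.1 everywhere else.

**BP oracle.** `bp_gradient` is a hand-written reverse-order chain rule
over the same layer VJPs, validated against central finite differences
(≤1e−5 relative error, including conv/batch-norm/pooling blocks).  It is
both the equivalence oracle and the BP training baseline, so PC and BP
comparisons share every layer implementation.

## Architectures

* `make_mlp3`: 3 affine layers, 800 hidden units by default, ReLU, optional
  dropout on hidden layers (rate 0.5 where enabled; the protocol names
  dropout without a rate).
* `make_alexnet3`: three conv blocks with the fixed (64, 128, 256) channel
  plan plus one affine classifier.  Kernel 3×3 stride 1, 2×2 max-pool per
  block are package defaults (the protocol does not state them) and are
  configurable.
* `make_protonet4`: four identical batch-norm conv blocks (the standard
  prototypical-network encoder); the flattened block-4 output is the
  embedding (64-dim for 28×28 inputs at 64 channels).

Parameters initialize from U(−1/√fan_in, +1/√fan_in) with an explicit seed.

## Task pipelines

**Class-incremental learning.** Tasks partition the classes (`disjoint`:
2×half; `split`: 5×2 in label order); training is strictly sequential with
no access to past data (audited by an instrumented loader in the tests),
one shared classifier head over all classes, 10% seeded validation split
per task.  The plateau schedule divides the learning rate by 3 after five
consecutive epochs without validation-loss improvement, floored at 1e−4;
training stops early once the floor is reached.  Default 20 epochs per
task.  Per task the best-validation model is recorded, used for the
evaluation matrix, and training continues from it.  Both algorithms
default to the cross-entropy objective so the comparison isolates the
learning rule (the classic squared-error one-hot clamp is available but
degrades within-task retention for *both* rules, confounding the
comparison).  Two evaluation conventions are implemented: *within-task*
(argmax restricted to each task's own classes — the convention that
benchmark tables of this protocol report, where a fully forgotten binary
task reads ~50%) and *strict class-incremental* (argmax over all classes).
Consolidation variants: EWC (diagonal Fisher from per-sample squared
objective gradients, quadratic anchor λ/2·ΣF(θ−θ*)² added to each layer's
local update; λ = 100 default) and IMM (unweighted or Fisher-precision-
weighted parameter merging of per-task snapshots).

**Long-tailed recognition.** Per-class counts follow
`N_l = N_max·γ^{−(l−1)/(L_c−1)}`, floored with minimum 1 (the floor is the
convention of the standard long-tail benchmark generators; note that
⌊5000·100^{−4/9}⌋ = ⌊645.77⌋ = 645).  The endpoint ratio is exactly γ
before rounding.  Training subsamples per class with a seed; test sets
stay balanced.  The six objectives expose both a batch-mean value and a
per-sample logit gradient, so each trains identically under BP and under
PC via the output-error coupling; reduction identities (focal→CE, CB→focal,
LDAM→CE, balanced-softmax→CE) hold to machine precision.

**Few-shot recognition.** Episodes draw N classes, k support and q = 15
query items (q configurable) without replacement.  Prototypes are support
means; queries are scored by softmax over negative squared Euclidean
distances.  The episodic loss gradient reaches support embeddings through
the prototypes (÷k) and enters PC through the output error node of the
encoder.  Evaluation embeds the class bank once with the deterministic
encoder and samples episodes in embedding space (equivalent and ~50×
faster).  The chance-level control draws input-independent embeddings
fresh per episode, for which episode accuracy is exactly 100/N % in
expectation; a randomly *initialized* convolutional encoder, by contrast,
scores far above chance on any separable bank because random convolutional
features preserve input similarity — a point worth remembering when
reading "untrained" baselines.

## Synthetic data

Classes are smooth low-frequency random fields (seeded white noise,
Gaussian-filtered, standardized) with enforced minimum pairwise
separation; samples add isotropic Gaussian noise σ, optionally small
integer translations.  Determinism is bit-exact under a fixed seed.  IDX
and directory-of-PNG writers/readers let the synthetic data flow through
the same paths as real benchmark files.

Study conditions (fixed, used by tests, CLI and the acceptance script):

* *Incremental suite*: 10 classes, 8×8 single-channel, 200 train / 100
  test per class, hidden width 64, 5 seeds, σ = 3.5 — calibrated once so a
  single 2-class task trains to ≈90% accuracy.
* *Long-tailed suite*: same classes at σ = 1.5 (near-ceiling base
  difficulty, mirroring the regime of the digit benchmark where γ = 10
  accuracy is ≈97%); N_max = 200.  At this scale (~800 optimizer steps vs
  ~47,000 in the benchmark protocol) fixed published learning rates are
  out of their operating regime, so both algorithms select their weight
  learning rate from the same grid.
* *Few-shot suite*: 50 character classes × 20 variants, 16×16, σ = 1.0
  (untrained-encoder 5-way 1-shot accuracy ≈60%, leaving headroom for
  training), encoder with 16 channels (16-dim embedding).

What passing on this data does and does not show: the generator produces
statistically independent class templates, so cross-task *feature sharing*
— the property that makes real image classes interfere and makes
catastrophic forgetting graded rather than all-or-nothing — is largely
absent.  Gradient-level results (equivalence, descent, oracle agreement)
transfer directly to real data; the *relative* PC-vs-BP behaviour on
sequential tasks does not necessarily transfer in either direction (see
Limitations).

## Numerical choices

Float64 throughout.  Divergent inference (F beyond 1000×(F₀+1)) raises a
diagnostic error naming η_v and the iteration; non-finite node values name
the layer.  Max-pool ties resolve to the first maximum; odd spatial sizes
are floor-cropped.  Batch-norm ε = 1e−5, running-stat momentum 0.1.
Accuracies are reported to 2 decimals with round-half-up (the mean of the
printed pair 92.80/98.91 is 95.854999… in floating point and rounds to
95.85, matching the printed table cell; an exact 95.855 would round to
95.86 — the benchmark tables themselves are inconsistent at this digit).
Episode-accuracy intervals are 1.96·SE over episodes.

## Limitations

* Under the fixed-prediction assumption with 20 iterations and η_v = 0.1,
  PC's effective per-layer learning rates are ≈(0.62, 0.88, 1.0)·η_θ for a
  3-layer network — PC is close to a reparametrized BP.  On the synthetic
  incremental suite the two algorithms are statistically indistinguishable
  in final average accuracy and task-1 forgetting (differences of ~1–2
  points with seed-to-seed variation of the same size, in either
  direction).  The package reports both; a robust stability gap between
  the rules is not reproduced at this scale.
* The stability sweep's forgetting trend is only measurable under the
  strict class-incremental evaluation (head drift dominates); within-task
  forgetting on this suite is ~0 at every learning rate.
* Recurrent or branched graphs, generative/unsupervised PC, and
  VGG/ResNet-scale networks are out of scope; conv networks are plain
  NumPy (im2col) and sized accordingly.
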