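# Methods

## Problem and model

`modalmil` predicts a binary lesion phenotype (the motivating application
is microvascular invasion of hepatocellular carcinoma) from a stack of
axial MRI slices of one lesion seen in five co-registered sequences: T2,
arterial, venous, delay and ADC.  The lesion is treated as a
multiple-instance-learning (MIL) bag: the bag is positive iff at least one
slice carries the positive signal, so per-slice labels are never needed.

The network has three stages.

1. **Slice encoder.**  One weight-shared CNN encodes every slice of every
   modality.  Each of L blocks (default L = 5, channels 16, 32, 64, 128,
   256) is conv 3x3 (pad 1) → ReLU → batch norm → 2x2 max pool; at 64x64
   input and depth 5 the pre-flatten map is 256x2x2, flattened (1024) and
   projected by one fully connected layer to a 128-d embedding.  Depths
   3–7 are supported; pooling stops once the spatial side reaches 1 px, so
   depths 6–7 remain well defined.  The ReLU→BN order inside a block
   follows the stage listing of the original architecture description.

2. **Modality attention (squeeze / excite / reweight).**  For modality k
   with embedding matrix m_k (s x 128), the descriptor d_k is the grand
   mean of m_k (global average pooling).  A two-layer excitation network
   maps d ∈ R^5 to attention weights a = gate(W2 relu(W1 d + b1) + b2).
   The printed excitation formula carries no output nonlinearity; the
   SE-net family it derives from uses a sigmoid gate, so the default gate
   is sigmoid (softmax and identity are available).  The hidden width
   defaults to 5 — with only five modalities there is nothing to reduce.
   Fused instance embeddings are h_i = Σ_k a_k · m_k[i]; a weighted sum
   keeps the instance dimension at 128, which is the only reading
   consistent with the stated 1x128 fused feature size.

3. **Dual-stream aggregator.**  The instance stream scores every h_i with
   a bias-free linear classifier W0 and max-pools: c_m = max_i W0 h_i; the
   argmax slice (lowest index on ties) is the critical instance h_m.  The
   bag stream forms queries q_i = Wq h_i and information vectors
   v_i = Wv h_i, measures the similarity of every instance to the critical
   one as the **cosine** of their queries,
   U_i = softmax_i(cos(q_i, q_m)) (max-subtracted softmax), builds the
   bag embedding b = Σ U_i v_i and scores it c_b = Wb b.  The bag logit is
   c(B) = (c_m + c_b)/2 and the predicted probability is sigmoid(c(B)).
   W0, Wq, Wv, Wb carry no biases, exactly as the aggregation equations
   are written; all other linear layers have biases.

   Cosine rather than raw inner product is deliberate: with 64–128-d
   queries at any reasonable weight scale, raw inner products reach
   magnitudes of hundreds, so the similarity softmax is born one-hot and
   its gradient vanishes — the bag stream then never trains (we observed
   exactly this: the full model underperformed the mean-pool baseline
   until the similarity was bounded).  The cosine keeps similarities in
   [-1, 1] and the stream trainable, and is how the method's own
   description characterizes the query comparison.

Ablation switches reduce the model to the literature baselines: without
attention every modality gets the fixed weight 1/5; without the aggregator
the bag logit is the mean of the instance scores (mean-pool MIL).  With
both off the model is the plain benchmark CNN.

Weight initialization is fan-in He/LeCun normal, except the two scalar
score heads W0 and Wb, which start near zero so initial bag logits sit
close to 0 (probability ~0.5) rather than deep in the sigmoid tails; with
one-bag batches this markedly stabilizes early training.

### Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over numpy arrays (`modalmil.nn`) with exactly
the operations the model needs (im2col convolution, batch norm with running
statistics, max pooling, linear maps, softmax, stable
binary-cross-entropy-on-logits) and an Adam optimizer.  All arithmetic is
float64.  Gradients of every nontrivial operation, and of the full
composed network, are verified against central finite differences in the
test suite.

## Preprocessing

Per case: (i) crop all five volumes to the in-plane bounding box of the
lesion mask expanded by `margin_mm` (default 10 mm, converted per axis via
the pixel spacing, clipped at the volume edge), keeping only slices with
nonzero mask; (ii) z-score each slice (population sd; constant slices map
to zeros); (iii) bilinear-resample to 64x64 (no anti-alias filter, so an
exact 2x reduction equals 2x2 average pooling); (iv) re-standardize, so
every network input slice has mean 0, sd 1 regardless of resampling
artifacts.  The margin is applied in-plane only — through-plane context is
already captured by keeping all lesion slices.  Crop boxes are 0-based
half-open intervals.

Training-time augmentation applies an independent horizontal and vertical
flip, each with probability 0.5, identically to every slice of every
modality of the bag (instances of one lesion stay anatomically aligned);
an optional 90° rotation flag exists but is off by default.  Augmentation
is re-drawn every epoch.

## Training protocol

Adam, learning rate 1e-4, weight decay 5e-3 (the "decay rate" is read as
L2 weight decay, its usual meaning next to Adam; an exponential lr-decay
mode is available), binary cross-entropy on the bag logit, one bag per
optimizer step (variable slice counts forbid larger batches), 100 epochs
by default.  All randomness (shuffling, augmentation, weight init) derives
from explicit seeds; two CPU runs with the same seed are identical.

Model selection is `best_val` by default: the checkpoint with the highest
validation AUC is restored after training.  This matters beyond
convention.  With a one-bag batch, training-mode batch-norm statistics are
per-bag statistics, so the network can exploit bag-level information that
is unavailable at evaluation time (running statistics); occasionally a run
fits the training set perfectly while its eval-mode predictions collapse.
Validation AUC is computed in eval mode, so best-val selection discards
such checkpoints.  A `final` mode is available.

## Evaluation protocol

Stratified 5-fold cross-validation implements the 4:1 train:test split:
each fold serves once as the held-out fifth.  Reported per fold, as
mean ± sd across folds, and pooled over concatenated held-out scores (both
aggregations are reported because either convention is common).  Metrics:
accuracy, sensitivity, specificity, PPV, NPV at a fixed probability
threshold of 0.5 (0/0 cells are reported as NaN with a warning), and AUC
with a 95% DeLong CI (midrank Mann–Whitney estimate; variance from the
structural components; CI = AUC ± 1.96 sd clipped to [0, 1]).  Models
sharing folds are compared with a two-sided paired t-test; identical
per-fold vectors return p = 1.  The ablation harness trains benchmark,
+attention, +aggregator and full variants on matched folds; the depth
sweep does the same across encoder depths 3–7.

## Synthetic lesion phantoms

The real cohort behind the method is private, so the package ships a
generator whose output exercises every mechanism the model claims:

* ellipsoidal lesion mask over s slices (s uniform on [3, 8]), in a 96x96
  field of view, 1 mm in-plane / 5 mm through-plane spacing (so the 10 mm
  margin rule is anisotropic in pixels);
* five modality volumes of i.i.d. Gaussian noise (sd 1);
* positive bags receive a Gaussian intensity blob (sigma = 6 px, amplitude
  5 by default) at a random in-mask location on max(1, round(0.5·s))
  witness slices; the blob is scaled per modality by the arterial-dominant
  weights (0.3, 1.0, 0.7, 0.4, 0.5) for (T2, arterial, venous, delay,
  ADC), mirroring the reported single-modality performance ordering;
  negative bags receive no blob anywhere.

Labels are therefore exactly MIL-consistent, the informative modality is
known (arterial), and the informative slices are known — so attention
recovery and witness localization are testable with ground truth.  The
default 100-case balanced cohort with 5:1 signal:noise is the standard
study condition in the tests.

What the phantoms do **not** emulate: MR contrast physics and realistic
texture, inter-modality registration error, scanner/protocol variation,
lesion-size/label confounds, and realistic class overlap.  Passing tests
show the pipeline recovers planted structure under the MIL assumption;
they say nothing about clinical performance on real cohorts.

## Scaled test conditions

The acceptance-style tests and `scripts/acceptance.py` run the full
pipeline at reduced problem size so one CPU completes them in minutes:
32x32 slices, a depth-3 encoder (channels 8, 16, 32, 64-d embedding),
learning rate 1e-3 with 10–25 epochs, cohorts of 60–100 bags, and 3-fold
cross-validation in the ablation.  The higher learning rate compensates
for the shorter schedule at this reduced width; all other protocol choices
(optimizer, weight decay, batch of one bag, augmentation, best-val
selection) are the defaults above.  The mechanism checks (attention
dominance, witness localization) read the final-epoch weights of the same
runs, i.e. the fully trained network; the no-signal null check scores a
50-case test half so its AUC estimate is tight around chance.

The ablation comparison (full model vs mean-pool benchmark) uses a
rare-witness cohort: exactly one signal slice per positive bag of 5–8
slices at 3:1 signal:noise.  This is a design requirement, not a
convenience.  At the default 5:1 amplitude with half the slices carrying
signal, *every* aggregation scheme reaches AUC ~1.0 and a component
comparison is degenerate; and when witnesses are common, mean pooling is
near-optimal by construction.  The dual-stream aggregator's claimed
advantage — weighting instances by similarity to the critical instance —
can only show where witness slices are a small minority, which is the
regime the real clinical task (AUC ~0.74, heterogeneous lesions) plausibly
occupies.

## Known limitations

* Batch norm with one-bag batches couples instances at training time (see
  above); best-val selection mitigates but does not remove the effect.
* The DeLong CI is asymptotic; with very few cases per fold it can touch
  the [0, 1] clip.
* The mean-pool benchmark is one of several defensible readings of
  "remove the aggregator"; max-pool-only is obtainable by disabling only
  the attention module and reading c_m.
* Checkpoints store float64 weights; files are a few MB at default width.
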