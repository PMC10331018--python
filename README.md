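# modalmil

Modality-attention, dual-stream multiple-instance learning for classifying
lesions from multi-sequence 3D MRI.

## The problem

Some lesion phenotypes — the motivating one is microvascular invasion
(MVI) of hepatocellular carcinoma — are confirmed only by postoperative
pathology, yet predicting them preoperatively from MRI would change
surgical planning.  Radiologists solve this by scanning *all* slices of a
lesion across *several* MRI sequences, leaning on the most informative
sequence and the most suspicious slices.  `modalmil` implements that
reading process as a weakly supervised network for researchers working on
lesion-level prediction from multi-parametric MRI.

A patient's lesion is a multiple-instance-learning (MIL) **bag**
B = {x_1, …, x_s}: its s axial slices, each seen in five co-registered
sequences (T2, arterial, venous, delay, ADC).  Only the bag label is
known, and a bag is positive iff at least one slice is positive:
c(B) = 0 iff Σ y_i = 0, else 1.

The model composes three parts:

* **Shared slice encoder** — a small CNN (five conv 3x3 → ReLU → batch
  norm → 2x2 max-pool blocks; 16…256 channels) embedding every 64x64
  slice into h ∈ R^128;
* **Modality attention** — squeeze each modality's embedding matrix m_k to
  a descriptor d_k by global average pooling, excite
  a = σ(W₂ relu(W₁ d)), and fuse m̃_i = Σ_k a_k m_k[i];
* **Dual-stream aggregator** — instance stream
  c_m = max_i W₀ h_i (the argmax slice is the *critical instance* h_m);
  bag stream U_i = softmax cos(W_q h_i, W_q h_m), b = Σ U_i W_v h_i,
  c_b = W_b b.  Final bag score c(B) = (c_m + c_b)/2.

The attention vector `a` and slice weights `U` are returned with every
prediction, so the model explains *which sequence* and *which slices*
drove each call.  Training follows the original protocol: Adam (lr 1e-4,
weight decay 5e-3), binary cross-entropy, one bag per step, stratified
5-fold cross-validation with accuracy/sensitivity/specificity/PPV/NPV and
DeLong AUC confidence intervals.  Because the clinical cohort behind the
method is private, the package ships a phantom generator that plants
known MIL structure (witness slices, arterial-dominant informativeness)
so every mechanism is testable end to end.  The numerical core is a
self-contained numpy autodiff engine — no GPU or deep-learning framework
required.

## Worked example

```python
import modalmil as mm

# 1. a synthetic cohort: 100 bags, half positive, arterial-dominant signal
cohort = mm.generate_cohort(mm.PhantomConfig(n_cases=100, seed=11))

# 2. crop to the lesion ROI (+10 mm margin), z-score, resize
bags = mm.prepare_cohort(cohort, mm.PreprocessConfig(target_size=32))

# 3. train a scaled-down model (depth-3 encoder) on 80 bags
ext = mm.ExtractorConfig(n_conv_layers=3, channels=(8, 16, 32),
                         embed_dim=64, input_size=32)
net = mm.MILNet(ext, seed=1)
cfg = mm.TrainConfig(lr=1e-3, epochs=15, model_selection="final", seed=1)
result = mm.train(net, bags[:80], cfg)
print(f"loss {result.loss_history[0]:.3f} -> {result.loss_history[-1]:.3f}")

# 4. held-out predictions with diagnostics
preds = mm.predict(net, bags[80:])
print(preds[["case_id", "label", "probability"]].head(3))
rep = mm.full_metrics(preds["label"], preds["probability"])
print(f"AUC {rep.auc:.3f} (95% CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f})")
```

output (deterministic for these seeds):

```
loss 0.397 -> 0.001
    case_id  label  probability
0  case_080      0     0.033052
1  case_081      0     0.061957
2  case_082      1     0.999981
AUC 1.000 (95% CI 1.000-1.000)
```

The training loss falls to near zero and the 20 held-out bags are ranked
perfectly: the network recovers the planted bag labels from witness
slices alone.  `preds` also carries the attention weights (`a_arterial`,
…) and per-slice similarity weights `U` for interpretability.

The same pipeline is scriptable from the shell:

```bash
modalmil simulate --n-cases 100 --seed 7 --out data/
modalmil preprocess --manifest data/manifest.csv --out prep/
modalmil cv --prepared prep/index.csv --seed 7 --out cv_out/
modalmil ablate --prepared prep/index.csv --seed 7 --out ablation/
```

Every command writes a run-manifest JSON (config snapshot, seeds,
artifacts) sufficient to re-run it bit-compatibly.

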