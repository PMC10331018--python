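"""Optimization protocol: Adam on binary cross-entropy, one bag per step.

Bags have variable slice counts, so the batch is a single bag per
optimizer step.  The default hyperparameters are Adam at learning rate
1e-4 with weight decay 5e-3 for 100 epochs; augmentation (bag-level
random flips) is re-drawn every epoch.  Model selection is either the
final epoch or the checkpoint with the best validation AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model import MILNet
from .preprocess import PreparedBag, PreprocessConfig, augment_bag


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 5e-3
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    augment: bool = True
    augment_prob: float = 0.5
    lr_decay: str = "none"        # "none" | "exp" (per-epoch multiplicative)
    lr_decay_rate: float = 5e-3   # used when lr_decay == "exp"
    model_selection: str = "best_val"  # "best_val" | "final"
    device: str = "cpu"

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("variable slice counts require batch_size == 1")
        if self.model_selection not in ("best_val", "final"):
            raise ValueError("model_selection must be best_val or final")
        if self.lr_decay not in ("none", "exp"):
            raise ValueError("lr_decay must be none or exp")
        if self.device != "cpu":
            raise ValueError("only cpu execution is available")


@dataclass
class TrainResult:
    loss_history: list[float]
    val_auc_history: list[float]
    best_state: dict
    final_state: dict
    best_epoch: int


def _bag_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    from .evaluation import auc_delong
    if len(np.unique(labels)) < 2:
        return float("nan")
    return auc_delong(labels, scores).auc


def train(model: MILNet, train_bags: list[PreparedBag], config: TrainConfig,
          val_bags: list[PreparedBag] | None = None) -> TrainResult:
    """Fit the model in place; returns loss/validation history and checkpoints."""
    config.validate()
    if not train_bags:
        raise ValueError("empty training set")
    labels = {b.label for b in train_bags}
    if labels != {0, 1}:
        raise ValueError(f"training set must contain both classes, got {labels}")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)
    aug_cfg = PreprocessConfig(augment=config.augment,
                               augment_prob=config.augment_prob)
    loss_history: list[float] = []
    val_history: list[float] = []
    best_auc, best_state, best_epoch = -np.inf, None, -1
    order = np.arange(len(train_bags))
    for epoch in range(config.epochs):
        if config.lr_decay == "exp":
            opt.lr = config.lr * (1.0 - config.lr_decay_rate) ** epoch
        rng.shuffle(order)
        losses = []
        for i in order:
            bag = train_bags[i]
            if config.augment:
                bag = augment_bag(bag, rng, aug_cfg)
            out = model.forward_bag(bag.slices, training=True)
            loss = nn.bce_with_logits(out.logit, float(bag.label))
            lv = float(loss.value)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, case {bag.case_id}; "
                    "lower the learning rate or check the inputs")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        loss_history.append(float(np.mean(losses)))
        if val_bags:
            preds = predict(model, val_bags)
            auc = _bag_auc(np.array([b.label for b in val_bags]),
                           preds["probability"].to_numpy())
            val_history.append(auc)
            if config.model_selection == "best_val" and auc > best_auc:
                best_auc, best_epoch = auc, epoch
                best_state = model.get_state()

    final_state = model.get_state()
    if best_state is None:
        best_state, best_epoch = final_state, config.epochs - 1
    if config.model_selection == "best_val" and val_bags:
        model.set_state(best_state)
    return TrainResult(loss_history=loss_history, val_auc_history=val_history,
                       best_state=best_state, final_state=final_state,
                       best_epoch=best_epoch)


def predict(model: MILNet, bags: list[PreparedBag]):
    """Eval-mode predictions with interpretability diagnostics.

    Returns a DataFrame with one row per case: predicted probability,
    modality-attention weights a, the critical slice index and the
    similarity weights U over slices.
    """
    import pandas as pd

    from .model import MODALITY_NAMES
    rows = []
    for bag in bags:
        out = model.forward_bag(bag.slices, training=False)
        row = {"case_id": bag.case_id, "label": bag.label,
               "probability": out.probability,
               "logit": out.aggregation.c_final,
               "critical_index": out.aggregation.critical_index}
        for name, a in zip(MODALITY_NAMES, out.attention.a):
            row[f"a_{name}"] = float(a)
        row["U"] = out.aggregation.U.tolist()
        rows.append(row)
    return pd.DataFrame(rows)
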