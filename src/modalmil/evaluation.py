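"""Evaluation protocol: confusion metrics, DeLong AUC confidence intervals,
stratified 5-fold cross-validation, fold-paired model comparison, and the
ablation harness over the attention / dual-stream components.

The cohort is split 4:1 into train and test five times (stratified k-fold),
so every case is tested exactly once; metrics are reported per fold, as
mean +/- sd over folds, and pooled over the concatenated held-out scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .preprocess import PreparedBag

METRIC_COLUMNS = ["accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"]


# ---------------------------------------------------------------------------
# confusion-table metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_pos: int
    n_neg: int
    threshold: float
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv,
                "npv": self.npv, "auc": self.auc,
                "auc_ci_lo": self.auc_ci[0], "auc_ci_hi": self.auc_ci[1],
                "n_pos": self.n_pos, "n_neg": self.n_neg,
                "threshold": self.threshold}


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0 at this threshold); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Accuracy/sensitivity/specificity/PPV/NPV from the 2x2 table."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    return MetricsReport(
        accuracy=(tp + tn) / len(labels),
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        ppv=_safe_ratio(tp, tp + fp, "ppv"),
        npv=_safe_ratio(tn, tn + fn, "npv"),
        n_pos=tp + fn, n_neg=tn + fp, threshold=threshold)


# ---------------------------------------------------------------------------
# DeLong AUC
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    auc: float
    variance: float
    ci95: tuple[float, float]


def auc_delong(labels, scores) -> DeLongResult:
    """Mann-Whitney AUC with DeLong variance and 95% CI.

    The AUC is the midrank (tie-corrected) Mann-Whitney statistic; its
    variance comes from the DeLong structural components V10 (one per
    positive) and V01 (one per negative).  The CI is auc +/- 1.96 sd,
    clipped to [0, 1].
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("DeLong AUC needs at least one case of each class")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # structural components: V10_i = P(pos_i outranks a random negative)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0.0, 1.0)),
          float(np.clip(auc + half, 0.0, 1.0)))
    return DeLongResult(auc=auc, variance=var, ci95=ci)


def full_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    rep = confusion_metrics(labels, scores, threshold)
    dl = auc_delong(labels, scores)
    rep.auc = dl.auc
    rep.auc_ci = dl.ci95
    return rep


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of case_ids to k test folds."""

    k: int
    assignments: dict
    seed: int
    stratified: bool = True

    def test_ids(self, fold: int) -> list:
        return [cid for cid, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [cid for cid, f in self.assignments.items() if f != fold]


def make_folds(case_ids, labels, k: int = 5, seed: int = 0) -> FoldPlan:
    case_ids = list(case_ids)
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(case_ids)), labels)):
        for i in test_idx:
            assignments[case_ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame      # one row per fold
    pooled: MetricsReport           # metrics on concatenated held-out scores
    predictions: pd.DataFrame       # per-case held-out predictions
    fold_plan: FoldPlan

    @property
    def mean_auc(self) -> float:
        return float(self.fold_metrics["auc"].mean())

    def summary(self) -> pd.DataFrame:
        agg = self.fold_metrics[METRIC_COLUMNS].agg(["mean", "std"])
        pooled = pd.Series({c: getattr(self.pooled, c) for c in METRIC_COLUMNS},
                           name="pooled")
        return pd.concat([agg, pooled.to_frame().T])


def run_cv(bags: list[PreparedBag], model_factory, train_config,
           fold_plan: FoldPlan | None = None, k: int = 5, seed: int = 0,
           val_fraction: float = 0.2, threshold: float = 0.5) -> CVResult:
    """Train/evaluate on each of k stratified folds (4:1 train:test at k=5).

    ``model_factory(fold) -> model`` builds a fresh model per fold; a model
    may also be any object with a ``predict_scores(bags)`` method (used for
    oracle tests).  When the training config selects best_val, a stratified
    ``val_fraction`` of the training fold is held out for model selection.
    """
    from .training import TrainConfig, predict, train

    by_id = {b.case_id: b for b in bags}
    labels = {b.case_id: b.label for b in bags}
    if fold_plan is None:
        ids = [b.case_id for b in bags]
        fold_plan = make_folds(ids, [labels[i] for i in ids], k=k, seed=seed)
    rows, pred_frames = [], []
    for fold in range(fold_plan.k):
        test = [by_id[i] for i in fold_plan.test_ids(fold)]
        trainset = [by_id[i] for i in fold_plan.train_ids(fold)]
        test_labels = np.array([b.label for b in test])
        if len(np.unique(test_labels)) < 2:
            raise ValueError(f"fold {fold} has a single-class test set; "
                             "use a stratified fold plan")
        model = model_factory(fold)
        if hasattr(model, "predict_scores"):
            scores = np.asarray(model.predict_scores(test), dtype=float)
            preds = pd.DataFrame({"case_id": [b.case_id for b in test],
                                  "label": test_labels,
                                  "probability": scores})
        else:
            cfg = train_config
            val = None
            if isinstance(cfg, TrainConfig) and cfg.model_selection == "best_val":
                tr_labels = [b.label for b in trainset]
                tr_idx, val_idx = train_test_split(
                    np.arange(len(trainset)), test_size=val_fraction,
                    stratify=tr_labels, random_state=cfg.seed + fold)
                val = [trainset[i] for i in val_idx]
                trainset = [trainset[i] for i in tr_idx]
            train(model, trainset, cfg, val_bags=val)
            preds = predict(model, test)
        rep = full_metrics(preds["label"].to_numpy(),
                           preds["probability"].to_numpy(), threshold)
        row = {"fold": fold, **rep.as_dict()}
        rows.append(row)
        preds = preds.assign(fold=fold)
        pred_frames.append(preds)
    all_preds = pd.concat(pred_frames, ignore_index=True)
    pooled = full_metrics(all_preds["label"].to_numpy(),
                          all_preds["probability"].to_numpy(), threshold)
    return CVResult(fold_metrics=pd.DataFrame(rows), pooled=pooled,
                    predictions=all_preds, fold_plan=fold_plan)


# ---------------------------------------------------------------------------
# model comparison and ablation
# ---------------------------------------------------------------------------

def compare_models(metrics_a, metrics_b) -> dict:
    """Two-sided paired t-test on per-fold metric values.

    Folds are shared between the two models, so the comparison is paired.
    Identical vectors (zero difference everywhere) return p = 1.0.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-fold metric vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 folds for a paired t-test")
    d = a - b
    if np.allclose(d, 0.0):
        return {"p_value": 1.0, "t_statistic": 0.0, "significant": False}
    t, p = stats.ttest_rel(a, b)
    return {"p_value": float(p), "t_statistic": float(t),
            "significant": bool(p < 0.05)}


ABLATION_VARIANTS = (
    ("benchmark", False, False),
    ("attention", True, False),
    ("aggregator", False, True),
    ("full", True, True),
)


def run_ablation(bags: list[PreparedBag], train_config, extractor_config=None,
                 k: int = 5, seed: int = 0, model_seed: int = 0) -> dict:
    """Cross-validate the 4 component variants on matched folds.

    Variants: benchmark (uniform modality weights + mean-pooled instance
    scores), +attention, +aggregator, and the full model.  Returns a dict
    with a 4x6 metrics table (fold means) and the per-variant CVResults.
    """
    from .model import ExtractorConfig, MILNet

    ids = [b.case_id for b in bags]
    labels = [b.label for b in bags]
    plan = make_folds(ids, labels, k=k, seed=seed)
    ext = extractor_config or ExtractorConfig()
    results, rows = {}, []
    for name, att, agg in ABLATION_VARIANTS:
        def factory(fold, _att=att, _agg=agg):
            return MILNet(ext, use_attention=_att, use_aggregator=_agg,
                          seed=model_seed + fold)
        res = run_cv(bags, factory, train_config, fold_plan=plan)
        results[name] = res
        rows.append({"variant": name, "attention": att, "aggregator": agg,
                     **{c: res.fold_metrics[c].mean() for c in METRIC_COLUMNS}})
    table = pd.DataFrame(rows).set_index("variant")
    return {"table": table, "results": results, "fold_plan": plan}


def depth_sweep(bags: list[PreparedBag], depths, train_config,
                base_extractor=None, k: int = 5, seed: int = 0,
                model_seed: int = 0) -> pd.DataFrame:
    """Cross-validate the extractor depth on matched folds; one row per depth."""
    import dataclasses

    from .model import ExtractorConfig, MILNet

    base = base_extractor or ExtractorConfig()
    for d in depths:
        cfg = dataclasses.replace(base, n_conv_layers=int(d), channels=None)
        cfg.validate()   # fail fast before any training
    ids = [b.case_id for b in bags]
    labels = [b.label for b in bags]
    plan = make_folds(ids, labels, k=k, seed=seed)
    rows = []
    for d in depths:
        cfg = dataclasses.replace(base, n_conv_layers=int(d), channels=None)

        def factory(fold, _cfg=cfg):
            return MILNet(_cfg, seed=model_seed + fold)
        res = run_cv(bags, factory, train_config, fold_plan=plan)
        rows.append({"depth": int(d),
                     **{c: res.fold_metrics[c].mean() for c in METRIC_COLUMNS}})
    return pd.DataFrame(rows)
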