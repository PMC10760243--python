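"""Cross-validation, training protocol, metrics and model comparison.

Splitting is stratified Monte Carlo (repeated random sub-sampling): each
fold is an independent stratified draw of validation and test cohorts,
not a partition of the sample.  With the floor rule, validation and test
each get floor(n / n_folds) subjects and training keeps the remainder —
which reproduces the printed (350, 58, 58) split of a 466-subject binary
cohort; explicit cohort sizes cover designs that deviate from the floor
rule (e.g. 95/95 out of 730, leaving 540 for training).

Training minimizes cross-entropy with Adam, halves the learning rate when
validation accuracy plateaus, stops early after a patience of epochs
without improvement, and restores the best-validation-epoch parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from . import nn
from .model import ClassifierModel, ModelConfig, build_model

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "FoldMetrics",
    "make_split_plan",
    "train_model",
    "evaluate",
    "aggregate_folds",
    "chi_squared_compare",
    "grid_search",
    "cross_validate",
    "DEFAULT_LR_GRID",
    "DEFAULT_BATCH_GRID",
]

DEFAULT_LR_GRID = (0.1, 0.01, 0.001, 0.0001, 0.00001)
DEFAULT_BATCH_GRID = (4, 8, 16, 32, 64)

METRIC_NAMES = ("test_accuracy", "balanced_accuracy", "f1", "precision", "recall", "auc")


@dataclass
class SplitPlan:
    """Repeated stratified train/validation/test assignments."""

    n_folds: int
    folds: list[dict[str, list]]  # keys: train, val, test (subject ids)
    seed: int
    cohort_size_rule: str

    def __post_init__(self) -> None:
        for i, fold in enumerate(self.folds):
            ids = fold["train"] + fold["val"] + fold["test"]
            if len(set(ids)) != len(ids):
                raise ValueError(f"fold {i}: train/val/test overlap")


def _stratified_counts(class_sizes: dict, total: int, n: int) -> dict:
    """Largest-remainder allocation of ``total`` slots across classes."""
    shares = {c: size * total / n for c, size in class_sizes.items()}
    counts = {c: int(np.floor(s)) for c, s in shares.items()}
    leftover = total - sum(counts.values())
    by_frac = sorted(shares, key=lambda c: (shares[c] - counts[c], str(c)), reverse=True)
    for c in by_frac[:leftover]:
        counts[c] += 1
    return counts


def make_split_plan(
    labels: Sequence,
    n_folds: int = 8,
    rule: str = "floor_n_over_folds",
    val_size: Optional[int] = None,
    test_size: Optional[int] = None,
    seed: int = 0,
    subject_ids: Optional[Sequence] = None,
) -> SplitPlan:
    """Draw ``n_folds`` independent stratified sub-samples.

    ``rule="floor_n_over_folds"`` sizes validation and test at
    floor(n / n_folds) each; ``rule="explicit"`` uses ``val_size`` and
    ``test_size``.  Per-class proportions in each cohort match the full
    sample within one subject (largest-remainder rounding).
    """
    labels = list(labels)
    n = len(labels)
    ids = list(subject_ids) if subject_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("subject_ids and labels length mismatch")
    class_idx: dict = {}
    for i, lab in enumerate(labels):
        class_idx.setdefault(lab, []).append(i)
    for c, members in class_idx.items():
        if len(members) < n_folds:
            raise ValueError(f"class {c!r} has {len(members)} subjects < n_folds={n_folds}")
    if rule == "floor_n_over_folds":
        v = t = n // n_folds
    elif rule == "explicit":
        if val_size is None or test_size is None:
            raise ValueError("explicit rule needs val_size and test_size")
        v, t = val_size, test_size
    else:
        raise ValueError(f"unknown cohort size rule {rule!r}")
    if v + t >= n:
        raise ValueError(f"validation+test ({v}+{t}) leave no training subjects out of {n}")

    class_sizes = {c: len(m) for c, m in class_idx.items()}
    val_counts = _stratified_counts(class_sizes, v, n)
    test_counts = _stratified_counts(class_sizes, t, n)
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        tr: list = []
        va: list = []
        te: list = []
        for c in sorted(class_idx, key=str):
            perm = rng.permutation(class_idx[c])
            nv, nt = val_counts[c], test_counts[c]
            va += [ids[i] for i in perm[:nv]]
            te += [ids[i] for i in perm[nv:nv + nt]]
            tr += [ids[i] for i in perm[nv + nt:]]
        folds.append({"train": tr, "val": va, "test": te})
    return SplitPlan(n_folds=n_folds, folds=folds, seed=seed, cohort_size_rule=rule)


@dataclass
class TrainConfig:
    """Optimization protocol for one model fit."""

    learning_rate: float = 0.001
    batch_size: int = 8
    max_epochs: int = 100
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    plateau_min_delta: float = 1e-4
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _batched_accuracy(model: ClassifierModel, x: np.ndarray, y: np.ndarray,
                      batch_size: int) -> float:
    model.eval_mode()
    correct = 0
    for i in range(0, len(x), batch_size):
        correct += int((model.predict(x[i:i + batch_size]) == y[i:i + batch_size]).sum())
    return correct / len(x)


def train_model(
    model: ClassifierModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Fit; return the model at its best validation epoch plus a history.

    History columns: epoch, train_loss, val_accuracy, learning_rate.
    Raises FloatingPointError with the epoch if the loss diverges.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net, lr=cfg.learning_rate)
    best_acc = -np.inf
    best_state = model.net.state()
    epochs_since_best = 0
    plateau_counter = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        model.train_mode()
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            model.net.zero_grad()
            logits = model.net.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_acc = _batched_accuracy(model, x_val, y_val, cfg.batch_size)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_accuracy": val_acc, "learning_rate": opt.lr})
        if val_acc > best_acc + cfg.plateau_min_delta:
            best_acc = val_acc
            best_state = model.net.state()
            epochs_since_best = 0
            plateau_counter = 0
        else:
            epochs_since_best += 1
            plateau_counter += 1
            if plateau_counter >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                plateau_counter = 0
        if epochs_since_best >= cfg.early_stop_patience:
            break
    model.net.load_state(best_state)
    model.eval_mode()
    return model, pd.DataFrame(rows)


@dataclass
class FoldMetrics:
    """Per-fold test metrics on the 0-100 scale, plus the confusion matrix."""

    fold_id: int
    test_accuracy: float
    balanced_accuracy: float
    f1: float
    precision: float
    recall: float
    auc: float
    confusion: np.ndarray = field(repr=False, default=None)
    n_test: int = 0
    n_correct: int = 0

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def evaluate(
    model: ClassifierModel,
    x_test: np.ndarray,
    y_test: np.ndarray,
    class_names: Sequence[str],
    fold_id: int = 0,
    batch_size: int = 16,
) -> FoldMetrics:
    """Accuracy, balanced accuracy, macro F1/precision/recall and AUC.

    Balanced accuracy is the mean of per-class recalls; F1/precision/
    recall are macro-averaged.  AUC uses the softmax scores: the
    positive-class ROC area for two classes (positive = "AD" when
    present), macro one-vs-rest for three.  Every class must appear in
    the test set, otherwise the balanced metrics are undefined and an
    error is raised.
    """
    if len(x_test) == 0:
        raise ValueError("empty test set")
    n_classes = len(class_names)
    present = set(np.unique(y_test).tolist())
    missing = [class_names[i] for i in range(n_classes) if i not in present]
    if missing:
        raise ValueError(f"class(es) absent from the test set: {missing}")
    model.eval_mode()
    scores = np.concatenate(
        [model.predict_proba(x_test[i:i + batch_size]) for i in range(0, len(x_test), batch_size)]
    )
    y_pred = scores.argmax(axis=1)
    labels = list(range(n_classes))
    if n_classes == 2:
        pos = class_names.index("AD") if "AD" in class_names else 1
        auc = roc_auc_score(y_test == pos, scores[:, pos])
    else:
        auc = roc_auc_score(y_test, scores, multi_class="ovr", average="macro", labels=labels)
    return FoldMetrics(
        fold_id=fold_id,
        test_accuracy=100.0 * accuracy_score(y_test, y_pred),
        balanced_accuracy=100.0 * balanced_accuracy_score(y_test, y_pred),
        f1=100.0 * f1_score(y_test, y_pred, average="macro", labels=labels, zero_division=0),
        precision=100.0 * precision_score(y_test, y_pred, average="macro", labels=labels, zero_division=0),
        recall=100.0 * recall_score(y_test, y_pred, average="macro", labels=labels, zero_division=0),
        auc=100.0 * float(auc),
        confusion=confusion_matrix(y_test, y_pred, labels=labels),
        n_test=len(y_test),
        n_correct=int((y_pred == y_test).sum()),
    )


def aggregate_folds(folds: Sequence[FoldMetrics]) -> pd.DataFrame:
    """Mean and sample standard deviation per metric, with "m ± s" strings."""
    if len(folds) < 2:
        raise ValueError("fold aggregation needs at least 2 folds")
    rows = []
    for metric in METRIC_NAMES:
        vals = np.array([getattr(f, metric) for f in folds], dtype=float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        rows.append({"metric": metric, "mean": mean, "sd": sd,
                     "formatted": f"{mean:.2f} ± {sd:.2f}"})
    return pd.DataFrame(rows).set_index("metric")


def chi_squared_compare(correct_a: int, n_a: int, correct_b: int, n_b: int
                        ) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on pooled counts.

    Compares two models' pooled correct/incorrect test counts as a 2x2
    contingency table.  Equal proportions give statistic 0, p = 1.
    """
    for correct, n in ((correct_a, n_a), (correct_b, n_b)):
        if not 0 <= correct <= n:
            raise ValueError(f"need 0 <= correct <= n, got {correct}/{n}")
    table = np.array([[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a marginal of the 2x2 table is zero; expected counts undefined")
    result = stats.chi2_contingency(table, correction=False)
    return float(result.statistic), float(result.pvalue)


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    model_config: ModelConfig,
    train_config: TrainConfig,
    class_names: Sequence[str],
    subject_index: Optional[dict] = None,
) -> tuple[list[FoldMetrics], list[pd.DataFrame]]:
    """Train and evaluate one model per fold of a split plan.

    ``subject_index`` maps subject id -> row of ``x``; defaults to the
    identity for integer ids.  Per-fold seeds fan out from the train
    config's master seed.
    """
    lookup = subject_index or {}
    def rows(ids):
        return np.array([lookup.get(i, i) for i in ids], dtype=int)

    metrics, histories = [], []
    for f, fold in enumerate(plan.folds):
        tr, va, te = rows(fold["train"]), rows(fold["val"]), rows(fold["test"])
        cfg = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + 1000 * f})
        mcfg = ModelConfig(**{**model_config.__dict__, "init_seed": model_config.init_seed + f})
        model = build_model(mcfg)
        model, hist = train_model(model, x[tr], y[tr], x[va], y[va], cfg)
        metrics.append(evaluate(model, x[te], y[te], class_names, fold_id=f))
        histories.append(hist)
    return metrics, histories


def grid_search(
    x: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    model_configs: Sequence[ModelConfig],
    train_configs: Sequence[TrainConfig],
    class_names: Sequence[str],
    subject_index: Optional[dict] = None,
) -> tuple[ModelConfig, TrainConfig, pd.DataFrame]:
    """Pick the (model, training) configuration with best mean validation accuracy.

    Tuning touches only the validation cohorts; held-out test metrics are
    for the caller to compute once, on the selected configuration.
    """
    lookup = subject_index or {}
    def rows(ids):
        return np.array([lookup.get(i, i) for i in ids], dtype=int)

    records = []
    best = (-np.inf, None, None)
    for mi, mcfg in enumerate(model_configs):
        for ti, tcfg in enumerate(train_configs):
            accs = []
            for f, fold in enumerate(plan.folds):
                tr, va = rows(fold["train"]), rows(fold["val"])
                cfg = TrainConfig(**{**tcfg.__dict__, "seed": tcfg.seed + 1000 * f})
                model = build_model(ModelConfig(**{**mcfg.__dict__, "init_seed": mcfg.init_seed + f}))
                model, _ = train_model(model, x[tr], y[tr], x[va], y[va], cfg)
                accs.append(_batched_accuracy(model, x[va], y[va], cfg.batch_size))
            mean_acc = float(np.mean(accs))
            records.append({"model_config": mi, "train_config": ti,
                            "learning_rate": tcfg.learning_rate,
                            "batch_size": tcfg.batch_size,
                            "mean_val_accuracy": mean_acc})
            if mean_acc > best[0]:
                best = (mean_acc, mcfg, tcfg)
    return best[1], best[2], pd.DataFrame(records)
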