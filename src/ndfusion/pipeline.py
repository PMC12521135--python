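"""Training / evaluation protocol.

A held-out test split (20% of the cohort, stratified) is fixed first; the
remaining 80% is divided by stratified 5-fold cross-validation into five
(train 64%, validation 16%) pairs.  Each fold trains the network with Adam
under the three-term loss, selects the epoch with the best balanced mean of
validation accuracy, recall and precision, and evaluates that checkpoint on
the common test set.  Reported metrics are the mean and sample SD across
the five test evaluations.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._autodiff import Adam
from .network import ModelConfig, MultimodalGraphNet
from .synthetic import (CohortConfig, generate_cohort, standardize_tabular,
                        train_feature_stats)

__all__ = ["TrainConfig", "FoldSplit", "split_data", "train_fold", "select_best",
           "compute_metrics", "aggregate_folds", "run_experiment"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (Adam, 100 epochs by default)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-7
    betas: tuple[float, float] = (0.9, 0.98)
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 2:
            raise ValueError("invalid training configuration")
        if not all(0 < b < 1 for b in self.betas):
            raise ValueError("betas must lie in (0, 1)")


@dataclass
class FoldSplit:
    """Indices of the fixed test split and the five train/validation folds."""

    test_ids: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int = 0


def split_data(n: int, labels: np.ndarray, seed: int = 0,
               test_frac: float = 0.2, n_folds: int = 5) -> FoldSplit:
    """Stratified 20% test split + stratified 5-fold CV of the remainder."""
    labels = np.asarray(labels).reshape(-1)
    if n < 10:
        raise ValueError("cohort too small to split")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    idx = np.arange(n)
    pool_ids, test_ids = train_test_split(
        idx, test_size=test_frac, stratify=labels, random_state=seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(pool_ids[tr], pool_ids[va])
             for tr, va in skf.split(pool_ids, labels[pool_ids])]
    return FoldSplit(test_ids=np.sort(test_ids), folds=folds, seed=seed)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray) -> dict[str, float]:
    """Accuracy, recall, precision, F1 (positive class) and AUC.

    ``scores`` are positive-class probabilities; hard predictions use a 0.5
    threshold upstream.  With no positive predictions, precision is reported
    as 0 with a warning.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    acc = (tp + tn) / len(y_true)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    if len(np.unique(y_true)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, scores))
    return {"acc": acc, "recall": recall, "precision": precision, "f1": f1,
            "auc": auc, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def select_best(history: list[dict]) -> int:
    """Epoch maximizing mean(validation acc, recall, precision); earliest wins ties."""
    if not history:
        raise ValueError("empty training history")
    means = [np.mean([h["val_acc"], h["val_recall"], h["val_precision"]])
             for h in history]
    return int(np.argmax(means))  # argmax returns the first maximum


def _eval_cohort(net: MultimodalGraphNet, volumes, tabular, labels) -> dict[str, float]:
    scores = net.predict_proba(volumes, tabular)
    return compute_metrics(labels, (scores >= 0.5).astype(int), scores)


def train_fold(net: MultimodalGraphNet,
               volumes: np.ndarray | None, tabular: np.ndarray,
               labels: np.ndarray,
               train_ids: np.ndarray, val_ids: np.ndarray,
               train_config: TrainConfig) -> tuple[list[list[np.ndarray]], list[dict]]:
    """Train one fold; returns (per-epoch checkpoints, epoch history).

    The cohort graph is rebuilt over every mini-batch during training and
    over the full validation cohort at each epoch's evaluation.
    """
    tc = train_config
    if len(train_ids) == 0 or len(val_ids) == 0:
        raise ValueError("empty train or validation split")
    opt = Adam(net.parameters(), lr=tc.learning_rate, betas=tc.betas,
               weight_decay=tc.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 11]))

    def batch_of(ids):
        vols = volumes[ids] if volumes is not None else None
        return vols, tabular[ids], labels[ids]

    history: list[dict] = []
    checkpoints: list[list[np.ndarray]] = []
    for epoch in range(tc.epochs):
        order = rng.permutation(len(train_ids))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), tc.batch_size):
            ids = train_ids[order[start:start + tc.batch_size]]
            if len(ids) < 2:
                continue  # graph and CSDM need at least two samples
            vols, tabs, ys = batch_of(ids)
            out = net.forward(vols, tabs)
            loss = net.losses(out, ys)["total"]
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: training diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        vols, tabs, ys = batch_of(val_ids)
        vm = _eval_cohort(net, vols, tabs, ys)
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_acc": vm["acc"], "val_recall": vm["recall"],
            "val_precision": vm["precision"],
        })
        checkpoints.append(net.state_dict())
    return checkpoints, history


def aggregate_folds(reports: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    """Mean and sample SD of every metric across folds."""
    if len(reports) < 2:
        raise ValueError("need at least two folds to aggregate")
    keys = ["acc", "recall", "precision", "f1", "auc"]
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in reports], dtype=float)
        out[k] = {"mean": float(np.nanmean(vals)),
                  "sd": float(np.nanstd(vals, ddof=1))}
    return out


def run_experiment(cohort_config: CohortConfig | None = None,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   data: tuple | None = None,
                   seed: int | None = None) -> dict:
    """The full protocol on one cohort.

    ``data`` may supply a pre-generated ``(records, volumes, labels)`` tuple;
    otherwise a synthetic cohort is generated from ``cohort_config``.
    Returns a result dict with per-fold and aggregate metric blocks plus the
    selected epochs and split sizes.
    """
    cc = cohort_config or CohortConfig()
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    if seed is not None:
        cc = dataclasses.replace(cc, seed=seed)
        tc = dataclasses.replace(tc, seed=seed)

    if data is None:
        need_vols = mc.modality != "tabular"
        records, volumes, labels = generate_cohort(cc, include_volumes=need_vols)
    else:
        records, volumes, labels = data
    split = split_data(len(labels), labels, seed=tc.seed)

    fold_reports: list[dict] = []
    selected_epochs: list[int] = []
    for k, (train_ids, val_ids) in enumerate(split.folds):
        stats = train_feature_stats([records[i] for i in train_ids])
        tab_all = standardize_tabular(records, stats)
        net = MultimodalGraphNet(mc, seed=tc.seed * 1000 + k)
        checkpoints, history = train_fold(
            net, volumes, tab_all, labels, train_ids, val_ids, tc)
        best = select_best(history)
        selected_epochs.append(best)
        net.load_state_dict(checkpoints[best])
        vols_test = volumes[split.test_ids] if volumes is not None else None
        report = _eval_cohort(net, vols_test, tab_all[split.test_ids],
                              labels[split.test_ids])
        report["fold"] = k
        report["best_epoch"] = best
        fold_reports.append(report)

    return {
        "config": {"train": asdict(tc)},
        "split_sizes": {"test": int(len(split.test_ids)),
                        "train": int(len(split.folds[0][0])),
                        "val": int(len(split.folds[0][1]))},
        "per_fold": fold_reports,
        "aggregate": aggregate_folds(fold_reports),
        "selected_epochs": selected_epochs,
        "n_parameters": MultimodalGraphNet(mc, seed=0).n_parameters(),
    }
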