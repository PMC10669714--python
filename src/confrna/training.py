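"""Training loops, cross-validation, and the evaluation protocols.

Single-fold training follows the reference ConF recipe: categorical
cross-entropy, Adam at learning rate 0.001, 220 epochs, batch size 200
(the defaults; desk-scale runs shrink epochs/batches through
``TrainConfig``).  On top of it sit ten-fold cross-validation, the
k-mer sweep (k = 1/2/3), and the robustness protocol (five disjoint
stratified subsets, each cross-validated independently).

Every protocol accepts a ``trainer`` callable so that cheap reference
classifiers can exercise the fold logic in tests without a full network
run; the default trainer is :func:`train_fold`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .autograd import Tensor, cross_entropy
from .conf_model import ConF, ModelConfig
from .evaluation import ConfusionCounts, MetricsReport, confusion, metrics, per_family_metrics
from .representation import build_vocab, tokenize_dataset
from .sequence_io import FoldPlan, LabeledDataset, make_folds

__all__ = [
    "TrainConfig",
    "FoldResult",
    "CVResult",
    "Adam",
    "train_fold",
    "cross_validate",
    "kmer_sweep",
    "robustness_protocol",
    "baseline_trainer",
    "summarize_distribution",
    "write_history_csv",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (reference ConF defaults)."""

    learning_rate: float = 0.001
    epochs: int = 220
    batch_size: int = 200
    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class FoldResult:
    """Outcome of training on all folds but one and testing on that one."""

    fold_index: int
    train_loss: list[float]
    train_accuracy: list[float]
    val_accuracy: list[float]
    report: MetricsReport
    per_family: dict[str, MetricsReport]
    counts: ConfusionCounts
    test_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    model: ConF | None = None


@dataclass
class CVResult:
    folds: list[FoldResult]
    aggregate: MetricsReport
    families: list[str]

    @property
    def fold_accuracies(self) -> list[float]:
        return [f.report.overall_accuracy for f in self.folds]

    def per_family_f1(self) -> np.ndarray:
        """(n_folds, n_families) F1 matrix for correlation analysis."""
        return np.array([
            [fold.per_family[fam].f1 for fam in self.families] for fold in self.folds
        ])


class Adam:
    """Adam with the standard moment defaults (b1=0.9, b2=0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _predict_batched(model: ConF, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    preds = [model.predict(x[i:i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.intp)


def train_fold(dataset: LabeledDataset, fold_plan: FoldPlan, fold_index: int,
               model_cfg: ModelConfig, train_cfg: TrainConfig) -> FoldResult:
    """Train on every fold except ``fold_index``; evaluate on it.

    Fully reproducible: the model initialization and the batch order are
    both derived from (train_cfg.seed, fold_index).
    """
    train_ids, test_ids = fold_plan.split(fold_index)
    train_set = dataset.subset(train_ids)
    test_set = dataset.subset(test_ids)
    if len(train_set) == 0:
        raise ValueError("training partition is empty")
    present = {r.family for r in train_set}
    missing = [f for f in dataset.families if f not in present]
    if missing:
        raise ValueError(f"families {missing} have no training members in fold {fold_index}")

    vocab = build_vocab(model_cfg.k)
    x_train = tokenize_dataset(train_set, vocab, model_cfg.max_len)
    x_test = tokenize_dataset(test_set, vocab, model_cfg.max_len)
    y_train = train_set.labels_as_indices()
    y_test = test_set.labels_as_indices()

    model = ConF(model_cfg, seed=_derived_seed(train_cfg.seed, fold_index, 1))
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(_derived_seed(train_cfg.seed, fold_index, 2))

    loss_hist, train_acc_hist, val_acc_hist = [], [], []
    n = len(x_train)
    for _ in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            scores = model.logits(x_train[batch])
            loss = cross_entropy(scores, y_train[batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
            correct += int((scores.data.argmax(axis=1) == y_train[batch]).sum())
        loss_hist.append(epoch_loss / n)
        train_acc_hist.append(correct / n)
        val_acc_hist.append(
            float((_predict_batched(model, x_test) == y_test).mean())
        )

    pred_idx = _predict_batched(model, x_test)
    y_pred = [dataset.families[i] for i in pred_idx]
    y_true = [r.family for r in test_set]
    counts = confusion(y_true, y_pred, dataset.families)
    return FoldResult(
        fold_index=fold_index,
        train_loss=loss_hist,
        train_accuracy=train_acc_hist,
        val_accuracy=val_acc_hist,
        report=metrics(counts, "macro"),
        per_family=per_family_metrics(counts),
        counts=counts,
        test_ids=[r.id for r in test_set],
        y_true=y_true,
        y_pred=y_pred,
        model=model,
    )


def baseline_trainer(classifier_factory: Callable[[], object]):
    """Wrap a cheap fit/predict classifier as a fold trainer (no epochs)."""

    def trainer(dataset, fold_plan, fold_index, model_cfg, train_cfg):
        train_ids, test_ids = fold_plan.split(fold_index)
        train_set = dataset.subset(train_ids)
        test_set = dataset.subset(test_ids)
        clf = classifier_factory()
        clf.fit(list(train_set), dataset.families)
        y_pred = clf.predict(list(test_set))
        y_true = [r.family for r in test_set]
        counts = confusion(y_true, y_pred, dataset.families)
        return FoldResult(
            fold_index=fold_index, train_loss=[], train_accuracy=[],
            val_accuracy=[], report=metrics(counts, "macro"),
            per_family=per_family_metrics(counts), counts=counts,
            test_ids=[r.id for r in test_set], y_true=y_true, y_pred=y_pred,
        )

    return trainer


def _aggregate(folds: list[FoldResult]) -> MetricsReport:
    """Unweighted mean of the per-fold macro metrics."""
    def mean(attr):
        return float(np.mean([getattr(f.report, attr) for f in folds]))

    return MetricsReport(
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        precision=mean("precision"),
        f1=mean("f1"),
        averaging="macro",
        overall_accuracy=mean("overall_accuracy"),
    )


def cross_validate(dataset: LabeledDataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, n_folds: int = 10,
                   trainer=None, plan: FoldPlan | None = None) -> CVResult:
    """k-fold rotation: every record is tested exactly once."""
    trainer = trainer or train_fold
    if plan is None:
        plan = make_folds(dataset, n_folds, train_cfg.seed)
    folds = [
        trainer(dataset, plan, i, model_cfg, train_cfg) for i in range(plan.n_folds)
    ]
    return CVResult(folds=folds, aggregate=_aggregate(folds),
                    families=list(dataset.families))


def kmer_sweep(dataset: LabeledDataset, ks: Sequence[int], model_cfg: ModelConfig,
               train_cfg: TrainConfig, n_folds: int = 10,
               trainer=None) -> dict[int, CVResult]:
    """Cross-validate once per k with identical folds and seeds across k."""
    plan = make_folds(dataset, n_folds, train_cfg.seed)
    return {
        k: cross_validate(dataset, replace(model_cfg, k=k), train_cfg,
                          n_folds=n_folds, trainer=trainer, plan=plan)
        for k in ks
    }


def robustness_protocol(dataset: LabeledDataset, model_cfg: ModelConfig,
                        train_cfg: TrainConfig, n_subsets: int = 5,
                        n_folds: int = 10, trainer=None) -> list[CVResult]:
    """Partition into stratified subsets; cross-validate each independently.

    Returns one accuracy distribution (a CVResult) per subset; subsets
    are pairwise disjoint and cover the dataset, and each subset's CV is
    seeded distinctly.
    """
    partition = make_folds(dataset, n_subsets, _derived_seed(train_cfg.seed, 7))
    results = []
    for s in range(n_subsets):
        subset = dataset.subset(partition.fold_ids(s))
        sub_cfg = replace(train_cfg, seed=_derived_seed(train_cfg.seed, 11, s))
        results.append(
            cross_validate(subset, model_cfg, sub_cfg, n_folds=n_folds, trainer=trainer)
        )
    return results


def summarize_distribution(values: Sequence[float]) -> dict[str, float]:
    """Box-plot summary: min, lower quartile, median, upper quartile, max."""
    arr = np.asarray(values, dtype=np.float64)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "min": float(arr.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(arr.max()),
    }


def write_history_csv(result: FoldResult, path: str | Path) -> None:
    """Per-epoch (epoch, loss, train accuracy, validation accuracy)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["epoch", "loss", "train_accuracy", "val_accuracy"])
        for e, (lo, ta, va) in enumerate(
            zip(result.train_loss, result.train_accuracy, result.val_accuracy), start=1
        ):
            writer.writerow([e, f"{lo:.6f}", f"{ta:.6f}", f"{va:.6f}"])
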