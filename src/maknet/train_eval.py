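"""Training and evaluation: Adam loop with best-validation checkpointing,
confusion matrices, the per-class/aggregate metric suite, and the ablation
and imbalance-strategy comparison drivers.

Metric conventions (chosen to match the standard reporting layout for this
task, and nonstandard in one place): per class, one-vs-rest precision,
recall, F1 and specificity; the per-class "accuracy" column REPEATS the
recall (the conventional table layout equates them).  The aggregate row
uses unweighted (macro) means for F1/recall/precision/specificity but
overall accuracy (trace/total) for the accuracy cell.  All reported cells
are rounded half-up to 4 decimals.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .dataset import CLASSES, BeatDataset
from .imbalance import FocalConfig, SmoteConfig, apply_smote, cross_entropy, focal_loss
from .network import MakNet, ModelConfig, build_model

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("accuracy", "f1_score", "recall", "precision", "specificity")


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Decimal half-up rounding (0.00005 -> 0.0001), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# confusion matrix and metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """5x5 count matrix; rows = true class, columns = predicted class, in
    the fixed (N, S, V, F, Q) order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion-matrix entries must be non-negative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        k = len(CLASSES)
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass
class MetricsReport:
    per_class: pd.DataFrame            # index = classes, columns = METRIC_COLUMNS
    zero_denominator: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self, cm: ConfusionMatrix | None = None) -> pd.DataFrame:
        frame = self.per_class.copy()
        if cm is not None:
            frame.loc["Sum"] = aggregate(self, cm)
        return frame


def evaluate(model: MakNet, dataset: BeatDataset, split: str | None = "test",
             batch_size: int = 256) -> ConfusionMatrix:
    """Confusion matrix of argmax predictions (ties break to the lowest
    class index) over one split, or the whole dataset if split is None."""
    part = dataset if split is None else dataset.split_subset(split)
    if len(part) == 0:
        raise ValueError(f"split {split!r} is empty")
    preds = model.predict(part.X, batch_size=batch_size)
    return ConfusionMatrix.from_labels(part.y_index, preds)


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics per class.  Zero-denominator cells are reported
    as 0 and flagged.  The accuracy column repeats the recall (table
    convention)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows, flagged = {}, []

    def ratio(num: int, den: int, cls: str, name: str) -> float:
        if den == 0:
            flagged.append((cls, name))
            return 0.0
        return num / den

    for i, cls in enumerate(cm.classes):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        recall = ratio(tp, tp + fn, cls, "recall")
        precision = ratio(tp, tp + fp, cls, "precision")
        specificity = ratio(tn, tn + fp, cls, "specificity")
        if precision + recall == 0:
            flagged.append((cls, "f1_score"))
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows[cls] = {"accuracy": recall, "f1_score": f1, "recall": recall,
                     "precision": precision, "specificity": specificity}
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    return MetricsReport(frame, flagged)


def aggregate(report: MetricsReport, cm: ConfusionMatrix) -> pd.Series:
    """The aggregate ("Sum") row: unweighted macro means of the per-class
    F1/recall/precision/specificity, but OVERALL accuracy (trace/total) for
    the accuracy cell; all rounded half-up to 4 decimals."""
    if len(report.per_class) != len(CLASSES):
        raise ValueError("aggregate expects per-class rows for all 5 classes")
    out = {"accuracy": round_half_up(np.trace(cm.counts) / cm.total)}
    for col in ("f1_score", "recall", "precision", "specificity"):
        out[col] = round_half_up(report.per_class[col].mean())
    return pd.Series(out)[list(METRIC_COLUMNS)]


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unrounded macro-averaged F1 (used for checkpoint selection)."""
    return float(per_class_metrics(cm).per_class["f1_score"].mean())


# --------------------------------------------------------------------------
# optimizer and training loop
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 5e-4
    epochs: int = 60
    loss: str = "ce"                       # "ce" or "focal"
    focal: FocalConfig | None = None
    seed: int = 0
    checkpoint_policy: str = "best_val_macro_f1"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.loss not in ("ce", "focal"):
            raise ValueError("loss must be 'ce' or 'focal'")
        if self.checkpoint_policy not in ("best_val_macro_f1", "last"):
            raise ValueError("checkpoint_policy must be 'best_val_macro_f1' or 'last'")


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def train(model: MakNet, dataset: BeatDataset, cfg: TrainConfig | None = None
          ) -> tuple[MakNet, list[dict]]:
    """Fixed-epoch Adam training with per-epoch seeded shuffling.

    Requires train and val tags.  History records mean train loss and
    validation macro-F1 per epoch; the returned model carries the parameters
    of the epoch with the best validation macro-F1 (ties keep the earlier
    epoch)."""
    cfg = TrainConfig() if cfg is None else cfg
    train_part = dataset.split_subset("train")
    val_part = dataset.split_subset("val")
    if len(train_part) == 0:
        raise ValueError("training split is empty")
    if len(val_part) == 0:
        raise ValueError("validation split is empty (needed for checkpointing)")
    if cfg.loss == "focal":
        focal_cfg = cfg.focal if cfg.focal is not None else FocalConfig()

    rng = np.random.default_rng(cfg.seed)
    model.reset_dropout_rng(cfg.seed + 101)
    optimizer = Adam(model.parameters(), cfg.learning_rate)
    X, y = train_part.X, train_part.y_index
    history: list[dict] = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = model.forward(X[idx], training=True)
            if cfg.loss == "ce":
                loss = cross_entropy(probs, y[idx])
            else:
                loss = focal_loss(probs, y[idx], focal_cfg)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        cm = evaluate(model, dataset, "val")
        score = macro_f1(cm)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_macro_f1": score})
        if score > best[0]:
            best = (score, copy.deepcopy(model.state_dict()))
        logger.debug("epoch %d: loss %.4f, val macro-F1 %.4f",
                     epoch, history[-1]["train_loss"], score)
    if cfg.checkpoint_policy == "best_val_macro_f1" and best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


# --------------------------------------------------------------------------
# study drivers
# --------------------------------------------------------------------------


def run_ablation(model_cfg: ModelConfig, dataset: BeatDataset,
                 variants: tuple[str, ...], train_cfg: TrainConfig | None = None,
                 seeds: tuple[int, ...] = (0,)
                 ) -> tuple[pd.DataFrame, list[dict]]:
    """Train each architecture variant with the identical recipe and seed
    set; evaluate on the test split.

    Returns (table, runs): the table has one row per variant with the five
    aggregate metrics (median across seeds); `runs` holds every
    (variant, seed) record with its aggregate row and test macro-F1.
    """
    train_cfg = TrainConfig() if train_cfg is None else train_cfg
    runs: list[dict] = []
    for variant in variants:
        for seed in seeds:
            m_cfg = ModelConfig(**{**vars(model_cfg), "seed": seed})
            t_cfg = TrainConfig(**{**vars(train_cfg), "seed": seed})
            model = build_model(m_cfg, variant)
            model, _ = train(model, dataset, t_cfg)
            cm = evaluate(model, dataset, "test")
            agg = aggregate(per_class_metrics(cm), cm)
            runs.append({"variant": variant, "seed": seed,
                         "aggregate": agg, "macro_f1": macro_f1(cm)})
    rows = {}
    for variant in variants:
        stack = pd.DataFrame([r["aggregate"] for r in runs if r["variant"] == variant])
        rows[variant] = stack.median()
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    return table, runs


def compare_imbalance(dataset: BeatDataset, model_cfg: ModelConfig,
                      strategies: tuple[str, ...] = ("none", "focal", "smote"),
                      train_cfg: TrainConfig | None = None,
                      focal_cfg: FocalConfig | None = None,
                      smote_cfg: SmoteConfig | None = None,
                      seeds: tuple[int, ...] = (0,)
                      ) -> tuple[pd.DataFrame, list[dict]]:
    """Compare imbalance strategies with a shared model config and seed set.

    "none" trains with cross-entropy on the data as is; "focal" swaps the
    loss; "smote" oversamples the training split to balance (validation and
    test untouched) and reverts to cross-entropy.  Returns (table, runs) as
    in `run_ablation`; each run record also carries per-class recalls.
    """
    train_cfg = TrainConfig() if train_cfg is None else train_cfg
    focal_cfg = FocalConfig() if focal_cfg is None else focal_cfg
    runs: list[dict] = []
    for strategy in strategies:
        if strategy not in ("none", "focal", "smote"):
            raise ValueError(f"unknown strategy {strategy!r}")
        for seed in seeds:
            data = dataset
            t_kwargs = {**vars(train_cfg), "seed": seed}
            if strategy == "focal":
                t_kwargs.update(loss="focal", focal=focal_cfg)
            else:
                t_kwargs.update(loss="ce", focal=None)
            if strategy == "smote":
                s_cfg = SmoteConfig() if smote_cfg is None else smote_cfg
                data = apply_smote(dataset, SmoteConfig(
                    k_neighbors=s_cfg.k_neighbors,
                    target_counts=s_cfg.target_counts, seed=seed))
            model = build_model(ModelConfig(**{**vars(model_cfg), "seed": seed}))
            model, _ = train(model, data, TrainConfig(**t_kwargs))
            cm = evaluate(model, data, "test")
            report = per_class_metrics(cm)
            runs.append({"strategy": strategy, "seed": seed,
                         "aggregate": aggregate(report, cm),
                         "per_class_recall": report.per_class["recall"].to_dict()})
    rows = {}
    for strategy in strategies:
        stack = pd.DataFrame([r["aggregate"] for r in runs if r["strategy"] == strategy])
        rows[strategy] = stack.median()
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    return table, runs
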