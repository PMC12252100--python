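"""Class-imbalance remedies: multi-class focal loss and from-scratch SMOTE.

Both losses operate on post-softmax probabilities of the true class p_t:
cross-entropy is -log(p_t); focal loss is alpha_y * (1 - p_t)^gamma *
(-log p_t), which reduces exactly to alpha-weighted cross-entropy at
gamma = 0.  Probabilities are clamped at 1e-12 below.

SMOTE synthesizes minority-class rows as convex combinations x + u*(nn - x)
of a sample and one of its k nearest same-class neighbours (exact Euclidean
search), with u ~ Uniform[0, 1].  It is applied to training rows only:
`apply_smote` is the dataset-level entry point and refuses anything but the
train split, so validation/test rows can never leak into the oversampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor
from .dataset import CLASSES, BeatDataset

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class FocalConfig:
    gamma: float = 2.0
    alpha: tuple[float, ...] = (1.0,) * len(CLASSES)  # per-class weights

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError(f"focusing parameter gamma must be >= 0, got {self.gamma}")
        if len(self.alpha) != len(CLASSES):
            raise ValueError(f"alpha must have {len(CLASSES)} entries")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha):
            raise ValueError("alpha entries must lie in [0, 1]")


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_counts: dict[str, int] | str = "equalize"   # or explicit class -> count
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


def _check_probs(probs: np.ndarray) -> None:
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        worst = float(np.max(np.abs(sums - 1.0)))
        raise ValueError(f"probabilities must sum to 1 (worst deviation {worst:.2e})")


def _true_class_probs(probs, true_class):
    """p_t for batched (n, C) or single (C,) inputs; returns Tensor."""
    t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    if t.ndim == 1:
        t = t.reshape(1, -1)
    y = np.atleast_1d(np.asarray(true_class, dtype=np.int64))
    _check_probs(t.data)
    return t.gather_rows(y).clip_min(EPS), y


def cross_entropy(probs, true_class) -> Tensor:
    """Mean -log(p_t) in nats.  Accepts numpy arrays or autodiff Tensors;
    returns a scalar Tensor (use .item() for the float)."""
    pt, _ = _true_class_probs(probs, true_class)
    return -(pt.log().mean())


def focal_loss(probs, true_class, cfg: FocalConfig | None = None) -> Tensor:
    """Mean alpha_y * (1 - p_t)^gamma * (-log p_t) in nats; differentiable
    with respect to the probabilities."""
    cfg = FocalConfig() if cfg is None else cfg
    pt, y = _true_class_probs(probs, true_class)
    alpha_y = np.asarray(cfg.alpha, dtype=np.float64)[y]
    modulator = (1.0 - pt) ** cfg.gamma if cfg.gamma != 0 else 1.0
    return (Tensor(alpha_y) * modulator * -(pt.log())).mean()


# --------------------------------------------------------------------------
# SMOTE
# --------------------------------------------------------------------------


def smote_oversample(features: np.ndarray, labels: np.ndarray,
                     cfg: SmoteConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes to their target counts.

    Original rows are preserved verbatim, in order, ahead of the synthetic
    rows; classes at or above target are never touched.  Every synthetic row
    is a convex combination of two original same-class rows.
    """
    cfg = SmoteConfig() if cfg is None else cfg
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if cfg.target_counts == "equalize":
        target = dict.fromkeys(counts, max(counts.values()))
    elif isinstance(cfg.target_counts, dict):
        target = dict(counts)
        for c, t in cfg.target_counts.items():
            if c in counts and t < counts[c]:
                raise ValueError(
                    f"target count {t} for class {c!r} is below its current {counts[c]}"
                )
            target[c] = t
    else:
        raise ValueError("target_counts must be 'equalize' or a class->count mapping")

    rng = np.random.default_rng(cfg.seed)
    new_X, new_y = [X], [y]
    for cls in sorted(counts):
        need = target.get(cls, counts[cls]) - counts[cls]
        if need <= 0:
            continue
        if counts[cls] < 2:
            raise ValueError(
                f"class {cls!r} has {counts[cls]} sample(s); SMOTE needs at least 2"
            )
        idx = np.flatnonzero(y == cls)
        k = cfg.k_neighbors
        if k > len(idx) - 1:
            logger.warning("clamping k_neighbors from %d to %d for class %s",
                           k, len(idx) - 1, cls)
            k = len(idx) - 1
        pts = X[idx]
        dist = cdist(pts, pts)
        np.fill_diagonal(dist, np.inf)
        nn = np.argsort(dist, axis=1)[:, :k]           # k nearest same-class rows
        base = rng.integers(0, len(idx), size=need)
        pick = nn[base, rng.integers(0, k, size=need)]
        u = rng.uniform(0.0, 1.0, size=(need, 1))
        synth = pts[base] + u * (pts[pick] - pts[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def apply_smote(dataset: BeatDataset, cfg: SmoteConfig | None = None) -> BeatDataset:
    """Oversample the training split of a tagged dataset; validation and
    test rows pass through untouched.  This is the only path from a
    BeatDataset into `smote_oversample`, and it forwards train-tagged rows
    exclusively."""
    if not np.any(dataset.split == "train"):
        raise ValueError(
            "apply_smote requires a dataset with train/val/test tags "
            "(run split_dataset first); refusing to oversample untagged rows"
        )
    train = dataset.split_subset("train")
    rest = dataset.subset(dataset.split != "train")
    X_aug, y_aug = smote_oversample(train.X, train.y, cfg)
    n_new = len(y_aug) - len(train)
    synth = BeatDataset(
        X_aug[len(train):], y_aug[len(train):],
        split=np.full(n_new, "train", dtype="<U5"),
        record_id=np.full(n_new, "smote", dtype="<U32"),
    )
    return BeatDataset.concatenate([train, synth, rest])
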