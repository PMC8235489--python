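"""Final one-vs-all hinge stage, multi-model score fusion, and evaluation.

The stacked bank representation h_n feeds C one-vs-all linear classifiers
per base model, each minimizing the L2-regularized hinge objective

    sum_n max(0, 1 - (w_c . h_n) y_n^c) + alpha ||w_c||^2,

with y_n^c = +1 iff image n belongs to class c, else -1.  A constant-1
column is appended to the representation so the bias is regularized with
the weights.  Per-model class scores are fused across the M base models
with per-(model, class) weights lambda_{m,c}; the default is the equal
weighting 1/M, i.e. the mean of the per-model scores, and the predicted
class is the argmax (ties to the lowest index).

Two ablations bracket the method: ``ablation_no_mi`` drops the confusion
machinery entirely and averages raw base-model scores; ``ablation_no_nir``
drops the stacked representation and lets every (class, model) subset vote
with its winning member class.  Evaluation uses mean class accuracy — the
unweighted mean of per-class accuracies, not pooled accuracy.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .confusion_bank import ConfusionBank, represent
from .errors import ConfigError
from .hinge import fit_binary_hinge, hinge_loss, hinge_objective

__all__ = [
    "FinalClassifier",
    "FusionWeights",
    "FusedScores",
    "hinge_loss",
    "hinge_objective",
    "train_final",
    "decision_scores",
    "fuse",
    "ablation_no_mi",
    "ablation_no_nir",
    "mean_class_accuracy",
    "per_class_accuracy",
]


@dataclasses.dataclass
class FinalClassifier:
    """C one-vs-all hinge classifiers over the stacked representation.

    weights : (C, width+1) — row c is w_c, last column the bias weight.
    """

    weights: np.ndarray
    alpha: float
    model_index: int = 1


@dataclasses.dataclass
class FusionWeights:
    """Per-(model, class) fusion coefficients lambda_{m,c}.

    The default (``FusionWeights.equal``) sets every entry to 1/M, making
    fusion the mean of the per-model scores; any positive constant would
    give the same argmax.
    """

    lambdas: np.ndarray  # (M, C)

    @classmethod
    def equal(cls, n_models: int, n_classes: int) -> "FusionWeights":
        return cls(np.full((n_models, n_classes), 1.0 / n_models))


@dataclasses.dataclass(frozen=True)
class FusedScores:
    scores: np.ndarray  # (N, C)

    @property
    def predicted_labels(self) -> np.ndarray:
        return np.argmax(self.scores, axis=1).astype(np.int64) + 1


def _augment(H: np.ndarray) -> np.ndarray:
    return np.hstack([H, np.ones((H.shape[0], 1))])


def train_final(
    H: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    model_index: int = 1,
) -> FinalClassifier:
    """Train the C one-vs-all hinge classifiers on a representation."""
    if alpha <= 0:
        raise ConfigError(f"alpha must be positive, got {alpha}")
    H = np.asarray(H, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if H.shape[0] != y.shape[0]:
        raise ConfigError("representation rows and labels are misaligned")
    n_classes = int(y.max())
    Ha = _augment(H)
    weights = np.zeros((n_classes, Ha.shape[1]))
    for c in range(1, n_classes + 1):
        pos = y == c
        if not pos.any():
            raise ConfigError(f"class {c} has no positive examples")
        y_pm = np.where(pos, 1.0, -1.0)
        weights[c - 1], _ = fit_binary_hinge(
            Ha, y_pm, alpha=alpha, max_iter=max_iter, tol=tol, seed=seed
        )
    return FinalClassifier(weights=weights, alpha=float(alpha), model_index=model_index)


def decision_scores(H: np.ndarray, clf: FinalClassifier) -> np.ndarray:
    """(N, C) matrix of w_c . h_n decision values."""
    return _augment(np.asarray(H, dtype=np.float64)) @ clf.weights.T


def fuse(
    per_model_scores: list[np.ndarray], weights: FusionWeights | None = None
) -> FusedScores:
    """Linearly combine M per-model score matrices into fused class scores."""
    if not per_model_scores:
        raise ConfigError("need at least one score matrix")
    shapes = {s.shape for s in per_model_scores}
    if len(shapes) != 1:
        raise ConfigError(f"score matrices disagree on shape: {shapes}")
    n, c = per_model_scores[0].shape
    m = len(per_model_scores)
    if weights is None:
        weights = FusionWeights.equal(m, c)
    lam = np.asarray(weights.lambdas, dtype=np.float64)
    if lam.shape != (m, c):
        raise ConfigError(f"fusion weights shape {lam.shape}, expected {(m, c)}")
    fused = np.zeros((n, c))
    for s, l in zip(per_model_scores, lam):
        fused += s * l[np.newaxis, :]
    return FusedScores(scores=fused)


def ablation_no_mi(base_scores: list[np.ndarray]) -> np.ndarray:
    """Averaged base-model predictions, no confusion modeling.

    Exactly the equal-weight fusion of the raw base score matrices; returns
    predicted labels.
    """
    return fuse(base_scores).predicted_labels


def ablation_no_nir(
    banks: list[ConfusionBank], Xs: list[np.ndarray]
) -> np.ndarray:
    """Subset-winner voting, no stacked representation.

    Each (class, model) subset emits the member class whose subset
    classifier scores highest on the image; the label is the majority vote
    over all C*M emissions, ties toward the lowest class index.
    """
    if not banks:
        raise ConfigError("need at least one trained bank")
    if len(banks) != len(Xs):
        raise ConfigError("need one feature matrix per bank")
    n = Xs[0].shape[0]
    n_classes = banks[0].n_classes
    votes = np.zeros((n, n_classes + 1), dtype=np.int64)
    for bank, X in zip(banks, Xs):
        H = represent(X, bank)  # (N, C*(K+1))
        blocks = H.reshape(n, bank.n_classes, bank.K + 1)
        winner_slot = np.argmax(blocks, axis=2)  # (N, C)
        winner_class = bank.orderings[np.arange(bank.n_classes)[np.newaxis, :], winner_slot]
        for c in range(bank.n_classes):
            np.add.at(votes, (np.arange(n), winner_class[:, c]), 1)
    return np.argmax(votes[:, 1:], axis=1).astype(np.int64) + 1


def per_class_accuracy(
    pred: np.ndarray, true: np.ndarray, n_classes: int | None = None
) -> np.ndarray:
    """Accuracy within each true class 1..C."""
    pred = np.asarray(pred, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    if pred.shape != true.shape:
        raise ConfigError("prediction and truth lengths differ")
    if n_classes is None:
        n_classes = int(true.max())
    acc = np.empty(n_classes)
    for c in range(1, n_classes + 1):
        mask = true == c
        if not mask.any():
            raise ConfigError(f"class {c} has no test images")
        acc[c - 1] = np.mean(pred[mask] == c)
    return acc


def mean_class_accuracy(
    pred: np.ndarray, true: np.ndarray, n_classes: int | None = None
) -> float:
    """Mean of per-class accuracies (every class weighted equally)."""
    return float(per_class_accuracy(pred, true, n_classes).mean())
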