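"""Confusion-classifier banks and stacked classifier-output representations.

For every class c a bank holds K+1 binary one-vs-all linear classifiers
g_{c,k}, one per member class of c's misclassification subset (class c
first, then the K selected classes in confusion-rank order).  Each g_{c,k}
is trained only on the subset's images — member class positive, the other
subset members negative; that restriction to mutually confusable images is
the point of the subset construction.

At representation time every classifier in the bank scores every image
(not just subset members) and the C*(K+1) raw decision values are
concatenated, block per class, into the new image representation.  Margins
are used rather than hard labels so the ranking information survives for
the final stage; hard +-1 outputs are available via ``output="label"``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .confusion_analysis import SubsetSpec
from .errors import ConfigError, NumericError
from .hinge import fit_standardized_hinge

__all__ = ["SubsetClassifier", "ConfusionBank", "train_bank", "represent"]


@dataclasses.dataclass(frozen=True)
class SubsetClassifier:
    """One binary member-vs-rest classifier of a subset; weights include bias."""

    weights: np.ndarray  # (d + 1,), last entry is the bias
    target_class: int
    owner: tuple[int, int, int]  # (c, m, k)


@dataclasses.dataclass
class ConfusionBank:
    """All C*(K+1) subset classifiers of one base model.

    weights : (C, K+1, d+1) array; weights[c-1, k] separates member k of
        class c's subset from the rest of that subset.
    orderings : (C, K+1) int array of member classes, class c first then
        the selected classes in rank order; fixed between training and
        representation building.
    """

    weights: np.ndarray
    orderings: np.ndarray
    model_index: int = 1

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def K(self) -> int:
        return self.weights.shape[1] - 1

    @property
    def n_classifiers(self) -> int:
        return self.n_classes * (self.K + 1)

    def classifier(self, c: int, k: int) -> SubsetClassifier:
        """The k-th (1-based) classifier of class c's subset."""
        return SubsetClassifier(
            weights=self.weights[c - 1, k - 1],
            target_class=int(self.orderings[c - 1, k - 1]),
            owner=(c, self.model_index, k),
        )


def _augment(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def train_bank(
    X: np.ndarray,
    y: np.ndarray,
    subsets: list[SubsetSpec],
    alpha: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ConfusionBank:
    """Train the C x (K+1) grid of subset classifiers for one base model.

    Training is independent per (c, k) pair — the grid can be computed in
    any order or in parallel with identical results, since each fit is
    deterministic in its own inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if not np.all(np.isfinite(X)):
        raise NumericError("non-finite feature values")
    n_classes = len(subsets)
    by_class = {s.class_index: s for s in subsets}
    if sorted(by_class) != list(range(1, n_classes + 1)):
        raise ConfigError("need exactly one subset per class 1..C")
    model_indices = {s.model_index for s in subsets}
    if len(model_indices) != 1:
        raise ConfigError("subsets reference different model indices")
    K = len(subsets[0].selected_classes)
    if any(len(s.selected_classes) != K for s in subsets):
        raise ConfigError("all subsets must share the same K")
    d = X.shape[1]
    weights = np.zeros((n_classes, K + 1, d + 1))
    orderings = np.zeros((n_classes, K + 1), dtype=np.int64)
    for c in range(1, n_classes + 1):
        spec = by_class[c]
        rows = spec.member_indices
        X_sub = X[rows]
        y_sub = y[rows]
        for k, member in enumerate(spec.member_classes):
            pos = y_sub == member
            if not pos.any():
                raise ConfigError(
                    f"subset of class {c}: member class {member} has no images"
                )
            y_pm = np.where(pos, 1.0, -1.0)
            weights[c - 1, k] = fit_standardized_hinge(
                X_sub, y_pm, alpha=alpha, max_iter=max_iter, tol=tol
            )
            orderings[c - 1, k] = member
    return ConfusionBank(weights=weights, orderings=orderings,
                         model_index=subsets[0].model_index)


def represent(X: np.ndarray, bank: ConfusionBank, output: str = "margin") -> np.ndarray:
    """Concatenated bank outputs for every image: an (N, C*(K+1)) matrix.

    Column layout follows the bank ordering: class-1 block (its K+1 member
    classifiers in order), then class 2, ...  Identical at train and test
    time.
    """
    X = np.asarray(X, dtype=np.float64)
    d = bank.weights.shape[2] - 1
    if X.shape[1] != d:
        raise ConfigError(f"features have {X.shape[1]} dims, bank expects {d}")
    flat = bank.weights.reshape(bank.n_classifiers, d + 1)
    H = _augment(X) @ flat.T
    if output == "label":
        H = np.where(H >= 0, 1.0, -1.0)
    elif output != "margin":
        raise ConfigError(f"unknown bank output mode {output!r}")
    return H
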