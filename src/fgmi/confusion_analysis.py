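"""Confusion-profile estimation and confused-class subset selection.

For each class c and base model m the base model's predictions on the
training images of class c are tallied into a per-class prediction
distribution d_c^m (a length-C vector of proportions summing to 1, sorted
non-increasingly for inspection).  The K classes on which class c's images
are most often misclassified — class c itself excluded from the ranking —
are selected, and the training images of those K classes plus class c form
that class's misclassification subset.

When a base model fits its training data too well the resubstitution
confusion profile degenerates (all mass on c); two mitigations are
provided: stratified cross-prediction of the confusion estimates
(``confusion_cv``), and a soft fallback that fills unfilled top-K slots by
the mean score class-c images assign to each other class.

All tie-breaks are toward the lower class index; the module is fully
deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import BaseModelHandle
from .errors import ConfigError

__all__ = [
    "ScoreMatrix",
    "ConfusionProfile",
    "SubsetSpec",
    "predict_with_base",
    "confusion_profile",
    "select_top_k",
    "build_subset",
    "analyze_confusion",
    "confusion_matrix_table",
]


@dataclasses.dataclass(frozen=True)
class ScoreMatrix:
    """Per-class scores of one base model with argmax predictions.

    ``predicted_labels`` are 1-based; ties go to the lowest class index.
    """

    scores: np.ndarray  # (N, C)
    model_index: int = 1

    @property
    def predicted_labels(self) -> np.ndarray:
        if self.scores.shape[0] == 0:
            return np.zeros(0, dtype=np.int64)
        return np.argmax(self.scores, axis=1).astype(np.int64) + 1

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]


@dataclasses.dataclass(frozen=True)
class ConfusionProfile:
    """Prediction distribution of one true class under one base model.

    proportions : fraction of class-c training images predicted as each
        class; non-negative, sums to 1.
    sorted_order : class indices (1-based) ordering proportions
        non-increasingly, ties toward the lower index.
    mean_scores : mean score the class-c images assign to each class;
        used only as a soft fallback when too few classes carry
        misclassification mass.
    """

    class_index: int
    model_index: int
    proportions: np.ndarray
    sorted_order: np.ndarray
    mean_scores: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class SubsetSpec:
    """The misclassification subset of one (class, model) pair."""

    class_index: int
    model_index: int
    selected_classes: tuple[int, ...]  # K confused classes, c excluded
    member_indices: np.ndarray  # training rows whose label is in the subset

    @property
    def member_classes(self) -> tuple[int, ...]:
        """Class c first, then the selected classes in rank order."""
        return (self.class_index, *self.selected_classes)

    @property
    def subset_size(self) -> int:
        return int(self.member_indices.shape[0])


def predict_with_base(model: BaseModelHandle, X: np.ndarray) -> ScoreMatrix:
    """Score a feature matrix with a base model.

    Returns an (N, C) :class:`ScoreMatrix`; an empty input yields an empty
    score matrix rather than an error.
    """
    X = np.asarray(X, dtype=np.float64)
    scores = np.asarray(model.score_fn(X), dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != X.shape[0]:
        raise ConfigError(
            f"base model returned shape {scores.shape} for {X.shape[0]} rows"
        )
    return ScoreMatrix(scores=scores, model_index=model.model_index)


def _descending_order(values: np.ndarray) -> np.ndarray:
    """Indices sorting values non-increasingly, ties toward lower index."""
    return np.argsort(-values, kind="stable")


def confusion_profile(pred: ScoreMatrix, y: np.ndarray, c: int) -> ConfusionProfile:
    """Per-class prediction distribution for true class ``c``.

    ``proportions[j-1]`` is the fraction of class-c images the model
    predicts as class j.
    """
    y = np.asarray(y, dtype=np.int64)
    n_classes = pred.n_classes
    mask = y == c
    n_c = int(mask.sum())
    if n_c == 0:
        raise ConfigError(f"class {c} has no training images")
    predicted = pred.predicted_labels[mask]
    counts = np.bincount(predicted, minlength=n_classes + 1)[1:]
    proportions = counts / n_c
    order = _descending_order(proportions) + 1
    mean_scores = pred.scores[mask].mean(axis=0)
    return ConfusionProfile(
        class_index=c,
        model_index=pred.model_index,
        proportions=proportions,
        sorted_order=order.astype(np.int64),
        mean_scores=mean_scores,
    )


def select_top_k(profile: ConfusionProfile, K: int) -> list[int]:
    """The K classes most confused with ``profile.class_index``.

    Class c itself is excluded from the ranking (it is always a subset
    member anyway).  If fewer than K other classes carry misclassification
    mass, the remaining slots are filled by descending mean base-model
    score, then by lowest class index.
    """
    c = profile.class_index
    n_classes = profile.proportions.shape[0]
    if K < 1 or K >= n_classes:
        raise ConfigError(f"need 1 <= K < C, got K={K}, C={n_classes}")
    props = profile.proportions
    others = np.array([j for j in range(1, n_classes + 1) if j != c])
    ranked = others[_descending_order(props[others - 1])]
    selected = [int(j) for j in ranked if props[j - 1] > 0][:K]
    if len(selected) < K:
        if profile.mean_scores is None:
            filler = [int(j) for j in others if j not in selected]
        else:
            pool = np.array([j for j in others if j not in selected])
            filler = [int(j) for j in pool[_descending_order(profile.mean_scores[pool - 1])]]
        selected.extend(filler[: K - len(selected)])
    return selected


def build_subset(
    y: np.ndarray, c: int, selected: list[int] | tuple[int, ...], m: int = 1
) -> SubsetSpec:
    """Collect the training rows of class c and its selected classes."""
    selected = tuple(int(j) for j in selected)
    if c in selected:
        raise ConfigError(f"selected classes must not contain class {c} itself")
    if len(set(selected)) != len(selected):
        raise ConfigError("selected classes must be distinct")
    y = np.asarray(y, dtype=np.int64)
    members = np.isin(y, np.array((c,) + selected))
    return SubsetSpec(
        class_index=c,
        model_index=m,
        selected_classes=selected,
        member_indices=np.flatnonzero(members),
    )


def analyze_confusion(
    pred: ScoreMatrix, y: np.ndarray, K: int
) -> tuple[list[ConfusionProfile], list[SubsetSpec]]:
    """Profiles and misclassification subsets for every class at once."""
    y = np.asarray(y, dtype=np.int64)
    profiles, subsets = [], []
    for c in range(1, pred.n_classes + 1):
        prof = confusion_profile(pred, y, c)
        sel = select_top_k(prof, K)
        profiles.append(prof)
        subsets.append(build_subset(y, c, sel, pred.model_index))
    return profiles, subsets


def confusion_matrix_table(profiles: list[ConfusionProfile]) -> np.ndarray:
    """Stack profiles into a C x C matrix (row = true class, col = predicted)."""
    return np.vstack([p.proportions for p in sorted(profiles, key=lambda p: p.class_index)])
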