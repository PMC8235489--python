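"""Scikit-learn style estimators: the package's primary public surface.

``LinearHingeClassifier`` is the L2-hinge one-vs-all linear classifier used
both as the default base ("prelearned") model and as the learner family for
subset and final classifiers.  ``ConfusionBankTransformer`` turns one
model's features into the stacked C*(K+1) classifier-output representation.
``FGMIClassifier`` runs the full pipeline over M base models: base
predictions -> confusion profiles -> top-K subsets -> confusion banks ->
stacked representations -> final hinge classifiers -> equal-weight fusion.

All estimators follow sklearn conventions (get_params/set_params, fitted
attributes with trailing underscores, clone-compatible constructors), so
the single-model classifiers compose with sklearn pipelines and model
selection.  ``FGMIClassifier`` additionally accepts a *list* of feature
matrices, one per base model, in both fit and predict.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import StratifiedKFold

from .confusion_analysis import ScoreMatrix, analyze_confusion
from .confusion_bank import ConfusionBank, represent, train_bank
from .data_model import DatasetMeta
from .errors import ConfigError, NumericError
from .final_stage import (
    FinalClassifier,
    FusionWeights,
    ablation_no_mi,
    ablation_no_nir,
    decision_scores,
    fuse,
    train_final,
)
from .hinge import fit_standardized_hinge

__all__ = ["LinearHingeClassifier", "ConfusionBankTransformer", "FGMIClassifier"]


def _check_X_y(X, y=None):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ConfigError("X must be a 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise NumericError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y).ravel()
    if y.shape[0] != X.shape[0]:
        raise ConfigError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    return X, y


class LinearHingeClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-all linear classification with L2-regularized hinge loss.

    Each class is separated from the rest by a binary linear classifier
    minimizing ``sum hinge + alpha ||w||^2`` (bias regularized with the
    weights); prediction is the argmax of the per-class decision values,
    ties toward the class listed first in ``classes_``.  Features are
    z-scored internally before each fit (statistics folded back into the
    stored raw-space ``coef_``), which keeps the solver well conditioned
    regardless of feature offsets and scales.

    Parameters
    ----------
    alpha : regularization strength (> 0).
    max_iter, tol : solver epoch cap and relative-objective stopping
        tolerance.
    random_state : kept for API compatibility; the solver is deterministic.

    Notes
    -----
    ``decision_function`` always returns an (N, C) matrix with one column
    per class, including for C = 2, because downstream confusion analysis
    expects per-class score columns.
    """

    def __init__(self, alpha: float = 1.0, max_iter: int = 1000,
                 tol: float = 1e-6, random_state: int | None = None):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ConfigError("need at least two classes")
        W = np.zeros((len(self.classes_), X.shape[1] + 1))
        for i, cls in enumerate(self.classes_):
            y_pm = np.where(y == cls, 1.0, -1.0)
            W[i] = fit_standardized_hinge(
                X, y_pm, alpha=self.alpha, max_iter=self.max_iter, tol=self.tol
            )
        self.coef_ = W[:, :-1]
        self.intercept_ = W[:, -1]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = _check_X_y(X)
        if X.shape[1] != self.n_features_in_:
            raise ConfigError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def _default_base():
    """Default base ("prelearned") model: one-vs-all linear hinge classifier.

    The same learner family as the subset and final stages, emulating the
    margin outputs of prelearned linear SVMs.  Their per-class decision
    values are not calibrated against each other — which is precisely the
    misclassification structure the rest of the pipeline harvests and the
    final stacked stage corrects.  Any classifier with a
    ``decision_function`` can be substituted.
    """
    return LinearHingeClassifier(alpha=1.0)


def _cross_val_scores(base, X, y, n_folds: int, seed: int | None) -> np.ndarray:
    """Out-of-fold decision scores (one column per class in 1..C order)."""
    n_classes = int(y.max())
    scores = np.zeros((X.shape[0], n_classes))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=None if seed is None else int(seed))
    for train_idx, test_idx in skf.split(X, y):
        est = clone(base).fit(X[train_idx], y[train_idx])
        fold = est.decision_function(X[test_idx])
        # fold classes may be a subset; align columns on the fold's classes_
        for j, cls in enumerate(est.classes_):
            scores[test_idx, int(cls) - 1] = fold[:, j]
    return scores


class ConfusionBankTransformer(TransformerMixin, BaseEstimator):
    """Stacked classifier-output representation for one base model.

    Fitting (1) trains/uses a base model, (2) tallies its per-class
    confusion profiles on the training data, (3) selects each class's
    top-K confused classes and (4) trains the C*(K+1) subset classifiers.
    ``transform`` concatenates the raw decision values of all subset
    classifiers into an (N, C*(K+1)) representation.

    Parameters
    ----------
    base_estimator : classifier with ``decision_function``; default is
        :class:`LinearHingeClassifier`.  Cloned and fit on the training
        data (the standard "prelearned on the same training set" setup).
    K : confused classes selected per class (1 <= K < C).
    subset_alpha : regularization of the subset classifiers.
    confusion_cv : 0 estimates confusion by resubstitution; >= 2 uses
        stratified out-of-fold predictions instead, which keeps profiles
        informative when the base model fits its training data perfectly.
    output : "margin" (default) or "label" for the bank outputs.
    """

    def __init__(self, base_estimator=None, K: int = 3, subset_alpha: float = 1.0,
                 confusion_cv: int = 0, output: str = "margin",
                 model_index: int = 1, max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int | None = None):
        self.base_estimator = base_estimator
        self.K = K
        self.subset_alpha = subset_alpha
        self.confusion_cv = confusion_cv
        self.output = output
        self.model_index = model_index
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_X_y(X, y)
        self.classes_ = np.unique(y)
        y_int = np.searchsorted(self.classes_, y) + 1
        n_classes = len(self.classes_)
        if not 1 <= self.K < n_classes:
            raise ConfigError(f"need 1 <= K < C, got K={self.K}, C={n_classes}")
        base = self.base_estimator if self.base_estimator is not None else _default_base()
        self.base_model_ = clone(base).fit(X, y_int)
        self.base_scores_ = np.asarray(self.base_model_.decision_function(X), float)
        if self.confusion_cv and self.confusion_cv >= 2:
            conf_scores = _cross_val_scores(base, X, y_int, self.confusion_cv,
                                            self.random_state)
        else:
            conf_scores = self.base_scores_
        pred = ScoreMatrix(scores=conf_scores, model_index=self.model_index)
        self.profiles_, self.subsets_ = analyze_confusion(pred, y_int, self.K)
        self.bank_ = train_bank(X, y_int, self.subsets_, alpha=self.subset_alpha,
                                max_iter=self.max_iter, tol=self.tol)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _check_X_y(X)
        return represent(X, self.bank_, output=self.output)


class FGMIClassifier(ClassifierMixin, BaseEstimator):
    """Fine-grained classification with misclassification information.

    The full pipeline over M base models.  For every base model a
    :class:`ConfusionBankTransformer` builds the stacked C*(K+1)
    representation; per model, C final one-vs-all hinge classifiers are
    trained on the (optionally per-column standardized) representation,
    and the M per-model class-score matrices are fused with equal weights
    (the mean).  The predicted class is the fused argmax.

    Parameters
    ----------
    base_estimator : base model template, cloned per feature table;
        default :class:`LinearHingeClassifier`.
    K : confused classes per class (1 <= K < C).
    alpha : regularization of the final classifiers (the paper-style
        sensible range is roughly 0.1-10).
    subset_alpha : regularization of the subset classifiers.
    confusion_cv : see :class:`ConfusionBankTransformer`.
    standardize : per-column standardization of the representation
        (statistics from the training split) before the final stage.
    bank_output : "margin" or "label" bank outputs.
    ablation : "none" (full method), "no_mi" (average raw base scores,
        no confusion machinery) or "no_nir" (subset-winner voting, no
        stacked representation); controls prediction only — fitting
        always trains the full pipeline.
    random_state : master seed for the cross-prediction folds.

    ``fit``/``predict`` accept either a single (N, d) matrix (M = 1) or a
    list of M matrices, one per base model.
    """

    def __init__(self, base_estimator=None, K: int = 3, alpha: float = 1.0,
                 subset_alpha: float = 1.0, confusion_cv: int = 0,
                 standardize: bool = True, bank_output: str = "margin",
                 ablation: str = "none", max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.base_estimator = base_estimator
        self.K = K
        self.alpha = alpha
        self.subset_alpha = subset_alpha
        self.confusion_cv = confusion_cv
        self.standardize = standardize
        self.bank_output = bank_output
        self.ablation = ablation
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _as_list(X) -> list[np.ndarray]:
        if isinstance(X, (list, tuple)):
            return [np.asarray(x, dtype=np.float64) for x in X]
        return [np.asarray(X, dtype=np.float64)]

    def _check_fitted_input(self, X) -> list[np.ndarray]:
        Xs = self._as_list(X)
        if len(Xs) != self.meta_.n_models:
            raise ConfigError(
                f"model was trained with {self.meta_.n_models} feature tables, "
                f"got {len(Xs)}"
            )
        for m, (x, d) in enumerate(zip(Xs, self.meta_.feature_dims), start=1):
            _check_X_y(x)
            if x.shape[1] != d:
                raise ConfigError(
                    f"table {m} has {x.shape[1]} features, expected {d}"
                )
        return Xs

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if self.ablation not in ("none", "no_mi", "no_nir"):
            raise ConfigError(f"unknown ablation {self.ablation!r}")
        Xs = self._as_list(X)
        y = np.asarray(y).ravel()
        for x in Xs:
            _check_X_y(x, y)
        self.classes_ = np.unique(y)
        y_int = np.searchsorted(self.classes_, y) + 1
        self.meta_ = DatasetMeta.from_data(Xs, y_int)
        if not 1 <= self.K < self.meta_.n_classes:
            raise ConfigError(
                f"need 1 <= K < C, got K={self.K}, C={self.meta_.n_classes}"
            )

        self.transformers_ = []
        self.final_ = []
        self.bank_means_ = []
        self.bank_scales_ = []
        for m, Xm in enumerate(Xs, start=1):
            seed = None if self.random_state is None else int(self.random_state) + m
            tf = ConfusionBankTransformer(
                base_estimator=self.base_estimator, K=self.K,
                subset_alpha=self.subset_alpha, confusion_cv=self.confusion_cv,
                output=self.bank_output, model_index=m,
                max_iter=self.max_iter, tol=self.tol, random_state=seed,
            ).fit(Xm, y_int)
            H = tf.transform(Xm)
            if self.standardize:
                mean = H.mean(axis=0)
                scale = H.std(axis=0)
                scale[scale == 0] = 1.0
            else:
                mean = np.zeros(H.shape[1])
                scale = np.ones(H.shape[1])
            H_std = (H - mean) / scale
            final = train_final(H_std, y_int, alpha=self.alpha,
                                max_iter=self.max_iter, tol=self.tol,
                                model_index=m)
            self.transformers_.append(tf)
            self.final_.append(final)
            self.bank_means_.append(mean)
            self.bank_scales_.append(scale)
        self.fusion_ = FusionWeights.equal(self.meta_.n_models, self.meta_.n_classes)
        return self

    # -- prediction ------------------------------------------------------

    @property
    def banks_(self) -> list[ConfusionBank]:
        return [tf.bank_ for tf in self.transformers_]

    def _per_model_final_scores(self, Xs: list[np.ndarray]) -> list[np.ndarray]:
        out = []
        for tf, final, mean, scale in zip(self.transformers_, self.final_,
                                          self.bank_means_, self.bank_scales_):
            H = (tf.transform(Xs[tf.model_index - 1]) - mean) / scale
            out.append(decision_scores(H, final))
        return out

    def base_score_matrices(self, Xs) -> list[np.ndarray]:
        """Raw (N, C) score matrices of the M fitted base models."""
        Xs = self._check_fitted_input(Xs)
        return [np.asarray(tf.base_model_.decision_function(x), float)
                for tf, x in zip(self.transformers_, Xs)]

    def decision_function(self, X):
        """Fused (N, C) class scores of the full method."""
        Xs = self._check_fitted_input(X)
        return fuse(self._per_model_final_scores(Xs), self.fusion_).scores

    def predict(self, X):
        Xs = self._check_fitted_input(X)
        if self.ablation == "no_mi":
            labels = ablation_no_mi(self.base_score_matrices(Xs))
        elif self.ablation == "no_nir":
            labels = ablation_no_nir(self.banks_, Xs)
        else:
            labels = fuse(self._per_model_final_scores(Xs),
                          self.fusion_).predicted_labels
        return self.classes_[labels - 1]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        """Fitted state as a plain dict (see :func:`fgmi.data_model.save_model`)."""
        if not hasattr(self, "meta_"):
            raise ConfigError("cannot serialize an unfitted model")
        return {
            "params": self.get_params(deep=False),
            "classes": np.asarray(self.classes_),
            "n_classes": self.meta_.n_classes,
            "K": self.K,
            "meta": {
                "n_images": self.meta_.n_images,
                "n_models": self.meta_.n_models,
                "n_classes": self.meta_.n_classes,
                "feature_dims": list(self.meta_.feature_dims),
            },
            "base_models": [tf.base_model_ for tf in self.transformers_],
            "banks": [
                {"weights": tf.bank_.weights, "orderings": tf.bank_.orderings}
                for tf in self.transformers_
            ],
            "subsets": [
                [(s.class_index, s.selected_classes, s.member_indices)
                 for s in tf.subsets_]
                for tf in self.transformers_
            ],
            "final_coefs": [f.weights for f in self.final_],
            "bank_means": self.bank_means_,
            "bank_scales": self.bank_scales_,
            "fusion": self.fusion_.lambdas,
        }

    @classmethod
    def from_dict(cls, state: dict) -> "FGMIClassifier":
        from .confusion_analysis import SubsetSpec

        clf = cls(**state["params"])
        meta = state["meta"]
        clf.meta_ = DatasetMeta(meta["n_images"], meta["n_models"],
                                meta["n_classes"], tuple(meta["feature_dims"]))
        clf.classes_ = np.asarray(state["classes"])
        clf.transformers_ = []
        for m, (base, bank, subs) in enumerate(
            zip(state["base_models"], state["banks"], state["subsets"]), start=1
        ):
            tf = ConfusionBankTransformer(K=clf.K, model_index=m,
                                          output=clf.bank_output)
            tf.base_model_ = base
            tf.bank_ = ConfusionBank(weights=bank["weights"],
                                     orderings=bank["orderings"], model_index=m)
            tf.subsets_ = [
                SubsetSpec(class_index=c, model_index=m,
                           selected_classes=tuple(sel), member_indices=idx)
                for c, sel, idx in subs
            ]
            tf.n_features_in_ = bank["weights"].shape[2] - 1
            clf.transformers_.append(tf)
        clf.final_ = [
            FinalClassifier(weights=w, alpha=clf.alpha, model_index=m)
            for m, w in enumerate(state["final_coefs"], start=1)
        ]
        clf.bank_means_ = list(state["bank_means"])
        clf.bank_scales_ = list(state["bank_scales"])
        clf.fusion_ = FusionWeights(np.asarray(state["fusion"]))
        return clf
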