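"""Synthetic benchmark generator with planted block-confusion structure.

Fine-grained datasets confuse classifiers in a biased way: a species is
mistaken for the handful of species that look like it, almost never for
the rest.  The generator emulates exactly that with a hierarchical
Gaussian model — B well-separated block centers (mutually >= delta_b
apart), C class means jittered ~delta_w around their block's center, and
images drawn as class mean + isotropic noise sd sigma.  With
delta_b >> delta_w a linear base model confuses classes within a block and
essentially never across blocks, giving a known ground truth ("which
classes are confusable") against which subset selection can be scored.

Each of the M base models sees the shared images plus independent
per-model Gaussian perturbation sd tau, so different models err on
different images and score fusion is non-trivially testable.

All randomness flows from the config seed through named
:class:`numpy.random.SeedSequence` streams, so generation is bit-exactly
reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .confusion_analysis import SubsetSpec
from .errors import ConfigError

__all__ = [
    "BlockConfusionConfig",
    "PlantedTruth",
    "make_confusable_dataset",
    "sample_from_truth",
    "planted_block_recovery_rate",
]


@dataclasses.dataclass(frozen=True)
class BlockConfusionConfig:
    """Generator settings.

    n_classes : C total classes; n_blocks must divide it with C/B >= 2.
    images_per_class : images drawn per class (>= 2).
    feature_dim : d; must be >= n_blocks so block centers can be placed
        along orthogonal directions.
    within_block_separation : delta_w, typical distance between class
        means of the same block (feature units).
    between_block_separation : delta_b, minimum distance between block
        centers; must exceed delta_w.
    noise_sd : sigma of the isotropic image noise.
    n_models : M base models.
    per_model_noise_sd : tau of the independent per-model feature
        perturbation (0 = all models see identical features).
    """

    n_classes: int = 12
    n_blocks: int = 3
    images_per_class: int = 40
    feature_dim: int = 10
    within_block_separation: float = 2.0
    between_block_separation: float = 20.0
    noise_sd: float = 1.0
    n_models: int = 1
    per_model_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_classes % self.n_blocks != 0:
            raise ConfigError("n_blocks must divide n_classes")
        if self.n_classes // self.n_blocks < 2:
            raise ConfigError("need at least 2 classes per block")
        if not (self.between_block_separation > self.within_block_separation > 0):
            raise ConfigError("need delta_b > delta_w > 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.per_model_noise_sd < 0:
            raise ConfigError("per_model_noise_sd must be non-negative")
        if self.images_per_class < 2:
            raise ConfigError("need at least 2 images per class")
        if self.feature_dim < self.n_blocks:
            raise ConfigError("feature_dim must be >= n_blocks")
        if self.n_models < 1:
            raise ConfigError("need at least one model")


@dataclasses.dataclass(frozen=True)
class PlantedTruth:
    """Planted structure: class -> block map and the exact class means."""

    block_of: np.ndarray  # (C,) block id 0..B-1 of each class (index c-1)
    class_means: np.ndarray  # (C, d)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _class_means(cfg: BlockConfusionConfig) -> PlantedTruth:
    rng = _rng(cfg.seed, 0)
    d, b, c = cfg.feature_dim, cfg.n_blocks, cfg.n_classes
    # random orthonormal directions scaled by delta_b: centers are
    # delta_b * sqrt(2) apart, satisfying the >= delta_b contract
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    centers = cfg.between_block_separation * q[:, :b].T  # (B, d)
    block_of = np.repeat(np.arange(b), c // b)
    jitter = rng.standard_normal((c, d))
    jitter *= (cfg.within_block_separation / np.sqrt(2)) / np.linalg.norm(
        jitter, axis=1, keepdims=True
    )
    return PlantedTruth(block_of=block_of, class_means=centers[block_of] + jitter)


def sample_from_truth(
    truth: PlantedTruth,
    images_per_class: int,
    noise_sd: float,
    n_models: int,
    per_model_noise_sd: float,
    seed: int,
    stream: int = 1,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw a fresh image sample from planted class means.

    Returns one (N, d) feature matrix per model and the (N,) label vector
    (classes 1..C, images grouped by class).  ``stream`` namespaces the
    random stream so train and test draws from the same seed differ.
    """
    c, d = truth.class_means.shape
    labels = np.repeat(np.arange(1, c + 1), images_per_class)
    rng = _rng(seed, stream, 0)
    shared = truth.class_means[labels - 1] + noise_sd * rng.standard_normal(
        (labels.shape[0], d)
    )
    features = []
    for m in range(1, n_models + 1):
        rng_m = _rng(seed, stream, m)
        features.append(
            shared + per_model_noise_sd * rng_m.standard_normal(shared.shape)
        )
    return features, labels


def make_confusable_dataset(
    cfg: BlockConfusionConfig,
) -> tuple[list[np.ndarray], np.ndarray, PlantedTruth]:
    """Generate a block-confusable dataset.

    Returns (per-model feature matrices, labels in 1..C, planted truth);
    deterministic in ``cfg.seed``.
    """
    truth = _class_means(cfg)
    features, labels = sample_from_truth(
        truth,
        cfg.images_per_class,
        cfg.noise_sd,
        cfg.n_models,
        cfg.per_model_noise_sd,
        cfg.seed,
        stream=1,
    )
    return features, labels, truth


def planted_block_recovery_rate(
    subsets: list[SubsetSpec], truth: PlantedTruth
) -> float:
    """Fraction of selected confused classes lying in their owner's block.

    Only defined when K equals (classes per block) - 1, i.e. when a
    perfect selection would recover exactly the owner's block mates.
    """
    b = int(truth.block_of.max()) + 1
    c = truth.block_of.shape[0]
    per_block = c // b
    hits = 0
    total = 0
    for s in subsets:
        if len(s.selected_classes) != per_block - 1:
            raise ConfigError(
                f"recovery rate needs K = C/B - 1 = {per_block - 1}, "
                f"got K = {len(s.selected_classes)}"
            )
        own = truth.block_of[s.class_index - 1]
        hits += sum(truth.block_of[j - 1] == own for j in s.selected_classes)
        total += len(s.selected_classes)
    if total == 0:
        raise ConfigError("no subsets given")
    return hits / total
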