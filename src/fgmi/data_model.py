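"""Dataset containers and text/artifact I/O.

Feature tables are delimited numeric text (comma or tab, autodetected from
the first line), one image per row, no header by default.  Labels are plain
text, one integer per line; arbitrary integer labels are relabeled to the
contiguous range 1..C (the internal convention throughout the package) and
the original->contiguous mapping is returned so predictions can be mapped
back.  Trained models round-trip through a single versioned artifact file.

Floats are written with 17 significant digits (``%.17g``), which makes the
write -> read round trip exact for IEEE double precision.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Callable

import joblib
import numpy as np

from .errors import ConfigError, DataFormatError, ModelIOError

__all__ = [
    "DatasetMeta",
    "BaseModelHandle",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
    "save_model",
    "load_model",
]

ARTIFACT_FORMAT = "fgmi-artifact"
ARTIFACT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class DatasetMeta:
    """Shape summary of a multi-model dataset.

    n_images : N, rows shared by every feature table
    n_models : M, number of base ("prelearned") models
    n_classes : C, classes labeled 1..C
    feature_dims : per-model feature dimension, length M
    """

    n_images: int
    n_models: int
    n_classes: int
    feature_dims: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_images < self.n_classes:
            raise ConfigError("need at least one image per class (N >= C)")
        if self.n_models < 1 or self.n_classes < 1:
            raise ConfigError("n_models and n_classes must be positive")
        if len(self.feature_dims) != self.n_models:
            raise ConfigError("feature_dims must have one entry per model")
        if any(d < 1 for d in self.feature_dims):
            raise ConfigError("feature dimensions must be positive")

    @classmethod
    def from_data(cls, features: list[np.ndarray], labels: np.ndarray) -> "DatasetMeta":
        n = len(labels)
        for m, X in enumerate(features, start=1):
            if X.shape[0] != n:
                raise ConfigError(
                    f"feature table {m} has {X.shape[0]} rows but there are {n} labels"
                )
        c = int(labels.max()) if n else 0
        counts = np.bincount(labels, minlength=c + 1)[1:]
        if c == 0 or np.any(counts == 0):
            raise ConfigError("every class in 1..C must appear at least once")
        return cls(n, len(features), c, tuple(int(X.shape[1]) for X in features))


@dataclasses.dataclass(frozen=True)
class BaseModelHandle:
    """A prelearned base model exposed as a score function.

    ``score_fn`` maps an (N, d) feature matrix to an (N, C) score matrix
    with one column per class in class order 1..C.
    """

    score_fn: Callable[[np.ndarray], np.ndarray]
    model_index: int = 1


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_feature_table(
    path: str | os.PathLike,
    delimiter: str | None = None,
    header: bool = False,
) -> np.ndarray:
    """Read a delimited numeric table into an (N, D) float matrix.

    The delimiter is autodetected from the first line (tab, else comma)
    unless given.  Ragged rows and non-numeric cells raise
    :class:`DataFormatError` naming the offending line (1-based, counting
    the header if present).
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read feature table {path}: {exc}") from exc
    start = 1 if header else 0
    rows: list[list[float]] = []
    width = -1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if delimiter is None:
            delimiter = _detect_delimiter(line)
        cells = line.split(delimiter)
        if width == -1:
            width = len(cells)
        elif len(cells) != width:
            raise DataFormatError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {width}"
            )
        try:
            row = [float(c) for c in cells]
        except ValueError:
            raise DataFormatError(f"{path}: line {lineno} has a non-numeric cell") from None
        if not all(np.isfinite(row)):
            raise DataFormatError(f"{path}: line {lineno} has a non-finite value")
        rows.append(row)
    if not rows:
        raise DataFormatError(f"{path}: empty feature table")
    return np.asarray(rows, dtype=np.float64)


def write_feature_table(
    X: np.ndarray, path: str | os.PathLike, delimiter: str = ","
) -> None:
    """Write a feature matrix as delimited text, exact under round trip."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ConfigError("feature table must be 2-D")
    np.savetxt(path, X, fmt="%.17g", delimiter=delimiter)


def read_labels(path: str | os.PathLike) -> tuple[np.ndarray, dict[int, int]]:
    """Read one integer label per line; relabel contiguously to 1..C.

    Returns the contiguous label vector and the original->contiguous
    mapping (sorted by original label, so the relabeling is stable across
    calls on the same file).
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read labels {path}: {exc}") from exc
    raw: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            raw.append(int(line.strip()))
        except ValueError:
            raise DataFormatError(f"{path}: line {lineno} is not an integer") from None
    if not raw:
        raise DataFormatError(f"{path}: empty label file")
    originals = sorted(set(raw))
    mapping = {orig: i + 1 for i, orig in enumerate(originals)}
    labels = np.asarray([mapping[v] for v in raw], dtype=np.int64)
    return labels, mapping


def write_labels(labels: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def save_model(artifact, path: str | os.PathLike) -> None:
    """Serialize a trained model to a single versioned container file.

    ``artifact`` is anything exposing ``to_dict()`` (e.g. a fitted
    :class:`fgmi.estimators.FGMIClassifier`) or a plain state dict.
    """
    state = artifact.to_dict() if hasattr(artifact, "to_dict") else dict(artifact)
    _check_consistent(state)
    payload = {
        "format": ARTIFACT_FORMAT,
        "version": ARTIFACT_VERSION,
        "state": state,
    }
    joblib.dump(payload, path)


def load_model(path: str | os.PathLike):
    """Load a model artifact saved by :func:`save_model`.

    Returns a fitted :class:`fgmi.estimators.FGMIClassifier`.
    """
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot load model artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != ARTIFACT_FORMAT:
        raise ModelIOError(f"{path} is not a model artifact")
    if payload.get("version") != ARTIFACT_VERSION:
        raise ModelIOError(
            f"{path}: unsupported artifact version {payload.get('version')!r}"
        )
    state = payload["state"]
    _check_consistent(state)
    from .estimators import FGMIClassifier

    return FGMIClassifier.from_dict(state)


def _check_consistent(state: dict) -> None:
    """Banks and final classifiers must agree on C and K."""
    try:
        c = int(state["n_classes"])
        k = int(state["K"])
        for bank in state["banks"]:
            if bank["weights"].shape[0] != c or bank["weights"].shape[1] != k + 1:
                raise ModelIOError(
                    f"bank shape {bank['weights'].shape} inconsistent with C={c}, K={k}"
                )
        for coef in state["final_coefs"]:
            if coef.shape != (c, c * (k + 1) + 1):
                raise ModelIOError(
                    f"final classifier shape {coef.shape} inconsistent with C={c}, K={k}"
                )
    except (KeyError, AttributeError, TypeError) as exc:
        raise ModelIOError(f"malformed artifact state: {exc}") from exc
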