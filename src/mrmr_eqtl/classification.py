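"""Nearest-neighbor genotype prediction and jackknife (LOOCV) accuracy.

Samples are compared on their continuous expression over the selected
genes with the cosine distance D = 1 - <u,v>/(||u|| ||v||); a query takes
the genotype of its nearest training sample.  Jackknife accuracy predicts
every sample from the remaining n-1 and aggregates correct calls per
genotype class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["JackknifeResult", "cosine_distance", "nna_predict", "jackknife_accuracy"]

logger = logging.getLogger(__name__)


@dataclass
class JackknifeResult:
    """Leave-one-out accuracy with per-genotype-class breakdown."""

    overall_accuracy: float
    per_class: dict[int, tuple[int, int]]  # class -> (n_correct, n_total)
    n_samples: int

    def __post_init__(self) -> None:
        total = sum(t for _, t in self.per_class.values())
        if total != self.n_samples:
            raise ValueError("per-class totals do not sum to n_samples")


def _norms(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=-1)
    if np.any(n == 0):
        raise ValueError("zero-norm feature vector: cosine similarity undefined")
    return n


def cosine_distance(v1: Sequence[float], v2: Sequence[float]) -> float:
    """1 - cosine similarity; 0 for parallel, 1 for orthogonal, 2 for antipodal."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("cosine_distance expects two equal-length 1-D vectors")
    na, nb = _norms(a), _norms(b)
    return float(1.0 - np.dot(a, b) / (na * nb))


def nna_predict(train: np.ndarray, labels: Sequence[int], query: Sequence[float]) -> int:
    """Label of the training sample nearest to ``query`` in cosine distance.

    Ties are broken by the smallest training index.
    """
    X = np.asarray(train, dtype=float)
    y = np.asarray(labels)
    q = np.asarray(query, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("train must be a non-empty samples x features matrix")
    if y.size != X.shape[0]:
        raise ValueError("labels length must match number of training samples")
    if q.shape != (X.shape[1],):
        raise ValueError("query length must match feature count")
    d = 1.0 - (X @ q) / (_norms(X) * _norms(q))
    return int(y[int(np.argmin(d))])


def jackknife_accuracy(features: np.ndarray, labels: Sequence[int]) -> JackknifeResult:
    """Leave-one-out nearest-neighbor accuracy.

    Each sample is predicted by the nearest of the other n-1 samples; the
    overall accuracy is the fraction of correct calls, also broken down per
    genotype class.  A class with a single member is allowed (it can never
    be predicted correctly) and is logged as a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a samples x features matrix")
    n = X.shape[0]
    if n < 2:
        raise ValueError("jackknife requires at least 2 samples")
    if X.shape[1] < 1:
        raise ValueError("jackknife requires at least 1 feature")
    if y.size != n:
        raise ValueError("labels length must match sample count")

    classes, counts = np.unique(y, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt == 1:
            logger.warning("genotype class %s has a single sample; it cannot be predicted correctly", c)

    norms = _norms(X)
    dist = 1.0 - (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(dist, np.inf)  # a sample never votes for itself
    nearest = np.argmin(dist, axis=1)  # ties -> smallest index
    predictions = y[nearest]
    correct = predictions == y

    per_class: dict[int, tuple[int, int]] = {}
    for c in classes:
        sel = y == c
        per_class[int(c)] = (int(correct[sel].sum()), int(sel.sum()))
    overall = float(correct.sum() / n)
    return JackknifeResult(overall_accuracy=overall, per_class=per_class, n_samples=n)
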