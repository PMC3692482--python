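"""Incremental feature selection over a gene ranking.

Nested prefixes of the ranked gene list are scored by jackknife
nearest-neighbor accuracy; the optimal affected-gene set is the shortest
prefix attaining the maximum of the resulting accuracy curve.  The full
curve is always computed (no early stopping) since it is itself an output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["IfsResult", "run_ifs"]


@dataclass
class IfsResult:
    """Accuracy curve over ranking prefixes and the optimal prefix."""

    curve: list[tuple[int, float]]  # (k, jackknife accuracy) for k = 1..K
    optimal_k: int
    optimal_genes: list[str]
    optimal_accuracy: float

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["k", "accuracy"])


def run_ifs(
    gene_order: Sequence[str],
    features: np.ndarray,
    labels: Sequence[int],
) -> IfsResult:
    """Score every prefix of a ranked gene list by LOOCV accuracy.

    Parameters
    ----------
    gene_order
        Ranked gene ids (mRMR or MaxRel order).
    features
        Continuous samples x genes matrix with columns in ``gene_order``.
    labels
        Per-sample genotype classes.

    The Gram matrix of the prefix features is grown one gene at a time, so
    the whole curve costs O(K n^2).  Curve point k depends only on the
    first k genes; on ties for the maximum accuracy the smallest k wins.
    """
    gene_order = list(gene_order)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    k_max = len(gene_order)
    if k_max == 0:
        raise ValueError("run_ifs requires a non-empty ranking")
    if X.ndim != 2 or X.shape[1] != k_max:
        raise ValueError("features must be samples x len(gene_order)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("run_ifs requires at least 2 samples")
    if y.size != n:
        raise ValueError("labels length must match sample count")

    curve: list[tuple[int, float]] = []
    gram = np.zeros((n, n))
    sq = np.zeros(n)
    for k in range(1, k_max + 1):
        col = X[:, k - 1]
        gram += np.outer(col, col)
        sq += col * col
        if np.any(sq == 0):
            raise ValueError(
                f"zero-norm sample over the first {k} selected genes: "
                "cosine distance undefined"
            )
        norms = np.sqrt(sq)
        dist = 1.0 - gram / np.outer(norms, norms)
        np.fill_diagonal(dist, np.inf)
        predictions = y[np.argmin(dist, axis=1)]
        curve.append((k, float((predictions == y).sum() / n)))

    accuracies = np.array([a for _, a in curve])
    optimal_k = int(np.argmax(accuracies)) + 1  # first max -> smallest k
    return IfsResult(
        curve=curve,
        optimal_k=optimal_k,
        optimal_genes=gene_order[:optimal_k],
        optimal_accuracy=float(accuracies[optimal_k - 1]),
    )
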