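"""Discretization and plug-in information estimators.

All information quantities are reported in bits (log base 2) and use the
plug-in (maximum-likelihood) estimator on empirical contingency counts,
with no bias correction.  Continuous expression values are discretized per
gene into three states (low / typical / high) at mean +/- t standard
deviations before any mutual-information computation; genotype vectors are
already discrete (1/2/3) and are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiscretizationRule",
    "discretize_gene",
    "discretize_matrix",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "mi_profile",
    "cmi_profile",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """Three-state per-gene discretization at mean +/- t standard deviations.

    ``t`` is expressed in (population) standard deviations of the gene's
    expression vector; the default of 1.0 SD mirrors the historical default
    of discrete-MI feature-selection software.
    """

    t: float = 1.0

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"discretization threshold must be > 0, got {self.t}")


def discretize_gene(
    values: Sequence[float], rule: DiscretizationRule | None = None
) -> np.ndarray:
    """Map a continuous expression vector to states {-1, 0, +1}.

    State -1 if v < mu - t*sigma, +1 if v > mu + t*sigma, 0 otherwise,
    where mu and sigma are the vector's mean and population standard
    deviation.  A constant vector (sigma = 0) maps to all zeros.
    """
    rule = rule or DiscretizationRule()
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D expression vector")
    if v.size < 2:
        raise ValueError("discretization requires at least 2 samples")
    if not np.all(np.isfinite(v)):
        raise ValueError("expression vector contains non-finite values")
    mu = v.mean()
    sd = v.std()
    states = np.zeros(v.size, dtype=np.int8)
    if sd > 0:
        states[v < mu - rule.t * sd] = -1
        states[v > mu + rule.t * sd] = 1
    return states


def discretize_matrix(
    values: np.ndarray, rule: DiscretizationRule | None = None
) -> np.ndarray:
    """Row-wise :func:`discretize_gene` for a genes x samples matrix."""
    rule = rule or DiscretizationRule()
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    if m.shape[1] < 2:
        raise ValueError("discretization requires at least 2 samples")
    if not np.all(np.isfinite(m)):
        raise ValueError("expression matrix contains non-finite values")
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    lo = mu - rule.t * sd
    hi = mu + rule.t * sd
    states = np.where(m < lo, -1, np.where(m > hi, 1, 0)).astype(np.int8)
    states[sd.ravel() == 0] = 0  # constant genes stay all-zero
    return states


def _as_state_vector(x: Sequence[int]) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1:
        raise ValueError("expected a 1-D discrete state vector")
    if a.size < 1:
        raise ValueError("state vector must have length >= 1")
    return a


def _joint_codes(vectors: list[np.ndarray]) -> np.ndarray:
    """Encode the per-sample joint state of several vectors as one integer code."""
    n = vectors[0].size
    codes = np.zeros(n, dtype=np.int64)
    for a in vectors:
        if a.size != n:
            raise ValueError("all vectors must have equal length")
        _, inv = np.unique(a, return_inverse=True)
        codes = codes * (int(inv.max()) + 1) + inv
    return codes


def _counts(vectors: list[np.ndarray]) -> np.ndarray:
    codes = _joint_codes(vectors)
    _, compact = np.unique(codes, return_inverse=True)
    return np.bincount(compact)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    # summing sorted terms makes the result invariant to cell enumeration order
    return float(-np.sort(p * np.log2(p)).sum())


def entropy(*vectors: Sequence[int]) -> float:
    """Joint plug-in entropy H(x1, ..., xk) in bits, with 0*log(0) = 0."""
    if not vectors:
        raise ValueError("entropy requires at least one vector")
    arrs = [_as_state_vector(v) for v in vectors]
    return _entropy_from_counts(_counts(arrs))


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information I(x; y) in bits.

    Computed as sum over contingency cells of p(x,y) log2[p(x,y)/(p(x)p(y))].
    Symmetric by construction (cell terms are summed in sorted order), and 0
    for a single sample.  Tiny negative rounding residues (> -1e-12) are
    possible and left uncorrected.
    """
    a = _as_state_vector(x)
    b = _as_state_vector(y)
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    ka = int(ia.max()) + 1
    kb = int(ib.max()) + 1
    table = np.bincount(ia * kb + ib, minlength=ka * kb).reshape(ka, kb)
    return _mi_from_table(table)


def _mi_from_table(table: np.ndarray) -> float:
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    nz = table > 0
    t = table[nz].astype(float)
    terms = t * np.log2(t)
    cell_sum = float(np.sort(terms).sum())
    r = rows[rows > 0].astype(float)
    c = cols[cols > 0].astype(float)
    row_sum = float(np.sort(r * np.log2(r)).sum())
    col_sum = float(np.sort(c * np.log2(c)).sum())
    # group the marginal sums so transposing the table cannot change the result
    return (cell_sum - (row_sum + col_sum) + n * np.log2(n)) / n


def _stack_condition(z) -> list[np.ndarray]:
    if isinstance(z, (tuple, list)):
        return [_as_state_vector(v) for v in z]
    return [_as_state_vector(z)]


def conditional_mutual_information(x, y, z) -> float:
    """Conditional mutual information I(x; y | z) in bits.

    Uses the entropy identity I(x;y|z) = H(x,z) + H(y,z) - H(z) - H(x,y,z);
    ``z`` may be a single state vector or a tuple of them (joint condition).
    Non-negative up to ~1e-12 rounding.
    """
    a = _as_state_vector(x)
    b = _as_state_vector(y)
    zs = _stack_condition(z)
    return (
        entropy(a, *zs) + entropy(b, *zs) - entropy(*zs) - entropy(a, b, *zs)
    )


# ---------------------------------------------------------------------------
# Vectorized profiles (one target vector against many gene state rows).
# These are the pipeline's workhorses; they compute the same plug-in MI as
# mutual_information, cell terms summed in sorted order per gene.
# ---------------------------------------------------------------------------


def mi_profile(states: np.ndarray, target: np.ndarray) -> np.ndarray:
    """I(gene_g; target) in bits for every row g of a genes x samples state matrix."""
    X = np.asarray(states)
    y = _as_state_vector(target)
    if X.ndim != 2:
        raise ValueError("states must be a 2-D genes x samples matrix")
    if X.shape[1] != y.size:
        raise ValueError(f"sample mismatch: {X.shape[1]} vs {y.size}")
    n = y.size
    x0 = X - X.min()
    kx = int(x0.max()) + 1 if x0.size else 1
    _, iy = np.unique(y, return_inverse=True)
    ky = int(iy.max()) + 1
    onehot = np.zeros((n, ky), dtype=np.float64)
    onehot[np.arange(n), iy] = 1.0
    counts = np.empty((X.shape[0], kx, ky), dtype=np.float64)
    for a in range(kx):
        counts[:, a, :] = (x0 == a).astype(np.float64) @ onehot
    rows = counts.sum(axis=2)
    cols = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell = np.where(counts > 0, counts * np.log2(counts), 0.0)
        rterm = np.where(rows > 0, rows * np.log2(rows), 0.0)
        cterm = np.where(cols > 0, cols * np.log2(cols), 0.0)
    cell_sum = np.sort(cell.reshape(X.shape[0], -1), axis=1).sum(axis=1)
    row_sum = np.sort(rterm, axis=1).sum(axis=1)
    col_sum = np.sort(cterm, axis=1).sum(axis=1)
    return (cell_sum - (row_sum + col_sum) + n * np.log2(n)) / n


def cmi_profile(states: np.ndarray, target: np.ndarray, condition) -> np.ndarray:
    """I(gene_g; target | condition) for every row g, by stratification.

    Equals sum over condition strata of p(z) * I(gene; target | z-stratum);
    identical to the entropy identity for plug-in estimates.
    """
    X = np.asarray(states)
    y = _as_state_vector(target)
    zs = _stack_condition(condition)
    codes = _joint_codes(zs)
    if codes.size != y.size or X.shape[1] != y.size:
        raise ValueError("states, target and condition must share sample count")
    n = y.size
    out = np.zeros(X.shape[0], dtype=float)
    for code in np.unique(codes):
        sel = codes == code
        w = sel.sum() / n
        out += w * mi_profile(X[:, sel], y[sel])
    return out
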