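"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with plain dict/loop arithmetic and
``math.fsum`` (correctly rounded summation), sharing no code with the
package's vectorized paths.
"""

from __future__ import annotations

import math
from collections import Counter


def joint_entropy_oracle(*vectors) -> float:
    """H(x1,...,xk) by direct cell counting."""
    n = len(vectors[0])
    counts = Counter(zip(*vectors))
    return -math.fsum((c / n) * math.log2(c / n) for c in counts.values())


def mi_oracle(x, y) -> float:
    """Plug-in MI by direct evaluation of the contingency-table formula."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    return math.fsum(
        (c / n) * math.log2((c / n) / ((px[a] / n) * (py[b] / n)))
        for (a, b), c in joint.items()
    )


def cmi_oracle(x, y, z) -> float:
    """I(x;y|z) as the stratified sum over condition values of p(z) I(x;y|z)."""
    n = len(x)
    strata = {}
    for xi, yi, zi in zip(x, y, z):
        strata.setdefault(zi, ([], []))
        strata[zi][0].append(xi)
        strata[zi][1].append(yi)
    return math.fsum(
        (len(xs) / n) * mi_oracle(xs, ys) for xs, ys in strata.values()
    )


def greedy_mrmr_oracle(states_rows, target, k, scheme="mid"):
    """Greedy mRMR selection order by exhaustive per-round scans.

    states_rows: list of per-gene state lists; returns list of selected
    row indices.  Round 1 maximizes MI with the target; later rounds
    maximize relevance - mean redundancy (or the quotient).  Scores within
    1e-12 of the round maximum are ties and go to the lowest index.
    """
    n_genes = len(states_rows)
    relevance = [mi_oracle(g, target) for g in states_rows]
    selected: list[int] = []
    remaining = list(range(n_genes))
    pair_mi: dict[tuple[int, int], float] = {}

    def mi_cached(i, j):
        key = (min(i, j), max(i, j))
        if key not in pair_mi:
            pair_mi[key] = mi_oracle(states_rows[i], states_rows[j])
        return pair_mi[key]

    for _ in range(k):
        scores = {}
        for i in remaining:
            if not selected:
                scores[i] = relevance[i]
            else:
                red = math.fsum(mi_cached(i, j) for j in selected) / len(selected)
                if scheme == "mid":
                    scores[i] = relevance[i] - red
                else:
                    scores[i] = relevance[i] / max(red, 1e-12)
        best = max(scores.values())
        pick = min(i for i in remaining if scores[i] >= best - 1e-12)
        selected.append(pick)
        remaining.remove(pick)
    return selected


def loocv_nna_oracle(features, labels) -> float:
    """Hand-unrolled leave-one-out nearest-neighbor accuracy (cosine)."""
    n = len(features)

    def cosine(u, v):
        dot = math.fsum(a * b for a, b in zip(u, v))
        nu = math.sqrt(math.fsum(a * a for a in u))
        nv = math.sqrt(math.fsum(b * b for b in v))
        return 1.0 - dot / (nu * nv)

    correct = 0
    for i in range(n):
        best_j, best_d = None, None
        for j in range(n):
            if j == i:
                continue
            d = cosine(features[i], features[j])
            if best_d is None or d < best_d:
                best_j, best_d = j, d
        correct += labels[best_j] == labels[i]
    return correct / n


def pr_curve_oracle(ranked_is_positive):
    """(recall, precision) after each rank, for a fully ordered ranking."""
    n_pos = sum(ranked_is_positive)
    points = []
    tp = 0
    for i, flag in enumerate(ranked_is_positive, start=1):
        tp += flag
        points.append((tp / n_pos, tp / i))
    return points


def average_precision_oracle(ranked_is_positive) -> float:
    """AP = mean over positives of precision at their ranks."""
    n_pos = sum(ranked_is_positive)
    tp = 0
    total = 0.0
    for i, flag in enumerate(ranked_is_positive, start=1):
        if flag:
            tp += 1
            total += tp / i
    return total / n_pos


def hypergeom_tail_oracle(N, K, n, k) -> float:
    """P(X >= k) by exact enumeration of binomial coefficients."""
    denom = math.comb(N, n)
    return math.fsum(
        math.comb(K, j) * math.comb(N - K, n - j) / denom
        for j in range(k, min(n, K) + 1)
    )
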