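"""Precision-recall evaluation of SNP-gene association scores.

Candidate pairs are ranked by a score (e.g. the MaxRel mutual information);
precision and recall against the planted truth are evaluated tie-aware at
every distinct score threshold, and the area under the PR curve is the
average-precision step integral.  Relative AUPR (RAUPR) rescales a set of
AUPRs by their maximum.  ``consensus_counts`` measures how many of a
reference table's pairs are confirmed by other methods' tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mrmr_eqtl.data_io import EqtlTable, ExpressionMatrix, GenotypeMatrix
from mrmr_eqtl.infotheory import DiscretizationRule, discretize_matrix, mi_profile
from mrmr_eqtl.simulator import SyntheticTruth

__all__ = [
    "PrCurve",
    "precision_recall",
    "aupr",
    "raupr",
    "consensus_counts",
    "relevance_scores",
    "pearson_abs_scores",
]

Pair = tuple[str, str]


@dataclass
class PrCurve:
    """(recall, precision) points at descending score thresholds."""

    points: list[tuple[float, float]]
    n_positives: int


def precision_recall(
    scores: Mapping[Pair, float],
    truth: SyntheticTruth | set[Pair],
    universe: Sequence[Pair],
) -> PrCurve:
    """Tie-aware precision-recall curve over an explicit candidate universe.

    Pairs absent from ``scores`` count as lowest-scored, so the recall
    denominator is always |truth|.  Pairs sharing a score form one
    threshold group; the curve has one point per distinct threshold, which
    makes it invariant to within-tie input order.
    """
    positives = truth.pair_set() if isinstance(truth, SyntheticTruth) else set(truth)
    if not positives:
        raise ValueError("empty truth: recall undefined")
    universe = list(universe)
    uni_set = set(universe)
    if len(uni_set) != len(universe):
        raise ValueError("universe contains duplicate pairs")
    if not positives <= uni_set:
        raise ValueError("truth pairs must be a subset of the universe")
    unknown = set(scores) - uni_set
    if unknown:
        raise ValueError(f"{len(unknown)} scored pairs are outside the universe")

    s = np.array([scores.get(p, -np.inf) for p in universe], dtype=float)
    is_pos = np.array([p in positives for p in universe])
    order = np.argsort(-s, kind="stable")
    s = s[order]
    is_pos = is_pos[order]

    n_pos = int(is_pos.sum())
    tp = np.cumsum(is_pos)
    ranks = np.arange(1, len(universe) + 1)
    # last index of each tie group = a distinct threshold
    group_end = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    points = [
        (float(tp[i] / n_pos), float(tp[i] / ranks[i])) for i in group_end
    ]
    return PrCurve(points=points, n_positives=n_pos)


def aupr(curve: PrCurve) -> float:
    """Average-precision step integral sum_i (R_i - R_{i-1}) * P_i."""
    total = 0.0
    prev_recall = 0.0
    for recall, precision in curve.points:
        total += (recall - prev_recall) * precision
        prev_recall = recall
    return float(total)


def raupr(auprs: Sequence[float]) -> list[float]:
    """Rescale AUPRs by their maximum (the best method maps to 1.0)."""
    values = list(auprs)
    if not values:
        raise ValueError("raupr requires at least one AUPR value")
    top = max(values)
    if top <= 0:
        raise ValueError("raupr requires a positive maximum AUPR")
    return [v / top for v in values]


def consensus_counts(
    tables: Sequence[EqtlTable],
    reference_index: int = 0,
    min_confirmations: int = 1,
) -> tuple[float, int]:
    """Fraction of the reference table's pairs found in >= k other tables."""
    if not 0 <= reference_index < len(tables):
        raise ValueError("reference_index out of range")
    if min_confirmations < 1:
        raise ValueError("min_confirmations must be >= 1")
    reference = tables[reference_index].pairs()
    if not reference:
        raise ValueError("reference table is empty")
    others = [t.pairs() for i, t in enumerate(tables) if i != reference_index]
    n_confirmed = sum(
        1
        for pair in reference
        if sum(pair in o for o in others) >= min_confirmations
    )
    return n_confirmed / len(reference), n_confirmed


# ---------------------------------------------------------------------------
# Whole-matrix association scores for benchmarking rankings.
# ---------------------------------------------------------------------------


def relevance_scores(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    t: float = 1.0,
) -> dict[Pair, float]:
    """MaxRel score (MI of discretized expression with genotype) for all pairs."""
    states = discretize_matrix(expression.values, DiscretizationRule(t))
    out: dict[Pair, float] = {}
    for i, snp in enumerate(genotypes.marker_ids):
        keep = ~genotypes.missing[i]
        mi = mi_profile(states[:, keep], genotypes.values[i, keep])
        for g, gene in enumerate(expression.gene_ids):
            out[(snp, gene)] = float(mi[g])
    return out


def pearson_abs_scores(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
) -> dict[Pair, float]:
    """|Pearson r| of expression with the additive genotype dose, per pair.

    The linear-model baseline: blind to pure-dominance (heterozygote-only)
    effects that mutual information can detect.
    """
    out: dict[Pair, float] = {}
    E = expression.values
    for i, snp in enumerate(genotypes.marker_ids):
        keep = ~genotypes.missing[i]
        g = genotypes.values[i, keep].astype(float)
        X = E[:, keep]
        gc = g - g.mean()
        Xc = X - X.mean(axis=1, keepdims=True)
        denom = np.sqrt((Xc**2).sum(axis=1) * (gc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (Xc @ gc) / denom, 0.0)
        for gidx, gene in enumerate(expression.gene_ids):
            out[(snp, gene)] = float(abs(r[gidx]))
    return out
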