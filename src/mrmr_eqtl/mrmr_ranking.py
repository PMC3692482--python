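"""Per-SNP gene ranking by maximum relevance and by mRMR.

Relevance of a gene is its mutual information with the genotype class;
redundancy is its mean mutual information with the already-selected genes.
Greedy mRMR selection uses the difference criterion (MID): round one picks
the most relevant gene, later rounds pick argmax(relevance - redundancy).
The quotient criterion (MIQ) is available as an alternative scheme.  With
covariates supplied, relevance is computed as conditional mutual
information given the joint covariate state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from mrmr_eqtl.infotheory import cmi_profile, mi_profile, mutual_information

__all__ = ["FeatureRanking", "relevance", "redundancy", "mrmr_rank"]

_MIQ_EPS = 1e-12  # redundancy floor for the quotient scheme
_TIE_TOL = 1e-12  # scores closer than this are ties (input order wins)


@dataclass
class FeatureRanking:
    """Ordered gene lists for one SNP.

    ``maxrel`` covers all genes, sorted by relevance (bits, descending,
    ties by input order).  ``mrmr`` holds the first K greedily selected
    genes as (gene_id, mrmr_score, relevance_bits) in selection order.
    """

    snp_id: str
    maxrel: list[tuple[str, float]]
    mrmr: list[tuple[str, float, float]]

    @property
    def k(self) -> int:
        return len(self.mrmr)

    def gene_order(self, which: str = "mrmr") -> list[str]:
        if which == "mrmr":
            return [g for g, _, _ in self.mrmr]
        if which == "maxrel":
            return [g for g, _ in self.maxrel]
        raise ValueError(f"unknown list {which!r} (expected 'mrmr' or 'maxrel')")


def relevance(gene: Sequence[int], genotype: Sequence[int]) -> float:
    """I(gene; genotype) in bits."""
    return mutual_information(gene, genotype)


def redundancy(gene: Sequence[int], selected: Sequence[Sequence[int]]) -> float:
    """Mean I(gene; s) over the already-selected genes s."""
    if len(selected) == 0:
        raise ValueError("redundancy requires at least one selected gene")
    return float(np.mean([mutual_information(gene, s) for s in selected]))


def mrmr_rank(
    states: np.ndarray,
    gene_ids: Sequence[str],
    genotype: Sequence[int],
    k: int,
    snp_id: str = "",
    scheme: str = "mid",
    covariates: Optional[Sequence[Sequence[int]]] = None,
) -> FeatureRanking:
    """Greedy mRMR selection of ``k`` genes plus the full MaxRel ranking.

    Parameters
    ----------
    states
        Discretized genes x samples state matrix.
    gene_ids
        Row labels of ``states``.
    genotype
        Per-sample genotype class labels (the target).
    k
        Number of genes to carry into the mRMR list (<= number of genes).
    scheme
        ``"mid"`` scores candidates by relevance - redundancy, ``"miq"`` by
        relevance / max(redundancy, eps).
    covariates
        Optional discrete covariate vectors; relevance then becomes
        conditional MI given their joint state (redundancy stays plain MI).

    Ties are broken by input gene order (first wins); scores within 1e-12
    of the round maximum count as tied, so genes whose contingency tables
    are permutations of each other (equal MI up to float rounding) resolve
    deterministically.  Selection is deterministic.
    """
    X = np.asarray(states)
    if X.ndim != 2:
        raise ValueError("states must be a 2-D genes x samples matrix")
    n_genes = X.shape[0]
    if n_genes == 0:
        raise ValueError("mrmr_rank requires at least one gene")
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must match number of state rows")
    if not 1 <= k <= n_genes:
        raise ValueError(f"k must be in [1, {n_genes}], got {k}")
    if scheme not in ("mid", "miq"):
        raise ValueError(f"unknown mrmr scheme {scheme!r}")
    y = np.asarray(genotype)
    if y.size != X.shape[1]:
        raise ValueError("genotype length must match sample count")

    if covariates:
        d = cmi_profile(X, y, tuple(covariates))
    else:
        d = mi_profile(X, y)

    order = np.argsort(-d, kind="stable")
    maxrel = [(str(gene_ids[i]), float(d[i])) for i in order]

    selected: list[int] = []
    mrmr: list[tuple[str, float, float]] = []
    red_sum = np.zeros(n_genes)
    available = np.ones(n_genes, dtype=bool)
    for round_no in range(k):
        if round_no == 0:
            score = d.copy()
        else:
            r = red_sum / round_no
            if scheme == "mid":
                score = d - r
            else:
                score = d / np.maximum(r, _MIQ_EPS)
        score[~available] = -np.inf
        # first index within tolerance of the max wins -> input-order ties
        pick = int(np.argmax(score >= score.max() - _TIE_TOL))
        selected.append(pick)
        available[pick] = False
        mrmr.append((str(gene_ids[pick]), float(score[pick]), float(d[pick])))
        if round_no < k - 1:
            red_sum += mi_profile(X, X[pick])
    return FeatureRanking(snp_id=snp_id, maxrel=maxrel, mrmr=mrmr)
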