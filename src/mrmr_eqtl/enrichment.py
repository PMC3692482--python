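"""Hypergeometric over-representation of a partner gene list.

For each SNP, tests whether its affected-gene set overlaps a partner list
(e.g. a hub gene's interaction partners) more than expected by chance,
using the upper tail of the hypergeometric distribution.  No
multiple-testing correction is applied by default; significance is flagged
at a raw p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from mrmr_eqtl.data_io import EqtlTable

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "enrich_all"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of one SNP's affected genes with the partner list."""

    snp_id: str
    k_overlap: int
    n_affected: int
    k_partners: int
    n_universe: int
    p_value: float
    significant: bool


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_all(
    table: EqtlTable,
    partner_set: Iterable[str],
    universe_set: Iterable[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail test per SNP in an eQTL table.

    The affected set of a SNP is the set of genes in its records,
    intersected with the universe; the partner list is likewise restricted
    to the universe.  Results are flagged at raw ``p < alpha`` by default;
    ``correction="bonferroni"`` divides alpha by the number of SNPs tested.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    universe = set(universe_set)
    if not universe:
        raise ValueError("empty universe")
    partners = set(partner_set) & universe
    affected: dict[str, set[str]] = {}
    for r in table.records:
        affected.setdefault(r.snp_id, set()).add(r.gene_id)

    n_tests = len(affected)
    if correction is None:
        threshold = alpha
    elif correction == "bonferroni":
        threshold = alpha / max(n_tests, 1)
    else:
        raise ValueError(f"unknown correction {correction!r}")

    results = []
    for snp_id in sorted(affected):
        genes = affected[snp_id] & universe
        n = len(genes)
        k = len(genes & partners)
        p = hypergeom_upper_tail(len(universe), len(partners), n, k)
        results.append(
            EnrichmentResult(
                snp_id=snp_id,
                k_overlap=k,
                n_affected=n,
                k_partners=len(partners),
                n_universe=len(universe),
                p_value=p,
                significant=p < threshold,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.snp_id))
    return results
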