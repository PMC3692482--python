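"""Per-SNP eQTL mapping workflow.

For each marker: treat the genotype as a class label, discretize expression,
rank genes by mRMR, score ranking prefixes by nearest-neighbor jackknife
accuracy (IFS), and — if the optimal prefix reaches the accuracy cutoff —
emit one eQTL record per optimal gene, annotated as cis, trans or ambiguous
by genomic distance.  Cis and trans association-score distributions can be
compared with a one-sided Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from joblib import Parallel, delayed
from scipy import stats

from mrmr_eqtl.data_io import (
    EqtlRecord,
    EqtlTable,
    ExpressionMatrix,
    GenotypeMatrix,
    align_samples,
)
from mrmr_eqtl.ifs import IfsResult, run_ifs
from mrmr_eqtl.infotheory import DiscretizationRule, discretize_matrix
from mrmr_eqtl.mrmr_ranking import FeatureRanking, mrmr_rank

__all__ = [
    "PipelineConfig",
    "CisTransSummary",
    "map_eqtls",
    "classify_cis_trans",
    "compare_cis_trans",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the mapping workflow.

    k_rank
        Number of top mRMR genes carried into IFS (clipped to the gene
        count).  Bounds LOOCV cost while exceeding plausible affected-set
        sizes.
    discretize_t
        Expression discretization threshold in standard deviations.
    mrmr_scheme
        "mid" (relevance - redundancy) or "miq" (quotient).
    ifs_list
        Which ranking IFS consumes: "mrmr" (default) or "maxrel".
    accuracy_cutoff
        Minimum LOOCV accuracy for a marker's optimal gene set to be
        reported (0.90 by default).
    cis_window_bp
        Same-chromosome SNP-to-gene-start distance (inclusive) under which
        a pair is called cis; 5 Mb by default.
    covariates
        Optional discrete covariate vectors (each aligned with the shared
        samples) used to condition relevance.
    pooled_ttest
        Use the pooled-variance t-test instead of Welch in
        :func:`compare_cis_trans`.
    threads
        Per-SNP parallelism; results are independent of the thread count.
    """

    k_rank: int = 50
    discretize_t: float = 1.0
    mrmr_scheme: str = "mid"
    ifs_list: str = "mrmr"
    accuracy_cutoff: float = 0.90
    cis_window_bp: int = 5_000_000
    covariates: Optional[list] = None
    pooled_ttest: bool = False
    threads: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_cutoff <= 1.01:
            raise ValueError("accuracy_cutoff must lie in [0, 1] (1.01 allowed to disable)")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")
        if self.k_rank <= 0:
            raise ValueError("k_rank must be positive")
        if self.mrmr_scheme not in ("mid", "miq"):
            raise ValueError(f"unknown mrmr_scheme {self.mrmr_scheme!r}")
        if self.ifs_list not in ("mrmr", "maxrel"):
            raise ValueError(f"unknown ifs_list {self.ifs_list!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class CisTransSummary:
    """Counts and a one-sided cis > trans score comparison."""

    n_cis: int
    n_trans: int
    n_ambiguous: int
    t_statistic: float
    p_one_sided: float


def classify_cis_trans(
    snp_position: Optional[tuple[str, int]],
    gene_position: Optional[tuple[str, int]],
    window_bp: int = 5_000_000,
) -> tuple[str, Optional[int]]:
    """Classify a SNP-gene pair as cis, trans or ambiguous.

    Ambiguous if either position is unknown; cis if both lie on the same
    chromosome with |snp_pos - gene_start| <= window_bp (inclusive); trans
    otherwise.  Returns (class, distance_bp); the distance is reported only
    for same-chromosome pairs.
    """
    if snp_position is None or gene_position is None:
        return "ambiguous", None
    snp_chrom, snp_pos = snp_position
    gene_chrom, gene_start = gene_position
    if str(snp_chrom) != str(gene_chrom):
        return "trans", None
    distance = abs(int(snp_pos) - int(gene_start))
    return ("cis" if distance <= window_bp else "trans"), distance


def _marker_records(
    marker_index: int,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    config: PipelineConfig,
):
    snp_id = genotypes.marker_ids[marker_index]
    keep = ~genotypes.missing[marker_index]
    labels = genotypes.values[marker_index, keep]
    n_used = int(keep.sum())
    if n_used < 2 or np.unique(labels).size < 2:
        logger.info("marker %s skipped: fewer than 2 genotype classes among %d samples", snp_id, n_used)
        return snp_id, None, None, []
    values = expression.values[:, keep]
    states = discretize_matrix(values, DiscretizationRule(config.discretize_t))
    covs = None
    if config.covariates:
        covs = [np.asarray(c)[keep] for c in config.covariates]
    k = min(config.k_rank, expression.n_genes)
    ranking = mrmr_rank(
        states,
        expression.gene_ids,
        labels,
        k,
        snp_id=snp_id,
        scheme=config.mrmr_scheme,
        covariates=covs,
    )
    if config.ifs_list == "mrmr":
        order = ranking.gene_order("mrmr")
    else:
        order = ranking.gene_order("maxrel")[:k]
    col_index = {g: i for i, g in enumerate(expression.gene_ids)}
    feats = values[[col_index[g] for g in order], :].T
    ifs_result = run_ifs(order, feats, labels)

    logger.info(
        "marker %s: n=%d optimal_k=%d accuracy=%.3f %s",
        snp_id,
        n_used,
        ifs_result.optimal_k,
        ifs_result.optimal_accuracy,
        "emitted" if ifs_result.optimal_accuracy >= config.accuracy_cutoff else "below cutoff",
    )
    records: list[EqtlRecord] = []
    if ifs_result.optimal_accuracy >= config.accuracy_cutoff:
        rel = dict((g, r) for g, r in ranking.maxrel)
        score = {g: s for g, s, _ in ranking.mrmr}
        snp_pos = (genotypes.positions or {}).get(snp_id)
        for gene in ifs_result.optimal_genes:
            gene_pos = (expression.positions or {}).get(gene)
            cls, dist = classify_cis_trans(snp_pos, gene_pos, config.cis_window_bp)
            records.append(
                EqtlRecord(
                    snp_id=snp_id,
                    gene_id=gene,
                    relevance_bits=rel[gene],
                    mrmr_score=score.get(gene, rel[gene]),
                    loocv_accuracy=ifs_result.optimal_accuracy,
                    cis_class=cls,
                    distance_bp=dist,
                )
            )
    return snp_id, ranking, ifs_result, records


def map_eqtls(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> tuple[EqtlTable, dict[str, IfsResult], dict[str, FeatureRanking]]:
    """Run the full per-SNP workflow and assemble the eQTL table.

    Samples are matched by id (sorted intersection).  Markers with missing
    calls are analysed on their called samples only; markers with a single
    genotype class are skipped.  Deterministic given inputs and config,
    independent of ``config.threads``.
    """
    config = config or PipelineConfig()
    g, e = align_samples(genotypes, expression)
    if g.n_samples < 2:
        raise ValueError("need at least 2 shared samples")
    if e.n_genes == 0:
        raise ValueError("expression matrix has no genes")

    worker = delayed(_marker_records)
    if config.threads > 1:
        results = Parallel(n_jobs=config.threads)(
            worker(i, g, e, config) for i in range(g.n_markers)
        )
    else:
        results = [_marker_records(i, g, e, config) for i in range(g.n_markers)]

    records: list[EqtlRecord] = []
    ifs_results: dict[str, IfsResult] = {}
    rankings: dict[str, FeatureRanking] = {}
    for snp_id, ranking, ifs_result, recs in results:
        if ranking is not None:
            rankings[snp_id] = ranking
            ifs_results[snp_id] = ifs_result
        records.extend(recs)
    return EqtlTable(records), ifs_results, rankings


def compare_cis_trans(
    table: EqtlTable,
    score_field: str = "mrmr_score",
    pooled: bool = False,
) -> CisTransSummary:
    """One-sided t-test of cis scores being greater than trans scores.

    Ambiguous records are counted but excluded from the test.  Welch
    (unequal-variance) by default; ``pooled=True`` switches to the
    pooled-variance statistic.  Degenerate zero-variance inputs fall back
    to a sign comparison of the means.
    """
    if score_field not in ("relevance_bits", "mrmr_score"):
        raise ValueError(f"unsupported score field {score_field!r}")
    cis = np.array([getattr(r, score_field) for r in table.records if r.cis_class == "cis"])
    trans = np.array([getattr(r, score_field) for r in table.records if r.cis_class == "trans"])
    n_amb = sum(1 for r in table.records if r.cis_class == "ambiguous")
    if cis.size < 2 or trans.size < 2:
        raise ValueError("compare_cis_trans needs at least 2 cis and 2 trans records")

    v1, v2 = cis.var(ddof=1), trans.var(ddof=1)
    diff = cis.mean() - trans.mean()
    if v1 == 0 and v2 == 0:
        t_stat = np.inf * np.sign(diff) if diff != 0 else 0.0
        p = 0.0 if diff > 0 else (1.0 if diff < 0 else 0.5)
    else:
        t_stat, p = stats.ttest_ind(
            cis, trans, equal_var=pooled, alternative="greater"
        )
    return CisTransSummary(
        n_cis=int(cis.size),
        n_trans=int(trans.size),
        n_ambiguous=int(n_amb),
        t_statistic=float(t_stat),
        p_one_sided=float(p),
    )
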