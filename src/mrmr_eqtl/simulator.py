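"""Synthetic F2-intercross genotype and expression generator.

Emulates the statistical structure of an F2 cross between two inbred
strains: per sample, two gamete haplotypes are simulated as two-state
Markov chains along each chromosome with recombination fraction r between
adjacent markers, so unlinked markers segregate 1:2:1.  Expression is
generated with planted cis and trans SNP effects (additive a and dominance
d terms), one propagation pass over a directed acyclic small-world
regulatory network, and Gaussian noise.  The planted direct SNP -> gene
pairs are returned as ground truth for precision-recall evaluation.

The generator reproduces the benchmark conditions of the published
evaluation (population size 250, 1000 genes and SNPs, small-world topology
with average node degree 10); it does not model steady-state regulatory
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from mrmr_eqtl.data_io import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "TruthPair",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters of a synthetic F2 eQTL dataset.

    Defaults follow the published benchmark conditions where stated
    (250 samples, 1000 SNPs, 1000 genes, small-world network of mean degree
    10); the remaining values are this generator's own choices of a
    realistic F2 design: 5 chromosomes, markers on a 1 Mb grid,
    recombination fraction 0.1 between adjacent markers, unit-variance
    expression noise, and planted effects of one noise SD.

    Planted genes are grouped into per-SNP blocks of size ``pleiotropy``
    (default 5): an active locus regulates a small module of genes, the
    hotspot structure typical of real eQTL data and of network-propagated
    benchmark generators.  Cis and trans blocks carry separate additive
    (a) and dominance (d) effect sizes, in units of the noise SD.
    """

    n_samples: int = 250
    n_snps: int = 1000
    n_genes: int = 1000
    n_chromosomes: int = 5
    recomb_fraction: float = 0.1
    marker_spacing_bp: int = 1_000_000
    cis_fraction: float = 0.05
    trans_fraction: float = 0.05
    pleiotropy: int = 5
    trans_pleiotropy: Optional[int] = None  # None -> same as pleiotropy
    cis_additive: float = 1.0
    cis_dominance: float = 0.0
    trans_additive: float = 1.0
    trans_dominance: float = 0.0
    network_degree: int = 10
    network_rewire_p: float = 0.1
    network_weight: float = 0.3
    noise_sd: float = 1.0
    cis_window_bp: int = 5_000_000
    unannotated_gene_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 1 or self.n_genes < 1:
            raise ValueError("n_samples, n_snps and n_genes must be positive")
        if not 0 < self.recomb_fraction <= 0.5:
            raise ValueError("recomb_fraction must lie in (0, 0.5]")
        for name in ("cis_fraction", "trans_fraction", "network_rewire_p", "unannotated_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cis_fraction + self.trans_fraction > 1.0:
            raise ValueError("cis_fraction + trans_fraction must not exceed 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.network_degree >= self.n_genes:
            raise ValueError("network_degree must be smaller than n_genes")
        if self.pleiotropy < 1:
            raise ValueError("pleiotropy must be >= 1")
        if self.trans_pleiotropy is not None and self.trans_pleiotropy < 1:
            raise ValueError("trans_pleiotropy must be >= 1")
        if self.n_chromosomes < 1 or self.marker_spacing_bp < 1:
            raise ValueError("need at least one chromosome and positive marker spacing")


@dataclass(frozen=True)
class TruthPair:
    snp_id: str
    gene_id: str
    kind: str  # "cis" | "trans"
    a: float  # additive effect
    d: float  # dominance effect


@dataclass
class SyntheticTruth:
    """Planted direct SNP -> gene effects (the evaluation's positives)."""

    pairs: list[TruthPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(p.snp_id, p.gene_id) for p in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate truth pairs")

    def pair_set(self) -> set[tuple[str, str]]:
        return {(p.snp_id, p.gene_id) for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.snp_id, p.gene_id, p.kind, p.a, p.d) for p in self.pairs],
            columns=["snp_id", "gene_id", "class", "a", "d"],
        )

    @classmethod
    def from_file(cls, path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", header=0, dtype={"snp_id": str, "gene_id": str})
        return cls(
            [
                TruthPair(str(r["snp_id"]), str(r["gene_id"]), str(r["class"]), float(r["a"]), float(r["d"]))
                for _, r in df.iterrows()
            ]
        )


def _marker_layout(spec: SimulationSpec) -> tuple[list[str], dict[str, tuple[str, int]], list[np.ndarray]]:
    """Assign markers evenly to chromosomes on a uniform bp grid."""
    per_chrom = [spec.n_snps // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_snps % spec.n_chromosomes):
        per_chrom[i] += 1
    marker_ids: list[str] = []
    positions: dict[str, tuple[str, int]] = {}
    chrom_slices: list[np.ndarray] = []
    idx = 0
    for c, m in enumerate(per_chrom, start=1):
        if m == 0:  # fewer markers than chromosomes
            continue
        ids = [f"snp{idx + j:04d}" for j in range(m)]
        for j, mid in enumerate(ids):
            positions[mid] = (f"chr{c}", (j + 1) * spec.marker_spacing_bp)
        chrom_slices.append(np.arange(idx, idx + m))
        marker_ids.extend(ids)
        idx += m
    return marker_ids, positions, chrom_slices


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Simulate F2 genotypes as paired gamete haplotype Markov chains.

    Each haplotype starts as a fair coin at the first marker of a
    chromosome and switches parental origin with probability r between
    adjacent markers; the genotype is 1/2/3 by the two-haplotype allele
    sum.  Marker positions lie on a uniform grid per chromosome.
    """
    rng = np.random.default_rng([spec.seed, 0])
    marker_ids, positions, chrom_slices = _marker_layout(spec)
    n = spec.n_samples
    values = np.empty((spec.n_snps, n), dtype=np.int8)
    for markers in chrom_slices:
        m = markers.size
        # 2 gametes per sample, Markov switching along the chromosome
        start = rng.integers(0, 2, size=(2 * n, 1))
        switches = rng.random((2 * n, m - 1)) < spec.recomb_fraction
        hap = (start + np.concatenate([np.zeros((2 * n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1)) % 2
        geno = hap[:n] + hap[n:] + 1  # 1..3
        values[markers, :] = geno.T
    sample_ids = [f"s{j:03d}" for j in range(n)]
    return GenotypeMatrix(marker_ids, sample_ids, values, positions=positions)


def _plant_pairs(
    spec: SimulationSpec,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int, str]], dict[str, tuple[str, int]]]:
    """Choose planted (snp_index, gene_index, kind) and gene positions.

    Planted genes are assigned to SNPs in blocks of ``spec.pleiotropy``;
    block SNPs are drawn without replacement so cis and trans loci are
    distinct markers.
    """
    n_cis = int(round(spec.cis_fraction * spec.n_genes))
    n_trans = int(round(spec.trans_fraction * spec.n_genes))
    if n_cis + n_trans > spec.n_genes:
        raise ValueError("cis_fraction + trans_fraction too large")
    gene_perm = rng.permutation(spec.n_genes)
    planted_genes = gene_perm[: n_cis + n_trans]
    trans_block = spec.trans_pleiotropy or spec.pleiotropy
    n_cis_snps = -(-n_cis // spec.pleiotropy)  # ceil
    n_trans_snps = -(-n_trans // trans_block)
    if n_cis_snps + n_trans_snps > spec.n_snps:
        raise ValueError("not enough SNPs for the requested planted blocks")
    block_snps = rng.choice(spec.n_snps, size=n_cis_snps + n_trans_snps, replace=False)
    snp_for_gene = np.concatenate(
        [
            np.repeat(block_snps[:n_cis_snps], spec.pleiotropy)[:n_cis],
            np.repeat(block_snps[n_cis_snps:], trans_block)[:n_trans],
        ]
    ).astype(int)

    chrom_span: dict[str, int] = {}
    for chrom, pos in genotypes.positions.values():
        chrom_span[chrom] = max(chrom_span.get(chrom, 0), pos)
    chroms = sorted(chrom_span)

    gene_pos: dict[str, tuple[str, int]] = {}
    # background positions for every gene
    for g in range(spec.n_genes):
        chrom = chroms[rng.integers(0, len(chroms))]
        gene_pos[f"g{g:04d}"] = (chrom, int(rng.integers(1, chrom_span[chrom] + 1)))

    pairs: list[tuple[int, int, str]] = []
    for rank, (g, s) in enumerate(zip(planted_genes, snp_for_gene)):
        kind = "cis" if rank < n_cis else "trans"
        gid = f"g{g:04d}"
        snp_chrom, snp_pos = genotypes.positions[genotypes.marker_ids[s]]
        if kind == "cis":
            offset = int(rng.integers(-spec.cis_window_bp, spec.cis_window_bp + 1))
            gene_pos[gid] = (snp_chrom, max(1, snp_pos + offset))
        else:
            # force a trans relationship: different chromosome, or far away
            while True:
                chrom = chroms[rng.integers(0, len(chroms))]
                pos = int(rng.integers(1, chrom_span[chrom] + 1))
                if chrom != snp_chrom or abs(pos - snp_pos) > spec.cis_window_bp:
                    gene_pos[gid] = (chrom, pos)
                    break
        pairs.append((int(s), int(g), kind))
    return pairs, gene_pos


def _acyclic_small_world(spec: SimulationSpec, rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """Directed acyclic regulatory edges from a Watts-Strogatz ring.

    Edges are oriented from the lower to the higher gene index, so the
    natural index order is a topological order and a single propagation
    pass suffices.
    """
    if spec.network_degree < 2 or spec.network_weight == 0.0:
        return []
    graph = nx.watts_strogatz_graph(
        spec.n_genes,
        k=spec.network_degree,
        p=spec.network_rewire_p,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    edges = []
    for u, v in graph.edges():
        u, v = (u, v) if u < v else (v, u)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        edges.append((u, v, sign * spec.network_weight))
    edges.sort(key=lambda e: (e[1], e[0]))
    return edges


def simulate_expression(
    genotypes: GenotypeMatrix, spec: SimulationSpec
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate expression with planted SNP effects and network propagation.

    For gene g:  e_g = mu_g + a*(geno - 2) + d*1(geno == 2)
    + sum over regulatory parents of w * e_parent + Normal(0, sigma^2),
    evaluated in one pass over the acyclic network's topological order.
    Only the direct SNP -> gene plantings are recorded as truth.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = genotypes.n_samples
    pairs, gene_pos = _plant_pairs(spec, genotypes, rng)
    edges = _acyclic_small_world(spec, rng)

    parents: dict[int, list[tuple[int, float]]] = {}
    for u, v, w in edges:
        parents.setdefault(v, []).append((u, w))

    mu = rng.normal(0.0, 1.0, size=spec.n_genes)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    genetic = np.zeros((spec.n_genes, n))
    truth_pairs: list[TruthPair] = []
    for s_idx, g_idx, kind in pairs:
        geno = genotypes.values[s_idx].astype(float)
        if kind == "cis":
            a, d = spec.cis_additive, spec.cis_dominance
        else:
            a, d = spec.trans_additive, spec.trans_dominance
        genetic[g_idx] += a * (geno - 2.0) + d * (geno == 2.0)
        truth_pairs.append(
            TruthPair(
                snp_id=genotypes.marker_ids[s_idx],
                gene_id=f"g{g_idx:04d}",
                kind=kind,
                a=a,
                d=d,
            )
        )

    expr = np.empty((spec.n_genes, n))
    for g in range(spec.n_genes):  # index order is topological
        e = mu[g] + genetic[g] + noise[g]
        for u, w in parents.get(g, ()):
            e = e + w * expr[u]
        expr[g] = e

    gene_ids = [f"g{g:04d}" for g in range(spec.n_genes)]
    if spec.unannotated_gene_fraction > 0:
        n_drop = int(round(spec.unannotated_gene_fraction * spec.n_genes))
        annotated_genes = {f"g{g:04d}" for g in truth_pairs_genes(truth_pairs)}
        droppable = [g for g in gene_ids if g not in annotated_genes]
        for gid in rng.permutation(droppable)[:n_drop]:
            gene_pos.pop(gid, None)
    expression = ExpressionMatrix(gene_ids, list(genotypes.sample_ids), expr, positions=gene_pos)
    return expression, SyntheticTruth(truth_pairs)


def truth_pairs_genes(pairs: list[TruthPair]) -> set[int]:
    return {int(p.gene_id[1:]) for p in pairs}


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, ExpressionMatrix, SyntheticTruth]:
    """Convenience wrapper: genotypes, expression and truth from one spec."""
    genotypes = simulate_genotypes(spec)
    expression, truth = simulate_expression(genotypes, spec)
    return genotypes, expression, truth
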