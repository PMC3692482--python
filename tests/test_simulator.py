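"""F2-intercross simulator: Mendelian ratios, linkage, planted effects."""

import numpy as np
import pytest
from scipy import stats

from mrmr_eqtl import (
    SimulationSpec,
    classify_cis_trans,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
)
from mrmr_eqtl.infotheory import DiscretizationRule, discretize_matrix, mi_profile


class TestGenotypes:
    def test_mendelian_one_two_one(self):
        spec = SimulationSpec(n_samples=5000, n_snps=4, n_genes=2, network_degree=1, seed=42)
        g = simulate_genotypes(spec)
        for row in g.values:
            counts = np.bincount(row, minlength=4)[1:4]
            chi2, p = stats.chisquare(counts, f_exp=5000 * np.array([0.25, 0.5, 0.25]))
            assert p > 0.01

    def test_free_recombination_limit(self):
        spec = SimulationSpec(n_samples=5000, n_snps=4, n_genes=2, n_chromosomes=1,
                              recomb_fraction=0.5, network_degree=1, seed=0)
        g = simulate_genotypes(spec)
        for i in range(3):
            r = np.corrcoef(g.values[i], g.values[i + 1])[0, 1]
            assert abs(r) < 0.05

    def test_tight_linkage_concordance(self):
        # per gamete P(no switch observed) = 1 - 2r(1-r); both gametes
        # concordant -> genotype concordance (1-2r(1-r))^2 ~ 0.96 at r=0.01
        spec = SimulationSpec(n_samples=1000, n_snps=4, n_genes=2, n_chromosomes=1,
                              recomb_fraction=0.01, network_degree=1, seed=1)
        g = simulate_genotypes(spec)
        for i in range(3):
            concordance = np.mean(g.values[i] == g.values[i + 1])
            assert concordance > 0.95

    def test_same_seed_bit_identical(self):
        spec = SimulationSpec(n_samples=50, n_snps=20, n_genes=10, network_degree=4, seed=9)
        a, ea, ta = simulate_dataset(spec)
        b, eb, tb = simulate_dataset(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ea.values, eb.values)
        assert ta.pairs == tb.pairs
        assert a.positions == b.positions and ea.positions == eb.positions

    def test_positions_on_uniform_grid(self):
        spec = SimulationSpec(n_samples=5, n_snps=10, n_genes=2, n_chromosomes=2, network_degree=1, seed=0)
        g = simulate_genotypes(spec)
        by_chrom = {}
        for mid in g.marker_ids:
            chrom, pos = g.positions[mid]
            by_chrom.setdefault(chrom, []).append(pos)
        assert len(by_chrom) == 2
        for positions in by_chrom.values():
            diffs = np.diff(positions)
            assert np.all(diffs == spec.marker_spacing_bp)


class TestExpression:
    def test_null_model_has_no_association(self):
        spec = SimulationSpec(
            n_samples=250, n_snps=10, n_genes=40, cis_additive=0.0, trans_additive=0.0,
            network_weight=0.0, cis_fraction=0.2, trans_fraction=0.2, seed=5,
        )
        g, e, truth = simulate_dataset(spec)
        states = discretize_matrix(e.values, DiscretizationRule(1.0))
        mis = np.concatenate([mi_profile(states, g.values[i]) for i in range(10)])
        assert mis.mean() < 0.05

    def test_large_additive_effect_is_top_mi_gene(self):
        hits = 0
        for seed in range(20):
            spec = SimulationSpec(
                n_samples=250, n_snps=10, n_genes=50, cis_fraction=1 / 50,
                trans_fraction=0.0, pleiotropy=1, cis_additive=3.0,
                network_weight=0.0, seed=seed,
            )
            g, e, truth = simulate_dataset(spec)
            (pair,) = truth.pairs
            snp_idx = g.marker_ids.index(pair.snp_id)
            states = discretize_matrix(e.values, DiscretizationRule(1.0))
            mi = mi_profile(states, g.values[snp_idx])
            hits += e.gene_ids[int(np.argmax(mi))] == pair.gene_id
        assert hits >= 19

    def test_dominance_only_effect_invisible_to_linear_dose(self):
        spec = SimulationSpec(
            n_samples=250, n_snps=5, n_genes=30, cis_fraction=1 / 30,
            trans_fraction=0.0, pleiotropy=1, cis_additive=0.0, cis_dominance=3.0,
            network_weight=0.0, seed=2,
        )
        g, e, truth = simulate_dataset(spec)
        (pair,) = truth.pairs
        snp_idx = g.marker_ids.index(pair.snp_id)
        gene_idx = e.gene_ids.index(pair.gene_id)
        geno = g.values[snp_idx].astype(float)
        expr = e.values[gene_idx]
        assert abs(np.corrcoef(geno, expr)[0, 1]) < 0.2
        states = discretize_matrix(e.values, DiscretizationRule(1.0))
        mi = mi_profile(states, g.values[snp_idx])
        assert mi[gene_idx] > 0.2  # clearly detected by MI

    def test_truth_cis_pairs_classify_as_cis(self):
        spec = SimulationSpec(
            n_samples=20, n_snps=30, n_genes=60, cis_fraction=0.3,
            trans_fraction=0.3, seed=8,
        )
        g, e, truth = simulate_dataset(spec)
        for p in truth.pairs:
            cls, _ = classify_cis_trans(
                g.positions[p.snp_id], e.positions[p.gene_id], spec.cis_window_bp
            )
            assert cls == p.kind

    def test_noise_monotonically_weakens_planted_mi(self):
        means = []
        for sd in (0.5, 1.5, 4.0):
            spec = SimulationSpec(
                n_samples=250, n_snps=10, n_genes=30, cis_fraction=0.2,
                trans_fraction=0.0, cis_additive=1.0, noise_sd=sd,
                network_weight=0.0, seed=3,
            )
            g, e, truth = simulate_dataset(spec)
            states = discretize_matrix(e.values, DiscretizationRule(1.0))
            vals = []
            for p in truth.pairs:
                mi = mi_profile(states, g.values[g.marker_ids.index(p.snp_id)])
                vals.append(mi[e.gene_ids.index(p.gene_id)])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_network_propagates_signal_acyclically(self):
        spec = SimulationSpec(
            n_samples=100, n_snps=5, n_genes=40, cis_fraction=0.0, trans_fraction=0.0,
            network_weight=0.5, network_degree=4, seed=4,
        )
        g, e, _ = simulate_dataset(spec)
        # network coupling induces correlated gene pairs beyond noise level
        corr = np.corrcoef(e.values)
        off_diag = np.abs(corr[np.triu_indices(40, k=1)])
        assert off_diag.max() > 0.3

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(n_snps=0)
        with pytest.raises(ValueError):
            SimulationSpec(recomb_fraction=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationSpec(n_genes=10, network_degree=10)
        with pytest.raises(ValueError):
            SimulationSpec(n_genes=10, network_degree=2, cis_fraction=0.8, trans_fraction=0.8)
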