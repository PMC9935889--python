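"""Synthetic catalogs, genomes, contig dropout and completeness estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

import magbias as mb
from magbias.simulate import ParametricModel


class TestCatalog:
    def test_constant_step_distribution_is_honoured(self):
        cat = mb.generate_catalog(1, mb.constant_steps(4), seed=0)
        assert len(cat) == 1
        assert cat.modules[0].n_steps == 4

    def test_poisson_catalog_invariants(self):
        cat = mb.generate_catalog(195, mb.poisson_steps(6.0), seed=1)
        ids = cat.module_ids
        assert len(ids) == 195
        assert len(set(ids)) == 195
        assert all(m.n_steps >= 1 for m in cat)
        assert all(len(step) >= 1 for m in cat for step in m.steps)

    def test_same_seed_same_catalog(self):
        a = mb.generate_catalog(50, seed=7)
        b = mb.generate_catalog(50, seed=7)
        assert a.modules == b.modules

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mb.generate_catalog(0, seed=0)
        with pytest.raises(ValueError):
            mb.constant_steps(0)
        with pytest.raises(ValueError):
            mb.generate_catalog(5, lambda rng, n: np.zeros(n, dtype=int), seed=0)


class TestCompleteGenome:
    def test_presence_prob_one_gives_full_modules(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog,
                                        module_presence_prob=1.0, seed=3)
        for module in catalog:
            k, f = mb.compute_fullness(g, module)
            assert f == 1.0

    def test_presence_prob_zero_leaves_only_markers(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog,
                                        module_presence_prob=0.0, n_sccg=37, seed=3)
        assert g.genes == mb.default_sccg_ids(37)

    def test_genes_conserved_across_contigs(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_contigs=42, seed=5)
        per_contig = {}
        for gene, contig in g.gene_to_contig.items():
            per_contig[contig] = per_contig.get(contig, 0) + 1
        assert sum(per_contig.values()) == len(g.genes)
        assert g.true_completeness == 1.0 and g.est_completeness == 1.0


class TestSubsampleContigs:
    def test_retention_070_keeps_7_of_10(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_contigs=10, seed=1)
        sub = mb.subsample_contigs(g, 0.7, seed=2)
        assert sub.n_contigs == 7

    def test_retention_one_is_identity_on_content(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, seed=1)
        sub = mb.subsample_contigs(g, 1.0, seed=2)
        assert sub.genes == g.genes
        assert sub.contigs == g.contigs
        assert sub.true_completeness == 1.0

    def test_round_half_up_and_replay_determinism(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_contigs=42, seed=1)
        a = mb.subsample_contigs(g, 0.8, seed=9)
        b = mb.subsample_contigs(g, 0.8, seed=9)
        assert a.n_contigs == 34  # round(0.8 * 42)
        assert a.contigs == b.contigs and a.genes == b.genes

    def test_invalid_retention(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, seed=1)
        for r in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                mb.subsample_contigs(g, r)

    @given(retention=st.floats(0.05, 1.0), seed=st.integers(0, 2**16))
    def test_subsample_never_adds_genes(self, catalog, retention, seed):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_contigs=20, seed=11)
        sub = mb.subsample_contigs(g, retention, seed=seed)
        assert sub.genes <= g.genes
        assert set(sub.contigs) <= set(g.contigs)
        assert 0.0 <= sub.true_completeness <= 1.0


class TestEstimateCompleteness:
    def test_fraction_of_markers_present(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_sccg=100, seed=1)
        removed = set(list(mb.default_sccg_ids(100))[:15])
        g.gene_to_contig = {k: v for k, v in g.gene_to_contig.items() if k not in removed}
        assert mb.estimate_completeness(g, mb.default_sccg_ids(100)) == pytest.approx(0.85)

    def test_complete_genome_scores_one(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, seed=1)
        assert mb.estimate_completeness(g, mb.default_sccg_ids(100)) == 1.0

    def test_empty_marker_set_rejected(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, seed=1)
        with pytest.raises(ValueError):
            mb.estimate_completeness(g, set())

    def test_estimate_is_unbiased_under_uniform_dropout(self, catalog):
        # markers ride on contigs, so E[estimate] = retention
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_contigs=200,
                                        n_sccg=100, seed=1)
        rng = np.random.default_rng(42)
        ests = []
        for _ in range(200):
            sub = mb.subsample_contigs(g, 0.8, seed=rng)
            ests.append(mb.estimate_completeness(sub, mb.default_sccg_ids(100)))
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.8) < 3 * max(se, 1e-6)


class TestContamination:
    def test_duplicated_markers_raise_contamination(self, catalog):
        g = mb.generate_complete_genome("g", "Firmicutes", catalog, n_sccg=100, seed=1)
        dirty = mb.add_contamination(g, 0.12, mb.default_sccg_ids(100), seed=2)
        assert dirty.contamination == pytest.approx(0.12)
        assert len(dirty.genes) == len(g.genes) + 12


class TestParametricDataset:
    def _flat_model(self, catalog, alpha=0.0, beta=0.0):
        return ParametricModel(
            intercepts={m.module_id: alpha for m in catalog},
            slopes={m.module_id: {p: beta for p in mb.DEFAULT_PHYLA} for m in catalog},
        )

    def test_zero_model_centres_fullness_at_half(self, catalog):
        mat = mb.generate_parametric_dataset(self._flat_model(catalog), catalog, 500, seed=8)
        assert abs(mat.values.to_numpy().mean() - 0.5) < 0.02

    def test_single_step_modules_give_binary_fullness(self):
        cat = mb.generate_catalog(10, mb.constant_steps(1), seed=3)
        model = ParametricModel(
            intercepts={m.module_id: 0.0 for m in cat},
            slopes={m.module_id: {p: 1.0 for p in mb.DEFAULT_PHYLA} for m in cat},
        )
        mat = mb.generate_parametric_dataset(model, cat, 100, seed=4)
        assert set(np.unique(mat.values.to_numpy())) <= {0.0, 1.0}

    def test_mean_fullness_matches_binomial_expectation(self, catalog):
        # alpha=0, beta=4 at completeness 1: E[f] = invlogit(4)
        model = self._flat_model(catalog, alpha=0.0, beta=4.0)
        mat = mb.generate_parametric_dataset(
            model, catalog, 2000, completeness_range=(1.0, 1.0), seed=12
        )
        vals = mat.values.to_numpy().ravel()
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expit(4.0)) < 3 * se

    def test_counts_are_consistent_with_fullness(self, parametric_matrix):
        steps = parametric_matrix.module_meta["n_steps"].to_numpy()
        np.testing.assert_allclose(
            parametric_matrix.values.to_numpy(),
            parametric_matrix.counts.to_numpy() / steps,
        )


class TestMechanisticRetention:
    def test_mean_fullness_ordering_across_retention(self, catalog):
        # stochastic monotonicity: deeper dropout, lower mean fullness
        g = mb.generate_complete_genome("g", "Firmicutes", catalog,
                                        module_presence_prob=1.0, n_contigs=200, seed=1)
        rng = np.random.default_rng(5)
        means = {}
        for r in (0.7, 0.9, 1.0):
            vals = []
            for _ in range(100):
                sub = mb.subsample_contigs(g, r, seed=rng)
                vals.append(np.mean([mb.compute_fullness(sub, m)[1] for m in catalog]))
            means[r] = (np.mean(vals), np.std(vals, ddof=1) / 10)
        assert means[0.7][0] <= means[0.9][0] + 2 * (means[0.7][1] + means[0.9][1])
        assert means[0.9][0] <= means[1.0][0] + 2 * means[0.9][1]
        assert means[0.7][0] < means[1.0][0]
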