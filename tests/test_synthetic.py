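"""Planted-structure generators: determinism, realized fractions, truth
consistency, and the combinatorial contracts of the network generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from duomics import synthetic
from duomics.synthetic import ConfigurationError, SyntheticConfig
from duomics.uorf import find_uorfs, uorf_gene_features


class TestConfigValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(frac_group1=0.5, frac_group2=0.4, frac_group3=0.2)

    def test_protein_coverage_floor(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_genes=2, protein_coverage=0.1)

    def test_clique_size_minimum(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(clique_size_range=(2, 4))

    def test_utr_range_must_fit_cassette(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(utr_length_range=(4, 6))


class TestOmicsDataset:
    def test_no_planted_effects_all_null(self):
        cfg = SyntheticConfig(n_genes=100, seed=1, frac_group1=0, frac_group2=0, frac_group3=0)
        transcript, protein, _, truth = synthetic.generate_omics_dataset(cfg)
        assert (truth["group"] == "none").all()
        assert (truth["de_transcript"] == "ns").all()
        assert transcript.shape == (100, 10)

    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_genes=200, seed=9)
        a = synthetic.generate_omics_dataset(cfg)
        b = synthetic.generate_omics_dataset(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_protein_coverage_and_shape(self):
        cfg = SyntheticConfig(n_genes=400, seed=2, protein_coverage=0.37)
        transcript, protein, id_map, truth = synthetic.generate_omics_dataset(cfg)
        assert len(protein) == round(0.37 * 400)
        assert len(transcript) == 400
        # planted grouped genes are always protein-measured
        grouped = truth.index[truth["group"] != "none"]
        measured = {g for g, p in zip(id_map["gene_id"], id_map["protein_id"]) if p}
        assert set(grouped) <= measured

    def test_group_labels_partition_and_match_de_labels(self):
        cfg = SyntheticConfig(n_genes=500, seed=3)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        assert truth.index.is_unique
        g1 = truth[truth["group"] == "1"]
        g2 = truth[truth["group"] == "2"]
        g3 = truth[truth["group"] == "3"]
        assert (g1["de_transcript"] == "up").all() and (g1["de_protein"] == "up").all()
        assert (g2["de_transcript"] == "up").all() and (g2["de_protein"] == "ns").all()
        assert (g3["de_transcript"] == "down").all() and (g3["de_protein"] == "down").all()

    def test_realized_fractions_within_three_binomial_sd(self):
        cfg = SyntheticConfig(n_genes=2000, seed=4, uorf_carrier_freq=0.43)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        n = len(truth)
        carriers = int((truth["uorf_count"] > 0).sum())
        sd = np.sqrt(n * 0.43 * 0.57)
        assert abs(carriers - 0.43 * n) <= 3 * sd


class TestUtrSet:
    def _features(self, cfg):
        _, _, id_map, truth = synthetic.generate_omics_dataset(cfg)
        utrs = synthetic.generate_utr_set(cfg, truth)
        anns = {tid: find_uorfs(seq, tid) for tid, seq in utrs.items()}
        t2g = id_map.set_index("transcript_id")["gene_id"]
        return uorf_gene_features(anns, t2g), truth

    def test_zero_carrier_frequency(self):
        feats, _ = self._features(SyntheticConfig(n_genes=80, seed=5, uorf_carrier_freq=0.0))
        assert (~feats["carrier"]).all()

    def test_full_carrier_frequency(self):
        feats, _ = self._features(SyntheticConfig(n_genes=80, seed=5, uorf_carrier_freq=1.0))
        assert feats["carrier"].all()

    def test_scanned_counts_equal_planted_counts(self):
        feats, truth = self._features(SyntheticConfig(n_genes=300, seed=6))
        np.testing.assert_array_equal(
            feats["n_uorfs"].sort_index().to_numpy(),
            truth["uorf_count"].sort_index().to_numpy(),
        )

    def test_deterministic(self):
        cfg = SyntheticConfig(n_genes=60, seed=7)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        assert synthetic.generate_utr_set(cfg, truth) == synthetic.generate_utr_set(cfg, truth)

    def test_reference_scale_carrier_count(self):
        """At the emulated background scale (5586 genes, 43% carriers) the
        realized carrier count lands within 3 binomial SDs of expectation."""
        cfg = SyntheticConfig(n_genes=5586, seed=8, uorf_carrier_freq=0.43)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        carriers = int((truth["uorf_count"] > 0).sum())
        mu = 0.43 * 5586
        sd = np.sqrt(5586 * 0.43 * 0.57)
        assert abs(carriers - mu) <= 3 * sd


class TestBackgroundNetwork:
    def test_pure_planted_cliques_edge_count(self):
        cfg = SyntheticConfig(
            n_genes=50, seed=10, background_edge_prob=0.0,
            n_clique_modules=2, clique_size_range=(4, 4),
        )
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        g = synthetic.generate_background_network(cfg, truth)
        assert g.number_of_edges() == 2 * 6  # 2 * C(4,2)

    def test_noise_free_components_are_cliques(self):
        cfg = SyntheticConfig(n_genes=60, seed=11, background_edge_prob=0.0, n_clique_modules=3)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        g = synthetic.generate_background_network(cfg, truth)
        import networkx as nx

        for comp in nx.connected_components(g):
            if len(comp) > 1:
                assert all(g.has_edge(a, b) for a, b in itertools.combinations(comp, 2))

    def test_planted_members_form_clique_with_truth_ids(self):
        from duomics.netgraph import is_clique

        cfg = SyntheticConfig(n_genes=100, seed=12, background_edge_prob=0.02)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        g = synthetic.generate_background_network(cfg, truth)
        for cid in range(cfg.n_clique_modules):
            members = set(truth.index[truth["clique_id"] == cid])
            assert len(members) >= 3
            assert is_clique(members, g)

    def test_edge_scores_in_unit_interval(self):
        cfg = SyntheticConfig(n_genes=80, seed=13, background_edge_prob=0.05)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        g = synthetic.generate_background_network(cfg, truth)
        scores = [d["score"] for _, _, d in g.edges(data=True)]
        assert all(0 < s <= 1 for s in scores)

    def test_noise_edge_count_near_expectation(self):
        cfg = SyntheticConfig(
            n_genes=200, seed=14, background_edge_prob=0.05, n_clique_modules=0
        )
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        g = synthetic.generate_background_network(cfg, truth)
        n_pairs = 200 * 199 // 2
        mu = n_pairs * 0.05
        sd = np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(g.number_of_edges() - mu) <= 4 * sd


class TestAnnotationSets:
    def test_enriched_terms_oversample_group(self):
        cfg = SyntheticConfig(n_genes=600, seed=15, term_size_range=(40, 40), enrichment_purity=0.8)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        terms = synthetic.generate_annotation_sets(cfg, truth)
        group2 = set(truth.index[truth["group"] == "2"])
        planted = terms[0]
        frac_in_group = len(planted.genes & group2) / len(planted.genes)
        assert frac_in_group >= 0.5  # strongly above the 5% base rate

    def test_truth_backref_consistent(self):
        cfg = SyntheticConfig(n_genes=300, seed=16)
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        terms = synthetic.generate_annotation_sets(cfg, truth)
        by_id = {t.term_id: t for t in terms}
        for gene, listed in truth["enriched_terms"].items():
            for tid in filter(None, listed.split(",")):
                assert gene in by_id[tid].genes

    def test_term_sizes_respect_range(self):
        cfg = SyntheticConfig(n_genes=300, seed=17, term_size_range=(10, 25))
        _, _, _, truth = synthetic.generate_omics_dataset(cfg)
        for t in synthetic.generate_annotation_sets(cfg, truth):
            assert 10 <= len(t.genes) <= 25


class TestSeedIsolation:
    def test_generators_use_independent_streams(self):
        """Regenerating one input does not perturb another: the network from
        the same config is identical whether or not UTRs were generated."""
        cfg = SyntheticConfig(n_genes=120, seed=18)
        _, _, _, truth_a = synthetic.generate_omics_dataset(cfg)
        _, _, _, truth_b = synthetic.generate_omics_dataset(cfg)
        synthetic.generate_utr_set(cfg, truth_a)  # consume the UTR stream only in run a
        ga = synthetic.generate_background_network(cfg, truth_a)
        gb = synthetic.generate_background_network(cfg, truth_b)
        assert sorted(ga.edges) == sorted(gb.edges)
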