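"""Cosine and random-walk-with-restart gene scoring."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

from varprior.ontology import GeneAnnotationMap, ancestor_closure
from varprior.phenoscore import (GENE_PREFIX, GeneScoreTable, PhenotypeVector,
                                 RWRConfig, annotate_phenotype_scores,
                                 best_gene_score_per_variant, build_rwr_graph,
                                 build_term_vector, cosine_score,
                                 gene_closures, rwr_scores, score_genes_cosine)

from conftest import brute_force_closure, random_dag


class TestTermVector:
    def test_chain_closure_bits(self, chain_graph):
        v = build_term_vector(chain_graph, {"HP:C"})
        assert v.set_terms == {"HP:B", "HP:C"}
        assert chain_graph.P == 2

    def test_all_non_root_terms_give_all_ones(self, chain_graph):
        v = build_term_vector(chain_graph, chain_graph.terms - chain_graph.roots)
        assert v.bits.all()

    def test_diamond_closure(self, diamond_graph):
        v = build_term_vector(diamond_graph, {"HP:D"})
        assert v.set_terms == {"HP:B", "HP:C", "HP:D"}

    def test_empty_terms_zero_vector(self, chain_graph):
        v = build_term_vector(chain_graph, set())
        assert not v.bits.any()


class TestCosine:
    def test_identity_is_one(self, diamond_graph):
        u = build_term_vector(diamond_graph, {"HP:D"})
        assert cosine_score(u, u) == pytest.approx(1.0)

    def test_disjoint_is_zero(self, diamond_graph):
        u = build_term_vector(diamond_graph, {"HP:B"})
        v = build_term_vector(diamond_graph, {"HP:C"})
        assert cosine_score(u, v) == 0.0

    def test_frozen_overlap_value(self):
        # |u|^2=3, |v|^2=2, overlap 2 -> 2/sqrt(6)
        dims = tuple("abcd")
        u = PhenotypeVector(dims=dims, bits=np.array([1, 1, 1, 0], dtype=np.uint8))
        v = PhenotypeVector(dims=dims, bits=np.array([1, 1, 0, 0], dtype=np.uint8))
        assert cosine_score(u, v) == pytest.approx(2 / math.sqrt(6), abs=1e-12)
        assert cosine_score(u, v) == cosine_score(v, u)

    def test_zero_vector_convention(self, chain_graph):
        z = build_term_vector(chain_graph, set())
        u = build_term_vector(chain_graph, {"HP:C"})
        assert cosine_score(z, u) == 0.0

    def test_dimension_mismatch_rejected(self, chain_graph, diamond_graph):
        u = build_term_vector(chain_graph, {"HP:C"})
        v = build_term_vector(diamond_graph, {"HP:D"})
        with pytest.raises(ValueError):
            cosine_score(u, v)

    def test_shared_term_never_decreases_similarity(self):
        # enumeration on <= 10-dim binary vectors: adding a bit shared by both
        # vectors never lowers their cosine
        rng = np.random.default_rng(5)
        dims = tuple(f"d{i}" for i in range(10))
        for _ in range(200):
            u = rng.integers(0, 2, size=10).astype(np.uint8)
            v = rng.integers(0, 2, size=10).astype(np.uint8)
            free = np.flatnonzero((u == 0) & (v == 0))
            if not free.size:
                continue
            j = int(free[0])
            base = cosine_score(PhenotypeVector(dims, u), PhenotypeVector(dims, v))
            u2, v2 = u.copy(), v.copy()
            u2[j] = v2[j] = 1
            after = cosine_score(PhenotypeVector(dims, u2), PhenotypeVector(dims, v2))
            assert after >= base - 1e-12


class TestScoreGenesCosine:
    def test_exact_annotation_match_scores_one(self, diamond_graph):
        gam = GeneAnnotationMap({"G1": {"HP:D"}, "G2": {"HP:B"}})
        table = score_genes_cosine(diamond_graph, gam, {"HP:D"})
        assert table.scores["G1"] == pytest.approx(1.0)
        assert table.ranked()[0][0] == "G1"

    def test_disjoint_gene_scores_zero(self, chain_graph):
        gam = GeneAnnotationMap({"G1": {"HP:B"}})
        # patient at HP:B only; gene at HP:C closes to {B,C}: overlap exists.
        # use separate branches of a diamond instead
        table = score_genes_cosine(chain_graph, gam, {"HP:B"})
        assert table.scores["G1"] == pytest.approx(1.0)

    def test_matches_bruteforce_closure_dot_product(self):
        rng = np.random.default_rng(11)
        graph = random_dag(rng, 60)
        non_root = sorted(graph.terms - graph.roots)
        gam = GeneAnnotationMap({
            f"G{i}": {non_root[j] for j in rng.choice(len(non_root), size=3, replace=False)}
            for i in range(10)
        })
        patient = {non_root[j] for j in rng.choice(len(non_root), size=4, replace=False)}
        table = score_genes_cosine(graph, gam, patient)
        pclosed = brute_force_closure(graph, patient)
        for gene, terms in gam.annotations.items():
            gclosed = brute_force_closure(graph, terms)
            expected = (len(pclosed & gclosed)
                        / math.sqrt(len(pclosed) * len(gclosed)))
            assert table.scores[gene] == pytest.approx(expected, abs=1e-12)


class TestRWRGraph:
    def test_two_node_graph_columns_stochastic(self, chain_graph):
        gam = GeneAnnotationMap({"G1": {"HP:C"}})
        rwr = build_rwr_graph(chain_graph, gam)
        sums = np.asarray(rwr.W.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_unit_weight_degree_three_splits_evenly(self, diamond_graph):
        gam = GeneAnnotationMap({"G1": {"HP:A"}})
        rwr = build_rwr_graph(diamond_graph, gam)
        col = rwr.W[:, rwr.node_index["HP:A"]].toarray().ravel()
        # HP:A neighbors: HP:B, HP:C, gene node -> 1/3 each
        nz = col[col > 0]
        assert len(nz) == 3
        assert np.allclose(nz, 1 / 3)

    def test_random_instance_column_sums(self):
        rng = np.random.default_rng(12)
        graph = random_dag(rng, 40)
        non_root = sorted(graph.terms - graph.roots)
        gam = GeneAnnotationMap({
            f"G{i}": {non_root[j] for j in rng.choice(len(non_root), size=2, replace=False)}
            for i in range(10)
        })
        rwr = build_rwr_graph(graph, gam, RWRConfig(gene_edge_weight=2.5))
        sums = np.asarray(rwr.W.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestRWRScores:
    def test_full_restart_leaves_mass_on_terms(self, chain_graph):
        gam = GeneAnnotationMap({"G1": {"HP:C"}})
        rwr = build_rwr_graph(chain_graph, gam)
        cfg = RWRConfig(restart_prob=1.0)
        table = rwr_scores(rwr, chain_graph, ["HP:C"], cfg)
        assert all(s == pytest.approx(0.0, abs=1e-12) for s in table.scores.values())

    def test_mirror_genes_score_equally(self, diamond_graph):
        gam = GeneAnnotationMap({"GB": {"HP:B"}, "GC": {"HP:C"}})
        rwr = build_rwr_graph(diamond_graph, gam)
        cfg = RWRConfig(restart_on_closure=False)
        table = rwr_scores(rwr, diamond_graph, ["HP:A"], cfg)
        assert table.scores["GB"] == pytest.approx(table.scores["GC"], abs=1e-12)

    def test_iterative_matches_dense_linear_solve(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            graph = random_dag(rng, int(rng.integers(8, 40)))
            non_root = sorted(graph.terms - graph.roots)
            gam = GeneAnnotationMap({
                f"G{i}": {non_root[j] for j in rng.choice(len(non_root), size=2,
                                                          replace=False)}
                for i in range(5)
            })
            cfg = RWRConfig(restart_prob=0.2)
            rwr = build_rwr_graph(graph, gam, cfg)
            terms = [non_root[int(rng.integers(0, len(non_root)))]]
            table = rwr_scores(rwr, graph, terms, cfg)
            # closed form p = r (I - (1-r) W)^-1 p0
            n = len(rwr.nodes)
            restart_terms = ancestor_closure(graph, terms) or set(terms)
            idx = [rwr.node_index[t] for t in restart_terms if t in rwr.node_index]
            p0 = np.zeros(n)
            p0[idx] = 1.0 / len(idx)
            W = rwr.W.toarray()
            p = cfg.restart_prob * np.linalg.solve(
                np.eye(n) - (1 - cfg.restart_prob) * W, p0
            )
            for g, score in table.scores.items():
                assert score == pytest.approx(
                    p[rwr.node_index[GENE_PREFIX + g]], abs=1e-8
                )

    def test_empty_patient_terms_rejected(self, chain_graph):
        gam = GeneAnnotationMap({"G1": {"HP:C"}})
        rwr = build_rwr_graph(chain_graph, gam)
        with pytest.raises(ValueError):
            rwr_scores(rwr, chain_graph, [], RWRConfig())


class TestBestGeneScore:
    TABLE = GeneScoreTable(method="cosine", scores={"G1": 0.3, "G2": 0.7})

    def test_maximum_over_genes(self):
        assert best_gene_score_per_variant(["G1", "G2"], self.TABLE) == 0.7

    def test_single_gene_passthrough(self):
        assert best_gene_score_per_variant(["G1"], self.TABLE) == 0.3

    def test_unscored_genes_floor_at_zero(self):
        assert best_gene_score_per_variant(["GX"], self.TABLE) == 0.0
        assert best_gene_score_per_variant([], self.TABLE) == 0.0


def test_annotate_phenotype_scores_attaches_both_features(small_cohort):
    import copy

    spec, graph, gam, cohort = small_cohort
    variants = copy.deepcopy(cohort.variants[:200])
    annotate_phenotype_scores(variants, graph, gam, cohort.patient_terms)
    for v in variants:
        assert 0.0 <= v.annotations["HPO-cosine"] <= 1.0
        assert 0.0 <= v.annotations["PyxisMap"] <= 1.0
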