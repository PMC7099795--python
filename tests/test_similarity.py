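"""Semantic and functional similarity against hand-derived and oracle values."""

import numpy as np
import pytest

from rflda.io import OntologyGraph
from rflda.similarity import (
    build_dag,
    disease_similarity_matrix,
    functional_similarity,
    lncrna_similarity_matrix,
    semantic_similarity,
)

from conftest import random_dag_parents

DELTA = 0.5


def naive_contributions(term, parents, delta):
    """Independent oracle: exhaustive path enumeration.

    The contribution of an ancestor is the max over all directed IS_A
    paths from the term to it of delta**(path length).
    """
    best = {term: 1.0}

    def walk(node, value):
        for parent in parents[node]:
            v = value * delta
            if v > best.get(parent, 0.0):
                best[parent] = v
            walk(parent, v)

    walk(term, 1.0)
    return best


class TestBuildDag:
    def test_isolated_term(self):
        onto = OntologyGraph(parents={"D": set()})
        dag = build_dag("D", onto, DELTA)
        assert dag.nodes == {"D"}
        assert dag.semantic_value == 1.0

    def test_chain(self, worked):
        case = worked["chain"]
        dag = build_dag(case["term"], case["ontology"], DELTA)
        assert dag.contributions == case["expected_contributions"]
        assert dag.semantic_value == case["expected_dv"]

    def test_diamond_max_over_children(self, worked):
        case = worked["diamond"]
        dag = build_dag(case["term"], case["ontology"], DELTA)
        assert dag.contributions == case["expected_contributions"]
        assert dag.semantic_value == case["expected_dv"]

    def test_delta_validation(self, worked):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                build_dag("D", worked["chain"]["ontology"], bad)

    def test_out_of_ontology_term_gets_self_dag(self):
        onto = OntologyGraph(parents={"A": set()})
        dag = build_dag("missing", onto, DELTA)
        assert not dag.in_ontology
        assert dag.contributions == {"missing": 1.0}

    @pytest.mark.parametrize("seed", range(30))
    @pytest.mark.parametrize("delta", [0.5, 0.8])
    def test_matches_path_enumeration_oracle(self, seed, delta):
        parents = random_dag_parents(seed)
        onto = OntologyGraph(parents=parents)
        term = max(parents)  # the highest-index node has the deepest closure
        dag = build_dag(term, onto, delta)
        oracle = naive_contributions(term, parents, delta)
        assert dag.nodes == set(oracle)
        for node, expected in oracle.items():
            assert dag.contributions[node] == pytest.approx(expected, abs=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_contributions_attenuate_with_distance(self, seed):
        """DC equals delta**(shortest IS_A distance): strictly smaller for
        strictly more distant ancestors when delta < 1, and 1 only at the
        term itself."""
        import networkx as nx

        parents = random_dag_parents(seed)
        onto = OntologyGraph(parents=parents)
        term = max(parents)
        dag = build_dag(term, onto, 0.5)
        graph = nx.DiGraph(
            (c, p) for c, ps in parents.items() for p in ps
        )
        graph.add_nodes_from(parents)
        dist = nx.single_source_shortest_path_length(graph, term)
        for node in dag.nodes:
            assert 0.0 < dag.contributions[node] <= 1.0
            assert dag.contributions[node] == pytest.approx(0.5 ** dist[node])
        assert dag.contributions[term] == 1.0


class TestSemanticSimilarity:
    def test_identical_dags(self, worked):
        dag = build_dag("D", worked["chain"]["ontology"], DELTA)
        assert semantic_similarity(dag, dag) == 1.0

    def test_disjoint_dags(self):
        a = build_dag("A", OntologyGraph(parents={"A": set()}), DELTA)
        b = build_dag("B", OntologyGraph(parents={"B": set()}), DELTA)
        assert semantic_similarity(a, b) == 0.0

    def test_siblings_one_third(self, worked):
        case = worked["siblings"]
        d1 = build_dag("d1", case["ontology"], DELTA)
        d2 = build_dag("d2", case["ontology"], DELTA)
        value = semantic_similarity(d1, d2)
        assert value == pytest.approx(case["expected_ds"], abs=1e-15)
        assert value == semantic_similarity(d2, d1)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_and_self_unity(self, seed):
        parents = random_dag_parents(seed)
        onto = OntologyGraph(parents=parents)
        dags = [build_dag(t, onto, DELTA) for t in sorted(parents)]
        for i, a in enumerate(dags):
            assert semantic_similarity(a, a) == 1.0
            for b in dags[i + 1 :]:
                v = semantic_similarity(a, b)
                assert 0.0 <= v <= 1.0
                assert v == semantic_similarity(b, a)


class TestDiseaseMatrix:
    def test_single_disease(self):
        onto = OntologyGraph(parents={"D": set()})
        dd = disease_similarity_matrix(["D"], onto, DELTA)
        assert dd.values.tolist() == [[1.0]]

    def test_disjoint_pair(self):
        onto = OntologyGraph(parents={"A": set(), "B": set()})
        dd = disease_similarity_matrix(["A", "B"], onto, DELTA)
        assert dd.values[0, 1] == 0.0
        assert dd.values[0, 0] == dd.values[1, 1] == 1.0

    def test_sibling_pair_off_diagonal(self, worked):
        case = worked["siblings"]
        dd = disease_similarity_matrix(list(case["terms"]), case["ontology"], DELTA)
        assert dd.values[0, 1] == pytest.approx(1 / 3, abs=1e-15)

    def test_tsv_roundtrip(self, worked, tmp_path):
        case = worked["siblings"]
        dd = disease_similarity_matrix(list(case["terms"]), case["ontology"], DELTA)
        dd.to_tsv(tmp_path / "dd.tsv")
        from rflda.similarity import SimilarityMatrix

        back = SimilarityMatrix.from_tsv(tmp_path / "dd.tsv")
        assert back.ids == dd.ids
        np.testing.assert_allclose(back.values, dd.values, atol=1e-9)


class TestFunctionalSimilarity:
    @pytest.fixture()
    def dd(self, worked):
        case = worked["siblings"]
        return disease_similarity_matrix(list(case["terms"]), case["ontology"], DELTA)

    def test_identical_sets(self, dd):
        assert functional_similarity({"d1"}, {"d1"}, dd) == 1.0

    def test_singletons(self, dd):
        assert functional_similarity({"d1"}, {"d2"}, dd) == pytest.approx(1 / 3)

    def test_two_vs_one(self, dd):
        assert functional_similarity({"d1", "d2"}, {"d1"}, dd) == pytest.approx(7 / 9)

    def test_empty_set_is_zero(self, dd):
        assert functional_similarity(set(), {"d1"}, dd) == 0.0
        assert functional_similarity({"d1"}, set(), dd) == 0.0

    def test_symmetry_on_random_sets(self, small_matrices):
        rng = np.random.default_rng(11)
        ids = small_matrices.dd.ids
        for _ in range(20):
            a = set(rng.choice(ids, size=rng.integers(1, 5), replace=False))
            b = set(rng.choice(ids, size=rng.integers(1, 5), replace=False))
            ab = functional_similarity(a, b, small_matrices.dd)
            assert ab == functional_similarity(b, a, small_matrices.dd)
            assert 0.0 <= ab <= 1.0
            assert functional_similarity(a, a, small_matrices.dd) == pytest.approx(1.0)


class TestLncrnaMatrix:
    def test_toy_values(self, worked):
        case = worked["ls_toy"]
        dd = disease_similarity_matrix(["d1", "d2"], case["ontology"], DELTA)
        ll = lncrna_similarity_matrix(case["ld"], dd)
        for (a, b), expected in case["expected_ls"].items():
            assert ll.lookup(a, b) == pytest.approx(expected, abs=1e-15)
            assert ll.lookup(b, a) == pytest.approx(expected, abs=1e-15)

    def test_identical_rows_give_unity(self, worked):
        import numpy as np

        from rflda.io import AssociationMatrix

        case = worked["ls_toy"]
        dd = disease_similarity_matrix(["d1", "d2"], case["ontology"], DELTA)
        ld = AssociationMatrix(("x", "y"), ("d1", "d2"), np.array([[1, 0], [1, 0]]))
        ll = lncrna_similarity_matrix(ld, dd)
        assert ll.values[0, 1] == 1.0

    def test_allzero_row_flagged_zero(self, worked):
        import numpy as np

        from rflda.io import AssociationMatrix

        case = worked["ls_toy"]
        dd = disease_similarity_matrix(["d1", "d2"], case["ontology"], DELTA)
        ld = AssociationMatrix(("x", "y"), ("d1", "d2"), np.array([[0, 0], [1, 0]]))
        ll = lncrna_similarity_matrix(ld, dd)
        assert ll.values[0, 1] == 0.0
        assert ll.values[0, 0] == 0.0  # degenerate entity: no unit diagonal
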