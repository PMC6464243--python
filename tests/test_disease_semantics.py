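import math

import networkx as nx
import numpy as np
import pytest

from mirdap.disease_semantics import (DiseaseDAG, SemanticConfig, build_dag,
                                      compute_ic, contributions,
                                      semantic_similarity_matrices,
                                      semantic_value, sv1, sv2)
from mirdap.io_formats import DiseaseOntology

EPS = SemanticConfig(epsilon=0.5)


def ontology(**tree_numbers):
    return DiseaseOntology({k: set(v) for k, v in tree_numbers.items()})


def path_enumeration_contribution(dag: DiseaseDAG, node: str, eps: float) -> float:
    """Independent oracle: max over all downward paths of eps**length.

    Enumerates every directed path from the disease up to ``node`` in the
    child->parent graph and takes the best decay.
    """
    if node == dag.disease:
        return 1.0
    best = 0.0
    for path in nx.all_simple_paths(dag.graph, dag.disease, node):
        best = max(best, eps ** (len(path) - 1))
    return best


class TestBuildDag:
    def test_single_root_number(self):
        dag = build_dag(ontology(X=["C04"]), "X")
        assert dag.nodes == {"X"} and dag.graph.number_of_edges() == 0

    def test_prefix_owned_by_other_disease(self):
        dag = build_dag(ontology(X=["C04.588"], Y=["C04"]), "X")
        assert dag.nodes == {"X", "Y"}
        assert list(dag.graph.edges) == [("X", "Y")]

    def test_union_of_chains_matches_prefix_enumeration(self):
        onto = ontology(X=["C04.5", "C06.5"])
        dag = build_dag(onto, "X")
        expected = {"X"}
        for tn in ["C04.5", "C06.5"]:
            parts = tn.split(".")
            for i in range(1, len(parts)):
                prefix = ".".join(parts[:i])
                expected.add(onto.owner_of(prefix) or prefix)
        assert dag.nodes == expected
        assert {"C04", "C06"} <= dag.nodes

    def test_unknown_disease_raises(self):
        with pytest.raises(KeyError):
            build_dag(ontology(X=["C04"]), "missing")


class TestContributions:
    def test_self_contribution_is_one(self):
        dag = build_dag(ontology(X=["C04"]), "X")
        assert contributions(dag, EPS)["X"] == 1.0

    def test_chain_decay(self):
        dag = build_dag(ontology(X=["C01.2.3"]), "X")
        c = contributions(dag, EPS)
        assert c["C01.2"] == 0.5 and c["C01"] == 0.25
        assert semantic_value(dag) == pytest.approx(1.75)

    def test_diamond_takes_max_over_paths(self):
        # two chains meeting at the same grandparent name
        onto = ontology(X=["C01.A.1", "C01.B.1"], G=["C01"])
        dag = build_dag(onto, "X")
        c = contributions(dag, EPS)
        assert c["G"] == pytest.approx(0.25)
        assert semantic_value(dag) == pytest.approx(1 + 0.5 + 0.5 + 0.25)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # random forest of tree numbers (<= 10 nodes after union)
        segs = ["1", "2"]
        numbers = set()
        for _ in range(rng.integers(1, 4)):
            depth = int(rng.integers(1, 5))
            numbers.add("C0." + ".".join(rng.choice(segs, size=depth)))
        onto = ontology(X=sorted(numbers))
        dag = build_dag(onto, "X")
        assert len(dag.nodes) <= 10
        eps = float(rng.uniform(0.2, 0.9))
        c = contributions(dag, SemanticConfig(epsilon=eps))
        for node in dag.nodes:
            assert c[node] == pytest.approx(
                path_enumeration_contribution(dag, node, eps), abs=1e-12)


class TestSimilarityModels:
    def test_sv1_identical_disease_is_one(self):
        dag = build_dag(ontology(X=["C01.2"]), "X")
        contributions(dag, EPS)
        assert sv1(dag, dag) == pytest.approx(1.0)

    def test_sv1_disjoint_is_zero(self):
        o = ontology(X=["C01.1"], Y=["D02.1"])
        a, b = build_dag(o, "X"), build_dag(o, "Y")
        contributions(a, EPS), contributions(b, EPS)
        assert sv1(a, b) == 0.0

    def test_sv1_child_of_root(self):
        o = ontology(X=["C01.1"], Y=["C01"])
        a, b = build_dag(o, "X"), build_dag(o, "Y")
        contributions(a, EPS), contributions(b, EPS)
        # shared node Y: 0.5 from X's side, 1.0 from Y's; DVs 1.5 and 1
        assert sv1(a, b) == pytest.approx((0.5 + 1.0) / (1.5 + 1.0))
        assert sv1(a, b) == pytest.approx(sv1(b, a))

    def test_ic_values(self):
        # plant a node ("R") in exactly 2 of the 8 corpus DAGs
        o = ontology(a=["R.1"], b=["R.2"], c=["S.1"], d=["S.2"],
                     e=["T.1"], f=["T.2"], g=["U.1"], h=["U.2"])
        dags = {}
        for name in "abcdefgh":
            dag = build_dag(o, name)
            contributions(dag, EPS)
            dags[name] = dag
        ic = compute_ic(o, dags, EPS)
        assert ic["R"] == pytest.approx(-math.log(2 / 8), abs=1e-4)
        assert ic["R"] == pytest.approx(1.3863, abs=1e-4)

    def test_ic_of_ubiquitous_node_is_zero(self):
        o = ontology(a=["C01.1"], b=["C01.2"])
        dags = {}
        for name in "ab":
            dag = build_dag(o, name)
            contributions(dag, EPS)
            dags[name] = dag
        ic = compute_ic(o, dags, EPS)
        assert ic["C01"] == 0.0

    def test_sv2_hand_example(self):
        # two-node graph d -> g with known IC values and DV = 1.5
        g = nx.DiGraph()
        g.add_edge("d", "g")
        dag = DiseaseDAG("d", g, contributions={"d": 1.0, "g": 0.5},
                         semantic_value=1.5)
        onto = ontology(d=["C01.1"])
        onto.ic_values = {"d": 1.3863, "g": 0.2877}
        assert sv2(dag, dag, onto) == pytest.approx(
            2 * (1.3863 + 0.2877) / 3.0, abs=1e-4)
        assert sv2(dag, dag, onto) == pytest.approx(1.116, abs=1e-3)

    def test_sv2_zero_when_all_nodes_ubiquitous(self):
        # single-disease corpus: every node is in every DAG, all IC = 0
        o = ontology(a=["C01.1.2"])
        sim = semantic_similarity_matrices(o, ["a"], EPS)
        assert np.allclose(sim.sv2.values, 0.0)


class TestMatrixAssembly:
    def test_coverage_flags(self):
        o = ontology(a=["C01.1"], b=["C01.2"], c=["C02.1"])
        sim = semantic_similarity_matrices(o, ["a", "b", "c", "x", "y"], EPS)
        assert sim.sv1.values.shape == (3, 3)
        assert sim.has_semantic == {"a": True, "b": True, "c": True,
                                    "x": False, "y": False}

    def test_no_coverage(self):
        o = ontology(z=["C01"])
        sim = semantic_similarity_matrices(o, ["x", "y"], EPS)
        assert sim.sv1.values.shape == (0, 0)
        assert not any(sim.has_semantic.values())

    def test_sv1_symmetry_range_and_self_similarity(self, tiny_bundle):
        diseases = tiny_bundle.associations.diseases
        sim = semantic_similarity_matrices(tiny_bundle.ontology, diseases, EPS)
        v = sim.sv1.values
        assert np.allclose(v, v.T)
        assert (v >= 0).all() and (v <= 1 + 1e-12).all()
        assert np.allclose(np.diag(v), 1.0)
        assert np.allclose(sim.sv2.values, sim.sv2.values.T)

    def test_monotonicity_shared_ancestor_increases_numerator(self):
        # adding one more shared ancestor level cannot decrease overlap
        o1 = ontology(X=["C01.1"], Y=["C01.2"])
        o2 = ontology(X=["C01.5.1"], Y=["C01.5.2"])
        s1 = semantic_similarity_matrices(o1, ["X", "Y"], EPS).sv1.loc("X", "Y")
        s2 = semantic_similarity_matrices(o2, ["X", "Y"], EPS).sv1.loc("X", "Y")
        assert s2 >= s1
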