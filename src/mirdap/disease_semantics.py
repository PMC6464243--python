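"""Disease semantic similarity from dotted tree-number hierarchies.

Each disease is described by the ancestor graph induced by its tree
numbers: every prefix obtained by truncating trailing dotted segments is
an ancestor, and a disease reached through several tree numbers is a
single merged node. Two similarity models are computed on these graphs:

* model 1 propagates a contribution value down the graph with a per-edge
  decay factor epsilon: the disease itself contributes 1, and an ancestor
  s contributes ``max(epsilon * D(s'))`` over its children s' inside the
  graph. The semantic value DV is the sum of contributions, and the
  similarity of two diseases is the sum of their contributions over
  shared ancestors divided by the sum of their semantic values.
* model 2 replaces the per-disease contribution of a shared node with a
  corpus-level information-content term ``-log(num(DAGs(s)) /
  num(diseases))``, so rare ancestors weigh more than ubiquitous ones.
  The denominator keeps the model-1 semantic values, hence model-2
  self-similarity is generally not 1 and values are not clipped to [0,1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError, StructuralError, UnknownEntityError
from .io_formats import DiseaseOntology, NamedMatrix


@dataclass
class SemanticConfig:
    """Tunables of the semantic models.

    epsilon: per-edge semantic decay in (0, 1); 0.5 is the conventional
        choice for this family of similarity models.
    log_base: base of the information-content logarithm ("natural", 2 or 10).
    """

    epsilon: float = 0.5
    log_base: str | float = "natural"

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ConfigurationError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if self.log_base not in ("natural", 2, 10, 2.0, 10.0, math.e):
            raise ConfigurationError(f"unsupported log base {self.log_base!r}")

    @property
    def log_divisor(self) -> float:
        if self.log_base == "natural" or self.log_base == math.e:
            return 1.0
        return math.log(float(self.log_base))


@dataclass
class DiseaseDAG:
    """Per-disease ancestor graph with contribution and semantic values.

    ``graph`` is a directed acyclic graph with child -> parent edges; the
    disease itself is always a node. ``contributions`` and
    ``semantic_value`` stay None until computed.
    """

    disease: str
    graph: nx.DiGraph
    contributions: dict[str, float] | None = None
    semantic_value: float | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def _prefixes(tree_number: str) -> list[str]:
    """All dotted prefixes of a tree number, shortest first."""
    parts = tree_number.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts))]


def _node_key(ontology: DiseaseOntology, tree_number: str, self_name: str,
              self_numbers: set[str]) -> str:
    if tree_number in self_numbers:
        return self_name
    owner = ontology.owner_of(tree_number)
    return owner if owner is not None else tree_number


def build_dag(ontology: DiseaseOntology, disease: str) -> DiseaseDAG:
    """Union ancestor graph of a disease across all its tree numbers.

    Nodes are keyed by the disease name owning the tree number when the
    ontology contains one, otherwise by the tree-number string itself;
    nodes reached via multiple tree numbers collapse into one.
    """
    numbers = ontology.numbers_for(disease)
    if not numbers:
        raise UnknownEntityError(f"disease {disease!r} has no tree numbers")
    g = nx.DiGraph()
    for tn in sorted(numbers):
        chain = _prefixes(tn)
        keys = [_node_key(ontology, p, disease, numbers) for p in chain]
        g.add_node(keys[0])
        for child, parent in zip(keys[1:], keys[:-1]):
            if child != parent:
                g.add_edge(child, parent)  # child -> parent
    g.add_node(disease)
    if not nx.is_directed_acyclic_graph(g):
        # A disease owning tree numbers at several depths of one chain makes
        # the name-merged graph cyclic; every strongly connected component
        # represents one merged entity, so contract each to a single node.
        g = _condense(g, disease)
    return DiseaseDAG(disease=disease, graph=g)


def _condense(g: nx.DiGraph, disease: str) -> nx.DiGraph:
    cond = nx.condensation(g)
    names = {}
    for scc_id, members in cond.nodes(data="members"):
        names[scc_id] = disease if disease in members else min(members)
    out = nx.DiGraph()
    out.add_nodes_from(names.values())
    for u, v in cond.edges:
        if names[u] != names[v]:
            out.add_edge(names[u], names[v])
    if not nx.is_directed_acyclic_graph(out):  # two SCCs sharing a name
        raise StructuralError(f"ancestor graph of {disease!r} cannot be "
                              "reduced to a DAG")
    return out


def contributions(dag: DiseaseDAG, config: SemanticConfig) -> dict[str, float]:
    """Model-1 contribution of every node to the disease's semantic value.

    The disease contributes 1; every ancestor s contributes the maximum of
    ``epsilon * D(s')`` over its children s' inside the graph, evaluated
    bottom-up. Stores the result on the DAG and returns it.
    """
    eps = config.epsilon
    contrib: dict[str, float] = {}
    # child -> parent edges: topological order yields children before parents
    for node in nx.topological_sort(dag.graph):
        if node == dag.disease:
            contrib[node] = 1.0
            continue
        children = list(dag.graph.predecessors(node))
        if not children:
            raise StructuralError(
                f"ancestor {node!r} of {dag.disease!r} is unreachable from the disease"
            )
        contrib[node] = max(eps * contrib[c] for c in children)
    dag.contributions = contrib
    dag.semantic_value = sum(contrib.values())
    return contrib


def semantic_value(dag: DiseaseDAG) -> float:
    """Sum of contributions over all nodes (>= 1, since the self node is 1)."""
    if dag.contributions is None:
        raise StructuralError("contributions not computed for this DAG")
    dag.semantic_value = sum(dag.contributions.values())
    return dag.semantic_value


def sv1(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Model-1 similarity: shared contributions over summed semantic values."""
    if dag_i.contributions is None or dag_j.contributions is None:
        raise StructuralError("contributions must be computed before sv1")
    shared = dag_i.nodes & dag_j.nodes
    num = sum(dag_i.contributions[s] + dag_j.contributions[s] for s in shared)
    return num / (dag_i.semantic_value + dag_j.semantic_value)


def compute_ic(ontology: DiseaseOntology, dags: dict[str, DiseaseDAG],
               config: SemanticConfig) -> dict[str, float]:
    """Corpus-level information content of every node across all DAGs.

    ``D'(s) = -log(num(DAGs(s)) / num(diseases))`` in the configured base.
    Counts and values are stored on the ontology for later queries.
    """
    counts: dict[str, int] = {}
    for dag in dags.values():
        for node in dag.nodes:
            counts[node] = counts.get(node, 0) + 1
    n = len(dags)
    div = config.log_divisor
    ic = {s: -math.log(c / n) / div for s, c in counts.items()}
    ontology.dag_counts = counts
    ontology.ic_values = ic
    ontology.num_diseases = n
    return ic


def sv2(dag_i: DiseaseDAG, dag_j: DiseaseDAG, ontology: DiseaseOntology) -> float:
    """Model-2 similarity: shared information content over model-1 DV sum.

    Each shared node contributes its corpus-level IC once per disease
    (i.e. ``2 * D'(s)``); the result is not bounded above by 1.
    """
    if not ontology.ic_values:
        raise StructuralError("information content not computed; call compute_ic")
    if dag_i.semantic_value is None or dag_j.semantic_value is None:
        raise StructuralError("semantic values must be computed before sv2")
    shared = dag_i.nodes & dag_j.nodes
    missing = [s for s in shared if s not in ontology.ic_values]
    if missing:
        raise UnknownEntityError(f"nodes absent from IC table: {missing}")
    num = sum(2.0 * ontology.ic_values[s] for s in shared)
    return num / (dag_i.semantic_value + dag_j.semantic_value)


@dataclass
class SemanticSimilarities:
    """Both similarity matrices over the ontology-covered diseases."""

    sv1: NamedMatrix
    sv2: NamedMatrix
    has_semantic: dict[str, bool]
    dags: dict[str, DiseaseDAG] = field(default_factory=dict, repr=False)


def semantic_similarity_matrices(
    ontology: DiseaseOntology,
    diseases: list[str],
    config: SemanticConfig | None = None,
) -> SemanticSimilarities:
    """Compute both similarity models for every ontology-covered disease.

    Diseases absent from the ontology get has_semantic=False and no matrix
    entry; fusion later fills those pairs from the interaction-profile
    kernel.
    """
    config = config or SemanticConfig()
    covered = [d for d in diseases if d in ontology]
    flags = {d: d in ontology for d in diseases}
    dags: dict[str, DiseaseDAG] = {}
    for d in covered:
        dag = build_dag(ontology, d)
        contributions(dag, config)
        dags[d] = dag
    if covered:
        compute_ic(ontology, dags, config)
    k = len(covered)
    m1 = np.zeros((k, k))
    m2 = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            m1[a, b] = m1[b, a] = sv1(dags[covered[a]], dags[covered[b]])
            m2[a, b] = m2[b, a] = sv2(dags[covered[a]], dags[covered[b]], ontology)
    return SemanticSimilarities(
        sv1=NamedMatrix(covered, covered, m1),
        sv2=NamedMatrix(covered, covered, m2),
        has_semantic=flags,
        dags=dags,
    )
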