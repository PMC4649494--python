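"""Disease semantic similarity from ontology DAGs.

Each annotated disease induces the directed acyclic graph of itself plus all
ancestor terms (its ancestor closure in the ontology). A term's contribution
to a disease's semantic value is the information content
``-log(k / N)`` where ``k`` is the number of disease DAGs the term appears in
and ``N`` the number of diseases in the corpus: terms shared by many disease
DAGs are generic and contribute little, rare terms are specific and
contribute much. The semantic value ``DV(A)`` sums the contributions over
``D(A)``, and the similarity of two diseases is the contribution mass of the
shared terms relative to ``DV(A) + DV(B)``:

    SS(A, B) = sum_{t in D(A) ∩ D(B)} (D_A(t) + D_B(t)) / (DV(A) + DV(B))

which is symmetric, lies in [0, 1], and equals 1 on the diagonal whenever
``DV(A) > 0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import EntityNotFoundError, InputError, StructuralError
from .matrices import SimilarityMatrix
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseDAG:
    """Ancestor-closed DAG of one disease: node set D(A) and edge set E(A)."""

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.disease not in self.nodes:
            raise StructuralError(f"disease {self.disease!r} missing from its own DAG")
        for parent, child in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise StructuralError("DAG edge endpoint outside node set")


@dataclass
class DagCorpus:
    """All disease DAGs of the annotated set, plus term occurrence counts."""

    dags: dict[str, DiseaseDAG]
    term_dag_count: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for dag in self.dags.values():
            for term in dag.nodes:
                counts[term] = counts.get(term, 0) + 1
        self.term_dag_count = counts

    @property
    def n_diseases(self) -> int:
        return len(self.dags)

    def dag(self, disease: str) -> DiseaseDAG:
        try:
            return self.dags[disease]
        except KeyError:
            raise EntityNotFoundError(f"disease {disease!r} not in corpus") from None


def build_dag(disease: str, parent_edges: list[tuple[str, str]]) -> DiseaseDAG:
    """Ancestor closure of ``disease`` in the global parent->child edge list.

    Multiple positions of one term merge automatically: the closure is the
    union over all paths to roots.
    """
    graph = nx.DiGraph(parent_edges)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise StructuralError(f"ontology contains a cycle: {cycle}")
    if disease not in graph:
        raise EntityNotFoundError(f"term {disease!r} absent from ontology")
    nodes = set(nx.ancestors(graph, disease)) | {disease}
    edges = {(u, v) for u, v in graph.edges if u in nodes and v in nodes}
    return DiseaseDAG(disease, frozenset(nodes), frozenset(edges))


def build_corpus(diseases: list[str], parent_edges: list[tuple[str, str]]) -> DagCorpus:
    return DagCorpus({d: build_dag(d, parent_edges) for d in diseases})


def term_contribution(term: str, corpus: DagCorpus, *, log_base: float = math.e) -> float:
    """Information content -log(term_dag_count / n_diseases) of one term."""
    count = corpus.term_dag_count.get(term)
    if count is None:
        raise EntityNotFoundError(f"term {term!r} occurs in no DAG of the corpus")
    return -math.log(count / corpus.n_diseases, log_base)


def semantic_value(dag: DiseaseDAG, corpus: DagCorpus, *,
                   log_base: float = math.e) -> float:
    """DV(A): total contribution of the disease and all its ancestors."""
    return sum(term_contribution(t, corpus, log_base=log_base) for t in dag.nodes)


def semantic_similarity(disease_a: str, disease_b: str, corpus: DagCorpus, *,
                        log_base: float = math.e) -> float:
    dag_a, dag_b = corpus.dag(disease_a), corpus.dag(disease_b)
    dv_a = semantic_value(dag_a, corpus, log_base=log_base)
    dv_b = semantic_value(dag_b, corpus, log_base=log_base)
    if dv_a + dv_b == 0.0:
        # every term of both DAGs occurs in all corpus DAGs: 0/0 case
        logger.warning(
            "degenerate semantic similarity for (%s, %s): DV(A)+DV(B)=0; "
            "returning %d", disease_a, disease_b, int(disease_a == disease_b),
        )
        return 1.0 if disease_a == disease_b else 0.0
    shared = dag_a.nodes & dag_b.nodes
    numerator = sum(
        2.0 * term_contribution(t, corpus, log_base=log_base) for t in shared
    )
    return numerator / (dv_a + dv_b)


def semantic_similarity_matrix(corpus: DagCorpus, disease_subset: list[str] | None = None,
                               *, log_base: float = math.e) -> SimilarityMatrix:
    """Pairwise semantic similarity over the annotated subset IS."""
    ids = list(corpus.dags) if disease_subset is None else list(disease_subset)
    for disease in ids:
        corpus.dag(disease)  # raises on absentees
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            value = semantic_similarity(ids[i], ids[j], corpus, log_base=log_base)
            values[i, j] = values[j, i] = value
    return SimilarityMatrix(tuple(ids), values, "SS")


# ---------------------------------------------------------------------------
# ontology file interface: parent->child edge TSV + disease->term mapping TSV

def load_ontology(edges_path, mapping_path) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Read the ontology edge list and the disease-name -> term-id mapping.

    Diseases absent from the mapping have no ontology annotation and fall
    outside the semantic-similarity subset IS.
    """
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(edges_path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in raw.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise InputError(f"{edges_path}: line {lineno} is not parent<TAB>child")
        if lineno == 1 and fields[0].lower() in {"parent", "parent_id"}:
            continue
        edges.append((fields[0], fields[1]))
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(mapping_path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in raw.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise InputError(f"{mapping_path}: line {lineno} is not disease<TAB>term")
        if lineno == 1 and fields[0].lower() in {"disease", "disease_id"}:
            continue
        mapping[fields[0]] = fields[1]
    return edges, mapping


def corpus_from_ontology(edges: list[tuple[str, str]], mapping: dict[str, str],
                         diseases: list[str]) -> tuple[DagCorpus, list[str]]:
    """Build the corpus for the network diseases that carry an annotation.

    Returns the corpus (keyed by disease name, DAGs over ontology term ids)
    and the annotated subset IS in the order of ``diseases``.
    """
    annotated = [d for d in diseases if d in mapping]
    # the DAG is built on ontology term ids; the corpus is keyed by disease
    # name, so two diseases mapped to the same term are maximally similar
    dags = {d: build_dag(mapping[d], edges) for d in annotated}
    return DagCorpus(dags), annotated
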