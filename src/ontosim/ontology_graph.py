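"""Ontology DAG construction and queries.

Terms are nodes of a rooted directed acyclic graph whose edges point from a
parent (more general term) to each of its children.  Only the ``is_a`` and
``part_of`` relations are kept and both are treated identically for the
topological measures; the relation label is retained on each edge because
the Wang comparator weights the two relation types differently.

The Gene Ontology has three parentless roots (biological_process,
molecular_function, cellular_component); they coexist in one graph and
carry distinct namespaces.  Synthetic DAGs typically have a single root
with namespace ``other``.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

__all__ = [
    "OntologyDAG",
    "StructureError",
    "parse_obo",
    "build_dag",
    "read_edge_list",
    "ancestors_self_inclusive",
    "descendants_self_inclusive",
    "levels",
    "topological_order",
]

#: Relations retained by default; the regulates family is dropped.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: OBO namespace tag -> short namespace code.
_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class StructureError(ValueError):
    """Raised when the input graph violates the DAG contract."""


class OntologyDAG:
    """Rooted DAG of ontology terms with typed (is_a/part_of) edges.

    Thin wrapper around a :class:`networkx.DiGraph` oriented parent->child.
    Node attribute ``namespace`` holds one of ``BP``/``MF``/``CC``/``other``;
    edge attribute ``relation`` holds the relation label.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        self._validate()
        self.roots = frozenset(n for n in graph if graph.in_degree(n) == 0)

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        g = self.graph
        if len(g) == 0:
            raise StructureError("ontology graph has no terms")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructureError(
                f"ontology graph contains a cycle through {cycle[0][0]!r}"
            )

    # -- queries -------------------------------------------------------------

    @property
    def terms(self) -> frozenset:
        return frozenset(self.graph.nodes)

    def __contains__(self, term) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    def _require(self, term) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")

    def parents(self, term) -> set:
        self._require(term)
        return set(self.graph.predecessors(term))

    def children(self, term) -> set:
        self._require(term)
        return set(self.graph.successors(term))

    def n_children(self, term) -> int:
        self._require(term)
        return self.graph.out_degree(term)

    def relation(self, parent, child) -> str:
        return self.graph.edges[parent, child]["relation"]

    def namespace(self, term) -> str:
        self._require(term)
        return self.graph.nodes[term].get("namespace", "other")

    def terms_in_namespace(self, namespace: str) -> set:
        return {t for t in self.graph if self.namespace(t) == namespace}

    def edges(self) -> Iterable[tuple]:
        """Yield (parent, child, relation) triples."""
        for p, c, rel in self.graph.edges(data="relation"):
            yield p, c, rel

    def leaves(self) -> set:
        return {n for n in self.graph if self.graph.out_degree(n) == 0}


def ancestors_self_inclusive(dag: OntologyDAG, term) -> set:
    """All terms on a directed path from a root down to ``term``, plus the
    term itself (the self-inclusive ancestor set T_t)."""
    dag._require(term)
    return nx.ancestors(dag.graph, term) | {term}


def descendants_self_inclusive(dag: OntologyDAG, term) -> set:
    dag._require(term)
    return nx.descendants(dag.graph, term) | {term}


def levels(dag: OntologyDAG) -> dict:
    """Longest-path depth of every term; roots sit at level 0.

    The longest (rather than shortest) path is used so that a child can
    never share a level with one of its parents.
    """
    level: dict = {}
    for t in topological_order(dag):
        preds = list(dag.graph.predecessors(t))
        level[t] = 0 if not preds else 1 + max(level[p] for p in preds)
    return level


def topological_order(dag: OntologyDAG) -> list:
    """Term ordering in which every parent precedes all of its children.

    Deterministic: ties are broken by sorted term identifier.
    """
    return list(nx.lexicographical_topological_sort(dag.graph, key=str))


def build_dag(
    edge_list: Iterable[tuple],
    namespaces: Mapping | None = None,
    extra_terms: Iterable | None = None,
) -> OntologyDAG:
    """Build a validated :class:`OntologyDAG` from (parent, child[, relation])
    tuples.

    Duplicate (parent, child) pairs are deduplicated with a warning; a cycle
    raises :class:`StructureError`.  ``extra_terms`` declares isolated terms
    (e.g. a lone root with no edges).
    """
    g = nx.DiGraph()
    seen: set = set()
    for edge in edge_list:
        if len(edge) == 2:
            parent, child = edge
            rel = "is_a"
        else:
            parent, child, rel = edge[:3]
        if (parent, child) in seen:
            warnings.warn(f"duplicate edge ({parent!r}, {child!r}) dropped")
            continue
        seen.add((parent, child))
        g.add_edge(parent, child, relation=rel)
    for t in extra_terms or ():
        g.add_node(t)
    for n in g.nodes:
        ns = namespaces.get(n, "other") if namespaces else "other"
        g.nodes[n]["namespace"] = ns
    return OntologyDAG(g)


def read_edge_list(stream) -> OntologyDAG:
    """Read the fixture TSV dialect: ``parent<TAB>child[<TAB>relation]``,
    ``#`` comments and an optional ``parent\\tchild...`` header line."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    edges = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() == "parent":
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed edge-list line: {raw!r}")
        edges.append(tuple(parts[:3]))
    return build_dag(edges)


def parse_obo(stream, keep_relations: Iterable[str] = DEFAULT_RELATIONS) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Obsolete terms are excluded; only the relations in ``keep_relations``
    (default ``is_a`` and ``part_of``) are retained, so the regulates family
    is dropped.  A term referenced as a parent but lacking its own stanza is
    materialized as a bare term with a warning.
    """
    keep = frozenset(keep_relations)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    multi = obonet.read_obo(stream, ignore_obsolete=True)

    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        ns = _NAMESPACE_CODES.get(data.get("namespace", ""), "other")
        g.add_node(node, namespace=ns, name=data.get("name"))
    # obonet orients edges child -> parent with the relation as the key.
    for child, parent, rel in multi.edges(keys=True):
        if rel not in keep:
            continue
        if parent not in g:
            warnings.warn(
                f"term {parent!r} referenced as a parent but has no stanza; "
                "materialized as a bare term"
            )
            g.add_node(parent, namespace="other", name=None)
        g.add_edge(parent, child, relation=rel)
    return OntologyDAG(g)


def write_obo(dag: OntologyDAG, stream) -> None:
    """Serialize a DAG as a minimal OBO 1.2 document (round-trips through
    :func:`parse_obo`)."""
    inv = {v: k for k, v in _NAMESPACE_CODES.items()}
    stream.write("format-version: 1.2\n")
    for term in sorted(dag.terms, key=str):
        stream.write(f"\n[Term]\nid: {term}\n")
        stream.write(f"name: {term}\n")
        ns = dag.namespace(term)
        if ns in inv:
            stream.write(f"namespace: {inv[ns]}\n")
        for parent in sorted(dag.parents(term), key=str):
            rel = dag.relation(parent, term)
            if rel == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {rel} {parent}\n")
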