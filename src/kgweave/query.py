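"""In-memory one-hop query answering over the canonicalized graph.

Queries follow the TRAPI message convention: a ``query_graph`` of exactly
two query nodes and one query edge, at least one node pinned by ids.
Matching is hierarchy-aware — category and predicate constraints expand to
their descendant closures in the semantic model — and identifier lookup
resolves through ``equivalent_identifiers``, so querying by any synonym of
a canonical concept finds it.  Edges with symmetric predicates match in
either orientation.  Results are deduplicated and deterministically
ordered (descending provenance-source count, then lexicographic binding),
and the returned ``knowledge_graph`` slice contains exactly the bound
nodes and edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IndexError_, QueryValidationError
from .graph_model import Assertion, CanonicalConcept, Concept, GraphDocument
from .semantic_model import SemanticModel

__all__ = ["QNode", "QEdge", "QueryGraph", "ResultSet", "GraphIndex",
           "index_graph", "answer_one_hop"]


@dataclass
class QNode:
    ids: list[str] | None = None
    categories: list[str] | None = None


@dataclass
class QEdge:
    subject: str
    object: str
    predicates: list[str] | None = None


@dataclass
class QueryGraph:
    """A one-hop query: exactly two qnodes, one qedge."""

    qnodes: dict[str, QNode]
    qedges: dict[str, QEdge]

    @classmethod
    def from_dict(cls, doc: dict) -> "QueryGraph":
        """Parse the TRAPI ``query_graph`` skeleton
        (``{"nodes": {...}, "edges": {...}}``)."""
        if "message" in doc:
            doc = doc["message"]
        if "query_graph" in doc:
            doc = doc["query_graph"]
        qnodes = {k: QNode(ids=v.get("ids"), categories=v.get("categories"))
                  for k, v in (doc.get("nodes") or {}).items()}
        qedges = {k: QEdge(subject=v.get("subject", ""), object=v.get("object", ""),
                           predicates=v.get("predicates"))
                  for k, v in (doc.get("edges") or {}).items()}
        return cls(qnodes, qedges)

    def validate(self) -> None:
        if len(self.qnodes) != 2:
            raise QueryValidationError(
                f"one-hop queries need exactly 2 query nodes (got {len(self.qnodes)})")
        if len(self.qedges) != 1:
            raise QueryValidationError(
                f"one-hop queries need exactly 1 query edge (got {len(self.qedges)})")
        qedge = next(iter(self.qedges.values()))
        for end in (qedge.subject, qedge.object):
            if end not in self.qnodes:
                raise QueryValidationError(f"query edge references unknown qnode {end!r}")
        if qedge.subject == qedge.object:
            raise QueryValidationError("query edge endpoints must be distinct qnodes")
        if not any(qn.ids for qn in self.qnodes.values()):
            raise QueryValidationError("at least one query node must be constrained by ids")


@dataclass
class ResultSet:
    """Ordered bindings plus the minimal knowledge_graph slice."""

    results: list[dict[str, str]]
    knowledge_graph: GraphDocument

    def to_dict(self) -> dict:
        from .graph_model import _edge_to_dict, _node_to_dict  # serialization helpers
        return {
            "results": self.results,
            "knowledge_graph": {
                "nodes": [_node_to_dict(n) for n in self.knowledge_graph.nodes],
                "edges": [_edge_to_dict(e) for e in self.knowledge_graph.edges],
            },
        }


def _edge_key(edge: Assertion) -> str:
    return f"{edge.subject}--{edge.predicate}--{edge.object}"


@dataclass
class GraphIndex:
    """Adjacency and synonym-resolving lookup over a canonicalized graph."""

    nodes: dict[str, Concept]
    alias: dict[str, str]                       # any known identifier -> canonical id
    out_edges: dict[str, list[int]]
    in_edges: dict[str, list[int]]
    edges: list[Assertion] = field(default_factory=list)

    def resolve(self, identifier: str) -> Concept | None:
        """Look a node up by its id or any equivalent identifier."""
        canonical = self.alias.get(identifier)
        return self.nodes.get(canonical) if canonical else None


def index_graph(graph: GraphDocument, model: SemanticModel) -> GraphIndex:
    """Build the in-memory index; duplicate node ids are an error."""
    nodes: dict[str, Concept] = {}
    alias: dict[str, str] = {}
    for node in graph.nodes:
        if node.id in nodes:
            raise IndexError_(f"duplicate node id {node.id}")
        nodes[node.id] = node
        alias[node.id] = node.id
        if isinstance(node, CanonicalConcept):
            for eq in node.equivalent_identifiers:
                alias[eq] = node.id
    edges = list(graph.edges)
    out_edges: dict[str, list[int]] = {nid: [] for nid in nodes}
    in_edges: dict[str, list[int]] = {nid: [] for nid in nodes}
    for i, edge in enumerate(edges):
        if edge.subject in out_edges:
            out_edges[edge.subject].append(i)
        if edge.object in in_edges:
            in_edges[edge.object].append(i)
    return GraphIndex(nodes, alias, out_edges, in_edges, edges)


def _category_closure(model: SemanticModel, categories: list[str] | None) -> set[str] | None:
    if not categories:
        return None
    out: set[str] = set()
    for c in categories:
        out |= model.expand_category(c)
    return out


def _node_categories(node: Concept) -> set[str]:
    if isinstance(node, CanonicalConcept) and node.all_categories:
        return set(node.all_categories)
    return {node.category}


def answer_one_hop(index: GraphIndex, query: QueryGraph,
                   model: SemanticModel) -> ResultSet:
    """Evaluate a validated one-hop query against the index.

    A graph edge matches iff its predicate lies in the descendant closure
    of a listed predicate (any, if unconstrained), each endpoint satisfies
    its qnode (id membership after synonym resolution; any category in
    the descendant closure of a listed category; unconstrained otherwise),
    and its direction matches subject -> object — except symmetric
    predicates, which match in either orientation.
    """
    query.validate()
    qedge_key, qedge = next(iter(query.qedges.items()))
    subj_key, obj_key = qedge.subject, qedge.object

    pred_closure: set[str] | None = None
    if qedge.predicates:
        pred_closure = set()
        for p in qedge.predicates:
            pred_closure |= model.expand_predicate(p)

    constraints = {}
    for qkey, qnode in query.qnodes.items():
        id_set = None
        if qnode.ids:
            id_set = {index.alias[i] for i in qnode.ids if i in index.alias}
        constraints[qkey] = (id_set, _category_closure(model, qnode.categories))

    def satisfies(node_id: str, qkey: str) -> bool:
        id_set, cat_closure = constraints[qkey]
        if id_set is not None and node_id not in id_set:
            return False
        if cat_closure is not None:
            node = index.nodes[node_id]
            if not (_node_categories(node) & cat_closure):
                return False
        return True

    # candidate edges: scan adjacency of the pinned side(s) when available
    candidate_idx: set[int] = set()
    pinned = [qk for qk in (subj_key, obj_key) if constraints[qk][0] is not None]
    if pinned:
        for qk in pinned:
            for nid in constraints[qk][0]:
                candidate_idx.update(index.out_edges.get(nid, []))
                candidate_idx.update(index.in_edges.get(nid, []))
    else:   # unreachable post-validation, kept for safety
        candidate_idx = set(range(len(index.edges)))

    bindings: set[tuple[str, str, str]] = set()   # (subj node, obj node, edge key)
    for i in sorted(candidate_idx):
        edge = index.edges[i]
        if pred_closure is not None and edge.predicate not in pred_closure:
            continue
        orientations = [(edge.subject, edge.object)]
        if edge.predicate in model.symmetric_predicates:
            orientations.append((edge.object, edge.subject))
        for s_node, o_node in orientations:
            if satisfies(s_node, subj_key) and satisfies(o_node, obj_key):
                bindings.add((s_node, o_node, _edge_key(edge)))

    edge_by_key = {_edge_key(e): e for e in index.edges}

    def order_key(binding: tuple[str, str, str]):
        edge = edge_by_key[binding[2]]
        return (-len(edge.provided_by), binding)

    results = [{subj_key: s, obj_key: o, qedge_key: ek}
               for s, o, ek in sorted(bindings, key=order_key)]

    bound_nodes = sorted({nid for s, o, _ in bindings for nid in (s, o)})
    bound_edges = sorted({ek for _, _, ek in bindings})
    kg = GraphDocument(
        nodes=[index.nodes[nid] for nid in bound_nodes],
        edges=[edge_by_key[ek] for ek in bound_edges],
        build_info={"stage": "query_slice"},
    )
    return ResultSet(results, kg)
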