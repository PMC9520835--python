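"""Concept canonicalization: coalesce synonymous nodes into canonical ones.

Different sources assert the same concept under different identifier
systems (e.g. a disease appearing as MONDO:0005180, DOID:14330,
EFO:0002508 and MESH:D010300, linked by ``biolink:same_as``-grade edges).
Canonicalization proceeds in five steps:

1. load the pre-canonicalized graph;
2. partition its nodes into disjoint equivalence blocks — the connected
   components of the undirected subgraph induced by equivalence-grade
   edges (the predicate set's descendant closure; transitive chains mean
   components, not literal cliques, are the right notion);
3. elect a canonical identifier per block using the semantic model's
   per-category identifier-prefix priority lists, and merge member
   annotations onto a :class:`~kgweave.graph_model.CanonicalConcept`;
4. remap every edge to canonical endpoint identifiers; and
5. merge edges sharing (subject, object, predicate), preserving provenance.

Equivalence edges collapse into self-loops and are dropped (counted);
substantive self-loops produced by remapping (e.g. a "treats" edge inside
one block) are retained and logged rather than silently destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConsistencyError, KGWeaveError
from .graph_model import (Assertion, CanonicalConcept, Concept, GraphDocument,
                          ordered_union, parse_curie)
from .merge import coalesce_edges
from .semantic_model import SemanticModel

__all__ = [
    "EquivalencePartition",
    "CanonicalizationLog",
    "build_partition",
    "choose_canonical",
    "build_canonical_graph",
    "canonicalize",
    "DEFAULT_EQUIVALENCE_PREDICATES",
]

DEFAULT_EQUIVALENCE_PREDICATES = frozenset({"biolink:same_as"})


@dataclass
class EquivalencePartition:
    """Disjoint, exhaustive blocks of pre-graph node ids."""

    blocks: list[list[str]]
    block_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.block_of:
            self.block_of = {nid: i for i, block in enumerate(self.blocks) for nid in block}


@dataclass
class CanonicalizationLog:
    block_count: int = 0
    max_block_size: int = 0
    dropped_equivalence_self_loops: int = 0
    retained_self_loops: list[tuple[str, str, str]] = field(default_factory=list)
    coalesced_count: int = 0


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:       # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic representative: lexicographically smaller root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_partition(graph: GraphDocument, model: SemanticModel,
                    equivalence_predicates=DEFAULT_EQUIVALENCE_PREDICATES,
                    ) -> EquivalencePartition:
    """Blocks = connected components of the synonymy subgraph.

    The synonymy subgraph is induced by edges whose predicate falls in the
    descendant closure of ``equivalence_predicates``; nodes with no such
    edges form singleton blocks.  Unknown predicates raise a lookup error.
    """
    closure: set[str] = set()
    for pred in sorted(equivalence_predicates):
        closure |= model.expand_predicate(pred)

    ids = sorted(graph.node_ids())
    uf = _UnionFind(ids)
    for edge in graph.edges:
        if edge.predicate in closure:
            if edge.subject in uf.parent and edge.object in uf.parent:
                uf.union(edge.subject, edge.object)

    groups: dict[str, list[str]] = {}
    for nid in ids:
        groups.setdefault(uf.find(nid), []).append(nid)
    blocks = [sorted(groups[root]) for root in sorted(groups)]
    return EquivalencePartition(blocks)


def choose_canonical(block: list[Concept], model: SemanticModel,
                     source_ranks: dict[str, int] | None = None) -> str:
    """Elect the canonical identifier of an equivalence block.

    The block's *dominant category* is the category of the member provided
    by the highest-precedence source (ties: lexicographically smallest
    member id).  Members are then ranked by their prefix's position in the
    model's priority list for that category — prefixes absent from the
    list rank after all listed ones — with lexicographic CURIE order as
    the tie-break.
    """
    if not block:
        raise KGWeaveError("cannot choose a canonical id for an empty block")
    dominant = _dominant_member(block, source_ranks)
    priority = model.prefix_priority.get(dominant.category, [])

    def sort_key(concept: Concept):
        prefix = parse_curie(concept.id).prefix
        try:
            pos = priority.index(prefix)
        except ValueError:
            pos = len(priority)
        return (pos, concept.id)

    return min(block, key=sort_key).id


def _dominant_member(block: list[Concept], source_ranks: dict[str, int] | None) -> Concept:
    source_ranks = source_ranks or {}
    fallback = len(source_ranks) + 1

    def key(concept: Concept):
        best = min((source_ranks.get(s, fallback) for s in concept.provided_by),
                   default=fallback)
        return (best, concept.id)

    return min(block, key=key)


def build_canonical_graph(pre: GraphDocument, partition: EquivalencePartition,
                          model: SemanticModel,
                          source_ranks: dict[str, int] | None = None,
                          equivalence_predicates=DEFAULT_EQUIVALENCE_PREDICATES,
                          ) -> tuple[GraphDocument, CanonicalizationLog]:
    """Steps 3–5: merge blocks into CanonicalConcepts, remap and merge edges."""
    pre_ids = pre.node_ids()
    covered = set(partition.block_of)
    if covered != pre_ids:
        missing = sorted(pre_ids - covered)[:5]
        extra = sorted(covered - pre_ids)[:5]
        raise ConsistencyError(
            f"partition does not cover the graph's node ids "
            f"(missing e.g. {missing}, extraneous e.g. {extra})")

    closure: set[str] = set()
    for pred in sorted(equivalence_predicates):
        closure |= model.expand_predicate(pred)

    by_id = {n.id: n for n in pre.nodes}
    log = CanonicalizationLog(block_count=len(partition.blocks),
                              max_block_size=max((len(b) for b in partition.blocks), default=0))

    canonical_of: dict[str, str] = {}
    nodes: list[CanonicalConcept] = []
    for block_ids in partition.blocks:
        members = [by_id[i] for i in block_ids]
        canon_id = choose_canonical(members, model, source_ranks)
        canon_member = by_id[canon_id]
        for i in block_ids:
            canonical_of[i] = canon_id
        name = canon_member.name or next((m.name for m in members if m.name), "")
        descriptions = [f"[{m.id}] {m.description}" for m in members if m.description]
        nodes.append(CanonicalConcept(
            id=canon_id,
            name=name,
            category=_dominant_member(members, source_ranks).category,
            iri=canon_member.iri,
            description=" ".join(descriptions),
            provided_by=ordered_union(*(m.provided_by for m in members)),
            publications=ordered_union(*(m.publications for m in members)),
            all_categories=sorted({m.category for m in members}),
            equivalent_identifiers=list(block_ids),
            all_names=sorted({m.name for m in members if m.name}),
        ))

    remapped: list[Assertion] = []
    for edge in pre.edges:
        subj = canonical_of[edge.subject]
        obj = canonical_of[edge.object]
        if edge.predicate in closure:
            if subj == obj:
                log.dropped_equivalence_self_loops += 1
                continue
            # an equivalence edge crossing blocks would contradict the partition
            raise ConsistencyError(
                f"equivalence edge ({edge.subject}, {edge.predicate}, {edge.object}) "
                f"crosses partition blocks")
        new = edge.copy()
        new.subject, new.object = subj, obj
        new = model.orient_assertion(new)   # symmetric normalization may re-order
        if new.subject == new.object:
            log.retained_self_loops.append(new.key)
        remapped.append(new)

    merged = coalesce_edges(remapped)
    log.coalesced_count = len(remapped) - len(merged)

    info = {
        "stage": "canonical",
        "model_version": model.version,
        "source_versions": pre.build_info.get("source_versions", {}),
        "pre_node_count": len(pre.nodes),
        "pre_edge_count": len(pre.edges),
    }
    return GraphDocument(list(nodes), merged, info), log


def canonicalize(pre: GraphDocument, model: SemanticModel,
                 source_ranks: dict[str, int] | None = None,
                 equivalence_predicates=DEFAULT_EQUIVALENCE_PREDICATES,
                 ) -> tuple[GraphDocument, EquivalencePartition, CanonicalizationLog]:
    """Convenience wrapper: partition then build the canonical graph."""
    partition = build_partition(pre, model, equivalence_predicates)
    graph, log = build_canonical_graph(pre, partition, model, source_ranks,
                                       equivalence_predicates)
    return graph, partition, log


def write_canonicalization_log(log: CanonicalizationLog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tdetail\n")
        fh.write(f"blocks\t{log.block_count}\n")
        fh.write(f"max_block_size\t{log.max_block_size}\n")
        fh.write(f"dropped_equivalence_self_loops\t{log.dropped_equivalence_self_loops}\n")
        fh.write(f"edges_coalesced\t{log.coalesced_count}\n")
        for s, o, p in log.retained_self_loops:
            fh.write(f"retained_self_loop\t{s} {p} {o}\n")
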