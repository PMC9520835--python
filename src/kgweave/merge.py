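"""Merge per-source GraphDocuments into the pre-canonicalized graph.

Nodes with identical CURIEs are unified across sources, with conflicts
resolved by source precedence (lower rank = loaded earlier = wins): the
category comes from the highest-precedence source, and name/description
from the highest-precedence source providing a non-empty value.  Edges are
then coalesced on (subject, object, predicate) with provenance preserved,
and edges whose endpoints are not declared by any source are removed and
logged for offline investigation (never silently materialized as nodes,
which would corrupt category statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError
from .graph_model import Assertion, GraphDocument, ordered_union

__all__ = ["MergeLog", "merge_graphs", "coalesce_edges", "screen_dangling"]


@dataclass
class MergeLog:
    """Bookkeeping for one merge: ``coalesced_count`` always equals
    input edges − output edges − dangling edges."""

    dangling_edges: list[tuple[Assertion, str]] = field(default_factory=list)
    category_conflicts: list[tuple[str, str, list[tuple[str, int]]]] = field(default_factory=list)
    coalesced_count: int = 0
    input_edge_count: int = 0
    output_edge_count: int = 0

    @property
    def dangling_count(self) -> int:
        return len(self.dangling_edges)


def coalesce_edges(edges: list[Assertion]) -> list[Assertion]:
    """One edge per (subject, object, predicate) key.

    Relations, provenance and publications of duplicates are unioned
    preserving first-seen order; key order follows first appearance.
    Assumes edges are already orientation-normalized.
    """
    merged: dict[tuple[str, str, str], Assertion] = {}
    for edge in edges:
        existing = merged.get(edge.key)
        if existing is None:
            merged[edge.key] = edge.copy()
        else:
            existing.relation = ordered_union(existing.relation, edge.relation)
            existing.provided_by = ordered_union(existing.provided_by, edge.provided_by)
            existing.publications = ordered_union(existing.publications, edge.publications)
    return list(merged.values())


def screen_dangling(graph: GraphDocument) -> tuple[GraphDocument, list[Assertion]]:
    """Drop edges whose subject or object has no node; return them."""
    ids = graph.node_ids()
    kept, removed = [], []
    for edge in graph.edges:
        if edge.subject in ids and edge.object in ids:
            kept.append(edge)
        else:
            removed.append(edge)
    return GraphDocument(graph.nodes, kept, dict(graph.build_info)), removed


def merge_graphs(parts: list[GraphDocument],
                 source_ranks: dict[str, int] | None = None,
                 build_info: dict | None = None) -> tuple[GraphDocument, MergeLog]:
    """Merge per-source documents (ordered by source rank) into one graph.

    ``source_ranks`` maps source-node ids to their configured ranks and is
    used only for conflict logging; precedence itself is positional —
    ``parts`` must already be in rank order, as produced by ingesting
    sources from a validated build configuration.
    """
    source_ranks = source_ranks or {}
    if len(set(source_ranks.values())) != len(source_ranks):
        raise ConfigError(f"duplicate source ranks: {sorted(source_ranks.values())}")

    log = MergeLog()
    merged_nodes: dict[str, object] = {}
    conflict_losers: dict[str, list[tuple[str, int]]] = {}

    for part_index, part in enumerate(parts):
        for node in part.nodes:
            existing = merged_nodes.get(node.id)
            if existing is None:
                merged_nodes[node.id] = node.copy()
                continue
            if node.category != existing.category:
                rank = min((source_ranks.get(s, part_index) for s in node.provided_by),
                           default=part_index)
                conflict_losers.setdefault(node.id, []).append((node.category, rank))
            if not existing.name and node.name:
                existing.name = node.name
            if not existing.description and node.description:
                existing.description = node.description
            existing.provided_by = ordered_union(existing.provided_by, node.provided_by)
            existing.publications = ordered_union(existing.publications, node.publications)

    for node_id, losers in sorted(conflict_losers.items()):
        log.category_conflicts.append((node_id, merged_nodes[node_id].category, losers))

    all_edges = [e for part in parts for e in part.edges]
    log.input_edge_count = len(all_edges)
    coalesced = coalesce_edges(all_edges)
    log.coalesced_count = len(all_edges) - len(coalesced)

    info = dict(build_info or {})
    info.setdefault("stage", "post_merge")
    info["source_versions"] = {
        part.build_info.get("source", f"part{i}"): part.build_info.get("source_version", "")
        for i, part in enumerate(parts)
    }
    graph = GraphDocument(list(merged_nodes.values()), coalesced, info)
    graph, removed = screen_dangling(graph)
    ids = graph.node_ids()
    log.dangling_edges = [
        (e, "missing " + " and ".join(x for x in (e.subject, e.object) if x not in ids))
        for e in removed
    ]
    log.output_edge_count = len(graph.edges)
    return graph, log


def write_merge_log(log: MergeLog, path) -> None:
    """TSV sidecar: one row per finding, plus summary counters."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tdetail\n")
        fh.write(f"input_edges\t{log.input_edge_count}\n")
        fh.write(f"output_edges\t{log.output_edge_count}\n")
        fh.write(f"coalesced\t{log.coalesced_count}\n")
        fh.write(f"dangling\t{log.dangling_count}\n")
        for edge, reason in log.dangling_edges:
            fh.write(f"dangling_edge\t{edge.subject} {edge.predicate} {edge.object}: {reason}\n")
        for node_id, winner, losers in log.category_conflicts:
            loser_txt = ", ".join(f"{c} (rank {r})" for c, r in losers)
            fh.write(f"category_conflict\t{node_id}: kept {winner}, dropped {loser_txt}\n")
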