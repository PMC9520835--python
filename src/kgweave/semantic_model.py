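"""The semantic layer: category and predicate hierarchies, relation
normalization, inverse-pair orientation, and identifier-prefix priorities.

The model is loaded from a single declarative YAML document (see
:func:`load_model`) and plays the role the Biolink model plays in production
biomedical knowledge graphs: it supplies

* a rooted tree of node categories (``biolink:PascalCase``) and a rooted
  tree of edge predicates (``biolink:snake_case``);
* inverse predicate pairs (e.g. ``has_part`` / ``part_of``) with exactly one
  member flagged canonical — only the canonical member appears in built
  graphs, with triples re-oriented accordingly;
* symmetric predicates, stored in a single normalized direction
  (lexicographically smaller CURIE as subject) so edge-coalescing keys are
  well defined;
* a per-source relation -> predicate map (the original phrasing is always
  preserved on the edge's ``relation`` field); and
* per-category ordered identifier-prefix priority lists used to elect
  canonical identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import (ConsistencyError, CycleError, MalformedCurieError, ModelError,
                     ModelLookupError)
from .graph_model import Assertion, GraphDocument, parse_curie

logger = logging.getLogger(__name__)

__all__ = ["SemanticModel", "ValidationReport", "load_model"]


@dataclass
class ValidationReport:
    """Outcome of validating a graph against the semantic model.

    ``violations`` holds (entity id, field, offending value, rule name)
    tuples; ``ok`` is true iff there are none.
    """

    violations: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class _Tree:
    """A rooted tree of names with closure queries."""

    def __init__(self, kind: str, children: dict[str, list[str]]):
        self.kind = kind
        self.children: dict[str, list[str]] = {}
        parent: dict[str, str] = {}
        for node, kids in children.items():
            self.children.setdefault(node, [])
            for kid in kids:
                if kid in parent:
                    raise ModelError(
                        f"{kind} {kid!r} has multiple parents ({parent[kid]!r}, {node!r})")
                parent[kid] = node
                self.children.setdefault(kid, [])
                self.children[node].append(kid)
        self.parent = parent
        self._check_cycles()
        roots = [n for n in self.children if n not in parent]
        if not roots:
            raise ModelError(f"missing root in {kind} hierarchy (every name has a parent)")
        if len(roots) > 1:
            raise ModelError(f"multiple roots in {kind} hierarchy: {sorted(roots)}")
        self.root = roots[0]
        self._closure: dict[str, frozenset[str]] = {}

    def _check_cycles(self) -> None:
        for start in self.children:
            seen = [start]
            node = start
            while node in self.parent:
                node = self.parent[node]
                if node in seen:
                    raise CycleError(self.kind, seen[seen.index(node):] + [node])
                seen.append(node)

    def __contains__(self, name: str) -> bool:
        return name in self.children

    def __len__(self) -> int:
        return len(self.children)

    def expand(self, name: str) -> set[str]:
        """Reflexive-transitive descendant closure of ``name``."""
        if name not in self.children:
            raise ModelLookupError(f"unknown {self.kind}: {name!r}")
        if name not in self._closure:
            out = {name}
            stack = list(self.children[name])
            while stack:
                n = stack.pop()
                out.add(n)
                stack.extend(self.children[n])
            self._closure[name] = frozenset(out)
        return set(self._closure[name])


@dataclass
class SemanticModel:
    """In-memory semantic layer; construct via :func:`load_model`."""

    categories: _Tree
    predicates: _Tree
    inverse_pairs: list[tuple[str, str]]          # (canonical, non-canonical)
    symmetric_predicates: set[str]
    relation_map: dict[tuple[str, str], str]      # (source, relation) -> predicate
    prefix_priority: dict[str, list[str]]         # category -> ordered prefixes
    version: str = ""

    def __post_init__(self) -> None:
        self._canonical_of = {nc: c for c, nc in self.inverse_pairs}

    # -- hierarchy closures -------------------------------------------------

    @property
    def root_category(self) -> str:
        return self.categories.root

    @property
    def root_predicate(self) -> str:
        return self.predicates.root

    def expand_category(self, category: str) -> set[str]:
        """``category`` plus all of its descendants."""
        return self.categories.expand(category)

    def expand_predicate(self, predicate: str) -> set[str]:
        """``predicate`` plus all of its descendants."""
        return self.predicates.expand(predicate)

    # -- relation normalization --------------------------------------------

    def map_relation(self, source: str, relation: str) -> tuple[str, str]:
        """Map a source relation string to a model predicate.

        Unmapped relations fall back to the predicate-tree root with a
        logged warning; the original phrasing is echoed back unchanged in
        either case so it can be preserved on the edge.
        """
        predicate = self.relation_map.get((source, relation))
        if predicate is None:
            logger.warning("unmapped relation (%s, %s): falling back to %s",
                           source, relation, self.root_predicate)
            predicate = self.root_predicate
        return predicate, relation

    # -- orientation --------------------------------------------------------

    def orient_assertion(self, edge: Assertion) -> Assertion:
        """Normalize edge direction; idempotent.

        Non-canonical inverse members are replaced by the canonical member
        with subject/object swapped; symmetric predicates are stored with
        the lexicographically smaller endpoint as subject.
        """
        if edge.predicate not in self.predicates:
            raise ModelLookupError(f"unknown predicate: {edge.predicate!r}")
        out = edge
        if edge.predicate in self._canonical_of:
            out = edge.copy()
            out.subject, out.object = edge.object, edge.subject
            out.predicate = self._canonical_of[edge.predicate]
        if out.predicate in self.symmetric_predicates and out.subject > out.object:
            flipped = out.copy()
            flipped.subject, flipped.object = out.object, out.subject
            out = flipped
        return out

    # -- validation ---------------------------------------------------------

    def validate_graph(self, graph: GraphDocument) -> ValidationReport:
        """Check a graph's semantic-layer consistency.

        One violation per node with an unknown category, per edge with an
        unknown predicate, per edge carrying a non-canonical inverse
        member, and per malformed CURIE (node ids and edge endpoints).
        """
        report = ValidationReport()
        for node in graph.nodes:
            try:
                parse_curie(node.id)
            except MalformedCurieError:
                report.violations.append((node.id, "id", node.id, "malformed_curie"))
            if node.category not in self.categories:
                report.violations.append(
                    (node.id, "category", node.category, "unknown_category"))
        for edge in graph.edges:
            eid = f"({edge.subject}, {edge.predicate}, {edge.object})"
            for fieldname, value in (("subject", edge.subject), ("object", edge.object)):
                try:
                    parse_curie(value)
                except MalformedCurieError:
                    report.violations.append((eid, fieldname, value, "malformed_curie"))
            if edge.predicate not in self.predicates:
                report.violations.append(
                    (eid, "predicate", edge.predicate, "unknown_predicate"))
            elif edge.predicate in self._canonical_of:
                report.violations.append(
                    (eid, "predicate", edge.predicate, "non_canonical_inverse"))
        return report


# ---------------------------------------------------------------------------
# loading


def _as_children_map(section, name: str) -> dict[str, list[str]]:
    if section is None:
        raise ModelError(f"missing section {name!r}")
    if not isinstance(section, dict):
        raise ModelError(f"section {name!r} must map parent -> list of children")
    out = {}
    for parent, kids in section.items():
        if kids is None:
            kids = []
        if not isinstance(kids, list):
            raise ModelError(f"children of {parent!r} in {name!r} must be a list")
        out[str(parent)] = [str(k) for k in kids]
    return out


def load_model(path: str | Path) -> SemanticModel:
    """Load the semantic-model YAML document.

    Sections: ``categories`` and ``predicates`` (parent -> children maps),
    ``inverse_pairs`` (list of ``{pair: [a, b], canonical: a}``),
    ``symmetric`` (list), ``relation_map`` (list of ``{source, relation,
    predicate}``), ``prefix_priority`` (category -> ordered prefix list),
    ``version``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ModelError("model file must be a mapping")

    categories = _Tree("category", _as_children_map(doc.get("categories"), "categories"))
    predicates = _Tree("predicate", _as_children_map(doc.get("predicates"), "predicates"))

    inverse_pairs: list[tuple[str, str]] = []
    for entry in doc.get("inverse_pairs") or []:
        pair = entry.get("pair") if isinstance(entry, dict) else None
        canonical = entry.get("canonical") if isinstance(entry, dict) else None
        if not isinstance(pair, list) or len(pair) != 2:
            raise ConsistencyError(f"inverse pair entry must have a 2-element 'pair': {entry!r}")
        a, b = str(pair[0]), str(pair[1])
        if a == b:
            raise ConsistencyError(f"inverse pair members must differ: {entry!r}")
        if canonical not in (a, b):
            raise ConsistencyError(
                f"inverse pair {{{a}, {b}}} must flag exactly one canonical member "
                f"from the pair (got {canonical!r})")
        for p in (a, b):
            if p not in predicates:
                raise ConsistencyError(f"inverse-pair predicate not in hierarchy: {p!r}")
        noncanonical = b if canonical == a else a
        inverse_pairs.append((str(canonical), noncanonical))
    flagged = [p for pair in inverse_pairs for p in pair]
    if len(set(flagged)) != len(flagged):
        raise ConsistencyError("a predicate appears in more than one inverse pair")

    symmetric = {str(p) for p in (doc.get("symmetric") or [])}
    for p in symmetric:
        if p not in predicates:
            raise ConsistencyError(f"symmetric predicate not in hierarchy: {p!r}")
        if p in flagged:
            raise ConsistencyError(f"symmetric predicate in an inverse pair: {p!r}")

    relation_map: dict[tuple[str, str], str] = {}
    for entry in doc.get("relation_map") or []:
        if not isinstance(entry, dict) or not {"source", "relation", "predicate"} <= set(entry):
            raise ModelError(f"relation_map entry needs source/relation/predicate: {entry!r}")
        predicate = str(entry["predicate"])
        if predicate not in predicates:
            raise ConsistencyError(f"relation_map predicate not in hierarchy: {predicate!r}")
        relation_map[(str(entry["source"]), str(entry["relation"]))] = predicate

    prefix_priority: dict[str, list[str]] = {}
    for category, prefixes in (doc.get("prefix_priority") or {}).items():
        if str(category) not in categories:
            raise ConsistencyError(f"prefix_priority category not in hierarchy: {category!r}")
        if not isinstance(prefixes, list):
            raise ModelError(f"prefix_priority for {category!r} must be a list")
        prefix_priority[str(category)] = [str(p) for p in prefixes]

    return SemanticModel(categories, predicates, inverse_pairs, symmetric,
                         relation_map, prefix_priority,
                         version=str(doc.get("version", "")))
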