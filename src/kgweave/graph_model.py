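"""Core graph data types and serializations.

A knowledge graph is held in memory as a :class:`GraphDocument` — a list of
:class:`Concept` nodes and :class:`Assertion` edges plus build metadata —
mirroring the JSON serialization (top-level keys ``nodes`` and ``edges``).
Two on-disk forms are supported:

* a JSON document (schema shipped in ``kgweave/schemas/graph_document.schema.json``);
* a two-file KGX-style TSV pair (``nodes.tsv`` + ``edges.tsv``) with
  ``|``-joined multivalued cells and a no-quoting dialect.

Both writers are deterministic: nodes are ordered by id, edges by
(subject, object, predicate), so identical graphs produce byte-identical
files.  Concept identifiers are CURIEs (``PREFIX:LOCAL_ID``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import MalformedCurieError, SchemaError, SerializationError

__all__ = [
    "Curie",
    "parse_curie",
    "Concept",
    "CanonicalConcept",
    "Assertion",
    "GraphDocument",
    "read_json",
    "write_json",
    "read_kgx_tsv",
    "write_kgx_tsv",
    "expand_iri",
    "ordered_union",
]

NODE_COLUMNS = ("id", "name", "category", "iri", "description", "provided_by", "publications")
EDGE_COLUMNS = ("subject", "predicate", "object", "relation", "provided_by", "publications")

#: characters that the no-quoting TSV dialect cannot represent
_FORBIDDEN = ("\t", "\n", "\r", "|")

#: fallback IRI template for prefixes absent from the configured expansion table
_FALLBACK_IRI = "http://identifiers.org/{prefix}/{local_id}"


@dataclass(frozen=True)
class Curie:
    """A compact URI: ``prefix:local_id``."""

    prefix: str
    local_id: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"


def parse_curie(text: str) -> Curie:
    """Split ``text`` on its first ``:`` into a :class:`Curie`.

    Raises :class:`MalformedCurieError` if there is no separator or either
    part is empty (e.g. the bare token ``CHEMBL112``, which must be repaired
    to a prefixed CURIE by the ingesting ETL before it enters the graph).
    """
    if not isinstance(text, str) or ":" not in text:
        raise MalformedCurieError(str(text), "no namespace separator")
    prefix, local_id = text.split(":", 1)
    if not prefix:
        raise MalformedCurieError(text, "empty prefix")
    if not local_id:
        raise MalformedCurieError(text, "empty local id")
    return Curie(prefix, local_id)


def expand_iri(curie: str, iri_bases: dict[str, str] | None = None) -> str:
    """Expand a CURIE to an IRI using a prefix -> IRI-base table.

    Prefixes absent from the table fall back to an identifiers.org-style
    template so that every node carries a syntactically valid IRI.
    """
    c = parse_curie(curie)
    if iri_bases and c.prefix in iri_bases:
        return iri_bases[c.prefix] + c.local_id
    return _FALLBACK_IRI.format(prefix=c.prefix.lower(), local_id=c.local_id)


def ordered_union(*sequences: Iterable[str]) -> list[str]:
    """Union of string sequences preserving first-seen order."""
    seen: dict[str, None] = {}
    for seq in sequences:
        for item in seq:
            seen.setdefault(item, None)
    return list(seen)


@dataclass
class Concept:
    """A graph node: one identified concept as asserted by >= 1 sources.

    ``provided_by`` lists the source-node CURIEs of the knowledge sources
    asserting the concept (first-seen order = source precedence order);
    ``publications`` lists supporting literature CURIEs.
    """

    id: str
    name: str = ""
    category: str = "biolink:NamedThing"
    iri: str = ""
    description: str = ""
    provided_by: list[str] = field(default_factory=list)
    publications: list[str] = field(default_factory=list)

    def copy(self) -> "Concept":
        return Concept(self.id, self.name, self.category, self.iri, self.description,
                       list(self.provided_by), list(self.publications))


@dataclass
class CanonicalConcept(Concept):
    """A node of the canonicalized graph: a whole equivalence block merged
    under an elected canonical identifier.

    ``equivalent_identifiers`` holds every pre-graph identifier of the block
    (including ``id`` itself); ``all_categories`` / ``all_names`` hold the
    union of member categories / non-empty names.
    """

    all_categories: list[str] = field(default_factory=list)
    equivalent_identifiers: list[str] = field(default_factory=list)
    all_names: list[str] = field(default_factory=list)

    def copy(self) -> "CanonicalConcept":
        return CanonicalConcept(self.id, self.name, self.category, self.iri,
                                self.description, list(self.provided_by),
                                list(self.publications), list(self.all_categories),
                                list(self.equivalent_identifiers), list(self.all_names))


@dataclass
class Assertion:
    """A directed edge (subject, predicate, object) with provenance.

    ``predicate`` is the normalized relationship type from the semantic
    model; ``relation`` preserves the original source phrasing(s).  After
    edge coalescing, (subject, object, predicate) is unique per graph and
    ``relation``/``provided_by``/``publications`` are first-seen-ordered
    unions over the coalesced duplicates.
    """

    subject: str
    object: str
    predicate: str
    relation: list[str] = field(default_factory=list)
    provided_by: list[str] = field(default_factory=list)
    publications: list[str] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.object, self.predicate)

    def copy(self) -> "Assertion":
        return Assertion(self.subject, self.object, self.predicate,
                         list(self.relation), list(self.provided_by), list(self.publications))


@dataclass
class GraphDocument:
    """A nodes+edges container with build metadata."""

    nodes: list[Concept] = field(default_factory=list)
    edges: list[Assertion] = field(default_factory=list)
    build_info: dict = field(default_factory=dict)

    def node_ids(self) -> set[str]:
        return {n.id for n in self.nodes}

    def sorted_copy(self) -> "GraphDocument":
        """Canonical ordering: nodes by id; edges by (subject, object,
        predicate) with full-record tie-breaks so multigraphs sort stably."""
        nodes = sorted((n.copy() for n in self.nodes), key=lambda n: n.id)
        edges = sorted(
            (e.copy() for e in self.edges),
            key=lambda e: (e.subject, e.object, e.predicate,
                           "|".join(e.relation), "|".join(e.provided_by)),
        )
        return GraphDocument(nodes, edges, dict(self.build_info))


# ---------------------------------------------------------------------------
# JSON serialization


def _node_to_dict(n: Concept) -> dict:
    d = {
        "id": n.id,
        "name": n.name,
        "category": n.category,
        "iri": n.iri,
        "description": n.description,
        "provided_by": list(n.provided_by),
        "publications": list(n.publications),
    }
    if isinstance(n, CanonicalConcept):
        d["all_categories"] = list(n.all_categories)
        d["equivalent_identifiers"] = list(n.equivalent_identifiers)
        d["all_names"] = list(n.all_names)
    return d


def _edge_to_dict(e: Assertion) -> dict:
    return {
        "subject": e.subject,
        "predicate": e.predicate,
        "object": e.object,
        "relation": list(e.relation),
        "provided_by": list(e.provided_by),
        "publications": list(e.publications),
    }


_NODE_REQUIRED = {"id": str, "name": str, "category": str, "iri": str,
                  "description": str, "provided_by": list, "publications": list}
_EDGE_REQUIRED = {"subject": str, "predicate": str, "object": str,
                  "relation": list, "provided_by": list, "publications": list}
_CANONICAL_EXTRA = {"all_categories": list, "equivalent_identifiers": list, "all_names": list}


def _check_fields(obj: dict, required: dict, path: str, optional: dict | None = None) -> None:
    if not isinstance(obj, dict):
        raise SchemaError("expected an object", path)
    allowed = dict(required)
    allowed.update(optional or {})
    for key, typ in required.items():
        if key not in obj:
            raise SchemaError(f"missing required field {key!r}", path)
    for key, value in obj.items():
        if key not in allowed:
            raise SchemaError(f"unknown field {key!r}", f"{path}.{key}")
        if not isinstance(value, allowed[key]):
            raise SchemaError(f"field {key!r} must be {allowed[key].__name__}", f"{path}.{key}")


def _validate_document(doc: dict) -> None:
    """Structural validation against the shipped GraphDocument schema."""
    if not isinstance(doc, dict):
        raise SchemaError("top level must be an object")
    for key in doc:
        if key not in ("nodes", "edges", "build_info"):
            raise SchemaError(f"unknown top-level key {key!r}", f"$.{key}")
    for key in ("nodes", "edges"):
        if key not in doc:
            raise SchemaError(f"missing top-level key {key!r}")
        if not isinstance(doc[key], list):
            raise SchemaError(f"{key!r} must be a list", f"$.{key}")
    if "build_info" in doc and not isinstance(doc["build_info"], dict):
        raise SchemaError("'build_info' must be an object", "$.build_info")
    for i, n in enumerate(doc["nodes"]):
        _check_fields(n, _NODE_REQUIRED, f"$.nodes[{i}]", optional=_CANONICAL_EXTRA)
    for i, e in enumerate(doc["edges"]):
        _check_fields(e, _EDGE_REQUIRED, f"$.edges[{i}]")


def write_json(graph: GraphDocument, path: str | Path) -> None:
    """Serialize ``graph`` as a JSON object with keys ``build_info``,
    ``nodes`` and ``edges``; deterministic given graph + build_info."""
    g = graph.sorted_copy()
    doc = {
        "build_info": g.build_info,
        "nodes": [_node_to_dict(n) for n in g.nodes],
        "edges": [_edge_to_dict(e) for e in g.edges],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False, sort_keys=False)
        fh.write("\n")


def read_json(path: str | Path) -> GraphDocument:
    """Load and validate a GraphDocument JSON file."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    _validate_document(doc)
    nodes: list[Concept] = []
    for d in doc["nodes"]:
        if "equivalent_identifiers" in d:
            nodes.append(CanonicalConcept(
                d["id"], d["name"], d["category"], d["iri"], d["description"],
                list(d["provided_by"]), list(d["publications"]),
                list(d.get("all_categories", [])),
                list(d["equivalent_identifiers"]),
                list(d.get("all_names", []))))
        else:
            nodes.append(Concept(d["id"], d["name"], d["category"], d["iri"],
                                 d["description"], list(d["provided_by"]),
                                 list(d["publications"])))
    edges = [Assertion(d["subject"], d["object"], d["predicate"], list(d["relation"]),
                       list(d["provided_by"]), list(d["publications"]))
             for d in doc["edges"]]
    return GraphDocument(nodes, edges, dict(doc.get("build_info", {})))


# ---------------------------------------------------------------------------
# KGX-style TSV serialization


def _cell(value: str | Sequence[str], owner: str, fieldname: str) -> str:
    if isinstance(value, str):
        parts = [value]
        text = value
    else:
        parts = list(value)
        text = "|".join(parts)
    for part in parts:
        for ch in _FORBIDDEN:
            if ch in part:
                raise SerializationError(
                    f"forbidden character {ch!r} in field {fieldname!r} of {owner}")
    return text


def write_kgx_tsv(graph: GraphDocument, directory: str | Path) -> tuple[Path, Path]:
    """Write ``nodes.tsv`` and ``edges.tsv`` under ``directory``.

    No quoting: values containing tab, newline, carriage return or ``|``
    are rejected with a :class:`SerializationError` naming the record and
    field.  Multivalued fields are ``|``-joined.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = graph.sorted_copy()
    nodes_path = directory / "nodes.tsv"
    edges_path = directory / "edges.tsv"
    with open(nodes_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(NODE_COLUMNS) + "\n")
        for n in g.nodes:
            owner = f"node {n.id}"
            row = [
                _cell(n.id, owner, "id"),
                _cell(n.name, owner, "name"),
                _cell(n.category, owner, "category"),
                _cell(n.iri, owner, "iri"),
                _cell(n.description, owner, "description"),
                _cell(n.provided_by, owner, "provided_by"),
                _cell(n.publications, owner, "publications"),
            ]
            fh.write("\t".join(row) + "\n")
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in g.edges:
            owner = f"edge ({e.subject}, {e.predicate}, {e.object})"
            row = [
                _cell(e.subject, owner, "subject"),
                _cell(e.predicate, owner, "predicate"),
                _cell(e.object, owner, "object"),
                _cell(e.relation, owner, "relation"),
                _cell(e.provided_by, owner, "provided_by"),
                _cell(e.publications, owner, "publications"),
            ]
            fh.write("\t".join(row) + "\n")
    return nodes_path, edges_path


def _split(cell: str) -> list[str]:
    return cell.split("|") if cell else []


def read_kgx_tsv(directory: str | Path) -> GraphDocument:
    """Read a ``nodes.tsv`` + ``edges.tsv`` pair written by
    :func:`write_kgx_tsv`."""
    directory = Path(directory)
    nodes: list[Concept] = []
    edges: list[Assertion] = []
    with open(directory / "nodes.tsv", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != NODE_COLUMNS:
            raise SchemaError(f"unexpected nodes.tsv header: {header}", "nodes.tsv:1")
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(NODE_COLUMNS):
                raise SchemaError(f"wrong column count ({len(cells)})", f"nodes.tsv:{lineno}")
            nodes.append(Concept(cells[0], cells[1], cells[2], cells[3], cells[4],
                                 _split(cells[5]), _split(cells[6])))
    with open(directory / "edges.tsv", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGE_COLUMNS:
            raise SchemaError(f"unexpected edges.tsv header: {header}", "edges.tsv:1")
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(EDGE_COLUMNS):
                raise SchemaError(f"wrong column count ({len(cells)})", f"edges.tsv:{lineno}")
            edges.append(Assertion(cells[0], cells[2], cells[1], _split(cells[3]),
                                   _split(cells[4]), _split(cells[5])))
    return GraphDocument(nodes, edges, {})
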