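"""Per-format ETL: turn raw knowledge-source files into GraphDocuments.

Three ingestion families are supported, mirroring how production biomedical
knowledge graphs consume their sources:

* **ontology sources** (``ontology_ttl`` / ``ontology_rdfxml``): a constrained
  ontology subset read with rdflib — class declarations, ``rdfs:label``,
  ``rdfs:comment``, ``rdfs:subClassOf`` (hierarchies are preserved, not
  flattened) and ``oboInOwl:hasDbXref`` cross-references, which become
  equivalence edges (default ``biolink:same_as``) feeding canonicalization;
* **triple TSV sources** (``triple_tsv``): header-carrying TSV with columns
  ``subject  relation  object  [publications]`` (SemMedDB-like NLP triples);
* **record sources** (``record_json`` / ``record_xml``): one record per
  entity with typed links to other identifiers (DrugBank-like).

Every emitted node and edge carries the source's retrieval node in
``provided_by``; relations are normalized through the semantic model with
the original phrasing preserved; all edges are orientation-normalized.
Row- and record-level problems are logged and skipped, never fatal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from lxml import etree
from rdflib import Graph as RDFGraph
from rdflib import Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import ConfigError, IngestError, MalformedCurieError, UnmappedPrefixError
from .graph_model import (Assertion, Concept, GraphDocument, expand_iri,
                          ordered_union, parse_curie)
from .semantic_model import SemanticModel

logger = logging.getLogger(__name__)

__all__ = [
    "SourceConfig",
    "BuildConfig",
    "load_build_config",
    "build_source_node",
    "ingest_ontology",
    "ingest_tsv_triples",
    "ingest_records",
    "ingest_source",
]

SUBCLASS_PREDICATE = "biolink:subclass_of"
DEFAULT_XREF_PREDICATE = "biolink:same_as"
SOURCE_NODE_CATEGORY = "biolink:InformationContentEntity"
SOURCE_NODE_PREFIX = "KGSOURCE"

_HAS_DBXREF = URIRef("http://www.geneontology.org/formats/oboInOwl#hasDbXref")

FORMATS = ("ontology_ttl", "ontology_rdfxml", "triple_tsv", "record_xml", "record_json")


@dataclass
class SourceConfig:
    """One knowledge source in the build configuration.

    ``rank`` is the load-order precedence (lower = earlier = higher
    precedence for category/name conflicts at merge time).
    ``prefix_rules`` repairs bare identifiers lacking a namespace: the
    longest matching leading-alphabetic key maps the token to a CURIE
    prefix (e.g. ``CHEMBL -> CHEMBL.COMPOUND`` turns ``CHEMBL112`` into
    ``CHEMBL.COMPOUND:CHEMBL112``).  ``prefix_map`` compresses ontology
    IRIs to CURIEs (CURIE prefix -> IRI base).
    """

    name: str
    version: str
    path: str
    format: str
    rank: int
    prefix_rules: dict[str, str] = field(default_factory=dict)
    prefix_map: dict[str, str] = field(default_factory=dict)
    category_rules: dict = field(default_factory=dict)   # {default, by_prefix}
    category_hints: dict[str, str] = field(default_factory=dict)
    xref_predicate: str = DEFAULT_XREF_PREDICATE
    relation_source: str = ""                             # defaults to name

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise ConfigError(f"unknown source format {self.format!r} for {self.name!r}")
        if not self.relation_source:
            self.relation_source = self.name

    @property
    def source_node_id(self) -> str:
        return f"{SOURCE_NODE_PREFIX}:{self.name}"


@dataclass
class BuildConfig:
    """The build configuration: sources in rank order plus shared tables."""

    sources: list[SourceConfig]
    model_path: str = ""
    iri_bases: dict[str, str] = field(default_factory=dict)
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        ranks = [s.rank for s in self.sources]
        names = [s.name for s in self.sources]
        if len(set(ranks)) != len(ranks):
            raise ConfigError(f"duplicate source ranks: {sorted(ranks)}")
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate source names: {sorted(names)}")
        self.sources = sorted(self.sources, key=lambda s: s.rank)

    def source_path(self, src: SourceConfig) -> Path:
        p = Path(src.path)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def ranks_by_source_node(self) -> dict[str, int]:
        return {s.source_node_id: s.rank for s in self.sources}


def load_build_config(path: str | Path) -> BuildConfig:
    """Load a YAML build configuration listing sources in rank order."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "sources" not in doc:
        raise ConfigError("build config must be a mapping with a 'sources' list")
    sources = []
    for entry in doc["sources"]:
        if not isinstance(entry, dict):
            raise ConfigError(f"source entry must be a mapping: {entry!r}")
        try:
            sources.append(SourceConfig(
                name=str(entry["name"]),
                version=str(entry.get("version", "")),
                path=str(entry["path"]),
                format=str(entry["format"]),
                rank=int(entry["rank"]),
                prefix_rules=dict(entry.get("prefix_rules") or {}),
                prefix_map=dict(entry.get("prefix_map") or {}),
                category_rules=dict(entry.get("category_rules") or {}),
                category_hints=dict(entry.get("category_hints") or {}),
                xref_predicate=str(entry.get("xref_predicate", DEFAULT_XREF_PREDICATE)),
                relation_source=str(entry.get("relation_source", "")),
            ))
        except KeyError as exc:
            raise ConfigError(f"source entry missing required key {exc}") from exc
    return BuildConfig(
        sources=sources,
        model_path=str(doc.get("model", "")),
        iri_bases=dict(doc.get("iri_bases") or {}),
        base_dir=path.parent,
    )


def build_source_node(src: SourceConfig, category: str = SOURCE_NODE_CATEGORY) -> Concept:
    """The retrieval-source node: a stable per-source CURIE whose name
    embeds the source version (``"<name> v<version>"``)."""
    node_id = src.source_node_id
    return Concept(
        id=node_id,
        name=f"{src.name} v{src.version}",
        category=category,
        iri=expand_iri(node_id),
        description=f"retrieval source: {src.name}, version {src.version}",
        provided_by=[node_id],
    )


def _repair_id(token: str, prefix_rules: dict[str, str]) -> str | None:
    """Return a CURIE for ``token``, repairing bare identifiers.

    Bare tokens (no ``:``) are matched against ``prefix_rules`` by their
    longest leading-alphabetic key; no match -> ``None`` (caller logs and
    skips).
    """
    if ":" in token:
        try:
            parse_curie(token)
            return token
        except MalformedCurieError:
            return None
    for key in sorted(prefix_rules, key=len, reverse=True):
        if token.startswith(key):
            return f"{prefix_rules[key]}:{token}"
    return None


def _assign_category(curie: str, rules: dict, model: SemanticModel) -> str:
    by_prefix = rules.get("by_prefix") or {}
    prefix = curie.split(":", 1)[0]
    category = by_prefix.get(prefix) or rules.get("default") or model.root_category
    return category


def _compress_iri(iri: str, prefix_map: dict[str, str]) -> str:
    best_prefix, best_base = None, ""
    for prefix, base in prefix_map.items():
        if iri.startswith(base) and len(base) > len(best_base):
            best_prefix, best_base = prefix, base
    if best_prefix is None:
        raise UnmappedPrefixError(iri)
    local = iri[len(best_base):]
    if not local:
        raise UnmappedPrefixError(iri)
    return f"{best_prefix}:{local}"


def _finish(src: SourceConfig, model: SemanticModel, nodes: list[Concept],
            edges: list[Assertion], counters: dict) -> GraphDocument:
    """Append the source node, orient all edges, stamp build_info."""
    nodes = nodes + [build_source_node(src)]
    edges = [model.orient_assertion(e) for e in edges]
    return GraphDocument(nodes, edges, {
        "stage": "ingest",
        "source": src.name,
        "source_version": src.version,
        "model_version": model.version,
        **counters,
    })


# ---------------------------------------------------------------------------
# ontology sources


def ingest_ontology(src: SourceConfig, model: SemanticModel,
                    iri_bases: dict[str, str] | None = None) -> GraphDocument:
    """Ingest a TTL or RDF/XML ontology under the constrained subset.

    One Concept per declared class (id = CURIE-compressed IRI); one
    ``biolink:subclass_of`` edge per ``rdfs:subClassOf`` axiom between
    named classes; one equivalence edge (``xref_predicate``) per
    ``oboInOwl:hasDbXref`` annotation.  Axioms outside the subset are
    ignored with a summary count in ``build_info``.
    """
    rdf_format = "turtle" if src.format == "ontology_ttl" else "xml"
    graph = RDFGraph()
    try:
        graph.parse(src.path, format=rdf_format)
    except Exception as exc:  # rdflib raises format-specific parse errors
        raise IngestError(f"cannot parse {src.path} as {rdf_format}: {exc}") from exc

    src_id = src.source_node_id
    classes = sorted(s for s in graph.subjects(RDF.type, OWL.Class)
                     if isinstance(s, URIRef))
    curie_of: dict[URIRef, str] = {c: _compress_iri(str(c), src.prefix_map) for c in classes}

    nodes: list[Concept] = []
    for cls in classes:
        curie = curie_of[cls]
        label = graph.value(cls, RDFS.label)
        comment = graph.value(cls, RDFS.comment)
        nodes.append(Concept(
            id=curie,
            name=str(label) if label else "",
            category=_assign_category(curie, src.category_rules, model),
            iri=expand_iri(curie, iri_bases),
            description=str(comment) if comment else "",
            provided_by=[src_id],
        ))

    edges: list[Assertion] = []
    ignored = 0
    skipped_xrefs = 0
    for s, o in graph.subject_objects(RDFS.subClassOf):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            subj = curie_of.get(s) or _compress_iri(str(s), src.prefix_map)
            obj = curie_of.get(o) or _compress_iri(str(o), src.prefix_map)
            edges.append(Assertion(subj, obj, SUBCLASS_PREDICATE,
                                   relation=["rdfs:subClassOf"], provided_by=[src_id]))
        else:
            ignored += 1
    for s, o in graph.subject_objects(_HAS_DBXREF):
        if not (isinstance(s, URIRef) and s in curie_of and isinstance(o, Literal)):
            ignored += 1
            continue
        try:
            parse_curie(str(o))
        except MalformedCurieError:
            logger.warning("%s: skipping non-CURIE xref %r on %s", src.name, str(o), curie_of[s])
            skipped_xrefs += 1
            continue
        edges.append(Assertion(curie_of[s], str(o), src.xref_predicate,
                               relation=["oboInOwl:hasDbXref"], provided_by=[src_id]))
    known = {RDF.type, RDFS.label, RDFS.comment, RDFS.subClassOf, _HAS_DBXREF}
    ignored += sum(1 for _, p, _ in graph if p not in known)

    edges.sort(key=lambda e: (e.subject, e.object, e.predicate))
    return _finish(src, model, nodes, edges,
                   {"ignored_axioms": ignored, "skipped_xrefs": skipped_xrefs})


# ---------------------------------------------------------------------------
# triple TSV sources


def ingest_tsv_triples(src: SourceConfig, model: SemanticModel,
                       iri_bases: dict[str, str] | None = None) -> GraphDocument:
    """Ingest a header-carrying TSV of (subject, relation, object
    [, publications]) triples.

    Nodes are materialized for every mentioned identifier (bare IDs
    repaired through ``prefix_rules``); malformed rows and irreparable
    identifiers are logged and skipped with counts in ``build_info``.
    """
    src_id = src.source_node_id
    nodes: dict[str, Concept] = {}
    edges: list[Assertion] = []
    skipped_rows = 0

    with open(src.path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["subject", "relation", "object"]:
            raise IngestError(
                f"{src.path}: expected header subject/relation/object[/publications], "
                f"got {header}")
        has_pubs = len(header) > 3 and header[3] == "publications"
        want = 4 if has_pubs else 3
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != want:
                logger.warning("%s:%d: wrong column count (%d), row skipped",
                               src.path, lineno, len(cells))
                skipped_rows += 1
                continue
            subj = _repair_id(cells[0], src.prefix_rules)
            obj = _repair_id(cells[2], src.prefix_rules)
            if subj is None or obj is None:
                bad = cells[0] if subj is None else cells[2]
                logger.warning("%s:%d: irreparable identifier %r, row skipped",
                               src.path, lineno, bad)
                skipped_rows += 1
                continue
            predicate, relation = model.map_relation(src.relation_source, cells[1])
            pubs = []
            if has_pubs and cells[3]:
                pubs = cells[3].split("|")
            for curie in (subj, obj):
                if curie not in nodes:
                    nodes[curie] = Concept(
                        id=curie,
                        category=_assign_category(curie, src.category_rules, model),
                        iri=expand_iri(curie, iri_bases),
                        provided_by=[src_id],
                    )
            edges.append(Assertion(subj, obj, predicate, relation=[relation],
                                   provided_by=[src_id], publications=pubs))

    return _finish(src, model, list(nodes.values()), edges, {"skipped_rows": skipped_rows})


# ---------------------------------------------------------------------------
# record sources


def _records_from_json(path: str) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and "records" in doc:
        doc = doc["records"]
    if not isinstance(doc, list):
        raise IngestError(f"{path}: expected a list of records")
    return doc


def _records_from_xml(path: str) -> list[dict]:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise IngestError(f"cannot parse {path} as XML: {exc}") from exc
    records = []
    for rec in tree.getroot().iter("record"):
        entry: dict = {k: rec.get(k) for k in ("id", "name", "category") if rec.get(k)}
        entry["links"] = [
            {"relation": link.get("relation"), "target": link.get("target"),
             "publications": (link.get("publications") or "").split("|")
                              if link.get("publications") else []}
            for link in rec.iter("link")
        ]
        desc = rec.findtext("description")
        if desc:
            entry["description"] = desc
        records.append(entry)
    return records


def ingest_records(src: SourceConfig, model: SemanticModel,
                   iri_bases: dict[str, str] | None = None) -> GraphDocument:
    """Ingest a record-oriented JSON or XML source.

    One Concept per record; one relation-mapped, oriented Assertion per
    typed link.  Link targets are *not* materialized as nodes — an edge to
    an identifier no source declares is screened as dangling at merge.
    Unknown category hints fall back to the root category with a warning;
    duplicate record ids are merged (provenance union) and logged.
    """
    records = (_records_from_json(src.path) if src.format == "record_json"
               else _records_from_xml(src.path))
    src_id = src.source_node_id
    nodes: dict[str, Concept] = {}
    edges: list[Assertion] = []
    skipped_records = 0
    duplicate_records = 0

    for i, rec in enumerate(records):
        rec_id_raw = rec.get("id")
        if not rec_id_raw:
            logger.warning("%s: record %d has no id, skipped", src.name, i)
            skipped_records += 1
            continue
        rec_id = _repair_id(str(rec_id_raw), src.prefix_rules)
        if rec_id is None:
            logger.warning("%s: record %d has irreparable id %r, skipped",
                           src.name, i, rec_id_raw)
            skipped_records += 1
            continue
        hint = str(rec.get("category", ""))
        category = src.category_hints.get(hint)
        if category is None:
            logger.warning("%s: unknown category hint %r on %s, using %s",
                           src.name, hint, rec_id, model.root_category)
            category = model.root_category
        if rec_id in nodes:
            duplicate_records += 1
            logger.warning("%s: duplicate record id %s merged", src.name, rec_id)
            existing = nodes[rec_id]
            if not existing.name and rec.get("name"):
                existing.name = str(rec["name"])
            existing.provided_by = ordered_union(existing.provided_by, [src_id])
        else:
            nodes[rec_id] = Concept(
                id=rec_id,
                name=str(rec.get("name", "")),
                category=category,
                iri=expand_iri(rec_id, iri_bases),
                description=str(rec.get("description", "")),
                provided_by=[src_id],
            )
        for link in rec.get("links", []):
            target = _repair_id(str(link.get("target", "")), src.prefix_rules)
            if target is None:
                logger.warning("%s: irreparable link target %r on %s, link skipped",
                               src.name, link.get("target"), rec_id)
                skipped_records += 1
                continue
            predicate, relation = model.map_relation(
                src.relation_source, str(link.get("relation", "")))
            edges.append(Assertion(rec_id, target, predicate, relation=[relation],
                                   provided_by=[src_id],
                                   publications=list(link.get("publications", []))))

    return _finish(src, model, list(nodes.values()), edges,
                   {"skipped_records": skipped_records,
                    "duplicate_records": duplicate_records})


def ingest_source(src: SourceConfig, model: SemanticModel,
                  iri_bases: dict[str, str] | None = None) -> GraphDocument:
    """Dispatch on ``src.format``."""
    if src.format in ("ontology_ttl", "ontology_rdfxml"):
        return ingest_ontology(src, model, iri_bases)
    if src.format == "triple_tsv":
        return ingest_tsv_triples(src, model, iri_bases)
    return ingest_records(src, model, iri_bases)
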