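"""Per-format ETL behaviour on hand-built miniature source files."""

import json

import pytest
from rdflib import Graph as RDFGraph

from kgweave.errors import IngestError, UnmappedPrefixError
from kgweave.ingest import (SourceConfig, build_source_node, ingest_ontology,
                            ingest_records, ingest_tsv_triples)

BASE = "http://example.org/onto/"

TTL = f"""\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix oboInOwl: <http://www.geneontology.org/formats/oboInOwl#> .
@prefix : <{BASE}> .

:D001 a owl:Class ;
    rdfs:label "disease root" .

:D002 a owl:Class ;
    rdfs:label "parkinsonism" ;
    rdfs:subClassOf :D001 .

:D003 a owl:Class ;
    rdfs:label "parkinson disease" ;
    rdfs:subClassOf :D002 ;
    oboInOwl:hasDbXref "MESH:D010300" .
"""


def onto_config(tmp_path, fmt="ontology_ttl", path="onto.ttl"):
    return SourceConfig(
        name="fixtureOnt", version="2024-01", path=str(tmp_path / path),
        format=fmt, rank=1, prefix_map={"FDIS": BASE},
        category_rules={"default": "biolink:Disease"})


class TestOntology:
    def test_counts_match_axioms(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text(TTL)
        doc = ingest_ontology(onto_config(tmp_path), disease_model)
        concepts = [n for n in doc.nodes if n.id != "KGSOURCE:fixtureOnt"]
        assert len(concepts) == 3                     # one per declared class
        assert len(doc.edges) == 3                    # 2 subClassOf + 1 xref
        assert {e.predicate for e in doc.edges} == \
            {"biolink:subclass_of", "biolink:same_as"}
        assert all(n.category == "biolink:Disease" for n in concepts)
        assert all(e.provided_by == ["KGSOURCE:fixtureOnt"] for e in doc.edges)

    def test_xref_becomes_equivalence_edge_to_curie(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text(TTL)
        doc = ingest_ontology(onto_config(tmp_path), disease_model)
        xref = [e for e in doc.edges if e.predicate == "biolink:same_as"]
        assert [(e.subject, e.object) for e in xref] == [("FDIS:D003", "MESH:D010300")]
        assert xref[0].relation == ["oboInOwl:hasDbXref"]

    def test_empty_ontology_valid(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text("")
        doc = ingest_ontology(onto_config(tmp_path), disease_model)
        assert [n.id for n in doc.nodes] == ["KGSOURCE:fixtureOnt"]
        assert doc.edges == []

    def test_rdfxml_ingestion_agrees_with_ttl(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text(TTL)
        g = RDFGraph()
        g.parse(tmp_path / "onto.ttl", format="turtle")
        g.serialize(tmp_path / "onto.owl", format="xml")
        ttl_doc = ingest_ontology(onto_config(tmp_path), disease_model)
        xml_doc = ingest_ontology(
            onto_config(tmp_path, fmt="ontology_rdfxml", path="onto.owl"), disease_model)
        assert sorted(n.id for n in xml_doc.nodes) == sorted(n.id for n in ttl_doc.nodes)
        assert sorted(e.key for e in xml_doc.edges) == sorted(e.key for e in ttl_doc.edges)

    def test_unmapped_iri_prefix_errors(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text(TTL)
        cfg = onto_config(tmp_path)
        cfg.prefix_map = {"FDIS": "http://other.example/"}
        with pytest.raises(UnmappedPrefixError, match=BASE):
            ingest_ontology(cfg, disease_model)

    def test_unparseable_file_errors(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text("@prefix broken")
        with pytest.raises(IngestError):
            ingest_ontology(onto_config(tmp_path), disease_model)

    def test_output_passes_model_validation(self, tmp_path, disease_model):
        (tmp_path / "onto.ttl").write_text(TTL)
        doc = ingest_ontology(onto_config(tmp_path), disease_model)
        assert disease_model.validate_graph(doc).ok


def tsv_config(tmp_path):
    return SourceConfig(
        name="fixtureDrugDB", version="5.1", path=str(tmp_path / "t.tsv"),
        format="triple_tsv", rank=2,
        prefix_rules={"CHEMBL": "CHEMBL.COMPOUND"},
        category_rules={"default": "biolink:NamedThing"})


class TestTsvTriples:
    def test_row_mapped_oriented_with_publications(self, tmp_path, disease_model):
        (tmp_path / "t.tsv").write_text(
            "subject\trelation\tobject\tpublications\n"
            "CHEBI:46195\ttreats_condition\tDOID:14330\tPMID:123\n")
        doc = ingest_tsv_triples(tsv_config(tmp_path), disease_model)
        [edge] = doc.edges
        assert edge.key == ("CHEBI:46195", "DOID:14330", "biolink:treats")
        assert edge.relation == ["treats_condition"]
        assert edge.publications == ["PMID:123"]
        assert {n.id for n in doc.nodes} == \
            {"CHEBI:46195", "DOID:14330", "KGSOURCE:fixtureDrugDB"}

    def test_bare_identifier_repaired_via_prefix_rule(self, tmp_path, disease_model):
        (tmp_path / "t.tsv").write_text(
            "subject\trelation\tobject\tpublications\n"
            "CHEMBL112\ttreats_condition\tDOID:14330\t\n")
        doc = ingest_tsv_triples(tsv_config(tmp_path), disease_model)
        assert doc.edges[0].subject == "CHEMBL.COMPOUND:CHEMBL112"

    def test_header_only_file_yields_empty_valid_document(self, tmp_path, disease_model):
        (tmp_path / "t.tsv").write_text("subject\trelation\tobject\tpublications\n")
        doc = ingest_tsv_triples(tsv_config(tmp_path), disease_model)
        assert doc.edges == []
        assert [n.id for n in doc.nodes] == ["KGSOURCE:fixtureDrugDB"]
        assert disease_model.validate_graph(doc).ok

    def test_bad_rows_skipped_and_counted(self, tmp_path, disease_model):
        (tmp_path / "t.tsv").write_text(
            "subject\trelation\tobject\tpublications\n"
            "only\ttwo\n"                                      # wrong column count
            "NOPREFIX999\ttreats_condition\tDOID:14330\t\n"    # irreparable bare id
            "CHEBI:1\ttreats_condition\tDOID:2\t\n")           # good
        doc = ingest_tsv_triples(tsv_config(tmp_path), disease_model)
        assert len(doc.edges) == 1
        assert doc.build_info["skipped_rows"] == 2


def record_config(tmp_path, fmt="record_json", path="r.json"):
    return SourceConfig(
        name="fixtureDrugDB", version="5.1", path=str(tmp_path / path),
        format=fmt, rank=3, category_hints={"drug": "biolink:Drug"})


class TestRecords:
    def test_record_with_two_links(self, tmp_path, disease_model):
        (tmp_path / "r.json").write_text(json.dumps({"records": [
            {"id": "DRUGBANK:DB00316", "name": "paracetamol", "category": "drug",
             "links": [{"relation": "treats_condition", "target": "DOID:14330"},
                       {"relation": "treats_condition", "target": "MONDO:0005180"}]},
        ]}))
        doc = ingest_records(record_config(tmp_path), disease_model)
        concepts = [n for n in doc.nodes if not n.id.startswith("KGSOURCE")]
        assert [n.id for n in concepts] == ["DRUGBANK:DB00316"]
        assert concepts[0].category == "biolink:Drug"
        assert len(doc.edges) == 2
        assert all(e.predicate == "biolink:treats" for e in doc.edges)

    def test_unknown_category_hint_falls_back_to_root(self, tmp_path, disease_model):
        (tmp_path / "r.json").write_text(json.dumps({"records": [
            {"id": "X:1", "name": "thing", "category": "widget", "links": []}]}))
        doc = ingest_records(record_config(tmp_path), disease_model)
        assert doc.nodes[0].category == "biolink:NamedThing"

    def test_duplicate_record_ids_merged_and_counted(self, tmp_path, disease_model):
        (tmp_path / "r.json").write_text(json.dumps({"records": [
            {"id": "X:1", "name": "", "category": "drug", "links": []},
            {"id": "X:1", "name": "late name", "category": "drug", "links": []}]}))
        doc = ingest_records(record_config(tmp_path), disease_model)
        concepts = [n for n in doc.nodes if not n.id.startswith("KGSOURCE")]
        assert len(concepts) == 1
        assert concepts[0].name == "late name"       # filled from the duplicate
        assert doc.build_info["duplicate_records"] == 1

    def test_record_without_id_skipped(self, tmp_path, disease_model):
        (tmp_path / "r.json").write_text(json.dumps({"records": [
            {"name": "anonymous", "category": "drug"}]}))
        doc = ingest_records(record_config(tmp_path), disease_model)
        assert [n.id for n in doc.nodes] == ["KGSOURCE:fixtureDrugDB"]
        assert doc.build_info["skipped_records"] == 1

    def test_xml_records_equivalent_to_json(self, tmp_path, disease_model):
        (tmp_path / "r.json").write_text(json.dumps({"records": [
            {"id": "DRUGBANK:DB00316", "name": "paracetamol", "category": "drug",
             "links": [{"relation": "treats_condition", "target": "DOID:14330",
                        "publications": ["PMID:9"]}]}]}))
        (tmp_path / "r.xml").write_text(
            '<records>\n'
            ' <record id="DRUGBANK:DB00316" name="paracetamol" category="drug">\n'
            '  <link relation="treats_condition" target="DOID:14330"'
            ' publications="PMID:9"/>\n'
            ' </record>\n'
            '</records>\n')
        jdoc = ingest_records(record_config(tmp_path), disease_model)
        xdoc = ingest_records(record_config(tmp_path, "record_xml", "r.xml"),
                              disease_model)
        assert sorted(n.id for n in jdoc.nodes) == sorted(n.id for n in xdoc.nodes)
        assert [e.key for e in jdoc.edges] == [e.key for e in xdoc.edges]
        assert jdoc.edges[0].publications == xdoc.edges[0].publications == ["PMID:9"]


class TestSourceNode:
    def test_name_embeds_version(self):
        src = SourceConfig(name="fixtureOnt", version="2024-01", path="x",
                           format="ontology_ttl", rank=1)
        node = build_source_node(src)
        assert node.name == "fixtureOnt v2024-01"
        assert node.id == "KGSOURCE:fixtureOnt"

    def test_distinct_sources_get_distinct_ids(self):
        a = build_source_node(SourceConfig("a", "1", "x", "triple_tsv", 1))
        b = build_source_node(SourceConfig("b", "1", "x", "triple_tsv", 2))
        assert a.id != b.id

    def test_every_tsv_edge_carries_the_source_id(self, tmp_path, disease_model):
        (tmp_path / "t.tsv").write_text(
            "subject\trelation\tobject\tpublications\n"
            "CHEBI:1\ttreats_condition\tDOID:2\t\n"
            "CHEBI:3\ttreats_condition\tDOID:4\tPMID:5\n")
        doc = ingest_tsv_triples(tsv_config(tmp_path), disease_model)
        assert all(e.provided_by == ["KGSOURCE:fixtureDrugDB"] for e in doc.edges)
        assert all(n.provided_by == ["KGSOURCE:fixtureDrugDB"] for n in doc.nodes)
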