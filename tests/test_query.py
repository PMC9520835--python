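"""One-hop query answering: synonym resolution, hierarchy closures,
symmetric orientation, and equivalence with a linear-scan oracle."""

import random

import pytest

from kgweave.errors import IndexError_, QueryValidationError
from kgweave.graph_model import Assertion, CanonicalConcept, GraphDocument
from kgweave.query import QueryGraph, answer_one_hop, index_graph
from tests.conftest import naive_closure, random_canonical_graph


def cnode(cid, category, aliases=(), all_cats=()):
    return CanonicalConcept(
        cid, name=cid, category=category,
        all_categories=sorted(set(all_cats) | {category}),
        equivalent_identifiers=sorted(set(aliases) | {cid}),
        provided_by=["KGSOURCE:s"])


def one_hop(ids=None, categories=None, predicates=None, reverse=False):
    n0 = {"ids": ids} if ids else {}
    n1 = {"categories": categories} if categories else {}
    sub, obj = ("n1", "n0") if reverse else ("n0", "n1")
    return QueryGraph.from_dict({
        "nodes": {"n0": n0, "n1": n1},
        "edges": {"e0": {"subject": sub, "object": obj,
                         **({"predicates": predicates} if predicates else {})}},
    })


@pytest.fixture()
def disease_gene_graph():
    nodes = [
        cnode("MONDO:0005180", "biolink:Disease",
              aliases=["DOID:14330", "MESH:D010300"]),
        cnode("NCBIGene:1", "biolink:Gene"),
        cnode("NCBIGene:2", "biolink:Gene"),
        cnode("NCBIGene:3", "biolink:Gene"),
        cnode("CHEBI:46195", "biolink:Drug"),
    ]
    edges = [
        Assertion("NCBIGene:1", "MONDO:0005180", "biolink:related_to",
                  provided_by=["KGSOURCE:a"]),
        Assertion("NCBIGene:2", "MONDO:0005180", "biolink:treats",
                  provided_by=["KGSOURCE:a", "KGSOURCE:b"]),
        Assertion("MONDO:0005180", "NCBIGene:3", "biolink:related_to",
                  provided_by=["KGSOURCE:a"]),
        Assertion("CHEBI:46195", "MONDO:0005180", "biolink:treats",
                  provided_by=["KGSOURCE:a"]),
    ]
    return GraphDocument(nodes, edges, {"stage": "canonical"})


class TestIndex:
    def test_lookup_via_equivalent_identifier(self, disease_gene_graph, disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        assert index.resolve("DOID:14330").id == "MONDO:0005180"
        assert index.resolve("MONDO:0005180").id == "MONDO:0005180"

    def test_unknown_id_resolves_to_nothing(self, disease_gene_graph, disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        assert index.resolve("HP:0000001") is None

    def test_duplicate_node_ids_rejected(self, disease_model):
        g = GraphDocument([cnode("A:1", "biolink:Gene"), cnode("A:1", "biolink:Gene")], [])
        with pytest.raises(IndexError_):
            index_graph(g, disease_model)

    def test_adjacency_matches_edge_scan(self, disease_model):
        rng = random.Random(53)
        for _ in range(20):
            g = random_canonical_graph(rng)
            index = index_graph(g, disease_model)
            for node in g.nodes:
                out_scan = sorted(i for i, e in enumerate(g.edges)
                                  if e.subject == node.id)
                in_scan = sorted(i for i, e in enumerate(g.edges)
                                 if e.object == node.id)
                assert sorted(index.out_edges[node.id]) == out_scan
                assert sorted(index.in_edges[node.id]) == in_scan


class TestValidation:
    @pytest.mark.parametrize("doc", [
        {"nodes": {"n0": {"ids": ["A:1"]}},
         "edges": {"e0": {"subject": "n0", "object": "n0"}}},          # 1 qnode
        {"nodes": {"n0": {"ids": ["A:1"]}, "n1": {}, "n2": {}},
         "edges": {"e0": {"subject": "n0", "object": "n1"}}},          # 3 qnodes
        {"nodes": {"n0": {"ids": ["A:1"]}, "n1": {}},
         "edges": {"e0": {"subject": "n0", "object": "nX"}}},          # dangling ref
        {"nodes": {"n0": {}, "n1": {}},
         "edges": {"e0": {"subject": "n0", "object": "n1"}}},          # no ids anywhere
    ])
    def test_malformed_queries_rejected(self, doc):
        with pytest.raises(QueryValidationError):
            QueryGraph.from_dict(doc).validate()


class TestAnswerOneHop:
    def test_gene_neighbors_of_disease_with_closure(self, disease_gene_graph,
                                                    disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        # related_to closure covers treats; Gene category excludes the drug
        rs = answer_one_hop(index, one_hop(ids=["MONDO:0005180"],
                                           categories=["biolink:Gene"],
                                           predicates=["biolink:related_to"],
                                           reverse=True),
                            disease_model)
        genes = {r["n1"] for r in rs.results}
        assert genes == {"NCBIGene:1", "NCBIGene:2"}
        assert len(rs.knowledge_graph.nodes) == 3
        assert len(rs.knowledge_graph.edges) == 2

    def test_query_by_synonym_finds_canonical_node(self, disease_gene_graph,
                                                   disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        via_alias = answer_one_hop(index, one_hop(ids=["DOID:14330"],
                                                  categories=["biolink:Gene"],
                                                  reverse=True),
                                   disease_model)
        via_canon = answer_one_hop(index, one_hop(ids=["MONDO:0005180"],
                                                  categories=["biolink:Gene"],
                                                  reverse=True),
                                   disease_model)
        assert via_alias.results == via_canon.results

    def test_unsatisfiable_category_gives_empty_resultset(self, disease_gene_graph,
                                                          disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        rs = answer_one_hop(index, one_hop(ids=["MONDO:0005180"],
                                           categories=["biolink:InformationContentEntity"]),
                            disease_model)
        assert rs.results == []
        assert rs.knowledge_graph.nodes == [] and rs.knowledge_graph.edges == []

    def test_symmetric_edge_matches_from_either_end(self, disease_model):
        g = GraphDocument(
            [cnode("CHEBI:1", "biolink:Drug"), cnode("CHEBI:2", "biolink:Drug")],
            [Assertion("CHEBI:1", "CHEBI:2", "biolink:interacts_with",
                       provided_by=["KGSOURCE:a"])])
        index = index_graph(g, disease_model)
        rs = answer_one_hop(index, one_hop(ids=["CHEBI:2"],
                                           predicates=["biolink:interacts_with"]),
                            disease_model)
        assert [r["n0"] for r in rs.results] == ["CHEBI:2"]
        assert [r["n1"] for r in rs.results] == ["CHEBI:1"]

    def test_directed_edge_does_not_match_reversed(self, disease_model):
        g = GraphDocument(
            [cnode("CHEBI:1", "biolink:Drug"), cnode("MONDO:1", "biolink:Disease")],
            [Assertion("CHEBI:1", "MONDO:1", "biolink:treats",
                       provided_by=["KGSOURCE:a"])])
        index = index_graph(g, disease_model)
        forward = answer_one_hop(index, one_hop(ids=["CHEBI:1"],
                                                predicates=["biolink:treats"]),
                                 disease_model)
        backward = answer_one_hop(index, one_hop(ids=["MONDO:1"],
                                                 predicates=["biolink:treats"]),
                                  disease_model)
        assert len(forward.results) == 1 and backward.results == []

    def test_result_order_by_provenance_then_binding(self, disease_gene_graph,
                                                     disease_model):
        index = index_graph(disease_gene_graph, disease_model)
        rs = answer_one_hop(index, one_hop(ids=["MONDO:0005180"],
                                           categories=["biolink:Gene"],
                                           reverse=True),
                            disease_model)
        # the doubly-sourced treats edge ranks first
        assert rs.results[0]["n1"] == "NCBIGene:2"


def brute_force_one_hop(graph, query, model):
    """Independent evaluator: naive closures + full edge scan."""
    qekey, qedge = next(iter(query.qedges.items()))
    skey, okey = qedge.subject, qedge.object
    alias = {}
    for n in graph.nodes:
        alias[n.id] = n.id
        for eq in n.equivalent_identifiers:
            alias[eq] = n.id
    cat_children = model.categories.children
    pred_children = model.predicates.children

    def want_preds():
        if not qedge.predicates:
            return None
        out = set()
        for p in qedge.predicates:
            out |= naive_closure(pred_children, p)
        return out

    def node_ok(nid, qn):
        if qn.ids is not None:
            if alias.get(nid) not in {alias.get(i) for i in qn.ids}:
                return False
        if qn.categories:
            want = set()
            for c in qn.categories:
                want |= naive_closure(cat_children, c)
            node = next(n for n in graph.nodes if n.id == nid)
            cats = set(node.all_categories) or {node.category}
            if not cats & want:
                return False
        return True

    preds = want_preds()
    found = set()
    for e in graph.edges:
        if preds is not None and e.predicate not in preds:
            continue
        ends = [(e.subject, e.object)]
        if e.predicate in model.symmetric_predicates:
            ends.append((e.object, e.subject))
        for s, o in ends:
            if node_ok(s, query.qnodes[skey]) and node_ok(o, query.qnodes[okey]):
                found.add((s, o, f"{e.subject}--{e.predicate}--{e.object}"))
    return found


def random_query(rng, graph):
    cats = ["biolink:Disease", "biolink:Gene", "biolink:ChemicalEntity",
            "biolink:NamedThing", "biolink:Drug"]
    preds = ["biolink:related_to", "biolink:treats", "biolink:interacts_with",
             "biolink:physically_interacts_with", "biolink:has_part"]
    node = rng.choice(graph.nodes)
    ids = [rng.choice(node.equivalent_identifiers)]
    if rng.random() < 0.3:
        ids.append(rng.choice(graph.nodes).id)
    n0 = {"ids": ids}
    n1 = {}
    if rng.random() < 0.6:
        n1["categories"] = [rng.choice(cats)]
    if rng.random() < 0.3:
        n1["ids"] = [rng.choice(graph.nodes).id]
    edge = {"subject": "n0", "object": "n1"}
    if rng.random() < 0.5:
        edge["subject"], edge["object"] = "n1", "n0"
    if rng.random() < 0.7:
        edge["predicates"] = rng.sample(preds, rng.randint(1, 2))
    return QueryGraph.from_dict({"nodes": {"n0": n0, "n1": n1}, "edges": {"e0": edge}})


class TestOracleEquivalence:
    def test_bindings_match_linear_scan_on_random_pairs(self, disease_model):
        rng = random.Random(61)
        for _ in range(40):
            g = random_canonical_graph(rng)
            index = index_graph(g, disease_model)
            query = random_query(rng, g)
            rs = answer_one_hop(index, query, disease_model)
            qekey = next(iter(query.qedges))
            qe = query.qedges[qekey]
            got = {(r[qe.subject], r[qe.object], r[qekey]) for r in rs.results}
            assert got == brute_force_one_hop(g, query, disease_model)
            # knowledge_graph minimality
            bound_nodes = {r[qe.subject] for r in rs.results} | \
                          {r[qe.object] for r in rs.results}
            assert {n.id for n in rs.knowledge_graph.nodes} == bound_nodes
            assert len(rs.results) == len(got)     # deduplicated
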