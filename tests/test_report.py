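"""Build reports, three-fold drift flags, degree statistics and the
power-law estimator."""

import math
import random

import pytest

from kgweave.errors import EstimationError, ParameterError
from kgweave.graph_model import (Assertion, CanonicalConcept, Concept,
                                 GraphDocument)
from kgweave.report import (BuildReport, compare_reports, compute_report,
                            count_meta_triples, degree_histogram,
                            fit_power_law, DegreeHistogram)
from tests.conftest import random_graph


class TestComputeReport:
    def test_empty_graph_all_zero(self):
        report = compute_report(GraphDocument(), "pre")
        assert report.total_nodes == report.total_edges == 0
        assert report.nodes_by_category == {} and report.edges_by_predicate == {}

    def test_counts_equal_group_by_oracle(self):
        rng = random.Random(13)
        g = random_graph(rng, n_nodes=80, n_edges=200)
        report = compute_report(g, "post_merge")
        cat_oracle: dict = {}
        for n in g.nodes:
            cat_oracle[n.category] = cat_oracle.get(n.category, 0) + 1
        assert report.nodes_by_category == cat_oracle
        pred_oracle: dict = {}
        for e in g.edges:
            pred_oracle[e.predicate] = pred_oracle.get(e.predicate, 0) + 1
        assert report.edges_by_predicate == pred_oracle
        assert sum(report.nodes_by_category.values()) == report.total_nodes
        assert sum(report.edges_by_predicate.values()) == report.total_edges

    def test_multi_provenance_counted_once_per_source(self):
        g = GraphDocument([Concept("A:1", provided_by=["KGSOURCE:a", "KGSOURCE:b"])], [])
        report = compute_report(g)
        assert report.nodes_by_source == {"KGSOURCE:a": 1, "KGSOURCE:b": 1}
        assert report.total_nodes == 1


class TestCompareReports:
    def r(self, **cats):
        return BuildReport(nodes_by_category=dict(cats),
                           total_nodes=sum(cats.values()))

    def test_three_and_a_half_fold_flagged(self):
        flags = compare_reports(self.r(d=100), self.r(d=350))
        assert [(f[0], f[1]) for f in flags if f[0] != "totals"] == \
            [("nodes_by_category", "d")]

    def test_two_and_a_half_fold_not_flagged(self):
        flags = compare_reports(self.r(d=100), self.r(d=250))
        assert [f for f in flags if f[0] == "nodes_by_category"] == []

    def test_exactly_three_fold_not_flagged(self):
        # the rule is *more than* three-fold
        flags = compare_reports(self.r(d=100), self.r(d=300))
        assert [f for f in flags if f[0] == "nodes_by_category"] == []

    def test_appearance_and_vanishing_flagged(self):
        old = BuildReport(edges_by_predicate={"biolink:treats": 5})
        new = BuildReport(edges_by_predicate={"biolink:affects": 2})
        reasons = {(f[1], f[4]) for f in compare_reports(old, new)
                   if f[0] == "edges_by_predicate"}
        assert reasons == {("biolink:treats", "vanished"),
                           ("biolink:affects", "appeared")}

    def test_shrinkage_flagged_symmetrically(self):
        flags = compare_reports(self.r(d=350), self.r(d=100))
        assert any(f[1] == "d" for f in flags)

    def test_fold_must_exceed_one(self):
        with pytest.raises(ParameterError):
            compare_reports(BuildReport(), BuildReport(), fold=1.0)


class TestDegreeHistogram:
    def test_path_graph(self):
        g = GraphDocument(
            [Concept("A:1"), Concept("B:2"), Concept("C:3")],
            [Assertion("A:1", "B:2", "biolink:related_to"),
             Assertion("B:2", "C:3", "biolink:related_to")])
        assert degree_histogram(g).counts == {1: 2, 2: 1}

    def test_self_loop_contributes_two(self):
        g = GraphDocument([Concept("A:1")],
                          [Assertion("A:1", "A:1", "biolink:related_to")])
        assert degree_histogram(g).counts == {2: 1}

    def test_handshake_identity_on_random_graphs(self):
        rng = random.Random(31)
        for _ in range(20):
            g = random_graph(rng, allow_self_loops=True)
            hist = degree_histogram(g)
            assert sum(k * c for k, c in hist.counts.items()) == 2 * len(g.edges)
            assert sum(hist.counts.values()) == hist.n == len(g.nodes)


class TestFitPowerLaw:
    def test_approx_closed_form_on_tiny_example(self):
        # degrees [1,1,2,4]: alpha = 1 + 4/(ln2 + ln2 + ln4 + ln8)
        hist = DegreeHistogram({1: 2, 2: 1, 4: 1}, 4)
        fit = fit_power_law(hist, xmin=1, method="approx")
        expected = 1 + 4 / (2 * math.log(2) + math.log(4) + math.log(8))
        assert fit.alpha == pytest.approx(expected)
        assert fit.alpha == pytest.approx(1.824, abs=5e-4)
        assert fit.n_tail == 4

    def test_all_degrees_equal_is_degenerate_or_error(self):
        hist = DegreeHistogram({3: 50}, 50)
        with pytest.raises(EstimationError):
            fit_power_law(hist, xmin=3)

    def test_exact_estimator_consistent_across_sample_sizes(self):
        # recovery error stays inside a band that tightens as n grows
        from kgweave.fixtures import generate_scale_free_graph
        for n, tol in ((1000, 0.2), (10000, 0.1), (100000, 0.05)):
            g = generate_scale_free_graph(n, 2.43, seed=5)
            fit = fit_power_law(degree_histogram(g), xmin=1)
            assert abs(fit.alpha - 2.43) < tol, n

    def test_exact_beats_approx_at_xmin_one(self):
        from kgweave.fixtures import generate_scale_free_graph
        g = generate_scale_free_graph(20000, 2.43, seed=2)
        hist = degree_histogram(g)
        exact = fit_power_law(hist, xmin=1).alpha
        approx = fit_power_law(hist, xmin=1, method="approx").alpha
        assert abs(exact - 2.43) < abs(approx - 2.43)


class TestMetaTriples:
    def test_multi_category_product_rule(self):
        nodes = [
            CanonicalConcept("C:1", category="biolink:ChemicalEntity",
                             all_categories=["biolink:ChemicalEntity",
                                             "biolink:SmallMolecule"],
                             equivalent_identifiers=["C:1"]),
            CanonicalConcept("D:1", category="biolink:Disease",
                             all_categories=["biolink:Disease"],
                             equivalent_identifiers=["D:1"]),
        ]
        g = GraphDocument(nodes, [Assertion("C:1", "D:1", "biolink:treats")])
        table = count_meta_triples(g)
        assert table.distinct == 2
        assert table.cells == {
            ("biolink:ChemicalEntity", "biolink:treats", "biolink:Disease"): 1,
            ("biolink:SmallMolecule", "biolink:treats", "biolink:Disease"): 1,
        }

    def test_single_category_totals_equal_edge_count(self):
        rng = random.Random(37)
        g = random_graph(rng, n_nodes=50, n_edges=120)
        table = count_meta_triples(g)
        assert table.total == len(g.edges)
        assert table.distinct == len({(  # independent combo count
            next(n.category for n in g.nodes if n.id == e.subject), e.predicate,
            next(n.category for n in g.nodes if n.id == e.object))
            for e in g.edges})

    def test_total_matches_per_edge_product_oracle(self):
        from tests.conftest import random_canonical_graph
        rng = random.Random(41)
        for _ in range(10):
            g = random_canonical_graph(rng)
            cats = {n.id: set(n.all_categories) for n in g.nodes}
            oracle = sum(len(cats[e.subject]) * len(cats[e.object]) for e in g.edges)
            assert count_meta_triples(g).total == oracle

    def test_multi_category_counts_dominate_primary_only(self):
        from tests.conftest import random_canonical_graph
        g = random_canonical_graph(random.Random(43), n_nodes=40, n_edges=100)
        truncated = GraphDocument(
            [Concept(n.id, category=n.category) for n in g.nodes], g.edges)
        assert count_meta_triples(g).distinct >= count_meta_triples(truncated).distinct
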