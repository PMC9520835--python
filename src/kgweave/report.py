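"""Build reports, cross-build drift flags, degree statistics, meta-triples.

A :class:`BuildReport` tabulates node and edge counts by source, category
and predicate (both before and after edge coalescing, via the ``stage``
marker), and :func:`compare_reports` flags anomalously large changes
between two builds — by default anything more than three-fold, plus keys
that appear or vanish outright.

Degree statistics treat the graph as directed but tabulate total (in+out)
degree; a self-loop contributes 2.  The degree distribution of large
integrated knowledge graphs is approximately scale-free — frequencies
decaying as ``k**-alpha`` — and :func:`fit_power_law` estimates ``alpha``
by discrete maximum likelihood.

Meta-triples are distinct (subject category, predicate, object category)
patterns; on canonicalized graphs each edge contributes the full product
of its endpoints' category sets, which is why canonicalization *increases*
the meta-triple count even as nodes and edges shrink.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import zeta

from .errors import EstimationError, ParameterError
from .graph_model import CanonicalConcept, GraphDocument

__all__ = [
    "BuildReport",
    "DegreeHistogram",
    "PowerLawFit",
    "MetaTripleTable",
    "compute_report",
    "compare_reports",
    "degree_histogram",
    "fit_power_law",
    "count_meta_triples",
]


@dataclass
class BuildReport:
    """Count tables for one build stage.

    Per-source counts attribute a node/edge once per providing source, so
    their sums may exceed the totals; category and predicate counts
    partition the totals exactly.
    """

    nodes_by_source: dict[str, int] = field(default_factory=dict)
    nodes_by_category: dict[str, int] = field(default_factory=dict)
    edges_by_source: dict[str, int] = field(default_factory=dict)
    edges_by_predicate: dict[str, int] = field(default_factory=dict)
    total_nodes: int = 0
    total_edges: int = 0
    stage: str = ""

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "totals": {"nodes": self.total_nodes, "edges": self.total_edges},
            "nodes_by_source": dict(sorted(self.nodes_by_source.items())),
            "nodes_by_category": dict(sorted(self.nodes_by_category.items())),
            "edges_by_source": dict(sorted(self.edges_by_source.items())),
            "edges_by_predicate": dict(sorted(self.edges_by_predicate.items())),
        }

    def to_text(self) -> str:
        lines = [f"stage: {self.stage}",
                 f"totals: {self.total_nodes} nodes, {self.total_edges} edges"]
        for family in ("nodes_by_source", "nodes_by_category",
                       "edges_by_source", "edges_by_predicate"):
            lines.append(f"\n{family}:")
            for key, count in sorted(getattr(self, family).items()):
                lines.append(f"  {key}\t{count}")
        return "\n".join(lines) + "\n"


def compute_report(graph: GraphDocument, stage: str = "") -> BuildReport:
    """Tabulate node/edge counts by source, category and predicate."""
    report = BuildReport(stage=stage or str(graph.build_info.get("stage", "")))
    report.total_nodes = len(graph.nodes)
    report.total_edges = len(graph.edges)
    for node in graph.nodes:
        report.nodes_by_category[node.category] = \
            report.nodes_by_category.get(node.category, 0) + 1
        for source in node.provided_by:
            report.nodes_by_source[source] = report.nodes_by_source.get(source, 0) + 1
    for edge in graph.edges:
        report.edges_by_predicate[edge.predicate] = \
            report.edges_by_predicate.get(edge.predicate, 0) + 1
        for source in edge.provided_by:
            report.edges_by_source[source] = report.edges_by_source.get(source, 0) + 1
    return report


_FAMILIES = ("nodes_by_source", "nodes_by_category", "edges_by_source",
             "edges_by_predicate")


def compare_reports(old: BuildReport, new: BuildReport,
                    fold: float = 3.0) -> list[tuple[str, str, int, int, str]]:
    """Flag count changes larger than ``fold`` between two builds.

    Returns (family, key, old count, new count, reason) tuples.  A ratio
    strictly greater than ``fold`` in either direction is flagged
    ("more than three-fold" at the default); keys present on only one
    side are flagged as "appeared"/"vanished" since a ratio is undefined
    at zero.  Totals are compared under the pseudo-family ``totals``.
    """
    if fold <= 1:
        raise ParameterError(f"fold threshold must exceed 1 (got {fold})")
    flags: list[tuple[str, str, int, int, str]] = []

    def check(family: str, key: str, o: int, n: int) -> None:
        if o == 0 and n == 0:
            return
        if o == 0:
            flags.append((family, key, o, n, "appeared"))
        elif n == 0:
            flags.append((family, key, o, n, "vanished"))
        elif n / o > fold or o / n > fold:
            flags.append((family, key, o, n, f"{max(n / o, o / n):.2f}-fold"))

    for family in _FAMILIES:
        old_map, new_map = getattr(old, family), getattr(new, family)
        for key in sorted(set(old_map) | set(new_map)):
            check(family, key, old_map.get(key, 0), new_map.get(key, 0))
    check("totals", "nodes", old.total_nodes, new.total_nodes)
    check("totals", "edges", old.total_edges, new.total_edges)
    return flags


# ---------------------------------------------------------------------------
# degree statistics


@dataclass
class DegreeHistogram:
    """Total (in+out) degree tabulation: degree k -> node count."""

    counts: dict[int, int]
    n: int

    def degrees(self) -> np.ndarray:
        """Expanded degree sequence (sorted ascending)."""
        out = np.concatenate([np.full(c, k, dtype=np.int64)
                              for k, c in sorted(self.counts.items())]) \
            if self.counts else np.empty(0, dtype=np.int64)
        return out


@dataclass
class PowerLawFit:
    """A fitted ``p(k) ~ k**-alpha`` tail (k >= xmin)."""

    alpha: float
    xmin: int
    n_tail: int
    degenerate: bool = False
    method: str = "exact"


def degree_histogram(graph: GraphDocument) -> DegreeHistogram:
    """Total degree of each node = number of edge endpoints referencing it
    (a self-loop contributes 2); isolated nodes count at degree 0."""
    degree = {n.id: 0 for n in graph.nodes}
    for edge in graph.edges:
        if edge.subject in degree:
            degree[edge.subject] += 1
        if edge.object in degree:
            degree[edge.object] += 1
    counts: dict[int, int] = {}
    for k in degree.values():
        counts[k] = counts.get(k, 0) + 1
    return DegreeHistogram(counts, len(degree))


def _log_zeta_deriv(alpha: float, xmin: int) -> float:
    h = 1e-6
    return (math.log(zeta(alpha + h, xmin)) - math.log(zeta(alpha - h, xmin))) / (2 * h)


def fit_power_law(hist: DegreeHistogram, xmin: int = 1,
                  method: str = "exact") -> PowerLawFit:
    """Discrete maximum-likelihood estimate of the power-law exponent.

    ``method="exact"`` (default) maximizes the discrete (Hurwitz-zeta)
    log-likelihood numerically; it is the estimator to use at small
    ``xmin``, where the closed-form approximation is substantially biased.
    ``method="approx"`` uses the closed form
    ``alpha = 1 + n / sum(ln(k_i / (xmin - 1/2)))``, which is accurate
    only for larger ``xmin``.

    Degrees below ``xmin`` are excluded; fewer than two distinct fitted
    degrees raise :class:`EstimationError`; a vanishing log-sum (all mass
    at ``xmin`` under the approximation) returns a degenerate-flagged fit.
    """
    if xmin < 1:
        raise ParameterError(f"xmin must be >= 1 (got {xmin})")
    if method not in ("exact", "approx"):
        raise ParameterError(f"unknown method {method!r}")
    tail = {k: c for k, c in hist.counts.items() if k >= xmin}
    n_tail = sum(tail.values())
    if len(tail) < 2:
        raise EstimationError(
            f"need >= 2 distinct degrees at/above xmin={xmin} (got {len(tail)})")

    ks = np.array(sorted(tail), dtype=float)
    cs = np.array([tail[int(k)] for k in ks], dtype=float)
    mean_log_k = float((cs * np.log(ks)).sum() / n_tail)

    if method == "approx":
        log_sum = float((cs * np.log(ks / (xmin - 0.5))).sum())
        if log_sum <= 1e-12:
            return PowerLawFit(alpha=float("inf"), xmin=xmin, n_tail=n_tail,
                               degenerate=True, method=method)
        return PowerLawFit(alpha=1.0 + n_tail / log_sum, xmin=xmin,
                           n_tail=n_tail, method=method)

    # exact: solve d/dalpha log L = 0  <=>  -zeta'(a, xmin)/zeta(a, xmin) = mean ln k
    def score(alpha: float) -> float:
        return -_log_zeta_deriv(alpha, xmin) - mean_log_k

    lo, hi = 1.01, 2.0
    while score(hi) > 0 and hi < 64:
        hi *= 2
    if score(lo) < 0 or score(hi) > 0:
        return PowerLawFit(alpha=float(hi), xmin=xmin, n_tail=n_tail,
                           degenerate=True, method=method)
    alpha = float(brentq(score, lo, hi, xtol=1e-8))
    return PowerLawFit(alpha=alpha, xmin=xmin, n_tail=n_tail, method=method)


# ---------------------------------------------------------------------------
# meta-triples


@dataclass
class MetaTripleTable:
    """Edge counts per (subject category, predicate, object category)."""

    cells: dict[tuple[str, str, str], int]

    @property
    def distinct(self) -> int:
        return len(self.cells)

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def to_rows(self) -> list[tuple[str, str, str, int]]:
        return [(cs, p, co, n) for (cs, p, co), n in sorted(self.cells.items())]


def count_meta_triples(graph: GraphDocument) -> MetaTripleTable:
    """Each edge increments every (cs, p, co) cell with cs/co drawn from
    its endpoints' category sets.

    On canonicalized graphs the category set is ``all_categories``, so an
    edge contributes ``|cats(subject)| * |cats(object)|`` cells; on
    single-category graphs exactly one.
    """
    cats: dict[str, list[str]] = {}
    for node in graph.nodes:
        if isinstance(node, CanonicalConcept) and node.all_categories:
            cats[node.id] = list(node.all_categories)
        else:
            cats[node.id] = [node.category]
    cells: dict[tuple[str, str, str], int] = {}
    for edge in graph.edges:
        for cs in cats.get(edge.subject, []):
            for co in cats.get(edge.object, []):
                key = (cs, edge.predicate, co)
                cells[key] = cells.get(key, 0) + 1
    return MetaTripleTable(cells)


# ---------------------------------------------------------------------------
# serialization helpers


def write_report(report: BuildReport, json_path=None, text_path=None) -> None:
    if json_path:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=False)
            fh.write("\n")
    if text_path:
        with open(text_path, "w", encoding="utf-8") as fh:
            fh.write(report.to_text())


def read_report(json_path) -> BuildReport:
    with open(json_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return BuildReport(
        nodes_by_source=dict(doc.get("nodes_by_source", {})),
        nodes_by_category=dict(doc.get("nodes_by_category", {})),
        edges_by_source=dict(doc.get("edges_by_source", {})),
        edges_by_predicate=dict(doc.get("edges_by_predicate", {})),
        total_nodes=int(doc.get("totals", {}).get("nodes", 0)),
        total_edges=int(doc.get("totals", {}).get("edges", 0)),
        stage=str(doc.get("stage", "")),
    )


def write_flags(flags, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family\tkey\told\tnew\treason\n")
        for family, key, o, n, reason in flags:
            fh.write(f"{family}\t{key}\t{o}\t{n}\t{reason}\n")
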