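"""Shared fixtures: a hand-written disease-domain semantic model, random
graph generators for property/oracle tests, and a suite-build helper."""

from __future__ import annotations

import logging
import random
from pathlib import Path

import pytest

from kgweave.graph_model import Assertion, CanonicalConcept, Concept, GraphDocument
from kgweave.semantic_model import SemanticModel, load_model

# quiet the (intentional) unmapped-relation fallback warnings in fixture builds
logging.getLogger("kgweave.semantic_model").setLevel(logging.ERROR)
logging.getLogger("kgweave.ingest").setLevel(logging.ERROR)

DISEASE_MODEL_YAML = """\
version: "test-1.0"
categories:
  biolink:NamedThing:
    - biolink:Disease
    - biolink:Gene
    - biolink:ChemicalEntity
    - biolink:InformationContentEntity
  biolink:ChemicalEntity:
    - biolink:SmallMolecule
    - biolink:Drug
predicates:
  biolink:related_to:
    - biolink:subclass_of
    - biolink:same_as
    - biolink:treats
    - biolink:interacts_with
    - biolink:has_part
    - biolink:part_of
  biolink:same_as:
    - biolink:exact_match
  biolink:interacts_with:
    - biolink:physically_interacts_with
inverse_pairs:
  - pair: [biolink:has_part, biolink:part_of]
    canonical: biolink:has_part
symmetric:
  - biolink:interacts_with
  - biolink:physically_interacts_with
relation_map:
  - {source: fixtureDrugDB, relation: treats_condition, predicate: biolink:treats}
prefix_priority:
  biolink:Disease: [MONDO, DOID, EFO, MESH]
  biolink:Drug: [CHEBI, DRUGBANK, UMLS]
"""

#: predicates legal in stored graphs (canonical orientation only)
CANONICAL_PREDICATES = [
    "biolink:related_to", "biolink:subclass_of", "biolink:same_as",
    "biolink:exact_match", "biolink:treats", "biolink:interacts_with",
    "biolink:physically_interacts_with", "biolink:has_part",
]


def make_model(yaml_text: str, tmp_path: Path) -> SemanticModel:
    path = tmp_path / "model.yaml"
    path.write_text(yaml_text, encoding="utf-8")
    return load_model(path)


@pytest.fixture()
def disease_model(tmp_path) -> SemanticModel:
    return make_model(DISEASE_MODEL_YAML, tmp_path)


@pytest.fixture(scope="session")
def disease_model_session(tmp_path_factory) -> SemanticModel:
    return make_model(DISEASE_MODEL_YAML, tmp_path_factory.mktemp("model"))


# ---------------------------------------------------------------------------
# random graph generators (shared by round-trip / partition / query tests)

_PREFIXES = ["MONDO", "DOID", "MESH", "CHEBI", "UMLS", "NCBIGene"]
_CATEGORIES = ["biolink:Disease", "biolink:Gene", "biolink:ChemicalEntity",
               "biolink:SmallMolecule", "biolink:Drug", "biolink:NamedThing"]


def random_graph(rng: random.Random, n_nodes: int = 0, n_edges: int = 0,
                 predicates=None, allow_self_loops: bool = False) -> GraphDocument:
    """A random plain (pre-style) graph with unique edge keys."""
    n_nodes = n_nodes or rng.randint(2, 200)
    n_edges = n_edges if n_edges else rng.randint(0, 3 * n_nodes)
    predicates = predicates or CANONICAL_PREDICATES
    ids = [f"{rng.choice(_PREFIXES)}:{i:05d}" for i in range(n_nodes)]
    nodes = [Concept(id=i, name=f"node {k}", category=rng.choice(_CATEGORIES),
                     iri=f"http://x.org/{k}", description="",
                     provided_by=[f"KGSOURCE:src{rng.randint(1, 3)}"],
                     publications=([f"PMID:{rng.randint(1, 999)}"]
                                   if rng.random() < 0.3 else []))
             for k, i in enumerate(ids)]
    keys: set[tuple[str, str, str]] = set()
    edges = []
    for _ in range(n_edges):
        s, o = rng.choice(ids), rng.choice(ids)
        if s == o and not allow_self_loops:
            continue
        # store symmetric predicates in normalized direction
        p = rng.choice(predicates)
        if p in ("biolink:interacts_with", "biolink:physically_interacts_with") and s > o:
            s, o = o, s
        if (s, o, p) in keys:
            continue
        keys.add((s, o, p))
        edges.append(Assertion(s, o, p, relation=[f"rel_{rng.randint(0, 5)}"],
                               provided_by=[f"KGSOURCE:src{rng.randint(1, 3)}"],
                               publications=([f"PMID:{rng.randint(1, 999)}"]
                                             if rng.random() < 0.3 else [])))
    return GraphDocument(nodes, edges, {"stage": "test", "seed": rng.random()})


def random_canonical_graph(rng: random.Random, n_nodes: int = 0,
                           n_edges: int = 0) -> GraphDocument:
    """A random canonicalized graph: CanonicalConcepts with aliases and
    multi-category annotations; no equivalence edges."""
    base = random_graph(rng, n_nodes or rng.randint(2, 60), n_edges,
                        predicates=[p for p in CANONICAL_PREDICATES
                                    if p not in ("biolink:same_as", "biolink:exact_match")])
    nodes = []
    for k, n in enumerate(base.nodes):
        aliases = [n.id] + [f"ALIAS{j}:{k:05d}" for j in range(rng.randint(0, 2))]
        cats = sorted({n.category} | ({rng.choice(_CATEGORIES)}
                                     if rng.random() < 0.4 else set()))
        nodes.append(CanonicalConcept(
            id=n.id, name=n.name, category=n.category, iri=n.iri,
            description=n.description, provided_by=list(n.provided_by),
            publications=list(n.publications), all_categories=cats,
            equivalent_identifiers=sorted(aliases), all_names=[n.name]))
    return GraphDocument(nodes, base.edges, {"stage": "canonical"})


# ---------------------------------------------------------------------------
# naive closure helpers (independent of SemanticModel.expand_* caches)


def naive_closure(children: dict[str, list[str]], name: str) -> set[str]:
    out = {name}
    for kid in children.get(name, []):
        out |= naive_closure(children, kid)
    return out


@pytest.fixture()
def suite_build(tmp_path):
    """Factory: generate a fixture suite and run the full pipeline on it."""
    from kgweave.fixtures import SuiteParams, generate_source_suite
    from kgweave.ingest import load_build_config
    from kgweave.orchestrator import plan_build, run_build

    def _build(seed: int = 1, params: SuiteParams | None = None):
        suite_dir = tmp_path / f"suite{seed}"
        out_dir = tmp_path / f"out{seed}"
        manifest, _paths = generate_source_suite(params, seed, suite_dir)
        config = load_build_config(suite_dir / "config.yaml")
        model = load_model(suite_dir / "model.yaml")
        plan = plan_build(config, out_dir, {})
        run_build(plan, config, out_dir, model, workers=1)
        return manifest, config, model, out_dir

    return _build
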