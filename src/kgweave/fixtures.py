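"""Synthetic knowledge-source suites with known ground truth.

:func:`generate_source_suite` writes a miniature multi-source build input
— one ontology (TTL classes, labels, ``rdfs:subClassOf``, xrefs), one or
two NLP-style triple TSV sources with publications, and one record-oriented
JSON source — plus the semantic-model file and a build configuration in
rank order.  The suite plants, under generator bookkeeping that is exact by
construction:

* synonym cliques: the same concept emitted under different per-source
  identifier prefixes, linked by xref / ``same_as`` assertions;
* cross-source duplicate triples (the TSV source re-asserting ontology
  subclass axioms), which must coalesce at merge;
* dangling edges (links to identifiers no source declares), which must be
  screened and logged.

The accompanying :class:`SuiteManifest` states the exact expected pre- and
post-canonicalization node/edge counts, the planted clique sets, and the
duplicate/dangler counts; the end-to-end pipeline must reproduce it
exactly.  Everything is a pure function of (parameters, seed).

:func:`generate_scale_free_graph` draws a degree sequence from a discrete
power law ``p(k) ~ k**-exponent`` (k >= 1) by inverse-CDF sampling and
realizes it with configuration-model stub matching (multi-edges and
self-loops kept, so the handshake identity is exact).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .graph_model import Assertion, Concept, GraphDocument

__all__ = ["SuiteParams", "SuiteManifest", "generate_source_suite",
           "generate_scale_free_graph", "FIXTURE_MODEL_YAML"]

# per-role source identity: (name, CURIE prefix, format)
_ROLES = [
    ("fixtureOntology", "FONT", "ontology_ttl"),
    ("fixtureTriples", "FSEM", "triple_tsv"),
    ("fixtureDrugDB", "FDB", "record_json"),
    ("fixtureTriples2", "FX4", "triple_tsv"),
]

_IRI_BASES = {
    "FONT": "http://example.org/fixture/font/",
    "FSEM": "http://example.org/fixture/fsem/",
    "FDB": "http://example.org/fixture/fdb/",
    "FX4": "http://example.org/fixture/fx4/",
    "FGHOST": "http://example.org/fixture/ghost/",
}

# TSV fact relations: relation string -> mapped predicate (None = unmapped,
# exercises the root-predicate fallback)
_TSV_RELATIONS = {
    "treats_condition": "biolink:treats",
    "component_of": "biolink:part_of",
    "binds": "biolink:physically_interacts_with",
    "linked_to": "biolink:associated_with",
    "frobnicates": None,
}
_RECORD_RELATIONS = {
    "targets": "biolink:affects",
    "treats": "biolink:treats",
}
_EQUIV_RELATION = ("equivalent_to", "biolink:same_as")
_DUP_RELATION = ("is_subtype_of", "biolink:subclass_of")

_ROOT_PREDICATE = "biolink:related_to"
_SYMMETRIC = {"biolink:interacts_with", "biolink:physically_interacts_with"}
_INVERSE_TO_CANONICAL = {"biolink:part_of": "biolink:has_part"}

FIXTURE_MODEL_YAML = """\
# Semantic layer for the synthetic fixture suite.
version: "fixture-1.0"
categories:
  biolink:NamedThing:
    - biolink:Disease
    - biolink:Drug
    - biolink:Gene
    - biolink:ChemicalEntity
    - biolink:Pathway
    - biolink:InformationContentEntity
  biolink:ChemicalEntity:
    - biolink:SmallMolecule
predicates:
  biolink:related_to:
    - biolink:subclass_of
    - biolink:same_as
    - biolink:treats
    - biolink:affects
    - biolink:interacts_with
    - biolink:has_part
    - biolink:part_of
    - biolink:associated_with
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
{relation_map}
prefix_priority:
{prefix_priority}
"""


@dataclass
class SuiteParams:
    """Generator parameters: the conditions every fixture build emulates."""

    n_concepts: int = 50
    n_sources: int = 3
    synonym_rate: float = 0.3
    duplicate_rate: float = 0.1
    dangler_rate: float = 0.05
    publication_rate: float = 0.5

    def validate(self) -> None:
        for name in ("synonym_rate", "duplicate_rate", "dangler_rate",
                     "publication_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1] (got {rate})")
        if not 2 <= self.n_sources <= len(_ROLES):
            raise ParameterError(
                f"n_sources must be in [2, {len(_ROLES)}] (got {self.n_sources})")
        if self.n_concepts < self.n_sources:
            raise ParameterError(
                f"n_concepts ({self.n_concepts}) must be >= n_sources "
                f"({self.n_sources})")


@dataclass
class SuiteManifest:
    """Exact ground truth for one generated suite."""

    seed: int
    params: dict
    true_cliques: list[list[str]]
    expected_node_count_pre: int
    expected_edge_count_pre: int
    expected_canonical_count: int
    expected_canonical_edge_count: int
    planted_duplicates: int
    planted_danglers: int
    detail: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=False)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "SuiteManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _oriented_key(subj: str, obj: str, predicate: str) -> tuple[str, str, str]:
    """The (subject, object, predicate) key after orientation normalization
    — mirrors the model's rules for the fixture predicates."""
    if predicate in _INVERSE_TO_CANONICAL:
        return (obj, subj, _INVERSE_TO_CANONICAL[predicate])
    if predicate in _SYMMETRIC and subj > obj:
        return (obj, subj, predicate)
    return (subj, obj, predicate)


def generate_source_suite(params: SuiteParams | None, seed: int,
                          out_dir: str | Path) -> tuple[SuiteManifest, dict[str, Path]]:
    """Write a synthetic source suite + build config under ``out_dir``.

    Returns the ground-truth manifest and a name -> path map of everything
    written.  Deterministic: the same (params, seed) yields byte-identical
    files and manifest.
    """
    params = params or SuiteParams()
    params.validate()
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    S = params.n_sources
    N = params.n_concepts
    roles = _ROLES[:S]
    prefixes = [r[1] for r in roles]
    tsv_role = 1                       # always present (S >= 2)
    record_role = 2 if S >= 3 else None

    def cid(role: int, i: int) -> str:
        return f"{prefixes[role]}:C{i:04d}"

    # -- concepts and synonym cliques --------------------------------------
    member_sources: list[list[int]] = []
    for i in range(1, N + 1):
        primary = rng.randrange(S)
        members = {primary}
        if S >= 2 and rng.random() < params.synonym_rate:
            k = rng.randint(1, S - 1)
            others = [s for s in range(S) if s != primary]
            members.update(rng.sample(others, k))
        member_sources.append(sorted(members))

    concept_ids: list[list[str]] = [
        [cid(s, i + 1) for s in members]
        for i, members in enumerate(member_sources)
    ]
    clique_index: dict[str, int] = {}
    for i, ids in enumerate(concept_ids):
        for node_id in ids:
            clique_index[node_id] = i

    root_id = f"{prefixes[0]}:C0000"
    clique_index[root_id] = -1
    declared = [root_id] + [node_id for ids in concept_ids for node_id in ids]

    # -- ontology hierarchy -------------------------------------------------
    onto_ids = [cid(0, i + 1) for i, members in enumerate(member_sources)
                if 0 in members]
    subclass_edges: list[tuple[str, str]] = []
    for j, child in enumerate(onto_ids):
        parent = rng.choice([root_id] + onto_ids[:j])
        subclass_edges.append((child, parent))

    # -- equivalence assertions --------------------------------------------
    onto_xrefs: list[tuple[str, str]] = []       # (FONT id, other id)
    tsv_equiv_rows: list[tuple[str, str, str]] = []
    n_equiv = 0
    for i, members in enumerate(member_sources):
        if len(members) < 2:
            continue
        ids = concept_ids[i]
        if 0 in members:
            font = cid(0, i + 1)
            for other in ids:
                if other != font:
                    onto_xrefs.append((font, other))
                    n_equiv += 1
        else:
            for a, b in zip(ids, ids[1:]):
                tsv_equiv_rows.append((a, _EQUIV_RELATION[0], b))
                n_equiv += 1

    # -- planted-key bookkeeping -------------------------------------------
    used_keys: set[tuple[str, str, str]] = set()
    used_canonical: set[tuple] = set()
    for child, parent in subclass_edges:
        used_keys.add((child, parent, "biolink:subclass_of"))
        used_canonical.add((clique_index[child], clique_index[parent],
                            "biolink:subclass_of"))
    for a, b in onto_xrefs:
        used_keys.add((a, b, "biolink:same_as"))
    for a, _, b in tsv_equiv_rows:
        used_keys.add((a, b, "biolink:same_as"))

    def sample_fact(subjects: list[str], relations: dict[str, str | None],
                    ) -> tuple[str, str, str, str]:
        """Draw a (subject, relation, object, predicate) whose oriented and
        canonicalized keys are both fresh and never intra-clique."""
        while True:
            subj = rng.choice(subjects)
            obj = rng.choice(declared)
            if subj == obj or clique_index[subj] == clique_index[obj]:
                continue
            relation = rng.choice(sorted(relations))
            predicate = relations[relation] or _ROOT_PREDICATE
            key = _oriented_key(subj, obj, predicate)
            ci, cj = clique_index[key[0]], clique_index[key[1]]
            if key[2] in _SYMMETRIC:
                # symmetric edges re-normalize direction after canonical
                # remapping, so their canonical key is the unordered pair
                ci, cj = sorted((ci, cj))
            ckey = (ci, cj, key[2])
            if key in used_keys or ckey in used_canonical:
                continue
            used_keys.add(key)
            used_canonical.add(ckey)
            return subj, relation, obj, predicate

    def maybe_pubs() -> list[str]:
        if rng.random() < params.publication_rate:
            return [f"PMID:{rng.randint(10**6, 10**7 - 1)}"]
        return []

    # -- TSV facts -----------------------------------------------------------
    # Triple sources declare nodes only through the triples that mention
    # them, so every TSV-member identifier gets a coverage fact (subject
    # position) in its own source's file before random fill-in.
    tsv_roles = [1] + ([3] if S >= 4 else [])
    fact_rows: dict[int, list[tuple[str, str, str, list[str]]]] = {}
    n_facts = 0
    for role in tsv_roles:
        member_ids = [cid(role, i + 1) for i, members in enumerate(member_sources)
                      if role in members]
        n_rows = 2 * N if role == 1 else max(len(member_ids), N // 4)
        rows: list[tuple[str, str, str, list[str]]] = []
        for member_id in member_ids:
            subj, relation, obj, _pred = sample_fact([member_id], _TSV_RELATIONS)
            rows.append((subj, relation, obj, maybe_pubs()))
        for _ in range(n_rows - len(rows)):
            subj, relation, obj, _pred = sample_fact(declared, _TSV_RELATIONS)
            rows.append((subj, relation, obj, maybe_pubs()))
        fact_rows[role] = rows
        n_facts += len(rows)
    tsv_fact_rows = fact_rows[1]

    # -- record source ------------------------------------------------------
    record_ids = ([cid(record_role, i + 1)
                   for i, members in enumerate(member_sources)
                   if record_role in members]
                  if record_role is not None else [])
    record_links: dict[str, list[dict]] = {rid: [] for rid in record_ids}
    n_record_links = 0
    if record_ids:
        for _ in range(N // 2):
            subj, relation, obj, _pred = sample_fact(record_ids, _RECORD_RELATIONS)
            record_links[subj].append({"relation": relation, "target": obj,
                                       "publications": maybe_pubs()})
            n_record_links += 1

    # -- danglers: links to identifiers no source declares ------------------
    n_danglers = round(params.dangler_rate * n_facts)
    dangler_subclass: list[tuple[str, str]] = []
    for k in range(n_danglers):
        ghost = f"FGHOST:G{k:03d}"
        if record_ids:
            subj = rng.choice(record_ids)
            record_links[subj].append({"relation": "targets", "target": ghost,
                                       "publications": []})
        else:
            subj = rng.choice([root_id] + onto_ids)
            dangler_subclass.append((subj, ghost))

    # -- duplicates: the TSV source re-asserts ontology subclass axioms -----
    n_duplicates = min(round(params.duplicate_rate * n_facts), len(subclass_edges))
    dup_rows = [(child, _DUP_RELATION[0], parent)
                for child, parent in rng.sample(subclass_edges, n_duplicates)]

    # -- write files ---------------------------------------------------------
    paths: dict[str, Path] = {}
    paths["model"] = out_dir / "model.yaml"
    paths["model"].write_text(_render_model(roles), encoding="utf-8")

    paths[roles[0][0]] = out_dir / "ontology.ttl"
    paths[roles[0][0]].write_text(
        _render_ttl(root_id, onto_ids, member_sources, subclass_edges + dangler_subclass,
                    onto_xrefs, prefixes), encoding="utf-8")

    tsv_rows = ([(a, r, b, []) for a, r, b in tsv_equiv_rows]
                + tsv_fact_rows
                + [(a, r, b, []) for a, r, b in dup_rows])
    paths[roles[1][0]] = out_dir / "triples.tsv"
    _write_tsv(paths[roles[1][0]], tsv_rows)

    if record_role is not None:
        records = []
        for i, members in enumerate(member_sources):
            if record_role not in members:
                continue
            rid = cid(record_role, i + 1)
            records.append({"id": rid, "name": f"concept {i + 1}",
                            "category": "drug", "links": record_links[rid]})
        paths[roles[2][0]] = out_dir / "drugs.json"
        with open(paths[roles[2][0]], "w", encoding="utf-8") as fh:
            json.dump({"records": records}, fh, indent=1, sort_keys=False)
            fh.write("\n")

    if S >= 4:
        paths[roles[3][0]] = out_dir / "triples2.tsv"
        _write_tsv(paths[roles[3][0]], fact_rows[3])

    paths["config"] = out_dir / "config.yaml"
    paths["config"].write_text(_render_config(roles, paths), encoding="utf-8")

    # -- manifest ------------------------------------------------------------
    cliques = [ids for ids in concept_ids if len(ids) >= 2]
    singletons = sum(1 for ids in concept_ids if len(ids) == 1)
    node_count_pre = len(declared) + S
    edge_count_pre = len(subclass_edges) + n_equiv + n_facts + n_record_links
    manifest = SuiteManifest(
        seed=seed,
        params=asdict(params),
        true_cliques=[sorted(ids) for ids in cliques],
        expected_node_count_pre=node_count_pre,
        expected_edge_count_pre=edge_count_pre,
        expected_canonical_count=len(cliques) + singletons + 1 + S,
        expected_canonical_edge_count=edge_count_pre - n_equiv,
        planted_duplicates=n_duplicates,
        planted_danglers=n_danglers,
        detail={
            "subclass_edges": len(subclass_edges),
            "equivalence_edges": n_equiv,
            "tsv_facts": n_facts,
            "record_links": n_record_links,
            "sources": [r[0] for r in roles],
        },
    )
    paths["manifest"] = out_dir / "manifest.json"
    manifest.write(paths["manifest"])
    return manifest, paths


def _render_model(roles) -> str:
    lines = []
    for name, _, fmt in roles:
        if fmt == "triple_tsv":
            table = dict(_TSV_RELATIONS)
            table[_EQUIV_RELATION[0]] = _EQUIV_RELATION[1]
            table[_DUP_RELATION[0]] = _DUP_RELATION[1]
        elif fmt == "record_json":
            table = dict(_RECORD_RELATIONS)
        else:
            continue
        for relation in sorted(table):
            predicate = table[relation]
            if predicate is None:
                continue   # left unmapped on purpose: exercises the fallback
            lines.append(f"  - {{source: {name}, relation: {relation}, "
                         f"predicate: {predicate}}}")
    priority = ", ".join(prefix for _, prefix, _ in roles)
    cats = ["biolink:NamedThing", "biolink:Disease", "biolink:Drug", "biolink:Gene",
            "biolink:ChemicalEntity", "biolink:SmallMolecule", "biolink:Pathway",
            "biolink:InformationContentEntity"]
    prio_lines = [f"  {c}: [{priority}]" for c in cats]
    return FIXTURE_MODEL_YAML.format(relation_map="\n".join(lines),
                                     prefix_priority="\n".join(prio_lines))


def _render_ttl(root_id, onto_ids, member_sources, subclass_edges, xrefs,
                prefixes) -> str:
    out = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix oboInOwl: <http://www.geneontology.org/formats/oboInOwl#> .",
        f"@prefix {prefixes[0]}: <{_IRI_BASES[prefixes[0]]}> .",
        "@prefix FGHOST: <" + _IRI_BASES["FGHOST"] + "> .",
        "",
    ]
    parents: dict[str, list[str]] = {}
    for child, parent in subclass_edges:
        parents.setdefault(child, []).append(parent)
    xref_of: dict[str, list[str]] = {}
    for a, b in xrefs:
        xref_of.setdefault(a, []).append(b)
    label_of = {root_id: "fixture root"}
    for i, members in enumerate(member_sources):
        if 0 in members:
            label_of[f"{prefixes[0]}:C{i + 1:04d}"] = f"concept {i + 1}"
    for cls in [root_id] + onto_ids:
        stmts = [f"{cls} a owl:Class", f'    rdfs:label "{label_of[cls]}"']
        stmts += [f"    rdfs:subClassOf {p}" for p in parents.get(cls, [])]
        stmts += [f'    oboInOwl:hasDbXref "{x}"' for x in xref_of.get(cls, [])]
        out.append(" ;\n".join(stmts) + " .")
        out.append("")
    return "\n".join(out)


def _write_tsv(path: Path, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject\trelation\tobject\tpublications\n")
        for subj, relation, obj, pubs in rows:
            fh.write(f"{subj}\t{relation}\t{obj}\t{'|'.join(pubs)}\n")


def _render_config(roles, paths) -> str:
    lines = ["# Build configuration for the synthetic fixture suite.",
             "model: model.yaml", "iri_bases:"]
    for prefix in sorted(_IRI_BASES):
        lines.append(f"  {prefix}: {_IRI_BASES[prefix]}")
    lines.append("sources:")
    for rank, (name, prefix, fmt) in enumerate(roles, start=1):
        lines += [
            f"  - name: {name}",
            f"    version: \"2024-0{rank}\"",
            f"    path: {paths[name].name}",
            f"    format: {fmt}",
            f"    rank: {rank}",
        ]
        if fmt.startswith("ontology"):
            lines += [
                "    prefix_map:",
                f"      {prefix}: {_IRI_BASES[prefix]}",
                f"      FGHOST: {_IRI_BASES['FGHOST']}",
                "    category_rules:",
                "      default: biolink:Disease",
            ]
        elif fmt == "triple_tsv":
            lines += [
                "    category_rules:",
                "      default: biolink:NamedThing",
            ]
        elif fmt == "record_json":
            lines += [
                "    category_hints:",
                "      drug: biolink:Drug",
            ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scale-free graph generator


def generate_scale_free_graph(n: int, exponent: float, seed: int,
                              k_max: int = 10**6) -> GraphDocument:
    """A configuration-model graph with power-law degrees.

    Degrees are drawn i.i.d. from ``p(k) ~ k**-exponent`` on
    ``1 <= k <= k_max`` by inverse-CDF sampling; the total degree is made
    even by incrementing the first node if needed; stubs are shuffled and
    paired.  Multi-edges and self-loops are kept: the realized total-degree
    sequence equals the drawn one exactly, so the handshake identity holds
    by construction.
    """
    if n < 100:
        raise ParameterError(f"n must be >= 100 (got {n})")
    if not exponent > 1:
        raise ParameterError(f"exponent must exceed 1 (got {exponent})")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1, dtype=np.float64)
    pmf = ks ** -float(exponent)
    cdf = np.cumsum(pmf / pmf.sum())
    degrees = np.minimum(np.searchsorted(cdf, rng.random(n)) + 1, k_max)
    if degrees.sum() % 2:
        degrees[0] += 1

    stubs = np.repeat(np.arange(n), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)

    ids = [f"SYN:N{i:06d}" for i in range(n)]
    provider = "KGSOURCE:syntheticScaleFree"
    nodes = [Concept(id=ids[i], name=f"synthetic node {i}",
                     category="biolink:NamedThing", provided_by=[provider])
             for i in range(n)]
    edges = [Assertion(ids[a], ids[b], _ROOT_PREDICATE, relation=["synthetic"],
                       provided_by=[provider])
             for a, b in pairs.tolist()]
    return GraphDocument(nodes, edges, {
        "stage": "synthetic_scale_free",
        "exponent": float(exponent),
        "seed": int(seed),
    })
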