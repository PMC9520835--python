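# Methods

This note documents the models, conventions and numerical choices behind
kgweave, and what its synthetic tests do and do not demonstrate.

## The semantic layer

The toolkit is parameterized by a declarative YAML model supplying: a rooted
category tree (node types), a rooted predicate tree (edge types), inverse
predicate pairs with exactly one canonical member, a set of symmetric
predicates, a per-source relation→predicate map, and per-category ordered
identifier-prefix priority lists.  This is a stand-in for a full
community-standard semantic model: it carries exactly the behaviours the
pipeline consumes (hierarchy closures, orientation, normalization,
identifier priorities) and nothing else — no slots, mixins or cross-ontology
mappings.

Conventions chosen where a convention had to be chosen:

* **Unmapped relations** fall back to the predicate-tree root with a logged
  warning rather than failing the build; the original phrasing is always
  preserved on the edge's `relation` field, so no information is destroyed.
* **Symmetric predicates** are stored in a single normalized direction
  (lexicographically smaller CURIE as subject).  Storage direction for a
  symmetric relation is semantically arbitrary, but a fixed convention makes
  the (subject, object, predicate) coalescing key well defined and merging
  deterministic.  Queries match symmetric edges from either end.
* **Inverse pairs**: edges arriving with the non-canonical member are
  rewritten to the canonical member with endpoints swapped
  (`A part_of B` → `B has_part A`).  Orientation is idempotent.

## Ingestion

Three source families cover the format spectrum of real builds:

* **Ontologies** (TTL / RDF/XML via rdflib), read under a constrained
  subset: class declarations, `rdfs:label`, `rdfs:comment`,
  `rdfs:subClassOf` (hierarchies are preserved, never flattened) and
  `oboInOwl:hasDbXref`.  Cross-references become equivalence *edges*
  (default `biolink:same_as`, configurable per source since not every
  xref in the wild is equivalence-grade) rather than node annotations,
  because the canonicalization partition is driven by edges.  Axioms
  outside the subset are counted and ignored.
* **Triple TSVs** (header `subject/relation/object[/publications]`),
  SemMedDB-like.  Nodes are materialized for every mentioned identifier.
* **Record sources** (JSON/XML), DrugBank-like: one concept per record plus
  typed links.  Link targets are *not* materialized — a link to an
  identifier no source declares must surface as a dangling edge.

Bare identifiers lacking a namespace (e.g. `CHEMBL112`) are repaired to
CURIEs through per-source prefix rules (longest leading-alphabetic match);
irreparable tokens skip the row with a logged warning.  Row- and
record-level problems never abort an ingest: they are logged, skipped and
counted, mirroring build-supervisor workflows where problematic content is
investigated offline.  IRIs are computed from a configured prefix→IRI-base
table, with an identifiers.org-style fallback.

## Merge

Nodes with identical CURIEs are unified across sources.  Precedence is the
configured source rank (lower = loaded earlier = wins): the category comes
from the highest-precedence source, and name/description take the first
non-empty value in precedence order — one knob for all conflict families.
Edges are coalesced on (subject, object, predicate) with `relation`,
`provided_by` and `publications` unioned in first-seen order.  Edges with an
undeclared endpoint are **removed** and logged, not auto-materialized:
silently inventing nodes would corrupt category statistics.  The merge log
maintains the exact identity *input edges = output + coalesced + dangling*.

## Canonicalization

Five steps: load the pre graph; partition nodes into equivalence blocks;
elect a canonical identifier per block; remap edges; merge same-key edges.

* **Blocks are connected components** (union-find) of the subgraph induced
  by the equivalence predicate set's descendant closure (default
  `same_as` + descendants).  Components, not literal cliques: synonymy
  asserted as a chain (A=B, B=C) must land in one block even though A–C is
  never asserted directly.
* **Election**: the block's *dominant category* is the category of the
  member provided by the highest-precedence source; the model's prefix
  priority list for that category ranks members (unlisted prefixes last),
  with lexicographic CURIE order as the final tie-break.  Everything is
  deterministic.
* The canonical node keeps the canonical member's name (falling back to any
  non-empty member name), unions provenance/publications, records all
  member categories in `all_categories`, all identifiers in
  `equivalent_identifiers`, and concatenates member descriptions tagged
  with their source identifier.
* Equivalence edges necessarily become within-block self-loops and are
  dropped (counted).  *Substantive* self-loops created by remapping (e.g. a
  treats edge between two members of one block) are retained and logged —
  dropping them would silently destroy assertions.

Name-similarity or external-synonym-table signals do not participate in
block formation; the partition is purely graph-edge-driven.  This is a
deliberate scope boundary and the natural extension point.

## QC and statistics

Reports count nodes and edges by source, category and predicate (per-source
counts attribute an entity once per providing source, so their sums may
exceed totals — documented behaviour, since the alternative attribution is
equally defensible).  Cross-build comparison flags any key whose count
ratio strictly exceeds the fold threshold (default 3) in either direction;
keys appearing from or vanishing to zero are flagged with dedicated reasons
because a ratio is undefined there.

Total degree is in+out with self-loops contributing 2; the histogram
satisfies Σ count = n and Σ k·count(k) = 2E identically.

**Power-law fitting.**  The default estimator is the exact discrete MLE:
α̂ solves −d/dα ln ζ(α, x_min) = mean(ln k) via Brent's method on a
bracketed interval (ζ is the Hurwitz zeta; the derivative is evaluated by
central difference at h = 10⁻⁶, far below the estimator's sampling error).
The widely quoted closed form α ≈ 1 + n/Σ ln(k_i/(x_min−½)) is exposed as
`method="approx"`: it is a continuous-distribution approximation whose bias
is substantial at x_min = 1 (it estimates ≈ 1.99 when the true exponent is
2.43) and only becomes acceptable for x_min ≳ 6, so it is not the default.
Degenerate inputs: fewer than two distinct degrees at/above x_min raise an
estimation error; a vanishing log-sum returns a degenerate-flagged fit.
x_min selection by KS minimization and goodness-of-fit testing are out of
scope.

Meta-triples: each edge increments every (subject category, predicate,
object category) cell drawn from its endpoints' category sets — on
canonicalized graphs the full product |cats(s)| × |cats(o)|, which is why
canonicalization *increases* meta-triple counts while shrinking nodes and
edges.

## Query engine

One-hop queries follow the TRAPI message skeleton: exactly two query nodes
and one query edge, at least one node pinned by ids.  Category and
predicate constraints expand to descendant closures — hierarchical matching
is the point of a typed layer, and subclass matching is what TRAPI
consumers expect.  Identifier lookup resolves through
`equivalent_identifiers`.  Results are deduplicated and ordered by
descending provenance-source count, then lexicographic binding — a
documented deterministic order chosen purely for reproducibility, since no
standard ranking criterion exists for bare one-hop lookups.  The returned
`knowledge_graph` contains exactly the bound nodes and edges.

## Build runner

An internal DAG executor (per-source ingest → merge → canonicalize →
statistics) with content-hash-based skipping: an ingest stage is skippable
iff its source file's SHA-256 is unchanged from the previous build and its
output exists, so unchanged sources are ignored until the merge step.
Hashes, never timestamps, for reproducibility.  Stages communicate through
files; independent ingest stages may run on a thread pool, and outputs are
byte-identical regardless of worker count.  An external workflow tool is
deliberately not required.

## The synthetic suite: what it emulates and what it does not

`generate_source_suite` emulates the *structural* phenomena the pipeline
must handle: overlapping sources asserting one concept under different
identifier prefixes (synonym cliques linked by xrefs or `same_as` triples,
including transitive chains), cross-source duplicate triples (the TSV
source re-asserting ontology subclass axioms), publication-annotated NLP
triples, record links to undeclared identifiers (danglers), an unmapped
relation exercising the root fallback, inverse-pair and symmetric-predicate
facts exercising orientation.  Default conditions: 50 concepts, 3 sources
(ontology TTL, triple TSV, record JSON), synonym rate 0.3, duplicate rate
0.1, dangler rate 0.05, publication rate 0.5 — small enough to audit by
hand, dense enough that every mechanism fires on every seed.  All sampling
is rejection-guarded so that the planted (subject, object, predicate) keys
are unique at *both* the pre and the canonical level; the manifest is
therefore an exact function of (parameters, seed), and the end-to-end test
demands exact equality, not tolerance.

What passing these tests shows: the mechanics — identifier algebra,
precedence, coalescing, partition/election, screening, statistics — are
exact on inputs whose ground truth is known.  What it does not show:
robustness to the *content* messiness of real distributions (inconsistent
xref semantics, malformed records at scale, category systems with thousands
of types), nor performance at 10⁷-node scale; the in-memory containers and
single-pass algorithms here target desk scale.

`generate_scale_free_graph` draws degrees i.i.d. from the discrete power law
p(k) ∝ k^−α on 1 ≤ k ≤ 10⁶ by inverse-CDF lookup, forces the total even by
incrementing the first node, and pairs shuffled stubs (configuration
model).  Multi-edges and self-loops are kept, so the realized total-degree
sequence equals the drawn one exactly and the handshake identity is exact
by construction.  Estimator-recovery runs use n = 10⁵ nodes — large enough
that the MLE's sampling error (≈ (α−1)/√n ≈ 0.005) sits well inside the
±0.05 recovery band, small enough to run in seconds.

## Known limitations

* No full OWL semantics; only the constrained ontology subset is read.
* Cross-source *semantic* deduplication happens only through asserted
  equivalence edges; no string matching or external synonym tables.
* The JSON/TSV dialects are this package's published formats (documented in
  `src/kgweave/schemas/`), not byte-level clones of any external system's
  files; the TSV dialect rejects tab/newline/pipe in values rather than
  escaping them, trading expressiveness for bit-exact round-trips.
* One-hop queries only; no multi-hop reasoning, scoring overlays, or full
  TRAPI conformance (attribute constraints, workflow operations).
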