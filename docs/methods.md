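# Methods

## The provenance model

`semprov` treats provenance as a typed RDF graph governed by a small
upper-level schema. Three top-level classes cover what provenance talks
about: `data` (anything consumed or produced), `process` (anything that
happens) and `agent` (anyone or anything responsible). `data` specializes
into `data_collection` — entities that participate in experiments or
analyses, the inputs to the `provenance()` operator — and `parameter`,
itself split along spatial, temporal and thematic dimensions
(`spatial_parameter`, `temporal_parameter`, `domain_parameter`): eight
classes in all. Eleven named relationships connect them; ten (`part_of`,
`contained_in`, `located_in`, `adjacent_to`, `transformation_of`,
`derives_from`, `preceded_by`, `has_participant`, `has_agent`,
`has_parameter`) follow the OBO Relation ontology's inventory of fundamental
relations, and `has_temporal_value` anchors processes to temporal
parameters. The registry is configurable, but five relationships are
mandatory because the query operators and the triple classifier are defined
over them: `preceded_by` (process→process), `derives_from` (data→data),
`has_agent`, `has_participant` and `has_parameter` (process→component).

Domain ontologies are built by monotone extension: new classes and
properties declare parents via `rdfs:subClassOf`/`rdfs:subPropertyOf`, a
child property's domain and range must refine its parent's, the subclass
relation must stay acyclic, and single inheritance is enforced — multiple
parents would buy nothing here and would complicate closure computation and
validation. Reasoning is deliberately limited to subclass/subproperty
closure and domain/range checking; full description-logic classification is
out of scope, because every use the toolkit makes of entailment (query
expansion, pattern validation, classification) needs only those closures.

## Pattern validation and instantiation

A provenance pattern is an ordered chain of classes, each linked to its
predecessor by a named relationship. Validation checks, per element, that
the class exists and that the connecting property's declared domain/range
subsume the adjacent classes; violations are reported, not raised, so a UI
can display them. Instantiation mints instance IRIs deterministically
(`namespace + class + "/" + counter`, overridable by caller-supplied
identifiers), types each node, attaches literal values via `rdf:value`
(validated against a class's declared datatype where one exists, e.g.
decimal temperatures), and links consecutive nodes with the pattern's
properties. A field may be skipped: its node is still created and typed so
the chain stays connected, but carries no value. Nominal form values
("High"/"Medium"/"Low") are emitted as literals on typed nodes by default;
passing a `URIRef` as the value makes the node itself the individual, so
both readings are available.

## Contextualized provenance encoding

The encoder represents statement-level provenance without reification.
A *provenance context* fixes a base IRI, the schema classes whose instances
carry context (each must specialize `data`), and the linking relationship —
`derives_from` by default, since a source-specific entity occurrence derives
from its source document. Every component of an extracted statement is
minted a contextualized IRI `base/‹context string›/‹entity name›`, where the
context string is the normalized source identifier. `mint_uri` percent-encodes
entity names verbatim and round-trips through `parse_uri`; extraction labels
are first normalized (trim, internal whitespace → `_`) because text-mined
labels routinely contain spaces.

Three granularities attach components to the source node
(`base/source/‹id›`): minimal links the subject only (1 triple),
intermediate the subject and predicate (2), exhaustive all three (3). The
intermediate mode's assumption — the object shares the subject's source —
is recorded once per graph as a flag triple so downstream consumers can
detect it; the flag is an assembly-level annotation and is excluded from
per-encoding cost summaries (which would otherwise lose strict ordering on
single-assertion batches). The reification baseline emits the plain
assertion triple, a statement node with exactly the four syntactic artifact
triples, and one attachment — the artifacts are counted as *extra* relative
to the asserted triple. Cost summaries count distinct triples, consistent
with single-graph set semantics: the assertion triple and `rdf:type` triples
are data, attachments/artifacts/annotations are provenance-specific, so
total = data + provenance holds and per-assertion costs are 1/2/3
(contextualized) vs 5 (reified) provenance triples.

Extraction metadata is typed through a shipped schema extension
(`extracted_entity` under `data_collection`, `extracted_relation` under
`data`, plus annotation relationships for confidence, publication year,
journal impact factor, source type/version). Registering the annotations as
schema properties is what lets provenance constraints be schema-typed and
makes the storage classifier agree with the encoder's ground-truth labels.

## Storage, classification, propagation

Data and provenance share one graph, because the data/provenance split is
application-relative (an incubation temperature is provenance for a
knockout experiment but data in a clinical record). The census rule is
schema-driven: a triple is provenance-specific iff its predicate is a schema
relationship (subproperties included by declaration) or its subject/object
is a transitive instance of `process`, `agent` or `parameter`. Counts are
instance-level; schema (TBox) triples are serialized separately and never
enter the census. `propagate()` exports the induced subgraph over the
bidirectional closure of schema-relationship edges from the requested
entities — bidirectional because creating processes point *at* their
outputs via `has_participant` while `preceded_by` points backwards — which
makes the export self-contained (types and literal annotations of every
closure node travel along) and monotone in the entity set.

Graphs read and write Turtle, N-Triples and RDF/XML through rdflib; TriG
input is accepted and collapsed to the default graph. N-Triples output is
canonicalized (sorted) so equal graphs serialize byte-identically, which is
what the determinism guarantees are stated over.

## Query operators

`provenance(e)` requires `e` to be a `data_collection` instance and returns:
`e`'s own triples; every process holding `e` as participant, closed
transitively over `preceded_by`; and per process its types, chain links,
agents, participants and parameters with their types and literal
annotations. Matching is best-effort — absent components shrink the result,
never fail — mirroring SPARQL `OPTIONAL` semantics, and deleting provenance
triples can only shrink the result to a subgraph. Provenance-of-provenance
is included to one level (the literal annotations of chain components), a
deliberate default.

`provenance_context(constraints)` evaluates each constraint existentially
over an entity's *scope* — the entity, its direct IRI objects, its creating
process chain, and the chain's components — and conjoins constraints.
Comparators are `= < > <= >= contains`; order comparators require numeric
values and silently fail (rather than error) on non-numeric literals, so a
malformed annotation never satisfies a threshold. The scope definition is
pinned identically in the direct implementation and the composed SPARQL
(a UNION of four scope branches per constraint), and the two routes are
cross-validated in the tests.

`provenance_compare(g1, g2)` abstracts instance IRIs to anonymous nodes
(schema class/property IRIs, standard vocabularies and literals are kept)
and tests graph isomorphism via rdflib's canonical comparison — so two runs
of the same protocol with the same parameter values compare equal whatever
their instance naming, while a single differing literal breaks equality.
Literal comparison is exact by default; an optional numeric tolerance
quantizes numeric literals to a step before comparison.

`provenance_merge(g1, g2)` returns the triple-set union and, for each data
entity participating in processes on both sides, adds one bridging
`preceded_by` link from the later phase's earliest process (no outgoing
`preceded_by`) to the earlier phase's latest (no incoming) — unless the two
are already closure-connected, a guard that keeps self-merge idempotent and
cycle-free. Ties are broken lexicographically for determinism.

Transitive closure over `⟨process, preceded_by⟩` — which SPARQL lacks as a
primitive — issues `ASK` probes of increasing path length, stopping at the
first `false`; a visited set plus a node-count bound guarantees termination
on cycles, and equal-depth discoveries are ordered lexicographically.

`compose_sparql` emits each operator as SPARQL 1.1 text: property positions
expand to subproperty `VALUES`/path alternations and class positions to
subclass `VALUES` (the RDFS-entailment expansion), provenance components sit
in `OPTIONAL` blocks (nesting capped at 50), and the returned `QueryPattern`
carries recomputable complexity metrics (distinct variables, triple
patterns, `OPTIONAL` nesting depth). The composed text executed by rdflib's
SPARQL engine must — and in the test suite does — reproduce the direct
implementations exactly. `provenance_compare`/`provenance_merge` compose to
the graph-extraction query; equivalence and union+bridging are computed on
the results, as they are graph-level rather than pattern-level operations.

Materialized provenance views cache `provenance()` results keyed per entity.
Staleness is tracked by a base-graph version counter: any mutation stales
every view on that graph — deliberately coarser than per-view overlap
tracking, because additions can make previously irrelevant triples relevant
to a view, and correctness (never serve stale data) dominates cache
retention here. Stale views fall through to fresh evaluation and are
rebuilt, so cached and uncached answers are always identical.

## Synthetic study conditions

The protocol generator emulates reverse-genetics provenance: by default four
steps (gene knockout → transfection → drug selection → cloning), each with
a three-researcher agent pool and the parameters such protocols record —
target gene (choice of six), transfection method (sonication or
electroporation), selection antibiotic (neomycin or hygromycin), drug
concentration (uniform 50–500), incubation temperature (uniform 24–37 °C) —
and two cloned samples per run. Each step consumes the previous sample and
produces the next (`derives_from`), and every triple is labeled
data/provenance at creation, so the classifier and operators are tested
against construction-time truth, not against themselves. Under these
defaults the provenance-specific share of a store is ≈ 87%, within the high
(87–98%) range characteristic of real experiment-provenance stores.

The corpus generator emulates literature extraction: assertions drawn from
disjoint subject/object name pools (no reflexive statements), five relation
types, confidence uniform on 0–10 (the scale extraction tools commonly
report), publication years uniform on 2000–2011 and one impact factor per
source uniform on 0.5–15. Sources are assigned in balanced fashion
(⌊n/k⌋ per source plus a sampled remainder, then shuffled) rather than
i.i.d., guaranteeing every source is used while staying near-uniform. Both
generators use a single `random.Random(seed)` stream; identical specs and
seeds reproduce byte-identical canonical serializations.

What the synthetic conditions do *not* capture: real protocol graphs are
irregular (missing annotations, heterogeneous step counts, shared samples
across runs), extraction corpora have heavy-tailed source and confidence
distributions, and real stores reach tens or hundreds of millions of
triples. Passing tests therefore establish correctness of the algorithms
and encodings, not performance at repository scale; the large-scale
query-latency behaviour of materialized views is explicitly out of scope.

## Numerical and size choices

Tests and the acceptance script run protocol graphs of 1–50 runs (hundreds
to a few thousand triples) and corpora of up to 1000 assertions — sizes
chosen so the whole suite exercises every operator, both evaluation routes
and 100 independently seeded oracle comparisons in well under a minute of
CPU. Literal equality in comparison is exact by default; numeric constraint
evaluation coerces through `float`. Discovery order everywhere is
depth-first by level with lexicographic IRI tie-breaks, so all outputs are
deterministic. Degenerate inputs are defined rather than accidental: empty
batches encode to empty graphs with zero counts, zero-run generation yields
an empty instance graph, empty constraint lists return all data entities,
and `merge(g, ∅) = g`.
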