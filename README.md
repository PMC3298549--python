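# semprov

A semantic provenance management toolkit for translational-research data.

Biomedical data accumulates provenance on both sides of publication: at the
bench (which knockout process, with which antibiotic and concentration,
produced this cloned sample?) and downstream of the literature (which
article asserted this subject–relation–object statement, with what extraction
confidence, in a journal of what impact factor?). `semprov` manages that
metadata end to end:

* **Representation** — an upper-level provenance schema with three top
  classes (`data`, `process`, `agent`), five parameter/data subclasses and
  eleven named relationships (`preceded_by`, `derives_from`, `has_agent`,
  `has_participant`, `has_parameter`, …), extensible into domain ontologies
  via `rdfs:subClassOf` / `rdfs:subPropertyOf` with cycle and
  domain/range-refinement checking.
* **Collection** — provenance *patterns* (chains of classes linked by
  relationships) validated against a schema, and deterministic instantiation
  of form-style field/value records into RDF.
* **Encoding** — contextualized provenance triples instead of RDF
  reification. Reifying one statement costs four syntactic artifact triples
  (`rdf:Statement`, `rdf:subject`, `rdf:predicate`, `rdf:object`) that carry
  no provenance content. The contextualized encoding instead mints
  source-specific IRIs, `base/‹context string›/‹entity name›`, e.g.
  `http://mor.nlm.nih.gov/bkr/PUBMED_17209178/lipoprotein`, and attaches the
  subject only (*minimal*, 1 extra triple), subject + predicate
  (*intermediate*, 2), or subject + predicate + object (*exhaustive*, 3) to
  the source node — always strictly cheaper than reification, with no blank
  nodes.
* **Storage & propagation** — data and provenance live in one RDF graph;
  triples are classified as provenance-specific by schema rules, and
  `propagate()` exports self-contained provenance bundles alongside the data.
* **Query** — four operators: `provenance(entity)` (the creating process
  chain with agents, participants and parameters, best-match under
  incomplete provenance), `provenance_context(constraints)` (data entities
  whose provenance passes constraints such as `confidence > 8`),
  `provenance_compare(g1, g2)` (equivalence up to instance renaming) and
  `provenance_merge(g1, g2)` (union with a bridging `preceded_by` link
  between protocol phases). Each operator is also emitted as SPARQL with
  subclass/subproperty expansion and `OPTIONAL`-wrapped components;
  transitive closure over `⟨process, preceded_by⟩` is computed by `ASK`
  probes of growing path length; materialized provenance views cache
  repeated queries transparently.
* **Synthesis** — seeded generators for protocol provenance chains and
  extraction corpora, with per-triple ground-truth labels so every operator
  can be tested against construction-time truth.

## Worked example

Encode the statement *lipoprotein → affects → inflammatory_cells*, extracted
from the article PMID 17209178, at every granularity:

```python
import semprov as sp

ctx = sp.default_extraction_context()          # base http://mor.nlm.nih.gov/bkr
assertion = sp.SourcedAssertion(
    "lipoprotein", "affects", "inflammatory_cells",
    sp.SourceDescriptor("literature", "PUBMED_17209178"),
)
for mode in ("minimal", "intermediate", "exhaustive", "reify"):
    s = sp.count_provenance_triples([assertion], mode, ctx)
    print(mode, s.total_triples, s.provenance_triples)
```

prints

```
minimal 3 2
intermediate 4 3
exhaustive 5 4
reify 7 6
```

— one data triple each, plus 1/2/3 provenance triples under the
contextualized encodings against 6 (4 reification artifacts + attachment +
source annotation) under reification. The intermediate encoding itself:

```
<…/bkr/PUBMED_17209178/lipoprotein> <…/bkr/PUBMED_17209178/affects> <…/bkr/PUBMED_17209178/inflammatory_cells> .
<…/bkr/PUBMED_17209178/lipoprotein> provenir:derives_from <…/bkr/source/PUBMED_17209178> .
<…/bkr/PUBMED_17209178/affects>     provenir:derives_from <…/bkr/source/PUBMED_17209178> .
<…/bkr/source/PUBMED_17209178>      sp:source_type "literature" .
```

The subject and predicate are linked to the source; the object's source is
assumed shared (the graph records that assumption as a flag triple).

From the shell, the same pipeline plus a constraint query:

```bash
semprov generate corpus --seed 1 --n 1000 --sources 50 --out corpus.tsv
semprov encode --corpus corpus.tsv --mode intermediate --out bkr.nt
semprov stats --graph bkr.nt
semprov query context --graph bkr.nt \
    --constraint "confidence > 8" \
    --constraint "publication_year > 2007" \
    --constraint "impact_factor > 5"
```

`stats` prints the data/provenance census of the single-graph store
(`total_triples=…`, `provenance_triples=…`, `provenance_fraction=…`), and
`query context` lists the contextualized IRIs of the entities whose
provenance clears all three thresholds. On the bench side,
`semprov generate protocol` emits a knockout → transfection →
drug-selection → cloning provenance graph, `semprov query provenance
--entity <cloned sample>` retrieves the drug and concentration used to
create it, and `semprov closure --start <process>` walks the process chain
backwards.

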