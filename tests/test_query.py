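"""Query operators vs brute-force oracles, SPARQL cross-validation, MPV."""

import random

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from semprov import pace, synth
from semprov.errors import (
    CompositionError,
    ConstraintError,
    LookupError_,
    MergeError,
    PreconditionError,
)
from semprov.namespaces import VALUE
from semprov.query import (
    ProvenanceConstraint,
    ViewCache,
    build_mpv,
    compose_sparql,
    execute_operator_sparql,
    provenance,
    provenance_compare,
    provenance_context,
    provenance_merge,
    query_with_mpv,
    transitive_closure,
)
from semprov.store import ProvenanceGraph

EX = "http://example.org/t/"


# ---------------------------------------------------------------------------
# independent oracles (plain traversals over the triple set, written without
# reference to the engine internals)
# ---------------------------------------------------------------------------


def oracle_provenance(pg, entity):
    """Brute-force reachable-provenance: linking processes, their
    preceded_by closure, and per-process components with types/literals."""
    schema = pg.schema
    sub = lambda name: {p.uri for p in schema.subproperties(name)}  # noqa: E731
    part, pre = sub("has_participant"), sub("preceded_by")
    comp = sub("has_agent") | sub("has_participant") | sub("has_parameter")
    triples = set(pg.graph)
    out = {t for t in triples if t[0] == entity}
    procs = {s for s, p, o in triples if o == entity and p in part}
    grown = True
    while grown:
        grown = False
        for s, p, o in triples:
            if s in procs and p in pre and o not in procs:
                procs.add(o)
                grown = True
    for s, p, o in triples:
        if s in procs:
            if p == RDF.type or p in pre:
                out.add((s, p, o))
            elif p in comp:
                out.add((s, p, o))
                for s2, p2, o2 in triples:
                    if s2 == o and (p2 == RDF.type or isinstance(o2, Literal)):
                        out.add((s2, p2, o2))
    return out


def oracle_closure(pg, start, prop_name="preceded_by"):
    """BFS with a visited set and lexicographic tie-break per depth."""
    uris = {p.uri for p in pg.schema.subproperties(prop_name)}
    adj = {}
    for s, p, o in pg.graph:
        if p in uris:
            adj.setdefault(s, set()).add(o)
    visited, order, frontier = {start}, [], [start]
    while frontier:
        nxt = sorted(
            {o for n in frontier for o in adj.get(n, set()) if o not in visited},
            key=str,
        )
        visited.update(nxt)
        order.extend(nxt)
        frontier = nxt
    return order


def random_protocol_graph(seed):
    """A randomized protocol graph: varying steps, params, runs, branching."""
    rng = random.Random(seed)
    classes = [
        "gene_knockout_process",
        "transfection_process",
        "drug_selection_process",
        "cloning_process",
        "plasmid_construction_process",
    ]
    params = ["target_gene", "antibiotic", "drug_concentration", "temperature", "priority"]
    steps = []
    for i in range(rng.randint(1, 4)):
        chosen = rng.sample(params, rng.randint(0, 2))
        steps.append(
            synth.StepSpec(
                rng.choice(classes),
                params=tuple(
                    synth.ParamSpec(p, ("choice", ("a", "b", "c")))
                    if p in ("target_gene", "antibiotic", "priority")
                    else synth.ParamSpec(p, ("uniform", 1.0, 9.0))
                    for p in chosen
                ),
                agent_pool=rng.randint(1, 3),
            )
        )
    spec = synth.ProtocolSpec(
        steps=tuple(steps), samples_per_run=rng.randint(1, 3), seed=seed
    )
    return synth.generate_experiment_graph(spec, n_runs=rng.randint(1, 4))


class TestProvenance:
    def test_drug_and_concentration_reachable_from_cloned_sample(self, protocol_result):
        """The provenance of a final cloned sample must surface the drug and
        concentration used during selection (the canonical retrieval query)."""
        pg = protocol_result.graph
        run = protocol_result.runs[0]
        sub = provenance(pg, run.final_samples[0])
        wanted = {
            rec.node
            for rec in protocol_result.records
            if rec.run == run.index and rec.param_class in ("antibiotic", "drug_concentration")
        }
        assert wanted
        for node in wanted:
            assert next(sub.graph.triples((node, VALUE, None)), None) is not None

    def test_entity_without_provenance_edges_returns_own_triples(self, demo_schema):
        pg = ProvenanceGraph(demo_schema)
        e = URIRef(EX + "orphan")
        pg.add((e, RDF.type, demo_schema.cls("sample").uri))
        pg.add((e, VALUE, Literal("x")))
        # unrelated triple must not leak in
        pg.add((URIRef(EX + "other"), RDF.type, demo_schema.cls("sample").uri))
        assert provenance(pg, e).triples() == {
            (e, RDF.type, demo_schema.cls("sample").uri),
            (e, VALUE, Literal("x")),
        }

    def test_unknown_entity_raises_lookup(self, protocol_result):
        with pytest.raises(LookupError_):
            provenance(protocol_result.graph, URIRef(EX + "nope"))

    def test_non_data_collection_instance_rejected(self, protocol_result):
        proc = protocol_result.runs[0].processes[0]
        with pytest.raises(PreconditionError):
            provenance(protocol_result.graph, proc)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle_on_random_graphs(self, seed):
        result = random_protocol_graph(seed)
        pg = result.graph
        for e in result.final_samples[:3]:
            assert provenance(pg, e).triples() == oracle_provenance(pg, e)

    def test_best_match_shrinks_under_deletion(self, protocol_result):
        """Removing provenance never makes the operator fail; the result
        contracts to a subgraph."""
        pg = protocol_result.graph.copy()
        e = protocol_result.runs[0].final_samples[0]
        before = provenance(pg, e).triples()
        rng = random.Random(0)
        prov_triples = [t for t, lab in pg.labels.items() if lab == "provenance"]
        for t in rng.sample(prov_triples, len(prov_triples) // 2):
            if t[1] == RDF.type and t[0] == e:
                continue  # keep the entity typed (operator precondition)
            pg.remove(t)
        after = provenance(pg, e).triples()
        assert after <= before


class TestProvenanceContext:
    def _expected(self, corpus, ctx, conf_min, year_min, if_min):
        by_entity = {}
        for r in corpus.records:
            iri = pace.mint_uri(
                ctx.base_uri, r["source_id"], pace.normalize_entity_name(r["subject"])
            ).render()
            by_entity.setdefault(iri, []).append(r)
        return {
            iri
            for iri, rs in by_entity.items()
            if any(r["confidence"] > conf_min for r in rs)
            and any(r["year"] > year_min for r in rs)
            and any(r["impact_factor"] > if_min for r in rs)
        }

    def test_matches_record_filter_oracle(self, corpus_graph):
        corpus, ctx, pg = corpus_graph
        constraints = [
            ProvenanceConstraint("impact_factor", ">", 5.0),
            ProvenanceConstraint("publication_year", ">", 2007),
            ProvenanceConstraint("confidence", ">", 8.0),
        ]
        got = provenance_context(pg, constraints)
        expected = self._expected(corpus, ctx, 8.0, 2007, 5.0)
        assert got == expected
        assert expected  # non-vacuous under the default study conditions

    def test_empty_constraints_return_all_data_entities(self, corpus_graph):
        corpus, ctx, pg = corpus_graph
        got = provenance_context(pg, [])
        dc = {c.uri for c in pg.schema.subclasses("data_collection")}
        expected = {s for s, _, o in pg.graph.triples((None, RDF.type, None)) if o in dc}
        assert got == expected

    def test_unsatisfiable_constraint_yields_empty_set(self, corpus_graph):
        _, _, pg = corpus_graph
        assert provenance_context(pg, [ProvenanceConstraint("confidence", ">", 10.0)]) == set()

    def test_unknown_target_rejected_even_on_empty_graph(self, extraction_ctx):
        pg = ProvenanceGraph(extraction_ctx.schema)
        with pytest.raises(ConstraintError):
            provenance_context(pg, [ProvenanceConstraint("reputation", ">", 1)])

    def test_parameter_constraint_on_protocol_graph(self, protocol_result):
        """Class-targeted constraint: samples created at temperature above a
        cutoff — checked against the generator's parameter records."""
        pg = protocol_result.graph
        cutoff = 30.0
        got = provenance_context(pg, [ProvenanceConstraint("temperature", ">", cutoff)])
        hot_runs = {
            rec.run
            for rec in protocol_result.records
            if rec.param_class == "temperature" and float(rec.value) > cutoff
        }
        # the cloning process (which carries the temperature) participates
        # with its input sample (s3 in the 4-step default) and the cloned
        # outputs; earlier samples never see it in their chain scope
        ns = "http://example.org/tcruzi/"
        expected = set()
        for run in protocol_result.runs:
            if run.index in hot_runs:
                expected.update(run.final_samples)
                expected.add(URIRef(f"{ns}sample/r{run.index}_s3"))
        assert got == expected

    def test_comparator_validation(self):
        with pytest.raises(ConstraintError):
            ProvenanceConstraint("confidence", ">", "high")
        with pytest.raises(ConstraintError):
            ProvenanceConstraint("confidence", "~", 1)

    def test_constraint_parsing(self):
        c = ProvenanceConstraint.parse("confidence > 8")
        assert (c.target, c.comparator, c.value) == ("confidence", ">", 8)
        c2 = ProvenanceConstraint.parse("predicate_name contains affect")
        assert c2.comparator == "contains"


class TestCompare:
    def test_reflexive(self, protocol_result):
        g = protocol_result.graph
        assert provenance_compare(g, g) is True

    def test_same_spec_different_instance_ids_equal(self):
        spec = synth.default_protocol_spec(seed=23)
        g1 = synth.generate_experiment_graph(spec, 2, instance_namespace="http://a.org/i/").graph
        g2 = synth.generate_experiment_graph(spec, 2, instance_namespace="http://b.org/j/").graph
        assert provenance_compare(g1, g2) is True
        assert provenance_compare(g2, g1) is True  # symmetric

    def test_differing_parameter_literal_not_equal(self):
        spec = synth.default_protocol_spec(seed=23)
        r1 = synth.generate_experiment_graph(spec, 2)
        r2 = synth.generate_experiment_graph(spec, 2, instance_namespace="http://b.org/j/")
        g2 = r2.graph
        temp = next(r for r in r2.records if r.param_class == "temperature")
        old = next(t for t in g2.graph.triples((temp.node, VALUE, None)))
        g2.remove(old)
        g2.add((temp.node, VALUE, Literal("99.9", datatype=old[2].datatype)))
        assert provenance_compare(r1.graph, g2) is False

    def test_numeric_tolerance_quantizes(self, demo_schema):
        def one(value):
            pg = ProvenanceGraph(demo_schema)
            n = URIRef(EX + "prm")
            pg.add((n, RDF.type, demo_schema.cls("temperature").uri))
            pg.add((n, VALUE, Literal(value)))
            return pg

        assert provenance_compare(one(36.50), one(36.52), numeric_tolerance=0.1)
        assert not provenance_compare(one(36.50), one(37.2), numeric_tolerance=0.1)

    def test_empty_graph_rejected(self, demo_schema, protocol_result):
        with pytest.raises(PreconditionError):
            provenance_compare(ProvenanceGraph(demo_schema), protocol_result.graph)


class TestMerge:
    def _phase(self, schema, ns, proc_cls, shared):
        pg = ProvenanceGraph(schema)
        p = URIRef(ns + "proc")
        pg.add((p, RDF.type, schema.cls(proc_cls).uri), "provenance")
        pg.add((shared, RDF.type, schema.cls("sample").uri), "data")
        pg.add((p, schema.prop("has_participant").uri, shared), "provenance")
        return pg, p

    def test_merge_with_empty_is_identity(self, protocol_result):
        g = protocol_result.graph
        empty = ProvenanceGraph(g.schema)
        assert provenance_merge(g, empty) == g

    def test_bridge_added_between_phases(self, demo_schema):
        shared = URIRef(EX + "ko_sample")
        g1, p1 = self._phase(demo_schema, EX + "ko/", "gene_knockout_process", shared)
        g2, p2 = self._phase(demo_schema, EX + "sc/", "drug_selection_process", shared)
        merged = provenance_merge(g1, g2)
        overlap = g1.triples() & g2.triples()
        assert len(merged) == len(g1) + len(g2) - len(overlap) + 1
        bridge = (p2, demo_schema.prop("preceded_by").uri, p1)
        assert bridge in merged
        # the merged chain is closure-traversable end to end
        assert transitive_closure(merged, p2) == [p1]

    def test_commutative_up_to_isomorphism_on_disjoint_graphs(self, demo_schema):
        g1, _ = self._phase(demo_schema, EX + "a/", "gene_knockout_process", URIRef(EX + "s1"))
        g2, _ = self._phase(demo_schema, EX + "b/", "cloning_process", URIRef(EX + "s2"))
        m12 = provenance_merge(g1, g2)
        m21 = provenance_merge(g2, g1)
        assert m12.triples() == m21.triples()

    def test_self_merge_adds_no_cycle(self, protocol_result):
        g = protocol_result.graph
        assert provenance_merge(g, g) == g

    def test_schema_mismatch_rejected(self, demo_schema, provenir):
        g1 = ProvenanceGraph(demo_schema)
        g1.add((URIRef(EX + "a"), RDF.type, demo_schema.cls("sample").uri))
        g2 = ProvenanceGraph(provenir)
        g2.add((URIRef(EX + "b"), RDF.type, provenir.cls("data").uri))
        with pytest.raises(MergeError):
            provenance_merge(g1, g2)


class TestTransitiveClosure:
    def test_no_outgoing_edges_empty(self, demo_schema):
        pg = ProvenanceGraph(demo_schema)
        p = URIRef(EX + "p")
        pg.add((p, RDF.type, demo_schema.cls("cloning_process").uri))
        assert transitive_closure(pg, p) == []

    def test_three_step_chain(self, demo_schema):
        pg = ProvenanceGraph(demo_schema)
        pre = demo_schema.prop("preceded_by").uri
        p1, p2, p3 = (URIRef(EX + f"p{i}") for i in (1, 2, 3))
        pg.add((p3, pre, p2))
        pg.add((p2, pre, p1))
        assert transitive_closure(pg, p3) == [p2, p1]

    def test_two_cycle_terminates_excluding_start(self, demo_schema):
        pg = ProvenanceGraph(demo_schema)
        pre = demo_schema.prop("preceded_by").uri
        p1, p2 = URIRef(EX + "p1"), URIRef(EX + "p2")
        pg.add((p1, pre, p2))
        pg.add((p2, pre, p1))
        assert transitive_closure(pg, p1) == [p2]

    def test_unknown_start_raises(self, demo_schema):
        pg = ProvenanceGraph(demo_schema)
        pg.add((URIRef(EX + "x"), RDF.type, demo_schema.cls("sample").uri))
        with pytest.raises(LookupError_):
            transitive_closure(pg, URIRef(EX + "ghost"))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bfs_oracle_on_random_graphs(self, seed, demo_schema):
        """Random process networks, cycles included."""
        rng = random.Random(seed)
        pg = ProvenanceGraph(demo_schema)
        pre = demo_schema.prop("preceded_by").uri
        n = rng.randint(2, 15)
        nodes = [URIRef(EX + f"n{i}") for i in range(n)]
        for node in nodes:
            pg.add((node, RDF.type, demo_schema.cls("gene_knockout_process").uri))
        for _ in range(rng.randint(1, 2 * n)):
            pg.add((rng.choice(nodes), pre, rng.choice(nodes)))
        start = rng.choice(nodes)
        assert transitive_closure(pg, start) == oracle_closure(pg, start)


class TestSparqlComposition:
    def test_unknown_operator_rejected(self, demo_schema):
        with pytest.raises(CompositionError):
            compose_sparql("provenance_of_provenance", None, demo_schema)

    def test_context_without_constraints_is_single_triple_pattern(self, demo_schema):
        text, pattern = compose_sparql("provenance_context", [], demo_schema)
        assert pattern.metrics[1] == 1  # one triple pattern
        assert pattern.metrics[2] == 0  # no OPTIONAL nesting
        assert "OPTIONAL" not in text

    def test_provenance_metrics_match_hand_counts_on_text(self, demo_schema):
        import re

        text, pattern = compose_sparql("provenance", URIRef(EX + "e"), demo_schema)
        variable_count, triple_count, nesting = pattern.metrics
        where = text.split("WHERE", 1)[1]
        assert variable_count == len(set(re.findall(r"\?\w+", where)))
        assert nesting == 3  # chain > component > type/literal blocks
        # recomputable from structure
        assert pattern.recompute_metrics() == pattern.metrics
        assert triple_count == len(pattern.triple_patterns)

    def test_emitted_query_is_valid_sparql(self, protocol_result):
        pg = protocol_result.graph
        text, _ = compose_sparql("provenance", protocol_result.final_samples[0], pg.schema)
        pg.graph.query(text)  # parses and executes without error

    @pytest.mark.parametrize("seed", range(6))
    def test_provenance_sparql_equals_direct(self, seed):
        result = random_protocol_graph(seed)
        pg = result.graph
        for e in result.final_samples[:2]:
            direct = provenance(pg, e).triples()
            via = execute_operator_sparql(pg, "provenance", e).triples()
            assert via == direct

    @pytest.mark.parametrize("seed", [1, 4])
    def test_context_sparql_equals_direct_on_corpus(self, seed):
        corpus = synth.generate_extraction_corpus(
            synth.CorpusSpec(n_assertions=60, n_sources=6, seed=seed)
        )
        ctx = pace.default_extraction_context()
        pg = pace.encode_corpus(list(corpus.assertions), "exhaustive", ctx)
        constraints = [
            ProvenanceConstraint("confidence", ">", 7.0),
            ProvenanceConstraint("publication_year", ">=", 2005),
        ]
        assert execute_operator_sparql(pg, "provenance_context", constraints) == (
            provenance_context(pg, constraints)
        )

    def test_context_sparql_equals_direct_on_protocol(self, protocol_result):
        pg = protocol_result.graph
        constraints = [ProvenanceConstraint("temperature", ">", 28.0)]
        assert execute_operator_sparql(pg, "provenance_context", constraints) == (
            provenance_context(pg, constraints)
        )

    def test_closure_probe_text(self, demo_schema):
        text, pattern = compose_sparql(
            "transitive_closure",
            {"start": URIRef(EX + "p3"), "depth": 2},
            demo_schema,
        )
        assert text.startswith("ASK")
        assert pattern.metrics[1] == 2


class TestMaterializedViews:
    def test_cold_cache_falls_through(self, protocol_result):
        pg = protocol_result.graph
        cache = ViewCache(pg)
        e = protocol_result.final_samples[0]
        assert query_with_mpv(cache, "provenance", e) == provenance(pg, e)
        assert cache.misses == 1 and cache.hits == 0

    def test_repeated_query_served_from_view(self, protocol_result):
        pg = protocol_result.graph
        cache = ViewCache(pg)
        e = protocol_result.final_samples[0]
        first = query_with_mpv(cache, "provenance", e)
        second = query_with_mpv(cache, "provenance", e)
        assert first == second
        assert cache.hits == 1

    def test_update_invalidates_view(self, protocol_result):
        pg = protocol_result.graph.copy()
        cache = ViewCache(pg)
        run = protocol_result.runs[0]
        e = run.final_samples[0]
        query_with_mpv(cache, "provenance", e)
        rec = next(r for r in protocol_result.records if r.run == run.index)
        old = next(pg.graph.triples((rec.node, VALUE, None)))
        pg.remove(old)
        pg.add((rec.node, VALUE, Literal("changed")))
        fresh = provenance(pg, e)
        assert query_with_mpv(cache, "provenance", e) == fresh
        assert (rec.node, VALUE, Literal("changed")) in fresh

    def test_build_mpv_fresh_view_matches_direct(self, protocol_result):
        pg = protocol_result.graph
        e = protocol_result.final_samples[1]
        view = build_mpv(pg, e)
        assert not view.stale
        assert view.subgraph == provenance(pg, e)

    @pytest.mark.parametrize("seed", range(4))
    def test_transparent_under_query_update_interleavings(self, seed):
        """Cached answers must equal uncached answers under arbitrary
        interleavings of queries, additions and removals."""
        result = random_protocol_graph(seed + 100)
        pg = result.graph
        cache = ViewCache(pg)
        rng = random.Random(seed)
        entities = result.final_samples
        spare = []
        for _ in range(25):
            action = rng.random()
            if action < 0.6:
                e = rng.choice(entities)
                assert query_with_mpv(cache, "provenance", e) == provenance(pg, e)
            elif action < 0.8 and len(pg) > 1:
                t = rng.choice(sorted(pg.triples(), key=str))
                pg.remove(t)
                spare.append(t)
            elif spare:
                pg.add(spare.pop())
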