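"""Provenance query operators, SPARQL composition, and materialized views.

Four operators form the query surface:

* :func:`provenance` — the full derivation history of a data entity: the
  chain of processes that created it (closed transitively over
  ``preceded_by``), with their agents, participants and parameters.
  Matching is *best-effort*: missing components shrink the result instead of
  failing, mirroring SPARQL ``OPTIONAL`` semantics over incomplete
  provenance.
* :func:`provenance_context` — the inverse direction: all data entities
  whose provenance satisfies a conjunction of constraints (e.g. confidence
  above a threshold, publication year after a cutoff).
* :func:`provenance_compare` — whether two provenance graphs describe
  equivalent conditions, i.e. are isomorphic once instance identifiers are
  abstracted away (literals and schema terms are kept).
* :func:`provenance_merge` — the union of two provenance graphs from
  consecutive protocol phases, with a bridging ``preceded_by`` link so the
  merged process chain stays traversable end to end.

Each operator also exists as a composed SPARQL query
(:func:`compose_sparql`), with class/property positions expanded through the
schema's subclass/subproperty closure (RDFS entailment) and provenance
components wrapped in ``OPTIONAL`` blocks; executing the composed text on a
SPARQL engine reproduces the direct implementation.  Transitive closure —
which SPARQL has no dedicated primitive for — is computed by issuing
existence (``ASK``) probes of increasing path length until one fails
(:func:`transitive_closure`).  A cache of materialized provenance views
(:class:`ViewCache`) serves repeated queries, falling back to fresh
evaluation whenever the base graph has changed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import RDF, RDFS, XSD

from .errors import (
    CompositionError,
    ConstraintError,
    LookupError_,
    MergeError,
    PreconditionError,
)
from .namespaces import SP, VALUE
from .schema import OntologySchema
from .store import ProvenanceGraph

__all__ = [
    "ProvenanceConstraint",
    "QueryPattern",
    "MaterializedProvenanceView",
    "ViewCache",
    "provenance",
    "provenance_context",
    "provenance_compare",
    "provenance_merge",
    "transitive_closure",
    "compose_sparql",
    "execute_operator_sparql",
    "build_mpv",
    "query_with_mpv",
]

COMPARATORS = ("=", "<", ">", "<=", ">=", "contains")
_COMPARATOR_ALIASES = {"≤": "<=", "≥": ">=", "==": "="}

#: default cap on OPTIONAL nesting / probe depth
MAX_DEPTH = 50


@dataclass(frozen=True)
class ProvenanceConstraint:
    """One conjunct of a provenance-context query.

    ``target`` names a schema class or property; ``comparator`` is one of
    ``= < > <= >= contains``; ``value`` is the literal to compare against.
    Order comparators require a numeric value.
    """

    target: str
    comparator: str
    value: object

    def __post_init__(self):
        comp = _COMPARATOR_ALIASES.get(self.comparator, self.comparator)
        if comp not in COMPARATORS:
            raise ConstraintError(f"unknown comparator {self.comparator!r}")
        object.__setattr__(self, "comparator", comp)
        if comp in ("<", ">", "<=", ">=") and not isinstance(self.value, (int, float)):
            raise ConstraintError(
                f"comparator {comp!r} requires a numeric value, got {self.value!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "ProvenanceConstraint":
        """Parse ``"confidence > 8"`` / ``"predicate contains affect"``."""
        m = re.match(r"\s*(\w+)\s*(<=|>=|=|<|>|contains)\s*(.+?)\s*$", text)
        if not m:
            raise ConstraintError(f"cannot parse constraint {text!r}")
        target, comp, raw = m.groups()
        try:
            value: object = int(raw)
        except ValueError:
            try:
                value = float(raw)
            except ValueError:
                value = raw.strip("\"'")
        return cls(target, comp, value)


# ---------------------------------------------------------------------------
# helpers shared by the direct implementations and the SPARQL composer
# ---------------------------------------------------------------------------


def _uris(schema: OntologySchema, prop_name: str) -> list[URIRef]:
    return sorted((p.uri for p in schema.subproperties(prop_name)), key=str)


def _role_uris(schema: OntologySchema) -> dict[str, list[URIRef]]:
    return {
        "agent": _uris(schema, "has_agent"),
        "participant": _uris(schema, "has_participant"),
        "parameter": _uris(schema, "has_parameter"),
        "preceded": _uris(schema, "preceded_by"),
    }


def _require_entity(pg: ProvenanceGraph, entity) -> URIRef:
    e = URIRef(str(entity))
    if (
        next(pg.graph.triples((e, None, None)), None) is None
        and next(pg.graph.triples((None, None, e)), None) is None
    ):
        raise LookupError_(f"entity not found in graph: {e}")
    return e


def _linking_processes(pg: ProvenanceGraph, entity: URIRef) -> set[URIRef]:
    part = set(_uris(pg.schema, "has_participant"))
    return {s for s, p, _ in pg.graph.triples((None, None, entity)) if p in part}


def _process_chain(pg: ProvenanceGraph, seeds: Iterable[URIRef]) -> set[URIRef]:
    pre = set(_uris(pg.schema, "preceded_by"))
    closure = set(seeds)
    frontier = list(closure)
    while frontier:
        node = frontier.pop()
        for _, p, o in pg.graph.triples((node, None, None)):
            if p in pre and o not in closure:
                closure.add(o)
                frontier.append(o)
    return closure


# ---------------------------------------------------------------------------
# provenance()
# ---------------------------------------------------------------------------


def provenance(pg: ProvenanceGraph, entity) -> ProvenanceGraph:
    """Best-match provenance subgraph of a data entity.

    The entity must be an instance of ``data_collection`` (or a subclass).
    The result contains the entity's own triples, its creating processes
    (every process holding it as participant, closed over ``preceded_by``),
    and for each process its type, chain links, agents, participants and
    parameters together with their types and literal annotations.  Absent
    components are simply omitted.
    """
    e = _require_entity(pg, entity)
    if not pg.is_instance_of(e, "data_collection"):
        raise PreconditionError(
            f"{e} is not an instance of data_collection (or a subclass)"
        )
    return _provenance_unchecked(pg, e)


def _provenance_unchecked(pg: ProvenanceGraph, e: URIRef) -> ProvenanceGraph:
    roles = _role_uris(pg.schema)
    pre = set(roles["preceded"])
    component_props = set(roles["agent"]) | set(roles["participant"]) | set(
        roles["parameter"]
    )
    out: set[tuple] = set(pg.graph.triples((e, None, None)))
    chain = _process_chain(pg, _linking_processes(pg, e))
    for proc in chain:
        for t in pg.graph.triples((proc, RDF.type, None)):
            out.add(t)
        for s, p, o in pg.graph.triples((proc, None, None)):
            if p in pre:
                out.add((s, p, o))
            elif p in component_props:
                out.add((s, p, o))
                for t in pg.graph.triples((o, RDF.type, None)):
                    out.add(t)
                for s2, p2, o2 in pg.graph.triples((o, None, None)):
                    if isinstance(o2, Literal):
                        out.add((s2, p2, o2))
    result = ProvenanceGraph(pg.schema, out, named_graph_id=pg.named_graph_id)
    return result


# ---------------------------------------------------------------------------
# provenance_context()
# ---------------------------------------------------------------------------


def _data_entities(pg: ProvenanceGraph) -> set[URIRef]:
    dc = {c.uri for c in pg.schema.subclasses("data_collection")}
    return {s for s, _, o in pg.graph.triples((None, RDF.type, None)) if o in dc}


def _scope_nodes(pg: ProvenanceGraph, e: URIRef) -> set[URIRef]:
    """Node scope a constraint may inspect: the entity, its direct IRI
    objects, its process chain, and the chain's components."""
    roles = _role_uris(pg.schema)
    component_props = set(roles["agent"]) | set(roles["participant"]) | set(
        roles["parameter"]
    )
    nodes = {e}
    for _, _, o in pg.graph.triples((e, None, None)):
        if isinstance(o, URIRef):
            nodes.add(o)
    chain = _process_chain(pg, _linking_processes(pg, e))
    nodes |= chain
    for proc in chain:
        for _, p, o in pg.graph.triples((proc, None, None)):
            if p in component_props and isinstance(o, URIRef):
                nodes.add(o)
    return nodes


def _literal_matches(lit, comparator: str, value) -> bool:
    if not isinstance(lit, Literal):
        return False
    v = lit.toPython()
    if comparator == "contains":
        return str(value) in str(v)
    if comparator == "=":
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            try:
                return float(v) == float(value)
            except (TypeError, ValueError):
                return False
        return str(v) == str(value)
    try:
        left = float(v)
    except (TypeError, ValueError):
        return False
    right = float(value)
    return {
        "<": left < right,
        ">": left > right,
        "<=": left <= right,
        ">=": left >= right,
    }[comparator]


def _check_constraint(
    pg: ProvenanceGraph, scope: set[URIRef], c: ProvenanceConstraint
) -> bool:
    schema = pg.schema
    if schema.has_property(c.target):
        prop_uris = {p.uri for p in schema.subproperties(c.target)}
        for s, p, o in pg.graph:
            if p in prop_uris and s in scope and _literal_matches(o, c.comparator, c.value):
                return True
        return False
    if schema.has_class(c.target):
        cls_uris = {cd.uri for cd in schema.subclasses(c.target)}
        for s, _, o in pg.graph.triples((None, RDF.type, None)):
            if s in scope and o in cls_uris:
                for _, _, v in pg.graph.triples((s, VALUE, None)):
                    if _literal_matches(v, c.comparator, c.value):
                        return True
        return False
    raise ConstraintError(f"constraint target {c.target!r} is not in the schema")


def provenance_context(
    pg: ProvenanceGraph, constraints: Sequence[ProvenanceConstraint]
) -> set[URIRef]:
    """Data entities whose provenance satisfies every constraint.

    Each constraint is checked existentially over the entity's provenance
    scope (the entity itself, its direct objects, its creating process
    chain and the chain's agents/participants/parameters); constraints
    combine conjunctively.  An empty constraint list returns all data
    entities.
    """
    # validate targets eagerly so unknown names fail even on empty graphs
    for c in constraints:
        if not (pg.schema.has_property(c.target) or pg.schema.has_class(c.target)):
            raise ConstraintError(f"constraint target {c.target!r} is not in the schema")
    out = set()
    for e in _data_entities(pg):
        scope = None
        ok = True
        for c in constraints:
            if scope is None:
                scope = _scope_nodes(pg, e)
            if not _check_constraint(pg, scope, c):
                ok = False
                break
        if ok:
            out.add(e)
    return out


# ---------------------------------------------------------------------------
# provenance_compare()
# ---------------------------------------------------------------------------

_KEEP_PREFIXES = (str(RDF), str(RDFS), str(XSD), str(SP))


def _abstract_instances(pg: ProvenanceGraph, numeric_tolerance: Optional[float]) -> Graph:
    schema = pg.schema
    keep: set[URIRef] = set()
    if schema is not None:
        keep |= {c.uri for c in schema.classes.values()}
        keep |= {p.uri for p in schema.properties.values()}

    mapping: dict[URIRef, BNode] = {}

    def conv(term):
        if isinstance(term, URIRef):
            if term in keep or str(term).startswith(_KEEP_PREFIXES):
                return term
            return mapping.setdefault(term, BNode())
        if (
            numeric_tolerance
            and isinstance(term, Literal)
            and isinstance(term.toPython(), (int, float))
            and not isinstance(term.toPython(), bool)
        ):
            q = round(float(term.toPython()) / numeric_tolerance)
            return Literal(q)
        return term

    g = Graph()
    for s, p, o in pg.graph:
        g.add((conv(s), conv(p), conv(o)))
    return g


def provenance_compare(
    g1: ProvenanceGraph,
    g2: ProvenanceGraph,
    numeric_tolerance: Optional[float] = None,
) -> bool:
    """True iff two provenance graphs describe equivalent conditions.

    Equivalence is isomorphism after abstracting instance identifiers:
    instance IRIs become anonymous nodes while literals and schema
    class/property IRIs are kept, so two runs of the same protocol with the
    same parameter values compare equal regardless of instance naming.
    Literal comparison is exact unless ``numeric_tolerance`` is given, in
    which case numeric literals are quantized to that step first.
    Reflexive and symmetric.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise PreconditionError("provenance_compare requires two non-empty graphs")
    return isomorphic(
        _abstract_instances(g1, numeric_tolerance),
        _abstract_instances(g2, numeric_tolerance),
    )


# ---------------------------------------------------------------------------
# provenance_merge()
# ---------------------------------------------------------------------------


def provenance_merge(g1: ProvenanceGraph, g2: ProvenanceGraph) -> ProvenanceGraph:
    """Union of two provenance graphs with chain bridging.

    Where a data entity produced in one phase is consumed by a process of
    the other (a shared IRI participating in processes on both sides), the
    earliest process of the later phase gains a ``preceded_by`` link to the
    latest process of the earlier phase — unless the two are already
    connected — so the merged protocol chain remains closure-traversable.
    """
    if g1.schema != g2.schema:
        raise MergeError("cannot merge graphs with different schemas")
    out = ProvenanceGraph(g1.schema, named_graph_id=g1.named_graph_id)
    for src in (g1, g2):
        for t in src.graph:
            out.graph.add(t)
            if t in src.labels:
                out.labels[t] = src.labels[t]
    pre_uri = g1.schema.prop("preceded_by").uri
    pre_uris = set(_uris(g1.schema, "preceded_by"))

    def latest(graph: ProvenanceGraph, procs: set[URIRef]) -> Optional[URIRef]:
        cands = [
            p
            for p in procs
            if not any(q in pre_uris for _, q, _ in graph.graph.triples((None, None, p)))
        ]
        return min(cands, key=str) if cands else None

    def earliest(graph: ProvenanceGraph, procs: set[URIRef]) -> Optional[URIRef]:
        cands = [
            p
            for p in procs
            if not any(q in pre_uris for _, q, _ in graph.graph.triples((p, None, None)))
        ]
        return min(cands, key=str) if cands else None

    def connected(a: URIRef, b: URIRef) -> bool:
        reach = _process_chain(out, {a})
        if b in reach:
            return True
        return a in _process_chain(out, {b})

    shared = _data_entities(g1) & _data_entities(g2)
    for e in sorted(shared, key=str):
        procs1 = _linking_processes(g1, e)
        procs2 = _linking_processes(g2, e)
        if not procs1 or not procs2:
            continue
        tail = latest(g1, procs1)
        head = earliest(g2, procs2)
        if tail is None or head is None or tail == head:
            continue
        if connected(head, tail):
            continue
        out.add((head, pre_uri, tail), "provenance")
    return out


# ---------------------------------------------------------------------------
# transitive closure via ASK probes
# ---------------------------------------------------------------------------


def _path_expr(uris: Sequence[URIRef]) -> str:
    inner = "|".join(f"<{u}>" for u in uris)
    return f"({inner})" if len(uris) > 1 else f"<{uris[0]}>"


def _chain_pattern(start: URIRef, path: str, depth: int) -> str:
    parts = []
    subj = f"<{start}>"
    for i in range(1, depth + 1):
        parts.append(f"{subj} {path} ?x{i} .")
        subj = f"?x{i}"
    return " ".join(parts)


def transitive_closure(
    pg: ProvenanceGraph,
    start,
    property: Optional[str] = None,
    max_depth: int = MAX_DEPTH,
) -> list[URIRef]:
    """All instances reachable from *start* via repeated *property* edges
    (default ``preceded_by``), in discovery order.

    SPARQL has no closure primitive, so reachability is probed with ASK
    queries of increasing path length; the first ``false`` terminates the
    loop.  A visited set guarantees termination on cycles (additionally
    bounded by the graph's node count); ties at equal depth are broken by
    lexicographic IRI order for deterministic output.
    """
    e = _require_entity(pg, start)
    prop = pg.schema.prop(property or "preceded_by")
    path = _path_expr(_uris(pg.schema, prop.name))
    visited = {e}
    order: list[URIRef] = []
    bound = min(max_depth, len(pg.nodes()) or 1)
    for depth in range(1, bound + 1):
        pattern = _chain_pattern(e, path, depth)
        if not bool(pg.graph.query(f"ASK {{ {pattern} }}").askAnswer):
            break
        rows = pg.graph.query(f"SELECT DISTINCT ?x{depth} WHERE {{ {pattern} }}")
        new = sorted(
            {row[0] for row in rows if row[0] not in visited}, key=str
        )
        if not new:
            break
        visited.update(new)
        order.extend(new)
    return order


# ---------------------------------------------------------------------------
# SPARQL composition
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    """One group pattern: triples, VALUES/FILTER/BIND lines, nested
    OPTIONALs and UNION alternatives."""

    triples: list = field(default_factory=list)  # (s, p, o) strings
    lines: list = field(default_factory=list)  # raw VALUES/FILTER/BIND text
    optionals: list = field(default_factory=list)  # nested _Block
    unions: list = field(default_factory=list)  # list of lists of _Block

    def triple(self, s: str, p: str, o: str) -> "_Block":
        self.triples.append((s, p, o))
        return self

    def raw(self, text: str) -> "_Block":
        self.lines.append(text)
        return self

    def values(self, var: str, terms: Sequence[URIRef]) -> "_Block":
        body = " ".join(f"<{t}>" for t in terms)
        return self.raw(f"VALUES {var} {{ {body} }}")

    def optional(self) -> "_Block":
        b = _Block()
        self.optionals.append(b)
        return b

    def union(self, *blocks: "_Block") -> "_Block":
        self.unions.append(list(blocks))
        return self

    def render(self, indent: int = 1) -> str:
        pad = "  " * indent
        out = []
        for s, p, o in self.triples:
            out.append(f"{pad}{s} {p} {o} .")
        for line in self.lines:
            out.append(f"{pad}{line}")
        for alternatives in self.unions:
            rendered = [
                "{\n" + b.render(indent + 1) + f"\n{pad}}}" for b in alternatives
            ]
            out.append(pad + " UNION ".join(rendered))
        for b in self.optionals:
            out.append(f"{pad}OPTIONAL {{\n{b.render(indent + 1)}\n{pad}}}")
        return "\n".join(out)

    # -- metrics -----------------------------------------------------------

    def triple_count(self) -> int:
        n = len(self.triples)
        for b in self.optionals:
            n += b.triple_count()
        for alternatives in self.unions:
            n += sum(b.triple_count() for b in alternatives)
        return n

    def nesting_depth(self) -> int:
        depth = 0
        for b in self.optionals:
            depth = max(depth, 1 + b.nesting_depth())
        for alternatives in self.unions:
            for b in alternatives:
                depth = max(depth, b.nesting_depth())
        return depth

    def variables(self) -> set[str]:
        out = set()
        for s, p, o in self.triples:
            for tok in (s, p, o):
                if tok.startswith("?"):
                    out.add(tok)
        for line in self.lines:
            out.update(re.findall(r"\?\w+", line))
        for b in self.optionals:
            out |= b.variables()
        for alternatives in self.unions:
            for b in alternatives:
                out |= b.variables()
        return out


@dataclass(frozen=True)
class QueryPattern:
    """Structure of a composed SPARQL query.

    ``metrics`` is ``(variable_count, triple_count, nesting_depth)`` and is
    always recomputable from the structure via :meth:`recompute_metrics`.
    """

    triple_patterns: tuple
    optional_blocks: tuple
    metrics: tuple

    @classmethod
    def from_block(cls, root: _Block) -> "QueryPattern":
        def gather(b: _Block):
            ts = list(b.triples)
            for alternatives in b.unions:
                for alt in alternatives:
                    ts.extend(gather(alt)[0])
            opts = []
            for ob in b.optionals:
                inner_ts, inner_opts = gather(ob)
                ts.extend(inner_ts)
                opts.append(inner_opts)
            return ts, opts

        def opt_shape(b: _Block):
            shape = [opt_shape(ob) for ob in b.optionals]
            for alternatives in b.unions:
                for alt in alternatives:
                    shape.extend(opt_shape(alt))
            return shape

        triples, _ = gather(root)

        def freeze(x):
            return tuple(freeze(i) for i in x) if isinstance(x, list) else x

        return cls(
            triple_patterns=tuple(triples),
            optional_blocks=freeze(opt_shape(root)),
            metrics=(
                len(root.variables()),
                root.triple_count(),
                root.nesting_depth(),
            ),
        )

    def recompute_metrics(self) -> tuple:
        variables = set()
        for s, p, o in self.triple_patterns:
            for tok in (s, p, o):
                if str(tok).startswith("?"):
                    variables.add(tok)

        def depth(children) -> int:
            # each entry is one OPTIONAL block holding its children's shapes
            return 1 + max((depth(c) for c in children), default=0)

        nd = max((depth(s) for s in self.optional_blocks), default=0)
        return (len(variables), len(self.triple_patterns), nd)


def _provenance_where(schema: OntologySchema, entity: URIRef) -> _Block:
    roles = _role_uris(schema)
    root = _Block()
    root.raw(f"BIND(<{entity}> AS ?e)")
    root.optional().triple("?e", "?ep", "?eo")
    chain = root.optional()
    chain.triple("?proc0", "?lp", "?e").values("?lp", roles["participant"])
    chain.triple("?proc0", f"{_path_expr(roles['preceded'])}*", "?proc")
    chain.optional().triple("?proc", "a", "?ptype")
    pre_b = chain.optional()
    pre_b.triple("?proc", "?pre", "?prev").values("?pre", roles["preceded"])
    for tag, role in (("ag", "agent"), ("part", "participant"), ("prm", "parameter")):
        b = chain.optional()
        b.triple("?proc", f"?{tag}_p", f"?{tag}").values(f"?{tag}_p", roles[role])
        b.optional().triple(f"?{tag}", "a", f"?{tag}_t")
        lit = b.optional()
        lit.triple(f"?{tag}", f"?{tag}_ap", f"?{tag}_lit")
        lit.raw(f"FILTER(isLiteral(?{tag}_lit))")
    return root


_PROVENANCE_CONSTRUCT = """CONSTRUCT {
  ?e ?ep ?eo .
  ?proc a ?ptype .
  ?proc ?pre ?prev .
  ?proc ?ag_p ?ag . ?ag a ?ag_t . ?ag ?ag_ap ?ag_lit .
  ?proc ?part_p ?part . ?part a ?part_t . ?part ?part_ap ?part_lit .
  ?proc ?prm_p ?prm . ?prm a ?prm_t . ?prm ?prm_ap ?prm_lit .
}"""


def _filter_expr(var: str, comparator: str, value) -> str:
    if comparator == "contains":
        return f'FILTER(CONTAINS(STR({var}), "{value}"))'
    if comparator == "=":
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return f"FILTER({var} = {value})"
        return f'FILTER(STR({var}) = "{value}")'
    return f"FILTER({var} {comparator} {value})"


def _constraint_check(
    block: _Block, subject: str, tag: str, c: ProvenanceConstraint, schema: OntologySchema
) -> _Block:
    """Append the existential check of constraint *c* on *subject* to *block*."""
    if schema.has_property(c.target):
        prop_uris = sorted((p.uri for p in schema.subproperties(c.target)), key=str)
        block.triple(subject, f"?cp{tag}", f"?cv{tag}").values(f"?cp{tag}", prop_uris)
    else:
        cls_uris = sorted((cd.uri for cd in schema.subclasses(c.target)), key=str)
        block.triple(subject, "a", f"?tc{tag}").values(f"?tc{tag}", cls_uris)
        block.triple(subject, f"<{VALUE}>", f"?cv{tag}")
    block.raw(_filter_expr(f"?cv{tag}", c.comparator, c.value))
    return block


def _constraint_union(
    schema: OntologySchema, i: int, c: ProvenanceConstraint
) -> list[_Block]:
    """UNION branches covering the constraint scope of ?e (mirrors
    :func:`_scope_nodes`): the entity itself, its direct IRI objects, its
    process chain, and the chain's components."""
    roles = _role_uris(schema)
    component = roles["agent"] + roles["participant"] + roles["parameter"]
    pre_star = f"{_path_expr(roles['preceded'])}*"

    b_self = _constraint_check(_Block(), "?e", f"s{i}", c, schema)

    b_obj = _Block().triple("?e", f"?op{i}", f"?xo{i}")
    _constraint_check(b_obj, f"?xo{i}", f"o{i}", c, schema)

    b_proc = _Block()
    b_proc.triple(f"?pp0_{i}", f"?plp{i}", "?e").values(f"?plp{i}", roles["participant"])
    b_proc.triple(f"?pp0_{i}", pre_star, f"?xp{i}")
    _constraint_check(b_proc, f"?xp{i}", f"p{i}", c, schema)

    b_comp = _Block()
    b_comp.triple(f"?cp0_{i}", f"?clp{i}", "?e").values(f"?clp{i}", roles["participant"])
    b_comp.triple(f"?cp0_{i}", pre_star, f"?cproc{i}")
    b_comp.triple(f"?cproc{i}", f"?crp{i}", f"?xc{i}").values(f"?crp{i}", component)
    _constraint_check(b_comp, f"?xc{i}", f"c{i}", c, schema)

    return [b_self, b_obj, b_proc, b_comp]


def _context_where(
    schema: OntologySchema, constraints: Sequence[ProvenanceConstraint]
) -> _Block:
    root = _Block()
    dc_uris = sorted((c.uri for c in schema.subclasses("data_collection")), key=str)
    root.triple("?e", "a", "?ecls").values("?ecls", dc_uris)
    for i, c in enumerate(constraints):
        if not (schema.has_property(c.target) or schema.has_class(c.target)):
            raise ConstraintError(
                f"constraint target {c.target!r} is not in the schema"
            )
        root.union(*_constraint_union(schema, i, c))
    return root


OPERATORS = (
    "provenance",
    "provenance_context",
    "provenance_compare",
    "provenance_merge",
    "transitive_closure",
)


def compose_sparql(
    operator: str, input, schema: OntologySchema
) -> tuple[str, QueryPattern]:
    """Compose the SPARQL query text for a provenance operator.

    Classes and properties are expanded through the schema's
    subclass/subproperty closure (RDFS entailment); provenance components
    are wrapped in OPTIONAL blocks so partial provenance still yields a
    best-match result.  Returns the query text together with its
    :class:`QueryPattern` (structure + complexity metrics).
    """
    if operator == "provenance":
        entity = URIRef(str(input))
        where = _provenance_where(schema, entity)
        text = f"{_PROVENANCE_CONSTRUCT}\nWHERE {{\n{where.render()}\n}}\n"
        return text, QueryPattern.from_block(where)
    if operator == "provenance_context":
        constraints = list(input or [])
        where = _context_where(schema, constraints)
        text = f"SELECT DISTINCT ?e\nWHERE {{\n{where.render()}\n}}\n"
        return text, QueryPattern.from_block(where)
    if operator == "transitive_closure":
        spec = dict(input)
        prop = schema.prop(spec.get("property", "preceded_by"))
        path = _path_expr(_uris(schema, prop.name))
        depth = int(spec.get("depth", 1))
        pattern = _chain_pattern(URIRef(str(spec["start"])), path, depth)
        where = _Block()
        for part in pattern.rstrip(" .").split(" . "):
            s, p, o = part.split(" ", 2)
            where.triple(s, p, o.rstrip(" ."))
        return f"ASK {{ {pattern} }}", QueryPattern.from_block(where)
    if operator in ("provenance_compare", "provenance_merge"):
        # graph-level operators: the composed query extracts each input
        # graph; equivalence / union+bridging are computed on the results
        where = _Block().triple("?s", "?p", "?o")
        text = "CONSTRUCT { ?s ?p ?o }\nWHERE {\n" + where.render() + "\n}\n"
        return text, QueryPattern.from_block(where)
    raise CompositionError(f"unknown query operator {operator!r}")


def execute_operator_sparql(pg: ProvenanceGraph, operator: str, input):
    """Execute an operator through its composed SPARQL text (rather than the
    direct in-memory implementation) — the cross-validation route.

    Returns a :class:`ProvenanceGraph` for ``provenance`` and a set of IRIs
    for ``provenance_context``.
    """
    text, _ = compose_sparql(operator, input, pg.schema)
    if operator == "provenance":
        res = pg.graph.query(text)
        out = ProvenanceGraph(pg.schema, named_graph_id=pg.named_graph_id)
        for t in res.graph:
            out.graph.add(t)
        return out
    if operator == "provenance_context":
        res = pg.graph.query(text)
        return {row[0] for row in res}
    raise CompositionError(
        f"operator {operator!r} is not executable through the SPARQL route"
    )


# ---------------------------------------------------------------------------
# materialized provenance views
# ---------------------------------------------------------------------------


@dataclass
class MaterializedProvenanceView:
    """A cached provenance subgraph keyed by entity.

    ``version`` is the base-graph version at materialization time; the view
    is stale whenever the base graph has moved past it.
    """

    key: tuple
    subgraph: ProvenanceGraph
    version: int
    stale: bool = False


def build_mpv(pg: ProvenanceGraph, key) -> MaterializedProvenanceView:
    """Materialize the provenance view of one entity."""
    entity = URIRef(str(key))
    return MaterializedProvenanceView(
        key=("provenance", entity),
        subgraph=provenance(pg, entity),
        version=pg.version,
    )


class ViewCache:
    """Transparent cache of materialized provenance views over one graph.

    Any mutation of the base graph (tracked by its version counter) marks
    cached views stale; stale views are never served — the query falls
    through to fresh evaluation and the view is rebuilt.
    """

    def __init__(self, pg: ProvenanceGraph):
        self.pg = pg
        self.views: dict[tuple, MaterializedProvenanceView] = {}
        self.hits = 0
        self.misses = 0

    def _fresh(self, view: MaterializedProvenanceView) -> bool:
        if view.version != self.pg.version:
            view.stale = True
        return not view.stale

    def provenance(self, entity) -> ProvenanceGraph:
        key = ("provenance", URIRef(str(entity)))
        view = self.views.get(key)
        if view is not None and self._fresh(view):
            self.hits += 1
            return view.subgraph.copy()
        self.misses += 1
        view = build_mpv(self.pg, entity)
        self.views[key] = view
        return view.subgraph.copy()

    def query(self, operator: str, *args):
        if operator == "provenance":
            return self.provenance(*args)
        # other operators are evaluated directly (no view caching)
        if operator == "provenance_context":
            return provenance_context(self.pg, *args)
        if operator == "transitive_closure":
            return transitive_closure(self.pg, *args)
        raise CompositionError(f"unknown query operator {operator!r}")


def query_with_mpv(cache: ViewCache, operator: str, *args):
    """Answer an operator call through the view cache; results are always
    identical to uncached evaluation."""
    return cache.query(operator, *args)
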