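"""Single-graph provenance storage.

Data and provenance triples are kept together in one RDF graph.  What counts
as "provenance" is application-driven (a temperature is provenance for a
knockout experiment but plain data in a clinical record), so the store never
hard-codes the split: :func:`classify_triples` derives it from the schema —
a triple is provenance-specific when its predicate is one of the schema's
provenance relationships (or a subproperty), or when its subject or object
is an instance of ``process``, ``agent`` or ``parameter`` (transitively
through the subclass tree).  Keeping both kinds of triple co-resident makes
propagation a subgraph export: :func:`propagate` carries the full provenance
closure along with the requested entities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Set, Union

from rdflib import Dataset, Graph, Literal, URIRef
from rdflib.namespace import RDF

from .errors import ClassificationError, GraphParseError, PropagationError
from .schema import OntologySchema

__all__ = [
    "ProvenanceGraph",
    "StorageStats",
    "classify_triples",
    "propagate",
    "read_graph",
    "write_graph",
    "canonical_nt",
]

_SUFFIX_FORMATS = {
    ".ttl": "turtle",
    ".nt": "nt",
    ".rdf": "xml",
    ".xml": "xml",
    ".trig": "trig",
}

#: classes whose instances make a triple provenance-specific
_PROVENANCE_ROLE_CLASSES = ("process", "agent", "parameter")


class ProvenanceGraph:
    """An RDF graph holding data and provenance together.

    Wraps an :class:`rdflib.Graph` with set semantics, an attached schema,
    optional per-triple ground-truth labels (``"data"`` /
    ``"provenance"``, populated by the synthetic generator), and a version
    counter that the query engine's view cache uses to detect staleness.
    """

    def __init__(
        self,
        schema: Optional[OntologySchema] = None,
        triples: Iterable[tuple] = (),
        named_graph_id: Optional[URIRef] = None,
    ):
        self.schema = schema
        self.named_graph_id = named_graph_id
        self.graph = Graph()
        self.labels: dict[tuple, str] = {}
        self.version = 0
        for t in triples:
            self.graph.add(t)

    # -- mutation ------------------------------------------------------------

    def add(self, triple: tuple, label: Optional[str] = None) -> None:
        self.graph.add(triple)
        if label is not None:
            if label not in ("data", "provenance"):
                raise ValueError(f"label must be 'data' or 'provenance', got {label!r}")
            self.labels[triple] = label
        self.version += 1

    def remove(self, triple: tuple) -> None:
        self.graph.remove(triple)
        self.labels.pop(triple, None)
        self.version += 1

    def update(self, triples: Iterable[tuple], label: Optional[str] = None) -> None:
        for t in triples:
            self.add(t, label)

    # -- views ---------------------------------------------------------------

    def triples(self) -> Set[tuple]:
        return set(self.graph)

    def nodes(self) -> Set:
        out = set()
        for s, _, o in self.graph:
            out.add(s)
            out.add(o)
        return out

    def copy(self) -> "ProvenanceGraph":
        g = ProvenanceGraph(self.schema, self.graph, self.named_graph_id)
        g.labels = dict(self.labels)
        return g

    def __len__(self):
        return len(self.graph)

    def __iter__(self):
        return iter(self.graph)

    def __contains__(self, triple):
        return triple in self.graph

    def __eq__(self, other):
        if not isinstance(other, ProvenanceGraph):
            return NotImplemented
        return set(self.graph) == set(other.graph)

    def __hash__(self):
        return hash(frozenset(self.graph))

    def __repr__(self):
        return f"ProvenanceGraph({len(self.graph)} triples)"

    # -- typing helpers ------------------------------------------------------

    def instance_classes(self) -> dict:
        """Map node -> set of schema class names it is typed to (directly)."""
        if self.schema is None:
            return {}
        out: dict = {}
        for s, _, o in self.graph.triples((None, RDF.type, None)):
            c = self.schema.class_for_uri(o) if isinstance(o, URIRef) else None
            if c is not None:
                out.setdefault(s, set()).add(c.name)
        return out

    def is_instance_of(self, node, class_name: str) -> bool:
        """True when *node* is typed (directly or via a subclass) to
        *class_name*."""
        classes = self.instance_classes().get(node, set())
        return any(self.schema.is_subclass(c, class_name) for c in classes)


@dataclass(frozen=True)
class StorageStats:
    """Triple census of a provenance graph."""

    total_triples: int
    provenance_triples: int

    def __post_init__(self):
        if not (0 <= self.provenance_triples <= self.total_triples):
            raise ValueError("provenance_triples must lie in [0, total_triples]")

    @property
    def provenance_fraction(self) -> float:
        """Provenance-specific share of the graph, in percent."""
        if self.total_triples == 0:
            return 0.0
        return 100.0 * self.provenance_triples / self.total_triples


def _provenance_instances(pg: ProvenanceGraph) -> set:
    """Nodes that are (transitive) instances of process, agent or parameter."""
    schema = pg.schema
    role_like = set()
    for node, classes in pg.instance_classes().items():
        for c in classes:
            if any(schema.is_subclass(c, role) for role in _PROVENANCE_ROLE_CLASSES):
                role_like.add(node)
                break
    return role_like


def classify_triples(pg: ProvenanceGraph) -> StorageStats:
    """Census of data vs provenance-specific triples.

    A triple is provenance-specific iff its predicate is a provenance
    relationship declared in the schema (subproperties included by
    declaration), or its subject or object is an instance — transitively
    through the subclass tree — of ``process``, ``agent`` or ``parameter``.
    Counts are instance-level: the schema's own TBox triples are not part of
    a :class:`ProvenanceGraph`.
    """
    if pg.schema is None:
        raise ClassificationError("graph has no schema; cannot classify triples")
    prov_prop_uris = {p.uri for p in pg.schema.properties.values()}
    role_nodes = _provenance_instances(pg)
    prov = 0
    for s, p, o in pg.graph:
        if p in prov_prop_uris or s in role_nodes or o in role_nodes:
            prov += 1
    return StorageStats(total_triples=len(pg.graph), provenance_triples=prov)


def provenance_edges(pg: ProvenanceGraph):
    """Iterate the graph's triples whose predicate is a schema provenance
    relationship."""
    prop_uris = {p.uri for p in pg.schema.properties.values()}
    for t in pg.graph:
        if t[1] in prop_uris:
            yield t


def propagate(pg: ProvenanceGraph, entities: Iterable[URIRef]) -> ProvenanceGraph:
    """Export a self-contained provenance bundle for *entities*.

    The bundle is the induced subgraph over the provenance closure of the
    entities: starting from each entity, provenance relationships are
    followed in both directions (an entity's creating process points *at*
    it via ``has_participant``; ``preceded_by`` chains point backwards in
    time), and every triple mentioning a closure node — including type
    triples and literal annotations — is carried along.  Monotone: a larger
    entity set always yields a supergraph.
    """
    entities = {URIRef(str(e)) for e in entities}
    present = pg.nodes()
    missing = entities - present
    if missing:
        raise PropagationError(missing)
    prop_uris = {p.uri for p in pg.schema.properties.values()} if pg.schema else set()
    # adjacency over provenance relationships, both directions
    fwd: dict = {}
    back: dict = {}
    for s, p, o in pg.graph:
        if p in prop_uris:
            fwd.setdefault(s, set()).add(o)
            back.setdefault(o, set()).add(s)
    closure = set(entities)
    frontier = list(entities)
    while frontier:
        n = frontier.pop()
        for nxt in fwd.get(n, set()) | back.get(n, set()):
            if nxt not in closure and not isinstance(nxt, Literal):
                closure.add(nxt)
                frontier.append(nxt)
    out = ProvenanceGraph(pg.schema, named_graph_id=pg.named_graph_id)
    for t in pg.graph:
        s, _, o = t
        if s in closure or o in closure:
            out.graph.add(t)
            if t in pg.labels:
                out.labels[t] = pg.labels[t]
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _format_for(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    try:
        return _SUFFIX_FORMATS[suffix]
    except KeyError:
        raise GraphParseError(
            f"cannot infer RDF format from suffix {suffix!r}; pass format="
        ) from None


_LINE_RE = re.compile(r"line[s]?[:\s]+(\d+)", re.IGNORECASE)


def read_graph(
    path: Union[str, Path],
    format: Optional[str] = None,
    schema: Optional[OntologySchema] = None,
) -> ProvenanceGraph:
    """Parse an RDF file (Turtle, N-Triples, RDF/XML; TriG is accepted and
    collapsed to the default graph).  Malformed input raises
    :class:`GraphParseError` carrying the offending line number when the
    underlying parser reports one."""
    fmt = _format_for(path, format)
    pg = ProvenanceGraph(schema)
    try:
        if fmt == "trig":
            ds = Dataset()
            ds.parse(str(path), format="trig")
            for g in ds.graphs():
                for t in g:
                    pg.graph.add(t)
        else:
            pg.graph.parse(str(path), format=fmt)
    except Exception as exc:  # rdflib raises format-specific exceptions
        msg = str(exc)
        line = None
        # notation3-family parsers count newlines seen so far
        if getattr(exc, "lines", None) is not None:
            line = exc.lines + 1
        if line is None:
            m = _LINE_RE.search(msg)
            line = int(m.group(1)) if m else None
        if line is None and "Invalid line:" in msg:
            # the N-Triples parser reports the offending text, not its number
            bad = msg.split("Invalid line:", 1)[1].strip()
            for i, text in enumerate(Path(path).read_text().splitlines(), start=1):
                if text.strip() == bad:
                    line = i
                    break
        raise GraphParseError(f"cannot parse {path} as {fmt}: {msg}", line=line) from exc
    return pg


def canonical_nt(graph: Union[ProvenanceGraph, Graph]) -> str:
    """Canonical (sorted) N-Triples serialization; byte-identical for equal
    triple sets, so suitable for diffing and determinism checks."""
    g = graph.graph if isinstance(graph, ProvenanceGraph) else graph
    text = g.serialize(format="nt")
    lines = sorted(line for line in text.splitlines() if line.strip())
    return "\n".join(lines) + ("\n" if lines else "")


def write_graph(
    graph: Union[ProvenanceGraph, Graph],
    path: Union[str, Path],
    format: Optional[str] = None,
) -> None:
    """Serialize to Turtle/N-Triples/RDF-XML.  N-Triples output is
    canonicalized (sorted) for reproducible, diffable files."""
    fmt = _format_for(path, format)
    g = graph.graph if isinstance(graph, ProvenanceGraph) else graph
    if fmt == "nt":
        Path(path).write_text(canonical_nt(g), encoding="utf-8")
    else:
        g.serialize(destination=str(path), format=fmt)
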