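"""Upper-level provenance schema and domain extensions.

The default schema shipped here is a small upper-level provenance ontology
with three top-level classes — ``data``, ``process`` and ``agent`` — and
five subclasses: ``data_collection`` and ``parameter`` under ``data``, and
``spatial_parameter`` / ``temporal_parameter`` / ``domain_parameter`` under
``parameter`` (eight classes in total).  Eleven named relationships link the
classes; ten of them are adapted from the OBO Relation ontology
(part_of, contained_in, located_in, adjacent_to, transformation_of,
derives_from, preceded_by, has_participant, has_agent, has_parameter) and
``has_temporal_value`` anchors processes to temporal parameters.

Domain-specific provenance ontologies are built by *extending* this schema
with ``rdfs:subClassOf`` / ``rdfs:subPropertyOf`` specializations; the
extension mechanism is monotone (base definitions are never removed) and
rejects dangling parents and subclass cycles.

The module also implements the form-capture core used to turn field/value
records into RDF: a *provenance pattern* (an ordered chain of classes linked
by properties) is validated against a schema and then instantiated with
concrete values, yielding plain RDF triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .errors import (
    ConfigError,
    CycleError,
    DatatypeError,
    ExtensionError,
    InstantiationError,
    LookupError_,
    SchemaError,
)
from .namespaces import PROVENIR, VALUE

__all__ = [
    "ClassDef",
    "PropertyDef",
    "OntologySchema",
    "PatternElement",
    "ProvenancePattern",
    "ValidationIssue",
    "ValidationReport",
    "default_provenir_schema",
    "demo_extension",
    "extend_schema",
    "subclasses_of",
    "subproperties_of",
    "validate_pattern",
    "instantiate_pattern",
    "schema_to_rdf",
    "schema_from_rdf",
    "load_extension_config",
    "load_pattern_config",
]

# datatype markers accepted in PropertyDef.range / ClassDef.value_datatype
_DATATYPE_ALIASES = {
    "string": XSD.string,
    "integer": XSD.integer,
    "int": XSD.integer,
    "decimal": XSD.decimal,
    "float": XSD.double,
    "double": XSD.double,
    "boolean": XSD.boolean,
    "date": XSD.date,
    "dateTime": XSD.dateTime,
    "gYear": XSD.gYear,
}


def _resolve_datatype(marker) -> Optional[URIRef]:
    if marker is None:
        return None
    if isinstance(marker, URIRef):
        return marker
    m = str(marker)
    if m.startswith("xsd:"):
        m = m[4:]
    if m in _DATATYPE_ALIASES:
        return _DATATYPE_ALIASES[m]
    if m.startswith(str(XSD)):
        return URIRef(m)
    return None


def is_datatype_marker(value) -> bool:
    """True when *value* names an XSD literal datatype rather than a class."""
    return _resolve_datatype(value) is not None


def _name_of(ref) -> str:
    if isinstance(ref, (ClassDef, PropertyDef)):
        return ref.name
    return str(ref)


@dataclass(frozen=True)
class ClassDef:
    """A named class in a provenance schema.

    ``parent`` is the name of the superclass (None for a top-level class).
    ``value_datatype`` optionally constrains the literal values instances of
    this class may carry when instantiated from a form field.
    """

    name: str
    uri: Optional[URIRef] = None
    parent: Optional[str] = None
    value_datatype: Optional[URIRef] = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise SchemaError("class name must be non-empty")
        if self.parent is not None:
            object.__setattr__(self, "parent", _name_of(self.parent))
        if self.uri is not None:
            object.__setattr__(self, "uri", URIRef(str(self.uri)))
        if self.value_datatype is not None:
            dt = _resolve_datatype(self.value_datatype)
            if dt is None:
                raise SchemaError(
                    f"unknown datatype marker {self.value_datatype!r} on class {self.name}"
                )
            object.__setattr__(self, "value_datatype", dt)


@dataclass(frozen=True)
class PropertyDef:
    """A named relationship with domain/range constraints.

    ``range`` is either the name of a class or an XSD datatype marker
    (``"xsd:decimal"``, ``"string"``, or an XSD URIRef) for literal-valued
    properties.
    """

    name: str
    domain: str
    range: str
    uri: Optional[URIRef] = None
    parent: Optional[str] = None

    def __post_init__(self):
        if not self.name or not self.name.strip():
            raise SchemaError("property name must be non-empty")
        object.__setattr__(self, "domain", _name_of(self.domain))
        if not is_datatype_marker(self.range):
            object.__setattr__(self, "range", _name_of(self.range))
        if self.parent is not None:
            object.__setattr__(self, "parent", _name_of(self.parent))
        if self.uri is not None:
            object.__setattr__(self, "uri", URIRef(str(self.uri)))

    @property
    def range_datatype(self) -> Optional[URIRef]:
        return _resolve_datatype(self.range)

    @property
    def range_is_datatype(self) -> bool:
        return self.range_datatype is not None


class OntologySchema:
    """An immutable registry of classes and properties.

    Invariants enforced at construction: names are unique per kind, every
    parent reference resolves, the subclass/subproperty relations are
    acyclic, property domains/ranges resolve to declared classes (or
    datatypes), and a child property's domain/range refine its parent's.
    """

    def __init__(
        self,
        base_namespace: str = str(PROVENIR),
        classes: Iterable[ClassDef] = (),
        properties: Iterable[PropertyDef] = (),
    ):
        self.base_namespace = str(base_namespace)
        self._classes: dict[str, ClassDef] = {}
        self._properties: dict[str, PropertyDef] = {}
        for c in classes:
            if c.name in self._classes:
                raise SchemaError(f"duplicate class name: {c.name}")
            if c.uri is None:
                c = replace(c, uri=URIRef(self.base_namespace + c.name))
            self._classes[c.name] = c
        for p in properties:
            if p.name in self._properties:
                raise SchemaError(f"duplicate property name: {p.name}")
            if p.uri is None:
                p = replace(p, uri=URIRef(self.base_namespace + p.name))
            self._properties[p.name] = p
        self._validate()
        self._class_by_uri = {c.uri: c for c in self._classes.values()}
        self._property_by_uri = {p.uri: p for p in self._properties.values()}

    # -- accessors ---------------------------------------------------------

    @property
    def classes(self) -> dict[str, ClassDef]:
        return dict(self._classes)

    @property
    def properties(self) -> dict[str, PropertyDef]:
        return dict(self._properties)

    def cls(self, name) -> ClassDef:
        name = _name_of(name)
        try:
            return self._classes[name]
        except KeyError:
            raise LookupError_(f"unknown class: {name}") from None

    def prop(self, name) -> PropertyDef:
        name = _name_of(name)
        try:
            return self._properties[name]
        except KeyError:
            raise LookupError_(f"unknown property: {name}") from None

    def class_for_uri(self, uri: URIRef) -> Optional[ClassDef]:
        return self._class_by_uri.get(uri)

    def property_for_uri(self, uri: URIRef) -> Optional[PropertyDef]:
        return self._property_by_uri.get(uri)

    def has_class(self, name) -> bool:
        return _name_of(name) in self._classes

    def has_property(self, name) -> bool:
        return _name_of(name) in self._properties

    # -- subclass machinery ------------------------------------------------

    def ancestors(self, name) -> list[str]:
        """Parent chain of a class, nearest first, excluding the class."""
        cur = self.cls(name)
        out = []
        while cur.parent is not None:
            cur = self.cls(cur.parent)
            out.append(cur.name)
        return out

    def is_subclass(self, sub, sup) -> bool:
        """Reflexive-transitive subclass test (by name)."""
        sub, sup = _name_of(sub), _name_of(sup)
        self.cls(sup)
        return sub == sup or sup in self.ancestors(sub)

    def is_subproperty(self, sub, sup) -> bool:
        sub, sup = _name_of(sub), _name_of(sup)
        self.prop(sup)
        cur = self.prop(sub)
        while True:
            if cur.name == sup:
                return True
            if cur.parent is None:
                return False
            cur = self.prop(cur.parent)

    def subclasses(self, name) -> set[ClassDef]:
        """Reflexive-transitive subclass closure."""
        root = self.cls(name)
        out = {root}
        changed = True
        while changed:
            changed = False
            names = {c.name for c in out}
            for c in self._classes.values():
                if c not in out and c.parent in names:
                    out.add(c)
                    changed = True
        return out

    def subproperties(self, name) -> set[PropertyDef]:
        root = self.prop(name)
        out = {root}
        changed = True
        while changed:
            changed = False
            names = {p.name for p in out}
            for p in self._properties.values():
                if p not in out and p.parent in names:
                    out.add(p)
                    changed = True
        return out

    # -- invariants --------------------------------------------------------

    def _check_acyclic(self, items: Mapping[str, object], kind: str):
        state: dict[str, int] = {}  # 0 in-progress, 1 done
        for start in items:
            if state.get(start) == 1:
                continue
            path, cur = [], start
            seen_local = {}
            while cur is not None:
                if state.get(cur) == 1:
                    break
                if cur in seen_local:
                    raise CycleError(path[path.index(cur):] + [cur])
                seen_local[cur] = len(path)
                path.append(cur)
                parent = items[cur].parent
                if parent is not None and parent not in items:
                    raise ExtensionError(
                        f"{kind} {cur!r} names unknown parent {parent!r}"
                    )
                cur = parent
            for n in path:
                state[n] = 1

    def _validate(self):
        self._check_acyclic(self._classes, "class")
        self._check_acyclic(self._properties, "property")
        for p in self._properties.values():
            if p.domain not in self._classes:
                raise ExtensionError(
                    f"property {p.name!r} has unknown domain {p.domain!r}"
                )
            if not p.range_is_datatype and p.range not in self._classes:
                raise ExtensionError(
                    f"property {p.name!r} has unknown range {p.range!r}"
                )
            if p.parent is not None:
                par = self._properties[p.parent]
                if not self.is_subclass(p.domain, par.domain):
                    raise SchemaError(
                        f"domain of {p.name!r} ({p.domain}) does not refine "
                        f"domain of parent {par.name!r} ({par.domain})"
                    )
                if par.range_is_datatype or p.range_is_datatype:
                    if p.range_datatype != par.range_datatype:
                        raise SchemaError(
                            f"range of {p.name!r} does not refine datatype range "
                            f"of parent {par.name!r}"
                        )
                elif not self.is_subclass(p.range, par.range):
                    raise SchemaError(
                        f"range of {p.name!r} ({p.range}) does not refine "
                        f"range of parent {par.name!r} ({par.range})"
                    )

    # -- equality ----------------------------------------------------------

    def __eq__(self, other):
        return (
            isinstance(other, OntologySchema)
            and self.base_namespace == other.base_namespace
            and self._classes == other._classes
            and self._properties == other._properties
        )

    def __hash__(self):
        return hash(
            (
                self.base_namespace,
                frozenset(self._classes.values()),
                frozenset(self._properties.values()),
            )
        )

    def __repr__(self):
        return (
            f"OntologySchema({len(self._classes)} classes, "
            f"{len(self._properties)} properties)"
        )


# ---------------------------------------------------------------------------
# default schema and demo extension
# ---------------------------------------------------------------------------

#: properties the query operators and the triple classifier depend on; an
#: extension may add properties but these five must stay present.
MANDATORY_PROPERTIES = (
    "preceded_by",
    "derives_from",
    "has_agent",
    "has_participant",
    "has_parameter",
)


def default_provenir_schema() -> OntologySchema:
    """The default upper-level provenance schema.

    Eight classes: top-level ``data``, ``process``, ``agent``;
    ``data_collection`` and ``parameter`` specialize ``data``; and the
    parameter class is specialized along the spatial, temporal and thematic
    dimensions (``spatial_parameter``, ``temporal_parameter``,
    ``domain_parameter``).  Eleven named relationships link them.  The call
    is pure: every invocation returns a structurally equal schema.
    """
    classes = [
        ClassDef("data"),
        ClassDef("process"),
        ClassDef("agent"),
        ClassDef("data_collection", parent="data"),
        ClassDef("parameter", parent="data"),
        ClassDef("spatial_parameter", parent="parameter"),
        ClassDef("temporal_parameter", parent="parameter"),
        ClassDef("domain_parameter", parent="parameter"),
    ]
    properties = [
        PropertyDef("part_of", domain="data", range="data"),
        PropertyDef("contained_in", domain="data", range="data"),
        PropertyDef("located_in", domain="data", range="spatial_parameter"),
        PropertyDef("adjacent_to", domain="data", range="data"),
        PropertyDef("transformation_of", domain="data", range="data"),
        PropertyDef("derives_from", domain="data", range="data"),
        PropertyDef("preceded_by", domain="process", range="process"),
        PropertyDef("has_participant", domain="process", range="data"),
        PropertyDef("has_agent", domain="process", range="agent"),
        PropertyDef("has_parameter", domain="process", range="parameter"),
        PropertyDef("has_temporal_value", domain="process", range="temporal_parameter"),
    ]
    return OntologySchema(str(PROVENIR), classes, properties)


def demo_extension(base: Optional[OntologySchema] = None) -> OntologySchema:
    """A small parasite-experiment-style domain extension.

    Models the reverse-genetics protocol chain (gene knockout →
    transfection → drug selection → cloning) with its samples, researchers
    and experiment parameters.  Purely illustrative: it exercises the
    extension mechanism and gives the generator and tests a realistic
    domain vocabulary.
    """
    base = base or default_provenir_schema()
    ns = "http://example.org/peo#"
    classes = [
        ClassDef("gene_knockout_process", URIRef(ns + "gene_knockout_process"), "process"),
        ClassDef("transfection_process", URIRef(ns + "transfection_process"), "process"),
        ClassDef("drug_selection_process", URIRef(ns + "drug_selection_process"), "process"),
        ClassDef("cloning_process", URIRef(ns + "cloning_process"), "process"),
        ClassDef("plasmid_construction_process", URIRef(ns + "plasmid_construction_process"), "process"),
        ClassDef("sample", URIRef(ns + "sample"), "data_collection"),
        ClassDef("researcher", URIRef(ns + "researcher"), "agent"),
        ClassDef("priority", URIRef(ns + "priority"), "domain_parameter"),
        ClassDef("target_gene", URIRef(ns + "target_gene"), "domain_parameter"),
        ClassDef("antibiotic", URIRef(ns + "antibiotic"), "domain_parameter"),
        ClassDef(
            "drug_concentration",
            URIRef(ns + "drug_concentration"),
            "domain_parameter",
            value_datatype=XSD.decimal,
        ),
        ClassDef(
            "temperature",
            URIRef(ns + "temperature"),
            "domain_parameter",
            value_datatype=XSD.decimal,
        ),
        ClassDef("transfection_method", URIRef(ns + "transfection_method"), "domain_parameter"),
    ]
    properties = [
        PropertyDef(
            "uses_antibiotic",
            domain="drug_selection_process",
            range="antibiotic",
            uri=URIRef(ns + "uses_antibiotic"),
            parent="has_parameter",
        ),
    ]
    return extend_schema(base, classes, properties)


def extend_schema(
    base: OntologySchema,
    new_classes: Sequence[ClassDef] = (),
    new_properties: Sequence[PropertyDef] = (),
) -> OntologySchema:
    """Merge domain specializations into *base*, returning a new schema.

    Every new class/property must name a parent (or domain/range) resolvable
    in the base or among the new items; the base schema is never mutated.
    Raises :class:`ExtensionError` on dangling references and
    :class:`CycleError` if the extension introduces a subclass/subproperty
    cycle.
    """
    classes = list(base.classes.values())
    known = {c.name for c in classes}
    for c in new_classes:
        if c.name in known:
            raise ExtensionError(f"class {c.name!r} already defined in base schema")
        known.add(c.name)
        classes.append(c)
    props = list(base.properties.values())
    known_p = {p.name for p in props}
    for p in new_properties:
        if p.name in known_p:
            raise ExtensionError(f"property {p.name!r} already defined in base schema")
        known_p.add(p.name)
        props.append(p)
    return OntologySchema(base.base_namespace, classes, props)


def subclasses_of(schema: OntologySchema, cls) -> set[ClassDef]:
    """Reflexive-transitive subclass closure of *cls* within *schema*."""
    return schema.subclasses(cls)


def subproperties_of(schema: OntologySchema, prop) -> set[PropertyDef]:
    """Reflexive-transitive subproperty closure of *prop* within *schema*."""
    return schema.subproperties(prop)


# ---------------------------------------------------------------------------
# provenance patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternElement:
    """One step of a provenance pattern: a class, and the property linking
    it to the previous element (None for the first element)."""

    class_name: str
    via: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "class_name", _name_of(self.class_name))
        if self.via is not None:
            object.__setattr__(self, "via", _name_of(self.via))


@dataclass(frozen=True)
class ProvenancePattern:
    """An ordered chain of classes linked by properties, used both to
    validate a form layout against a schema and to instantiate captured
    values as RDF."""

    elements: tuple[PatternElement, ...]

    def __init__(self, elements: Iterable):
        elems = []
        for e in elements:
            if isinstance(e, PatternElement):
                elems.append(e)
            elif isinstance(e, (tuple, list)):
                cls_name, via = (e + (None,))[:2] if isinstance(e, tuple) else (list(e) + [None])[:2]
                elems.append(PatternElement(cls_name, via))
            else:
                elems.append(PatternElement(e))
        object.__setattr__(self, "elements", tuple(elems))

    def __len__(self):
        return len(self.elements)


@dataclass(frozen=True)
class ValidationIssue:
    element_index: int
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def valid(self) -> bool:
        return not self.issues

    def messages(self) -> list[str]:
        return [i.message for i in self.issues]


def validate_pattern(pattern: ProvenancePattern, schema: OntologySchema) -> ValidationReport:
    """Check a provenance pattern for consistency with a schema.

    Violations (unknown classes/properties, domain/range incompatibilities)
    are collected into the report, never raised.  A connecting property is
    compatible when the previous element's class is a subclass of its
    declared domain and the current element's class a subclass of its
    declared range.
    """
    issues: list[ValidationIssue] = []
    prev_cls: Optional[str] = None
    for i, el in enumerate(pattern.elements):
        cls_ok = schema.has_class(el.class_name)
        if not cls_ok:
            issues.append(ValidationIssue(i, f"unknown class {el.class_name!r}"))
        if i == 0:
            if el.via is not None:
                issues.append(
                    ValidationIssue(i, "first element must not have a connecting property")
                )
        else:
            if el.via is None:
                issues.append(ValidationIssue(i, "missing connecting property"))
            elif not schema.has_property(el.via):
                issues.append(ValidationIssue(i, f"unknown property {el.via!r}"))
            else:
                p = schema.prop(el.via)
                if prev_cls is not None and schema.has_class(prev_cls):
                    if not schema.is_subclass(prev_cls, p.domain):
                        issues.append(
                            ValidationIssue(
                                i,
                                f"domain violation: {prev_cls!r} is not a subclass "
                                f"of {p.domain!r} (domain of {p.name!r})",
                            )
                        )
                if cls_ok:
                    if p.range_is_datatype:
                        issues.append(
                            ValidationIssue(
                                i,
                                f"property {p.name!r} has a literal range and cannot "
                                "connect classes",
                            )
                        )
                    elif not schema.is_subclass(el.class_name, p.range):
                        issues.append(
                            ValidationIssue(
                                i,
                                f"range violation: {el.class_name!r} is not a subclass "
                                f"of {p.range!r} (range of {p.name!r})",
                            )
                        )
        prev_cls = el.class_name
    return ValidationReport(tuple(issues))


_SKIP = object()


def instantiate_pattern(
    pattern: ProvenancePattern,
    values: Mapping[str, object],
    schema: OntologySchema,
    instance_namespace: str,
    identifiers: Optional[Mapping[str, URIRef]] = None,
) -> set[tuple]:
    """Turn captured field values into RDF triples along a pattern.

    ``values`` maps each element's field name (its class name) to a literal
    value, to an IRI (``URIRef`` — the value *is* the instance), or to
    ``None`` to mark the field skipped (the node is still created and typed
    so the chain stays connected, but carries no value).  Instance IRIs are
    minted deterministically as ``namespace + class_name + "/" + counter``
    unless ``identifiers`` supplies one.  Returns a set of rdflib triples.
    """
    report = validate_pattern(pattern, schema)
    if not report.valid:
        raise InstantiationError(
            "pattern invalid under schema: " + "; ".join(report.messages())
        )
    field_names = [el.class_name for el in pattern.elements]
    unknown = set(values) - set(field_names)
    if unknown:
        raise InstantiationError(
            "values for unknown fields: " + ", ".join(sorted(unknown))
        )
    missing = [f for f in field_names if f not in values]
    if missing:
        raise InstantiationError(
            "no value (and no skip marker) for fields: " + ", ".join(missing)
        )
    identifiers = identifiers or {}
    ns = instance_namespace if instance_namespace.endswith(("/", "#")) else instance_namespace + "/"
    triples: set[tuple] = set()
    prev_node = None
    counter = 0
    for el in pattern.elements:
        cdef = schema.cls(el.class_name)
        raw = values.get(el.class_name, _SKIP)
        if el.class_name in identifiers:
            node = URIRef(str(identifiers[el.class_name]))
            literal = None if raw is None or raw is _SKIP else raw
        elif isinstance(raw, URIRef):
            node = raw
            literal = None
        else:
            counter += 1
            node = URIRef(f"{ns}{el.class_name}/{counter}")
            literal = None if raw is None else raw
        triples.add((node, RDF.type, cdef.uri))
        if literal is not None:
            if isinstance(literal, URIRef):
                pass
            else:
                dt = cdef.value_datatype
                if dt is not None:
                    lit = Literal(str(literal), datatype=dt)
                    # rdflib leaves .value unset for ill-typed lexical forms
                    if dt != XSD.string and lit.value is None:
                        raise DatatypeError(
                            f"value {literal!r} for field {el.class_name!r} does not "
                            f"conform to datatype {dt}"
                        )
                else:
                    lit = Literal(str(literal))
                triples.add((node, VALUE, lit))
        if prev_node is not None and el.via is not None:
            triples.add((prev_node, schema.prop(el.via).uri, node))
        prev_node = node
    return triples


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def schema_to_rdf(schema: OntologySchema) -> Graph:
    """Serialize a schema as RDFS (classes, subClassOf/subPropertyOf,
    domain/range, labels)."""
    g = Graph()
    g.bind("provenir", PROVENIR)
    g.bind("rdfs", RDFS)
    for c in schema.classes.values():
        g.add((c.uri, RDF.type, RDFS.Class))
        g.add((c.uri, RDFS.label, Literal(c.name)))
        if c.parent is not None:
            g.add((c.uri, RDFS.subClassOf, schema.cls(c.parent).uri))
        if c.value_datatype is not None:
            g.add((c.uri, RDFS.range, c.value_datatype))
    for p in schema.properties.values():
        g.add((p.uri, RDF.type, RDF.Property))
        g.add((p.uri, RDFS.label, Literal(p.name)))
        g.add((p.uri, RDFS.domain, schema.cls(p.domain).uri))
        if p.range_is_datatype:
            g.add((p.uri, RDFS.range, p.range_datatype))
        else:
            g.add((p.uri, RDFS.range, schema.cls(p.range).uri))
        if p.parent is not None:
            g.add((p.uri, RDFS.subPropertyOf, schema.prop(p.parent).uri))
    return g


def schema_from_rdf(graph: Graph, base_namespace: str = str(PROVENIR)) -> OntologySchema:
    """Rebuild a schema from its RDFS serialization (inverse of
    :func:`schema_to_rdf` for schemas it produced)."""

    def local_name(uri: URIRef) -> str:
        lbl = graph.value(uri, RDFS.label)
        if lbl is not None:
            return str(lbl)
        s = str(uri)
        for sep in ("#", "/"):
            if sep in s:
                s = s.rsplit(sep, 1)[1]
                break
        return s

    class_uris = set(graph.subjects(RDF.type, RDFS.Class))
    prop_uris = set(graph.subjects(RDF.type, RDF.Property))
    names = {u: local_name(u) for u in class_uris | prop_uris}
    classes = []
    for u in class_uris:
        parent = graph.value(u, RDFS.subClassOf)
        rng = graph.value(u, RDFS.range)
        classes.append(
            ClassDef(
                names[u],
                u,
                names[parent] if parent is not None else None,
                value_datatype=rng if rng is not None else None,
            )
        )
    properties = []
    for u in prop_uris:
        dom = graph.value(u, RDFS.domain)
        rng = graph.value(u, RDFS.range)
        parent = graph.value(u, RDFS.subPropertyOf)
        rng_val = names[rng] if rng in class_uris else URIRef(str(rng))
        properties.append(
            PropertyDef(
                names[u],
                domain=names[dom],
                range=rng_val,
                uri=u,
                parent=names[parent] if parent is not None else None,
            )
        )
    return OntologySchema(base_namespace, classes, properties)


# ---------------------------------------------------------------------------
# config-file ingestion (YAML/JSON)
# ---------------------------------------------------------------------------


def _load_config_data(source: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc


def load_extension_config(
    source: Union[str, Path, Mapping], base: Optional[OntologySchema] = None
) -> OntologySchema:
    """Build an extended schema from a YAML/JSON definition.

    Expected shape::

        classes:
          - {name: gene_knockout_process, parent: process}
          - {name: temperature, parent: domain_parameter, datatype: decimal}
        properties:
          - {name: uses_antibiotic, parent: has_parameter,
             domain: drug_selection_process, range: antibiotic}

    Unknown keys are rejected.
    """
    data = _load_config_data(source)
    base = base or default_provenir_schema()
    allowed_top = {"classes", "properties", "base_namespace"}
    unknown = set(data) - allowed_top
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(unknown)))
    classes = []
    for item in data.get("classes", []) or []:
        extra = set(item) - {"name", "parent", "uri", "datatype"}
        if extra:
            raise ConfigError(
                f"unknown keys in class entry {item.get('name')!r}: "
                + ", ".join(sorted(extra))
            )
        classes.append(
            ClassDef(
                item["name"],
                URIRef(item["uri"]) if "uri" in item else None,
                item.get("parent"),
                value_datatype=item.get("datatype"),
            )
        )
    properties = []
    for item in data.get("properties", []) or []:
        extra = set(item) - {"name", "parent", "uri", "domain", "range"}
        if extra:
            raise ConfigError(
                f"unknown keys in property entry {item.get('name')!r}: "
                + ", ".join(sorted(extra))
            )
        properties.append(
            PropertyDef(
                item["name"],
                domain=item["domain"],
                range=item["range"],
                uri=URIRef(item["uri"]) if "uri" in item else None,
                parent=item.get("parent"),
            )
        )
    return extend_schema(base, classes, properties)


def load_pattern_config(source: Union[str, Path, Mapping]) -> ProvenancePattern:
    """Read a provenance pattern from YAML/JSON::

        pattern:
          - {class: gene_knockout_process}
          - {class: researcher, via: has_agent}
    """
    data = _load_config_data(source)
    if set(data) != {"pattern"}:
        raise ConfigError("pattern config must contain exactly the key 'pattern'")
    elements = []
    for item in data["pattern"]:
        extra = set(item) - {"class", "via"}
        if extra:
            raise ConfigError(
                "unknown keys in pattern element: " + ", ".join(sorted(extra))
            )
        elements.append(PatternElement(item["class"], item.get("via")))
    return ProvenancePattern(elements)
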