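"""Exception hierarchy for the semprov toolkit.

All library errors derive from :class:`SemprovError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class SemprovError(Exception):
    """Base class for all semprov errors."""


class SchemaError(SemprovError):
    """A schema violates its structural invariants."""


class ExtensionError(SchemaError):
    """A schema extension references an unknown parent class or property."""


class CycleError(SchemaError):
    """A subclass/subproperty cycle was introduced.

    The offending cycle is available as the ``cycle`` attribute
    (a list of names, first == last).
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("subclass/subproperty cycle: " + " -> ".join(self.cycle))


class LookupError_(SemprovError):
    """A class, property or graph entity was not found."""


class InstantiationError(SemprovError):
    """A form value could not be instantiated against a pattern."""


class DatatypeError(InstantiationError):
    """A form value violates the declared datatype of a property."""


class MintingError(SemprovError):
    """A contextualized IRI could not be minted (e.g. empty entity name)."""


class ModeError(SemprovError):
    """Unknown provenance-encoding granularity mode."""


class ClassificationError(SemprovError):
    """Triples cannot be classified (e.g. graph without a schema)."""


class PropagationError(SemprovError):
    """Propagation was requested for entities absent from the graph.

    Missing IRIs are listed in the ``missing`` attribute.
    """

    def __init__(self, missing):
        self.missing = sorted(str(m) for m in missing)
        super().__init__("entities not present in graph: " + ", ".join(self.missing))


class GraphParseError(SemprovError):
    """An RDF file could not be parsed; ``line`` holds the offending line
    number when the underlying parser reports one."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PreconditionError(SemprovError):
    """An operator precondition failed (e.g. entity is not a data_collection)."""


class ConstraintError(SemprovError):
    """A provenance constraint refers to an unknown class/property or is
    ill-typed for its value."""


class MergeError(SemprovError):
    """Provenance graphs cannot be merged (schema mismatch)."""


class CompositionError(SemprovError):
    """Unknown query operator passed to the SPARQL composer."""


class GenerationError(SemprovError):
    """A synthetic-data spec is invalid."""


class ConfigError(SemprovError):
    """A config file is malformed or contains unknown keys."""
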