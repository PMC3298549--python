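"""Shared RDF namespaces.

PROVENIR is the namespace of the upper-level provenance schema shipped by
:mod:`semprov.schema`; SP holds the toolkit's own annotation vocabulary
(value/label/confidence predicates and graph-level flags that the upper
schema does not name).
"""

from rdflib import Namespace
from rdflib.namespace import RDF, RDFS, XSD  # noqa: F401  (re-exported)

PROVENIR = Namespace("http://purl.org/semprov/provenir#")
SP = Namespace("http://purl.org/semprov/terms#")

#: predicate carrying the literal value of an instantiated form field or a
#: generated parameter (kept distinct from rdfs:label, which is descriptive)
VALUE = RDF.value

#: annotation predicates for extraction provenance
CONFIDENCE = SP["confidence"]
PUBLICATION_YEAR = SP["publication_year"]
IMPACT_FACTOR = SP["impact_factor"]
SOURCE_VERSION = SP["source_version"]
SOURCE_TYPE = SP["source_type"]

#: graph-level flag recorded by the intermediate encoding granularity: the
#: object of each triple is assumed to share the source of its subject and
#: predicate
ASSUMES_SHARED_OBJECT_SOURCE = SP["assumesSharedObjectSource"]

#: reserved path segment for source nodes under a contextualized base IRI
SOURCE_SEGMENT = "source"
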