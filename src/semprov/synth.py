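"""Synthetic provenance graphs and extraction corpora.

Two generators provide ground-truth-labeled inputs for the rest of the
toolkit:

* :func:`generate_experiment_graph` emulates bench-protocol provenance in
  the style of reverse-genetics experiments on *Trypanosoma cruzi*: each run
  is a chain of processes (gene knockout → transfection → drug selection →
  cloning by default), each process linked back to its predecessor with
  ``preceded_by`` and annotated with an agent (researcher), its input/output
  samples and its parameter values (target gene, transfection method,
  selection antibiotic, drug concentration, incubation temperature).  Every
  emitted triple carries a data/provenance ground-truth label, so the triple
  classifier and the query operators can be checked against construction-time
  truth rather than against themselves.

* :func:`generate_extraction_corpus` emulates a literature-extraction batch:
  subject–relation–object assertions attributed to journal-article sources,
  each with a tool-assigned confidence score, and each source carrying a
  publication year and a journal impact factor.  The plain record table is
  returned alongside, so constraint queries can be validated by direct
  filtering.

Both generators draw from a single seeded pseudo-random stream (no global
random state); the same spec and seed always reproduce a byte-identical
canonical serialization.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .errors import GenerationError
from .namespaces import IMPACT_FACTOR, VALUE
from .pace import SourceDescriptor, SourcedAssertion, extraction_extension
from .schema import OntologySchema, demo_extension
from .store import ProvenanceGraph

__all__ = [
    "ParamSpec",
    "StepSpec",
    "ProtocolSpec",
    "CorpusSpec",
    "ProtocolRun",
    "SynthProtocol",
    "SynthCorpus",
    "default_protocol_spec",
    "default_corpus_spec",
    "generate_experiment_graph",
    "generate_extraction_corpus",
]


@dataclass(frozen=True)
class ParamSpec:
    """A parameter emitted by a protocol step.

    ``distribution`` must be fully parameterized: ``("choice", options)``,
    ``("uniform", low, high)`` or ``("constant", value)``.
    """

    param_class: str
    distribution: tuple

    def __post_init__(self):
        d = tuple(self.distribution)
        object.__setattr__(self, "distribution", d)
        if not d:
            raise GenerationError("distribution must be non-empty")
        kind = d[0]
        if kind == "choice":
            if len(d) != 2 or not tuple(d[1]):
                raise GenerationError("choice distribution needs a non-empty option list")
            object.__setattr__(self, "distribution", ("choice", tuple(d[1])))
        elif kind == "uniform":
            if len(d) != 3 or not (float(d[1]) <= float(d[2])):
                raise GenerationError("uniform distribution needs low <= high")
        elif kind == "constant":
            if len(d) != 2:
                raise GenerationError("constant distribution needs exactly one value")
        else:
            raise GenerationError(f"unknown distribution kind {kind!r}")

    def draw(self, rng: random.Random):
        kind = self.distribution[0]
        if kind == "choice":
            return rng.choice(self.distribution[1])
        if kind == "uniform":
            low, high = float(self.distribution[1]), float(self.distribution[2])
            return round(rng.uniform(low, high), 2)
        return self.distribution[1]


@dataclass(frozen=True)
class StepSpec:
    """One protocol step: its process class, parameters and agent pool size."""

    process_class: str
    params: tuple = ()
    agent_pool: int = 1

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))
        if self.agent_pool < 1:
            raise GenerationError("agent_pool must be >= 1")


@dataclass(frozen=True)
class ProtocolSpec:
    """Recipe for synthetic experiment-protocol provenance chains.

    ``samples_per_run`` is the branching factor of the final step (how many
    cloned samples each run yields).
    """

    steps: tuple
    samples_per_run: int = 1
    seed: int = 0
    agent_class: str = "researcher"
    sample_class: str = "sample"

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        if not self.steps:
            raise GenerationError("a protocol needs at least one step")
        if self.samples_per_run < 1:
            raise GenerationError("samples_per_run must be >= 1")


def default_protocol_spec(seed: int = 0, samples_per_run: int = 2) -> ProtocolSpec:
    """The default reverse-genetics-style protocol: four steps with the
    parameters a knockout/strain-creation chain records."""
    genes = tuple(f"Tc{g}" for g in ("CZP1", "CZP2", "GP72", "PUF6", "KAP4", "MSH2"))
    return ProtocolSpec(
        steps=(
            StepSpec(
                "gene_knockout_process",
                params=(ParamSpec("target_gene", ("choice", genes)),),
                agent_pool=3,
            ),
            StepSpec(
                "transfection_process",
                params=(
                    ParamSpec(
                        "transfection_method", ("choice", ("sonication", "electroporation"))
                    ),
                ),
                agent_pool=3,
            ),
            StepSpec(
                "drug_selection_process",
                params=(
                    ParamSpec("antibiotic", ("choice", ("neomycin", "hygromycin"))),
                    ParamSpec("drug_concentration", ("uniform", 50.0, 500.0)),
                ),
                agent_pool=3,
            ),
            StepSpec(
                "cloning_process",
                params=(ParamSpec("temperature", ("uniform", 24.0, 37.0)),),
                agent_pool=3,
            ),
        ),
        samples_per_run=samples_per_run,
        seed=seed,
    )


@dataclass(frozen=True)
class ParamRecord:
    """Ground-truth record of one generated parameter value."""

    run: int
    step: int
    param_class: str
    value: object
    node: URIRef


@dataclass(frozen=True)
class ProtocolRun:
    """Ground truth for one run: its process chain and final samples."""

    index: int
    processes: tuple
    final_samples: tuple


@dataclass(frozen=True)
class SynthProtocol:
    """A generated protocol graph plus its construction-time ground truth."""

    graph: ProvenanceGraph
    runs: tuple
    records: tuple

    @property
    def final_samples(self) -> list[URIRef]:
        return [s for run in self.runs for s in run.final_samples]


def generate_experiment_graph(
    spec: ProtocolSpec,
    n_runs: int,
    instance_namespace: str = "http://example.org/tcruzi/",
    schema: Optional[OntologySchema] = None,
) -> SynthProtocol:
    """Emit *n_runs* independent protocol chains with ground-truth labels.

    Per run: an initial sample; per step a process (``preceded_by`` its
    predecessor) with an agent from the step's pool, its input sample as
    participant, freshly drawn parameter values, and one output sample
    (``samples_per_run`` cloned samples for the final step), each output
    ``derives_from`` its input.  Agents for every step pool are emitted up
    front.  Sample typing triples are data; everything touching processes,
    agents and parameters is provenance.  Identical seeds yield identical
    graphs.
    """
    if n_runs < 0:
        raise GenerationError("n_runs must be >= 0")
    schema = schema or demo_extension()
    for step in spec.steps:
        if not schema.has_class(step.process_class):
            raise GenerationError(f"unknown process class {step.process_class!r}")
        for p in step.params:
            if not schema.has_class(p.param_class):
                raise GenerationError(f"unknown parameter class {p.param_class!r}")
    rng = random.Random(spec.seed)
    ns = instance_namespace if instance_namespace.endswith(("/", "#")) else instance_namespace + "/"
    pg = ProvenanceGraph(schema, named_graph_id=URIRef(ns.rstrip("/#")))

    type_uri = lambda name: schema.cls(name).uri  # noqa: E731
    prop = lambda name: schema.prop(name).uri  # noqa: E731
    agent_cls = type_uri(spec.agent_class)
    sample_cls = type_uri(spec.sample_class)

    # agents: one disjoint pool per step, emitted up front (none for an
    # empty batch — zero runs yield an empty instance graph)
    pools: list[list[URIRef]] = []
    if n_runs > 0:
        for si, step in enumerate(spec.steps):
            pool = []
            for k in range(step.agent_pool):
                a = URIRef(f"{ns}agent/step{si}_{k}")
                pg.add((a, RDF.type, agent_cls), "provenance")
                pg.add((a, VALUE, Literal(f"researcher_{si}_{k}")), "provenance")
                pool.append(a)
            pools.append(pool)

    runs = []
    records = []
    for r in range(n_runs):
        s_in = URIRef(f"{ns}sample/r{r}_s0")
        pg.add((s_in, RDF.type, sample_cls), "data")
        prev_proc = None
        procs = []
        finals = []
        for si, step in enumerate(spec.steps):
            proc = URIRef(f"{ns}process/r{r}_p{si}")
            procs.append(proc)
            pg.add((proc, RDF.type, type_uri(step.process_class)), "provenance")
            agent = rng.choice(pools[si])
            pg.add((proc, prop("has_agent"), agent), "provenance")
            if prev_proc is not None:
                pg.add((proc, prop("preceded_by"), prev_proc), "provenance")
            pg.add((proc, prop("has_participant"), s_in), "provenance")
            for pi, pspec in enumerate(step.params):
                value = pspec.draw(rng)
                node = URIRef(f"{ns}param/r{r}_p{si}_{pi}")
                pg.add((proc, prop("has_parameter"), node), "provenance")
                pg.add((node, RDF.type, type_uri(pspec.param_class)), "provenance")
                lit = (
                    Literal(str(value), datatype=XSD.decimal)
                    if isinstance(value, float)
                    else Literal(str(value))
                )
                pg.add((node, VALUE, lit), "provenance")
                records.append(ParamRecord(r, si, pspec.param_class, value, node))
            last = si == len(spec.steps) - 1
            n_out = spec.samples_per_run if last else 1
            outs = []
            for k in range(n_out):
                suffix = f"r{r}_final{k}" if last else f"r{r}_s{si + 1}"
                s_out = URIRef(f"{ns}sample/{suffix}")
                pg.add((s_out, RDF.type, sample_cls), "data")
                pg.add((proc, prop("has_participant"), s_out), "provenance")
                pg.add((s_out, prop("derives_from"), s_in), "provenance")
                outs.append(s_out)
            if last:
                finals = outs
            s_in = outs[0]
            prev_proc = proc
        runs.append(ProtocolRun(r, tuple(procs), tuple(finals)))
    return SynthProtocol(pg, tuple(runs), tuple(records))


# ---------------------------------------------------------------------------
# extraction corpora
# ---------------------------------------------------------------------------

_SUBJECTS = (
    "lipoprotein",
    "interleukin_13",
    "cyclooxygenase_2",
    "tumor_necrosis_factor",
    "transforming_growth_factor_beta",
    "heat_shock_protein_70",
    "nitric_oxide_synthase",
    "cruzipain",
)
_PREDICATES = ("affects", "inhibits", "stimulates", "interacts_with", "treats")
_OBJECTS = (
    "inflammatory_cells",
    "cardiac_myocytes",
    "gene_expression",
    "immune_response",
    "apoptosis",
    "macrophages",
    "cell_proliferation",
    "oxidative_stress",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a synthetic extraction corpus.

    Confidence scores are uniform over ``confidence_range`` (the 0–10 scale
    text-mining tools commonly report), publication years uniform integers
    over ``year_range``, and each source draws one journal impact factor
    uniform over ``impact_factor_range``.
    """

    n_assertions: int
    n_sources: int
    confidence_range: tuple = (0.0, 10.0)
    year_range: tuple = (2000, 2011)
    impact_factor_range: tuple = (0.5, 15.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_assertions < 0 or self.n_sources < 1:
            raise GenerationError("need n_assertions >= 0 and n_sources >= 1")
        for name in ("confidence_range", "year_range", "impact_factor_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise GenerationError(f"{name} must be a non-empty interval")


def default_corpus_spec(seed: int = 0) -> CorpusSpec:
    return CorpusSpec(n_assertions=1000, n_sources=50, seed=seed)


@dataclass(frozen=True)
class SynthCorpus:
    """Generated assertions plus the flat ground-truth record table."""

    assertions: tuple
    records: tuple  # dicts: subject, predicate, object, source_id, year, impact_factor, confidence
    sources: tuple


def generate_extraction_corpus(
    spec: CorpusSpec, schema: Optional[OntologySchema] = None
) -> SynthCorpus:
    """Draw a corpus of sourced assertions with the stated distributions.

    Subjects and objects come from disjoint name pools (so no assertion is
    reflexive); each assertion picks a source uniformly.  The parallel
    record table mirrors every generated value for oracle-style filtering.
    """
    schema = schema or extraction_extension()
    rng = random.Random(spec.seed)
    subject_cls = schema.cls("extracted_entity")
    relation_cls = schema.cls("extracted_relation")

    sources = []
    source_meta = {}
    for i in range(spec.n_sources):
        sid = f"PUBMED_{17000000 + rng.randrange(1000000)}_{i}"
        year = rng.randint(int(spec.year_range[0]), int(spec.year_range[1]))
        impact = round(rng.uniform(*map(float, spec.impact_factor_range)), 2)
        src = SourceDescriptor(
            "literature",
            sid,
            publication_date=str(year),
            annotations={IMPACT_FACTOR: impact},
        )
        sources.append(src)
        source_meta[sid] = (year, impact)

    # balanced source assignment: n // k per source plus a sampled remainder,
    # then shuffled — near-uniform, with every source covered when n >= k
    assignment: list[SourceDescriptor] = []
    if spec.n_assertions and sources:
        base, rem = divmod(spec.n_assertions, len(sources))
        for s in sources:
            assignment.extend([s] * base)
        assignment.extend(rng.sample(sources, rem))
        rng.shuffle(assignment)

    assertions = []
    records = []
    for i in range(spec.n_assertions):
        src = assignment[i]
        subj = rng.choice(_SUBJECTS) + f"_{i % 17}"
        pred = rng.choice(_PREDICATES)
        obj = rng.choice(_OBJECTS) + f"_{i % 13}"
        conf = round(rng.uniform(*map(float, spec.confidence_range)), 2)
        assertions.append(
            SourcedAssertion(
                subj,
                pred,
                obj,
                src,
                confidence=conf,
                subject_class=subject_cls,
                predicate_class=relation_cls,
                object_class=subject_cls,
            )
        )
        year, impact = source_meta[src.source_id]
        records.append(
            {
                "subject": subj,
                "predicate": pred,
                "object": obj,
                "source_id": src.source_id,
                "year": year,
                "impact_factor": impact,
                "confidence": conf,
            }
        )
    return SynthCorpus(tuple(assertions), tuple(records), tuple(sources))
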