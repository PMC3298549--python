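import pytest

from semprov import pace, synth
from semprov.schema import default_provenir_schema, demo_extension


@pytest.fixture(scope="session")
def provenir():
    return default_provenir_schema()


@pytest.fixture(scope="session")
def demo_schema():
    return demo_extension()


@pytest.fixture(scope="session")
def extraction_ctx():
    return pace.default_extraction_context()


@pytest.fixture(scope="session")
def lipoprotein_assertion():
    """The canonical extracted statement: lipoprotein affects inflammatory
    cells, from the article PMID 17209178."""
    return pace.SourcedAssertion(
        "lipoprotein",
        "affects",
        "inflammatory_cells",
        pace.SourceDescriptor("literature", "PUBMED_17209178"),
    )


@pytest.fixture(scope="session")
def protocol_result():
    """A small knockout→cloning protocol batch with ground truth."""
    spec = synth.default_protocol_spec(seed=11)
    return synth.generate_experiment_graph(spec, n_runs=4)


@pytest.fixture(scope="session")
def corpus_graph():
    """An exhaustively encoded extraction corpus plus its record table."""
    spec = synth.CorpusSpec(n_assertions=150, n_sources=10, seed=5)
    corpus = synth.generate_extraction_corpus(spec)
    ctx = pace.default_extraction_context()
    graph = pace.encode_corpus(list(corpus.assertions), "exhaustive", ctx)
    return corpus, ctx, graph
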