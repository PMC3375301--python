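import logging

import pytest
from hypothesis import HealthCheck, settings

from camp.ontology import Concept, Ontology
from camp.synth import CorpusSpec, make_corpus, make_fig1_fixture, make_sod_fixture

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

logging.getLogger("camp").setLevel(logging.ERROR)


def ontology_from_edges(namespace: str, parents: dict[str, tuple[str, ...]]) -> Ontology:
    """Small helper: build an ontology from {id: parent ids} with ids as labels."""
    return Ontology(
        namespace=namespace,
        concepts={
            cid: Concept(id=cid, label=cid.replace(":", " "), parents=tuple(ps))
            for cid, ps in parents.items()
        },
    )


@pytest.fixture(scope="session")
def fig1():
    """The packaged hearing-loss worked-example fixture: (hpo, mp, lexical axioms)."""
    return make_fig1_fixture()


@pytest.fixture(scope="session")
def sod():
    """The synthetic Septo-Optic-Dysplasia scenario."""
    return make_sod_fixture()


@pytest.fixture(scope="session")
def corpus42(tmp_path_factory):
    """The default synthetic corpus (seed 42) written to disk once per session."""
    directory = tmp_path_factory.mktemp("corpus42")
    truth = make_corpus(CorpusSpec(seed=42), directory)
    return directory, truth
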