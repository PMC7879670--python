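import numpy as np
import pytest

from geff.annotations import AnnotationMatrix
from geff.ontology import OntologyDAG

from tests.oracles import closure_bf, random_dag


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """c -> b -> a (a is the root)."""
    return OntologyDAG([("b", "a", "is_a"), ("c", "b", "is_a")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """d -> {b, c} -> a."""
    return OntologyDAG(
        [
            ("b", "a", "is_a"),
            ("c", "a", "is_a"),
            ("d", "b", "is_a"),
            ("d", "c", "is_a"),
        ]
    )


def make_random_closed_matrix(rng, dag, parents, n_genes, density=0.25):
    """A random ancestor-closed annotation matrix over ``dag``'s terms."""
    terms = sorted(dag.terms)
    values = (rng.random((n_genes, len(terms))) < density).astype(np.uint8)
    values = closure_bf(values, terms, parents)
    return AnnotationMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        terms=terms,
        values=values,
        closed=True,
    )


@pytest.fixture
def random_world():
    """(dag, parents, closed matrix) for property tests."""
    rng = np.random.default_rng(7)
    dag, parents = random_dag(rng, 25)
    mat = make_random_closed_matrix(rng, dag, parents, n_genes=12)
    return dag, parents, mat
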