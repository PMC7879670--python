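import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geff.calibration import (
    STAGE_ANCESTOR_AVERAGED,
    STAGE_CALIBRATED,
    LikelihoodMatrix,
    ancestor_average,
    true_path_fix,
)
from geff.exceptions import ValidationError

from tests.oracles import ancestor_average_bf, random_dag, true_path_fix_bf


def lm(dag, values, stage="raw"):
    terms = sorted(dag.terms)
    return LikelihoodMatrix(
        genes=[f"g{i}" for i in range(values.shape[0])],
        terms=terms,
        values=values,
        stage=stage,
    )


def test_single_ancestor_average(chain_dag):
    # terms sorted: a, b, c ; p(g,a)=0.6, p(g,b)=0.4
    raw = lm(chain_dag, np.array([[0.6, 0.4, 0.0]]))
    out = ancestor_average(raw, chain_dag)
    assert out.stage == STAGE_ANCESTOR_AVERAGED
    assert out.values[0, out.term_index("b")] == pytest.approx((0.6 + 0.4) / 2)


def test_two_ancestor_average(diamond_dag):
    # d has ancestors {a, b, c}; restrict scenario to parents b=0.2, c=0.8
    # plus root a; use a diamond where mean(0.2, 0.8, a) is explicit.
    raw = lm(diamond_dag, np.array([[0.5, 0.2, 0.8, 0.5]]))  # a, b, c, d
    out = ancestor_average(raw, diamond_dag)
    # ancestors(d) = {a, b, c} -> mean = (0.5 + 0.2 + 0.8)/3 = 0.5
    assert out.values[0, out.term_index("d")] == pytest.approx((0.5 + 0.5) / 2)


def test_root_average_is_raw_value(chain_dag):
    raw = lm(chain_dag, np.array([[0.3, 0.9, 0.1]]))
    out = ancestor_average(raw, chain_dag)
    assert out.values[0, out.term_index("a")] == pytest.approx(0.3)


def test_parents_only_variant(chain_dag):
    raw = lm(chain_dag, np.array([[0.9, 0.1, 0.5]]))
    out = ancestor_average(raw, chain_dag, transitive=False)
    # c's parents-only set is {b}: (0.1 + 0.5)/2
    assert out.values[0, out.term_index("c")] == pytest.approx(0.3)
    full = ancestor_average(raw, chain_dag, transitive=True)
    # transitive set {a, b}: ((0.9+0.1)/2 + 0.5)/2
    assert full.values[0, full.term_index("c")] == pytest.approx(0.5)


def test_true_path_fix_chain(chain_dag):
    avg = lm(
        chain_dag,
        np.array([[0.3, 0.7, 0.1]]),  # a, b, c
        stage=STAGE_ANCESTOR_AVERAGED,
    )
    out = true_path_fix(avg, chain_dag)
    vals = {t: out.values[0, out.term_index(t)] for t in "abc"}
    assert vals == {"a": pytest.approx(0.7), "b": pytest.approx(0.7), "c": pytest.approx(0.1)}


def test_leaf_unchanged_by_fix(chain_dag):
    avg = lm(chain_dag, np.array([[0.3, 0.2, 0.9]]), stage=STAGE_ANCESTOR_AVERAGED)
    out = true_path_fix(avg, chain_dag)
    assert out.values[0, out.term_index("c")] == pytest.approx(0.9)
    assert out.stage == STAGE_CALIBRATED


def test_stage_preconditions_enforced(chain_dag):
    raw = lm(chain_dag, np.zeros((1, 3)))
    with pytest.raises(ValidationError):
        true_path_fix(raw, chain_dag)
    with pytest.raises(ValidationError):
        ancestor_average(
            lm(chain_dag, np.zeros((1, 3)), stage=STAGE_CALIBRATED), chain_dag
        )


@pytest.mark.parametrize("seed", list(range(6)))
def test_both_stages_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    dag, parents = random_dag(rng, int(rng.integers(5, 40)))
    terms = sorted(dag.terms)
    values = rng.random((6, len(terms)))
    raw = LikelihoodMatrix(
        genes=[f"g{i}" for i in range(6)], terms=terms, values=values
    )
    avg = ancestor_average(raw, dag)
    np.testing.assert_allclose(
        avg.values, ancestor_average_bf(values, terms, parents), atol=1e-12
    )
    fixed = true_path_fix(avg, dag)
    np.testing.assert_allclose(
        fixed.values, true_path_fix_bf(avg.values, terms, parents), atol=1e-12
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_calibrated_likelihoods_monotone_along_hierarchy(seed):
    """After calibration l(g, ancestor) >= l(g, descendant), always."""
    rng = np.random.default_rng(seed)
    dag, parents = random_dag(rng, 20)
    terms = sorted(dag.terms)
    raw = LikelihoodMatrix(
        genes=["g0", "g1"], terms=terms, values=rng.random((2, len(terms)))
    )
    fixed = true_path_fix(ancestor_average(raw, dag), dag)
    for t in terms:
        j = fixed.term_index(t)
        for anc in dag.ancestors(t):
            assert (
                fixed.values[:, fixed.term_index(anc)] >= fixed.values[:, j] - 1e-12
            ).all()


def test_fix_is_idempotent_and_range_preserving(random_world):
    dag, _, _ = random_world
    rng = np.random.default_rng(0)
    terms = sorted(dag.terms)
    raw = LikelihoodMatrix(
        genes=["g"], terms=terms, values=rng.random((1, len(terms)))
    )
    once = true_path_fix(ancestor_average(raw, dag), dag)
    again = true_path_fix(
        LikelihoodMatrix(
            genes=once.genes,
            terms=once.terms,
            values=once.values,
            stage=STAGE_ANCESTOR_AVERAGED,
        ),
        dag,
    )
    np.testing.assert_array_equal(once.values, again.values)
    assert once.values.min() >= 0.0 and once.values.max() <= 1.0


def test_result_independent_of_gene_ordering(random_world):
    dag, _, _ = random_world
    rng = np.random.default_rng(1)
    terms = sorted(dag.terms)
    values = rng.random((5, len(terms)))
    raw = LikelihoodMatrix(
        genes=[f"g{i}" for i in range(5)], terms=terms, values=values
    )
    out = true_path_fix(ancestor_average(raw, dag), dag)
    perm = [3, 1, 4, 0, 2]
    raw_p = LikelihoodMatrix(
        genes=[f"g{i}" for i in perm], terms=terms, values=values[perm]
    )
    out_p = true_path_fix(ancestor_average(raw_p, dag), dag)
    np.testing.assert_allclose(out.values[perm], out_p.values)
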