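import numpy as np
import pytest

from geff.annotations import AnnotationMatrix
from geff.calibration import STAGE_CALIBRATED, LikelihoodMatrix
from geff.ensemble import EnsembleConfig, PredictionRecord, PredictionSet
from geff.evaluation import evaluate, sweep
from geff.ontology import OntologyDAG


@pytest.fixture
def dag():
    return OntologyDAG([("b", "a", "is_a"), ("c", "b", "is_a")])


def updated_matrix(cells, genes, terms):
    mat = AnnotationMatrix(
        genes=genes, terms=terms,
        values=np.zeros((len(genes), len(terms)), dtype=np.uint8),
        role="updated_validation",
    )
    for g, t in cells:
        mat.values[mat.gene_index(g), mat.term_index(t)] = 1
    return mat


def preds(*pairs):
    return PredictionSet(
        records=[PredictionRecord(g, t, likelihood=0.9) for g, t in pairs]
    )


def test_half_confirmed(dag):
    updated = updated_matrix([("g1", "b")], ["g1"], ["a", "b", "c"])
    report = evaluate(preds(("g1", "b"), ("g1", "c")), updated, dag)
    assert report.n_predictions == 2
    assert report.precision == pytest.approx(0.5)


def test_all_confirmed_and_avg_level(dag):
    updated = updated_matrix([("g1", "b"), ("g1", "c")], ["g1"], ["a", "b", "c"])
    report = evaluate(preds(("g1", "b"), ("g1", "c")), updated, dag)
    assert report.precision == pytest.approx(1.0)
    assert report.avg_level == pytest.approx((1 + 2) / 2)


def test_empty_prediction_set_reports_undefined_precision(dag):
    updated = updated_matrix([], ["g1"], ["a"])
    report = evaluate(preds(), updated, dag)
    assert report.n_predictions == 0
    assert report.precision is None
    assert report.avg_level is None


def test_restrict_shared_excludes_unshared_pairs(dag):
    updated = updated_matrix([("g1", "b")], ["g1"], ["a", "b", "c"])
    p = preds(("g1", "b"), ("ghost", "b"), ("g1", "c"))
    strict = evaluate(p, updated, dag, restrict_shared=True)
    assert strict.n_predictions == 2
    assert strict.precision == pytest.approx(0.5)
    loose = evaluate(p, updated, dag, restrict_shared=False)
    assert loose.n_predictions == 3
    assert loose.precision == pytest.approx(1 / 3)


def test_precision_invariant_to_record_order(dag):
    updated = updated_matrix([("g1", "b")], ["g1"], ["a", "b", "c"])
    a = evaluate(preds(("g1", "b"), ("g1", "c")), updated, dag)
    b = evaluate(preds(("g1", "c"), ("g1", "b")), updated, dag)
    assert a.precision == b.precision and a.n_predictions == b.n_predictions


@pytest.mark.parametrize("seed", [0, 1])
def test_report_matches_bruteforce_recomputation(dag, seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(8)]
    terms = ["a", "b", "c"]
    upd_cells = {
        (g, t) for g in genes for t in terms if rng.random() < 0.4
    }
    updated = updated_matrix(sorted(upd_cells), genes, terms)
    pred_pairs = [
        (g, t) for g in genes for t in terms if rng.random() < 0.3
    ]
    report = evaluate(preds(*pred_pairs), updated, dag)
    n = len(pred_pairs)
    confirmed = sum(1 for pair in pred_pairs if pair in upd_cells)
    levels = {"a": 0, "b": 1, "c": 2}
    assert report.n_predictions == n
    assert report.precision == pytest.approx(confirmed / n)
    assert report.avg_level == pytest.approx(
        sum(levels[t] for _, t in pred_pairs) / n
    )


class TestSweep:
    @pytest.fixture
    def instance(self, dag):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        terms = ["a", "b", "c"]
        mats = [
            LikelihoodMatrix(
                genes=genes, terms=terms,
                values=rng.random((10, 3)), stage=STAGE_CALIBRATED,
            )
            for _ in range(5)
        ]
        known = AnnotationMatrix(
            genes=genes, terms=terms,
            values=(rng.random((10, 3)) < 0.2).astype(np.uint8),
        )
        updated = AnnotationMatrix(
            genes=genes, terms=terms,
            values=(rng.random((10, 3)) < 0.5).astype(np.uint8),
            role="updated_validation",
        )
        return mats, known, updated

    def test_n_non_increasing_in_rho_and_x(self, dag, instance):
        mats, known, updated = instance
        rho_cfgs = [EnsembleConfig(n=5, mode="avg", rho=r) for r in (0.2, 0.5, 0.8)]
        table = sweep(rho_cfgs, mats, known, updated, dag)
        assert list(table["N"]) == sorted(table["N"], reverse=True)
        x_cfgs = [
            EnsembleConfig(n=5, mode="vote", x=x, rho=0.5) for x in range(1, 6)
        ]
        table = sweep(x_cfgs, mats, known, updated, dag)
        assert list(table["N"]) == sorted(table["N"], reverse=True)

    def test_sweep_rows_equal_individual_evaluate_calls(self, dag, instance):
        from geff.ensemble import combine_vote

        mats, known, updated = instance
        cfgs = [EnsembleConfig(n=5, mode="vote", x=x, rho=0.5) for x in (1, 3, 5)]
        table = sweep(cfgs, mats, known, updated, dag)
        for row, cfg in zip(table.itertuples(), cfgs):
            report = evaluate(
                combine_vote(mats, known, cfg.x, cfg.rho), updated, dag
            )
            assert row.N == report.n_predictions
            assert row.precision == pytest.approx(report.precision)


def test_single_model_report_is_mean_of_member_reports(dag):
    from geff.ensemble import combine_avg
    from geff.evaluation import single_model_report

    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(12)]
    terms = ["a", "b", "c"]
    mats = [
        LikelihoodMatrix(
            genes=genes, terms=terms,
            values=rng.random((12, 3)), stage=STAGE_CALIBRATED,
        )
        for _ in range(3)
    ]
    known = AnnotationMatrix(
        genes=genes, terms=terms,
        values=(rng.random((12, 3)) < 0.2).astype(np.uint8),
    )
    updated = AnnotationMatrix(
        genes=genes, terms=terms,
        values=(rng.random((12, 3)) < 0.5).astype(np.uint8),
        role="updated_validation",
    )
    sm = single_model_report(mats, known, updated, dag, rho=0.5)
    members = [
        evaluate(combine_avg([m], known, 0.5), updated, dag) for m in mats
    ]
    assert sm.n_predictions == round(
        sum(r.n_predictions for r in members) / 3
    )
    assert sm.precision == pytest.approx(
        np.mean([r.precision for r in members])
    )
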