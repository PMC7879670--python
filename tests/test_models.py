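import numpy as np
import pytest

from geff.annotations import AnnotationMatrix
from geff.exceptions import ValidationError
from geff.models import (
    CrossOrganismConfig,
    select_terms,
    select_training_genes,
    train_models,
    predict_raw,
)

def matrix(genes, terms, values, role="source_original"):
    return AnnotationMatrix(
        genes=genes, terms=terms, values=np.asarray(values, dtype=np.uint8),
        role=role, closed=True,
    )


class TestSelectTerms:
    def test_intersection(self):
        assert select_terms({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}

    def test_identity(self):
        assert select_terms({"a", "b"}, {"a", "b"}) == {"a", "b"}

    def test_disjoint_errors(self):
        with pytest.raises(ValidationError):
            select_terms({"a"}, {"b"})


class TestSelectTrainingGenes:
    def test_threshold_boundary(self):
        mat = matrix(
            ["g5", "g4"], ["t1", "t2", "t3", "t4", "t5"],
            [[1, 1, 1, 1, 1], [1, 1, 1, 1, 0]],
        )
        T = {"t1", "t2", "t3", "t4", "t5"}
        assert select_training_genes(mat, T, 5) == ["g5"]

    def test_counts_restricted_to_term_set(self):
        terms = [f"t{i}" for i in range(10)]
        row = [1] * 10
        mat = matrix(["g"], terms, [row])
        with pytest.raises(ValidationError):
            # 10 annotations overall but only 3 inside T
            select_training_genes(mat, {"t0", "t1", "t2"}, 5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_row_sum_filter(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        terms = [f"t{i}" for i in range(12)]
        values = (rng.random((30, 12)) < 0.4).astype(np.uint8)
        mat = matrix(genes, terms, values)
        T = set(rng.choice(terms, size=6, replace=False).tolist())
        expected = [
            g
            for i, g in enumerate(genes)
            if sum(values[i, j] for j, t in enumerate(terms) if t in T) >= 3
        ]
        assert select_training_genes(mat, T, 3) == expected


def planted_rule_world(n_genes=200, seed=0):
    """tc ('t_c') is 1 exactly when tb ('t_b') is 1; other terms random."""
    rng = np.random.default_rng(seed)
    terms = ["t_a", "t_b", "t_c", "t_d"]
    tb = (rng.random(n_genes) < 0.5).astype(np.uint8)
    ta = (rng.random(n_genes) < 0.5).astype(np.uint8)
    td = (rng.random(n_genes) < 0.5).astype(np.uint8)
    values = np.stack([ta, tb, tb.copy(), td], axis=1)
    genes = [f"g{i}" for i in range(n_genes)]
    return matrix(genes, terms, values), terms


class TestTrainModels:
    def cfg(self, terms, **kw):
        kw.setdefault("min_gene_annotations", 1)
        kw.setdefault("classifier_params", {"n_estimators": 25})
        return CrossOrganismConfig(term_set=set(terms), **kw)

    def test_one_model_per_term_with_leak_free_features(self):
        mat, terms = planted_rule_world(50)
        ms = train_models(mat, mat, self.cfg(terms))
        assert set(ms.models) == set(terms)
        for tc, model in ms.models.items():
            assert tc not in model.feature_terms
            assert len(model.feature_terms) == 3

    def test_all_zero_label_column_gives_degenerate_zero_model(self):
        mat = matrix(
            ["g1", "g2"], ["t1", "t2", "t3"], [[1, 1, 0], [1, 0, 0]]
        )
        ms = train_models(mat, mat, self.cfg(["t1", "t2", "t3"]))
        assert ms.models["t3"].degenerate_value == 0.0
        assert ms.models["t1"].degenerate_value == 1.0

    def test_planted_rule_recovered(self):
        mat, terms = planted_rule_world()
        ms = train_models(mat, mat, self.cfg(terms))
        raw = predict_raw(ms, mat)
        j = raw.term_index("t_c")
        tb = mat.values[:, mat.term_index("t_b")]
        with_tb = raw.values[tb == 1, j]
        without_tb = raw.values[tb == 0, j]
        assert with_tb.min() > without_tb.max()
        assert with_tb.min() > 0.5

    def test_reproducible_given_seeds(self):
        mat, terms = planted_rule_world(80)
        a = predict_raw(train_models(mat, mat, self.cfg(terms, base_seed=5)), mat)
        b = predict_raw(train_models(mat, mat, self.cfg(terms, base_seed=5)), mat)
        np.testing.assert_array_equal(a.values, b.values)

    def test_shape_mismatch_rejected(self):
        mat, terms = planted_rule_world(20)
        other = matrix(["x"], list(mat.terms), [[1, 1, 1, 1]])
        with pytest.raises(ValidationError):
            train_models(other, mat, self.cfg(terms))


class TestPredictRaw:
    def test_degenerate_constant_propagates(self):
        mat = matrix(["g1", "g2"], ["t1", "t2"], [[1, 0], [1, 0]])
        cfg = CrossOrganismConfig(term_set={"t1", "t2"}, min_gene_annotations=1)
        ms = train_models(mat, mat, cfg)
        raw = predict_raw(ms, mat)
        np.testing.assert_array_equal(raw.values[:, raw.term_index("t2")], [0.0, 0.0])
        np.testing.assert_array_equal(raw.values[:, raw.term_index("t1")], [1.0, 1.0])

    def test_all_zero_feature_row_scored_in_range(self):
        mat, terms = planted_rule_world(60)
        cfg = CrossOrganismConfig(
            term_set=set(terms), min_gene_annotations=1,
            classifier_params={"n_estimators": 10},
        )
        ms = train_models(mat, mat, cfg)
        empty = matrix(["novel"], list(mat.terms), [[0, 0, 0, 0]], role="target_known")
        raw = predict_raw(ms, empty)
        assert raw.values.min() >= 0.0 and raw.values.max() <= 1.0

    def test_missing_feature_term_rejected(self):
        mat, terms = planted_rule_world(30)
        cfg = CrossOrganismConfig(term_set=set(terms), min_gene_annotations=1)
        ms = train_models(mat, mat, cfg)
        partial = matrix(["g"], ["t_a", "t_b"], [[1, 0]])
        with pytest.raises(ValidationError):
            predict_raw(ms, partial)


def test_knn_classifier_supported():
    mat, terms = planted_rule_world(100)
    cfg = CrossOrganismConfig(
        term_set=set(terms), min_gene_annotations=1, classifier_kind="knn"
    )
    raw = predict_raw(train_models(mat, mat, cfg), mat)
    j = raw.term_index("t_c")
    tb = mat.values[:, mat.term_index("t_b")]
    assert raw.values[tb == 1, j].mean() > raw.values[tb == 0, j].mean()


def test_modelset_save_load_roundtrip(tmp_path):
    mat, terms = planted_rule_world(60)
    cfg = CrossOrganismConfig(
        term_set=set(terms), min_gene_annotations=1,
        classifier_params={"n_estimators": 10},
    )
    from geff.models import ModelSet

    ms = train_models(mat, mat, cfg)
    ms.save(str(tmp_path / "models"))
    back = ModelSet.load(str(tmp_path / "models"))
    assert back.terms == ms.terms
    np.testing.assert_array_equal(
        predict_raw(back, mat).values, predict_raw(ms, mat).values
    )
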