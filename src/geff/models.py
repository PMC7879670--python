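"""Per-term binary classifiers and cross-organism term/gene selection.

The annotation-discovery problem is recast as supervised multi-label
classification by binary relevance: for each *class-term* tc in the working
term set T, a binary classifier predicts whether a gene carries tc from the
gene's annotation profile over all other terms of T.  Training pairs a
perturbed (artificially outdated) source matrix, supplying the features,
with the original source matrix, supplying the labels; the fitted models are
then applied to the target organism's known annotation rows.

Cross-organism transfer needs no gene orthology: models see only term
profiles, so the working vocabulary is the intersection of source and target
term sets, and training genes are the source genes carrying at least
``min_gene_annotations`` annotations inside that vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .annotations import AnnotationMatrix
from .calibration import STAGE_RAW, LikelihoodMatrix
from .exceptions import ValidationError

__all__ = [
    "CrossOrganismConfig",
    "ClassifierModel",
    "ModelSet",
    "select_terms",
    "select_training_genes",
    "train_models",
    "predict_raw",
]

RANDOM_FOREST = "random_forest"
KNN = "knn"


@dataclass
class CrossOrganismConfig:
    """Term set, gene-selection threshold and base-learner choice.

    ``term_set`` is the shared vocabulary T (source ∩ target terms); ``None``
    lets pipeline drivers derive it from the data.  ``min_gene_annotations``
    keeps only source genes with at least that many annotations inside T
    (default 5).  ``classifier_kind`` is ``random_forest`` (100 trees;
    confidence = fraction of trees voting positive) or ``knn`` (k = 5;
    confidence = fraction of positive neighbours).
    """

    term_set: set[str] | None = None
    min_gene_annotations: int = 5
    classifier_kind: str = RANDOM_FOREST
    classifier_params: dict[str, Any] = field(default_factory=dict)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.term_set is not None and not self.term_set:
            raise ValidationError("term set must be non-empty")
        if self.min_gene_annotations < 1:
            raise ValidationError("min_gene_annotations must be >= 1")
        if self.classifier_kind not in (RANDOM_FOREST, KNN):
            raise ValidationError(
                f"unknown classifier kind {self.classifier_kind!r}"
            )


@dataclass
class ClassifierModel:
    """One fitted binary model for a class-term.

    Either ``scorer`` is a fitted estimator exposing ``predict_proba`` or,
    when the training labels had a single class, ``degenerate_value`` holds
    the constant confidence any calibrated learner would converge to.
    """

    class_term: str
    feature_terms: tuple[str, ...]
    scorer: Any = None
    degenerate_value: float | None = None

    def __post_init__(self) -> None:
        if self.class_term in self.feature_terms:
            raise ValidationError(
                f"class term {self.class_term!r} leaked into its feature set"
            )
        if (self.scorer is None) == (self.degenerate_value is None):
            raise ValidationError(
                "exactly one of scorer / degenerate_value must be set"
            )

    def score(self, features: np.ndarray) -> np.ndarray:
        """Confidence in [0, 1] for each row of ``features``."""
        if self.degenerate_value is not None:
            return np.full(features.shape[0], self.degenerate_value)
        proba = self.scorer.predict_proba(features)
        positive = list(self.scorer.classes_).index(1)
        return np.clip(proba[:, positive], 0.0, 1.0)


@dataclass
class ModelSet:
    """One classifier per term of the working vocabulary, with provenance."""

    models: dict[str, ClassifierModel]
    terms: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.models) != set(self.terms):
            raise ValidationError("model set must hold exactly one model per term")

    def save(self, directory: str) -> None:
        """Persist fitted models (one artifact per term) plus a JSON manifest."""
        import json
        from pathlib import Path

        import joblib

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"terms": self.terms, "provenance": self.provenance, "models": {}}
        for i, (tc, model) in enumerate(sorted(self.models.items())):
            entry = {
                "class_term": tc,
                "feature_terms": list(model.feature_terms),
                "degenerate_value": model.degenerate_value,
            }
            if model.scorer is not None:
                fname = f"model_{i:05d}.joblib"
                joblib.dump(model.scorer, out / fname)
                entry["artifact"] = fname
            manifest["models"][tc] = entry
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str) -> "ModelSet":
        import json
        from pathlib import Path

        import joblib

        out = Path(directory)
        manifest = json.loads((out / "manifest.json").read_text())
        models = {}
        for tc, entry in manifest["models"].items():
            scorer = (
                joblib.load(out / entry["artifact"]) if "artifact" in entry else None
            )
            models[tc] = ClassifierModel(
                class_term=tc,
                feature_terms=tuple(entry["feature_terms"]),
                scorer=scorer,
                degenerate_value=entry["degenerate_value"],
            )
        return cls(
            models=models,
            terms=manifest["terms"],
            provenance=manifest.get("provenance", {}),
        )


def select_terms(source_terms: set[str], target_terms: set[str]) -> set[str]:
    """The shared vocabulary T = TS ∩ TT; empty intersection is an error."""
    shared = set(source_terms) & set(target_terms)
    if not shared:
        raise ValidationError(
            "source and target organisms share no ontology terms"
        )
    return shared


def select_training_genes(
    source: AnnotationMatrix, term_set: set[str], k: int
) -> list[str]:
    """Source genes with at least ``k`` annotations to terms of ``term_set``."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    cols = [j for j, t in enumerate(source.terms) if t in term_set]
    sums = source.values[:, cols].sum(axis=1)
    genes = [g for g, s in zip(source.genes, sums) if s >= k]
    if not genes:
        raise ValidationError(
            f"no source gene has >= {k} annotations inside the shared term set"
        )
    return genes


def _model_seed(base_seed: int, perturbation_seed: int, term_idx: int) -> int:
    ss = np.random.SeedSequence(
        [abs(int(base_seed)), abs(int(perturbation_seed)), term_idx]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _make_estimator(cfg: CrossOrganismConfig, seed: int):
    if cfg.classifier_kind == RANDOM_FOREST:
        params = {"n_estimators": 100, **cfg.classifier_params}
        return RandomForestClassifier(random_state=seed, **params)
    params = {"n_neighbors": 5, **cfg.classifier_params}
    return KNeighborsClassifier(**params)


def train_models(
    perturbed: AnnotationMatrix,
    original: AnnotationMatrix,
    cfg: CrossOrganismConfig,
    perturbation_seed: int = 0,
) -> ModelSet:
    """Fit one binary model per term of T on (perturbed features, original labels).

    For each class-term tc, features are the perturbed matrix's columns over
    T \\ {tc} and labels the original matrix's tc column, restricted to the
    selected training genes.  A label column with a single class yields a
    degenerate constant model instead of a fit.  Fitting is seeded from
    ``cfg.base_seed``, ``perturbation_seed`` and the term index, so runs are
    reproducible.
    """
    if cfg.term_set is None:
        raise ValidationError("config term_set must be resolved before training")
    terms = sorted(cfg.term_set)
    for mat, label in ((perturbed, "perturbed"), (original, "original")):
        missing = [t for t in terms if not mat.has_term(t)]
        if missing:
            raise ValidationError(
                f"{label} matrix lacks shared terms, e.g. {missing[:5]}"
            )
    if perturbed.genes != original.genes:
        raise ValidationError(
            "perturbed and original matrices must share gene indexing"
        )

    train_genes = select_training_genes(
        original, cfg.term_set, cfg.min_gene_annotations
    )
    rows = np.array([original.gene_index(g) for g in train_genes])
    pert_cols = np.array([perturbed.term_index(t) for t in terms])
    orig_cols = np.array([original.term_index(t) for t in terms])
    X_all = perturbed.values[np.ix_(rows, pert_cols)]
    Y_all = original.values[np.ix_(rows, orig_cols)]

    models: dict[str, ClassifierModel] = {}
    for j, tc in enumerate(terms):
        feature_terms = tuple(t for t in terms if t != tc)
        feat_idx = [i for i in range(len(terms)) if i != j]
        y = Y_all[:, j]
        if y.min() == y.max():  # single-class label column
            models[tc] = ClassifierModel(
                class_term=tc,
                feature_terms=feature_terms,
                degenerate_value=float(y[0]),
            )
            continue
        est = _make_estimator(
            cfg, _model_seed(cfg.base_seed, perturbation_seed, j)
        )
        est.fit(X_all[:, feat_idx], y)
        models[tc] = ClassifierModel(
            class_term=tc, feature_terms=feature_terms, scorer=est
        )
    return ModelSet(
        models=models,
        terms=terms,
        provenance={
            "n_training_genes": len(train_genes),
            "perturbation_seed": perturbation_seed,
            "base_seed": cfg.base_seed,
            "classifier_kind": cfg.classifier_kind,
            "source_role": original.role,
        },
    )


def predict_raw(
    model_set: ModelSet, target_known: AnnotationMatrix
) -> LikelihoodMatrix:
    """Raw likelihood p(g, t) for every target gene and every term of T.

    Feature rows come from the target organism's known (unperturbed)
    annotation matrix.  Genes with an all-zero feature row are still scored:
    the estimator's confidence for the empty profile is a legitimate
    (typically low) likelihood.
    """
    missing = [t for t in model_set.terms if not target_known.has_term(t)]
    if missing:
        raise ValidationError(
            f"target matrix lacks model terms, e.g. {missing[:5]}"
        )
    cols = {t: target_known.term_index(t) for t in model_set.terms}
    values = np.empty((len(target_known.genes), len(model_set.terms)))
    for j, tc in enumerate(model_set.terms):
        model = model_set.models[tc]
        feat_cols = [cols[t] for t in model.feature_terms]
        values[:, j] = model.score(target_known.values[:, feat_cols])
    return LikelihoodMatrix(
        genes=list(target_known.genes),
        terms=list(model_set.terms),
        values=values,
        stage=STAGE_RAW,
    )
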