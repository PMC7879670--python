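"""Model/Results interface over the cross-organism ensemble pipeline.

:class:`CrossOrganismAnnotationModel` bundles the ontology, the source
organism's known annotation matrix (training data) and the target organism's
known matrix (prediction input) together with the ensemble settings.
``fit()`` performs the expensive work — n seeded perturbations, one
classifier per shared term per perturbation, raw scoring of the target and
True-Path-Rule calibration — and returns a
:class:`CrossOrganismAnnotationResults` holding the n calibrated likelihood
matrices.  Prediction extraction (AVG or x-of-n voting at a threshold rho)
and evaluation against a later annotation snapshot are cheap post-fit
operations, so threshold and voting grids can be explored without
retraining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from .annotations import (
    AnnotationMatrix,
    build_matrix,
    filter_reliable,
    load_gaf,
)
from .calibration import LikelihoodMatrix, ancestor_average, true_path_fix
from .ensemble import (
    MODE_AVG,
    MODE_VOTE,
    EnsembleConfig,
    PredictionSet,
    combine_avg,
    combine_vote,
)
from .evaluation import EvaluationReport, evaluate, sweep
from .exceptions import ValidationError
from .models import CrossOrganismConfig, predict_raw, select_terms, train_models
from .ontology import OntologyDAG, load_obo
from .perturbation import make_perturbation_set

__all__ = ["CrossOrganismAnnotationModel", "CrossOrganismAnnotationResults"]


class CrossOrganismAnnotationModel:
    """Ensemble predictor of novel target-organism annotations.

    Parameters
    ----------
    dag
        The ontology over which both organisms are annotated.
    source_known
        Ancestor-closed annotation matrix of the better-annotated source
        organism; supplies both training features (after perturbation) and
        training labels.
    target_known
        Ancestor-closed known matrix of the target organism whose missing
        annotations are to be predicted.
    n_models, perturbation_p, seeds
        Ensemble size, per-cell deletion probability of the perturbation,
        and the n distinct perturbation seeds (defaults: 5, 0.1, 1..n).
    classifier, classifier_params, min_gene_annotations, base_seed
        Base-learner settings, passed through to the per-term classifiers.
    """

    def __init__(
        self,
        dag: OntologyDAG,
        source_known: AnnotationMatrix,
        target_known: AnnotationMatrix,
        *,
        n_models: int = 5,
        perturbation_p: float = 0.1,
        seeds: Iterable[int] | None = None,
        classifier: str = "random_forest",
        classifier_params: dict[str, Any] | None = None,
        min_gene_annotations: int = 5,
        base_seed: int = 0,
    ) -> None:
        self.dag = dag
        self.source_known = source_known
        self.target_known = target_known
        self.n_models = int(n_models)
        self.perturbation_p = float(perturbation_p)
        self.seeds = (
            tuple(seeds) if seeds is not None else tuple(range(1, n_models + 1))
        )
        if len(self.seeds) != self.n_models:
            raise ValidationError(
                f"need {self.n_models} perturbation seeds, got {len(self.seeds)}"
            )
        shared = select_terms(
            source_known.annotated_terms(), target_known.annotated_terms()
        )
        self.cross_config = CrossOrganismConfig(
            term_set=shared,
            min_gene_annotations=min_gene_annotations,
            classifier_kind=classifier,
            classifier_params=classifier_params or {},
            base_seed=base_seed,
        )

    @classmethod
    def from_files(
        cls,
        obo_path: str,
        source_path: str,
        target_path: str,
        *,
        include_iea_only: bool = False,
        include_part_of: bool = False,
        **kwargs: Any,
    ) -> "CrossOrganismAnnotationModel":
        """Build the model from an OBO file and two GAF/TSV annotation files.

        Annotations supported only by uncurated evidence (IEA/ND) are
        dropped unless ``include_iea_only`` is set; matrices are
        ancestor-closed on load.
        """
        dag = load_obo(obo_path, include_part_of=include_part_of)
        source = build_matrix(
            filter_reliable(load_gaf(source_path), include_iea_only),
            dag,
            role="source_original",
        )
        target = build_matrix(
            filter_reliable(load_gaf(target_path), include_iea_only),
            dag,
            role="target_known",
        )
        return cls(dag, source, target, **kwargs)

    def fit(self) -> "CrossOrganismAnnotationResults":
        """Train the n-member ensemble and calibrate target likelihoods."""
        perturbed_set = make_perturbation_set(
            self.source_known, self.perturbation_p, list(self.seeds), self.dag
        )
        calibrated: list[LikelihoodMatrix] = []
        n_training_genes = 0
        for seed, perturbed in zip(self.seeds, perturbed_set):
            ms = train_models(
                perturbed,
                self.source_known,
                self.cross_config,
                perturbation_seed=seed,
            )
            n_training_genes = ms.provenance["n_training_genes"]
            raw = predict_raw(ms, self.target_known)
            calibrated.append(
                true_path_fix(ancestor_average(raw, self.dag), self.dag)
            )
        terms = sorted(self.cross_config.term_set)
        return CrossOrganismAnnotationResults(
            model=self,
            calibrated=calibrated,
            known=self.target_known.restrict_terms(terms),
            n_training_genes=n_training_genes,
        )


@dataclass
class CrossOrganismAnnotationResults:
    """Fitted ensemble state: n calibrated likelihood matrices plus extractors."""

    model: CrossOrganismAnnotationModel
    calibrated: list[LikelihoodMatrix]
    known: AnnotationMatrix
    n_training_genes: int = 0
    _cache: dict[Any, PredictionSet] = field(default_factory=dict, repr=False)

    def predict(
        self, mode: str = MODE_VOTE, x: int | None = None, rho: float = 0.8
    ) -> PredictionSet:
        """Extract predicted novel annotations under one combination rule."""
        n = len(self.calibrated)
        if mode == MODE_VOTE and x is None:
            x = n
        key = (mode, x, rho)
        if key not in self._cache:
            cfg = EnsembleConfig(
                n=n,
                mode=mode,
                x=x if mode == MODE_VOTE else None,
                rho=rho,
                p=self.model.perturbation_p,
                seeds=self.model.seeds,
            )
            if mode == MODE_AVG:
                ps = combine_avg(self.calibrated, self.known, rho, config=cfg)
            else:
                ps = combine_vote(self.calibrated, self.known, x, rho, config=cfg)
            self._cache[key] = ps
        return self._cache[key]

    def evaluate(
        self,
        updated: AnnotationMatrix,
        mode: str = MODE_VOTE,
        x: int | None = None,
        rho: float = 0.8,
        restrict_shared: bool = False,
    ) -> EvaluationReport:
        """Score one configuration against a later annotation snapshot."""
        return evaluate(
            self.predict(mode, x, rho), updated, self.model.dag, restrict_shared
        )

    def sweep(
        self,
        updated: AnnotationMatrix,
        configs: Iterable[EnsembleConfig],
        restrict_shared: bool = False,
    ) -> pd.DataFrame:
        """Evaluate a grid of ensemble configurations without retraining."""
        return sweep(
            configs,
            self.calibrated,
            self.known,
            updated,
            self.model.dag,
            restrict_shared=restrict_shared,
        )

    def predictions_frame(
        self, mode: str = MODE_VOTE, x: int | None = None, rho: float = 0.8
    ) -> pd.DataFrame:
        """Ranked predictions as a DataFrame ready for CSV export."""
        ps = self.predict(mode, x, rho)
        cfg = ps.config_snapshot
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "term": r.term,
                    "term_name": self.model.dag.name(r.term) or "",
                    "likelihood": r.likelihood,
                    "votes": r.votes,
                    "n": cfg.n,
                    "mode": cfg.mode,
                    "rho": cfg.rho,
                    "p": cfg.p,
                }
                for r in ps.records
            ]
        )

    def summary(self) -> str:
        """Human-readable account of the fitted ensemble."""
        m = self.model
        lines = [
            "Cross-organism annotation ensemble",
            "=" * 42,
            f"shared terms (T):        {len(self.known.terms)}",
            f"source genes (trained):  {self.n_training_genes}",
            f"target genes (scored):   {len(self.known.genes)}",
            f"ensemble members (n):    {len(self.calibrated)}",
            f"perturbation p:          {m.perturbation_p}",
            f"classifier:              {m.cross_config.classifier_kind}",
            f"perturbation seeds:      {list(m.seeds)}",
            "",
            "predictions at rho=0.8 (novel pairs only):",
        ]
        for label, mode, x in (
            ("AVG", MODE_AVG, None),
            ("1-of-n vote", MODE_VOTE, 1),
            (f"{len(self.calibrated)}-of-n vote", MODE_VOTE, len(self.calibrated)),
        ):
            ps = self.predict(mode, x, 0.8)
            lines.append(f"  {label:<14} N = {len(ps)}")
        return "\n".join(lines)
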