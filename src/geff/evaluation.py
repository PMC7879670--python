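"""Score predicted novel annotations against a later annotation snapshot.

Following the old-version/new-version protocol, a prediction made from the
known (older) matrix counts as confirmed when the same gene-term pair is
annotated in the updated (later) matrix.  Three summary measures are
reported: the number of predictions N, their precision Pr (confirmed
fraction), and the average ontology level of the predicted terms (deeper
terms denote more specific, hence more valuable, functions).

Measured precision is a lower bound on true precision: a predicted
annotation absent from the updated snapshot may simply not have been
discovered yet.  This caveat is recorded in the report metadata, never
adjusted for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import pandas as pd

from .annotations import AnnotationMatrix
from .calibration import LikelihoodMatrix
from .ensemble import (
    MODE_AVG,
    EnsembleConfig,
    PredictionSet,
    combine_avg,
    combine_vote,
)
from .exceptions import ValidationError
from .ontology import OntologyDAG

__all__ = ["EvaluationReport", "evaluate", "single_model_report", "sweep"]

PRECISION_CAVEAT = (
    "precision may underestimate true precision: unconfirmed predictions "
    "may be annotations not yet discovered in the updated snapshot"
)


@dataclass
class EvaluationReport:
    """N, precision and average predicted-term level for one configuration.

    ``precision`` and ``avg_level`` are None (undefined, not 0 or 1) when
    there are no scored predictions.
    """

    n_predictions: int
    precision: float | None
    avg_level: float | None
    config_snapshot: EnsembleConfig | None = None
    validation_role: str = "updated_validation"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precision is not None and not 0.0 <= self.precision <= 1.0:
            raise ValidationError("precision must lie in [0, 1]")


def evaluate(
    predictions: PredictionSet,
    updated: AnnotationMatrix,
    dag: OntologyDAG,
    restrict_shared: bool = False,
) -> EvaluationReport:
    """Confirm predictions against the updated matrix and summarize.

    With ``restrict_shared`` set, predictions involving genes or terms
    absent from the updated matrix are excluded before scoring (mirroring
    evaluation over genes and terms shared between the two snapshot
    versions); otherwise such predictions count as unconfirmed.
    """
    records = predictions.records
    excluded = 0
    if restrict_shared:
        kept = [
            r
            for r in records
            if updated.has_gene(r.gene) and updated.has_term(r.term)
        ]
        excluded = len(records) - len(kept)
        records = kept

    n = len(records)
    if n == 0:
        return EvaluationReport(
            n_predictions=0,
            precision=None,
            avg_level=None,
            config_snapshot=predictions.config_snapshot,
            metadata={"excluded_unshared": excluded, "caveat": PRECISION_CAVEAT},
        )
    confirmed = sum(
        1
        for r in records
        if updated.has_gene(r.gene)
        and updated.has_term(r.term)
        and updated.value(r.gene, r.term) == 1
    )
    levels = [dag.term_level(r.term) for r in records]
    return EvaluationReport(
        n_predictions=n,
        precision=confirmed / n,
        avg_level=sum(levels) / n,
        config_snapshot=predictions.config_snapshot,
        metadata={"excluded_unshared": excluded, "caveat": PRECISION_CAVEAT},
    )


def single_model_report(
    mats: list[LikelihoodMatrix],
    known: AnnotationMatrix,
    updated: AnnotationMatrix,
    dag: OntologyDAG,
    rho: float,
    restrict_shared: bool = False,
) -> EvaluationReport:
    """The SM baseline: mean performance of the n models scored separately.

    Each member is thresholded at rho on its own (no ensemble combination);
    N, precision and average level are the means over members, with
    undefined member precisions excluded from the precision mean.
    """
    reports = [
        evaluate(combine_avg([m], known, rho), updated, dag, restrict_shared)
        for m in mats
    ]
    n_mean = sum(r.n_predictions for r in reports) / len(reports)
    precisions = [r.precision for r in reports if r.precision is not None]
    levels = [r.avg_level for r in reports if r.avg_level is not None]
    return EvaluationReport(
        n_predictions=round(n_mean),
        precision=sum(precisions) / len(precisions) if precisions else None,
        avg_level=sum(levels) / len(levels) if levels else None,
        metadata={
            "method": "single_model_mean",
            "n_members": len(mats),
            "mean_n_predictions": n_mean,
            "caveat": PRECISION_CAVEAT,
        },
    )


def _combine(
    cfg: EnsembleConfig,
    mats: list[LikelihoodMatrix],
    known: AnnotationMatrix,
) -> PredictionSet:
    if cfg.mode == MODE_AVG:
        return combine_avg(mats, known, cfg.rho, config=cfg)
    return combine_vote(mats, known, cfg.x, cfg.rho, config=cfg)


def sweep(
    configs: Iterable[EnsembleConfig],
    mats: list[LikelihoodMatrix],
    known: AnnotationMatrix,
    updated: AnnotationMatrix,
    dag: OntologyDAG,
    target: str = "target",
    restrict_shared: bool = False,
) -> pd.DataFrame:
    """Evaluate many ensemble configurations over one set of trained models.

    The calibrated likelihood matrices are computed once upstream and reused
    across every (mode, x, rho) combination, so threshold grids are cheap.
    Returns one row per configuration with columns target, mode, x, n, p,
    rho, N, precision, avg_level.
    """
    rows = []
    for cfg in configs:
        report = evaluate(
            _combine(cfg, mats, known), updated, dag, restrict_shared
        )
        rows.append(
            {
                "target": target,
                "mode": cfg.mode,
                "x": cfg.x,
                "n": cfg.n,
                "p": cfg.p,
                "rho": cfg.rho,
                "N": report.n_predictions,
                "precision": report.precision,
                "avg_level": report.avg_level,
            }
        )
    return pd.DataFrame(rows)
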