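"""Combine calibrated likelihood matrices into predicted novel annotations.

n models (one per perturbation seed) each give a calibrated likelihood for
every candidate gene-term pair.  Two combination rules produce the final
predictions, always restricted to pairs *not* already annotated in the
target's known matrix:

* **AVG** — the final likelihood is the mean of the n model likelihoods; a
  pair is predicted when the mean reaches the threshold rho.
* **x-of-n voting** — a pair is predicted when at least x of the n models
  individually reach rho.  x = 1 is the union of the single-model prediction
  sets, x = n their intersection.

Threshold comparison is inclusive (>= rho) so rho = 1.0 remains satisfiable;
an absolute tolerance of 1e-12 absorbs floating-point representation error in
averaged likelihoods (mean(0.6..1.0) must still count as reaching 0.8).
For voted predictions the reported likelihood is the mean of the likelihoods
that passed the threshold — a ranking convenience, since the voting rule
itself is purely a decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .annotations import AnnotationMatrix
from .calibration import STAGE_CALIBRATED, LikelihoodMatrix
from .exceptions import ValidationError

__all__ = [
    "EnsembleConfig",
    "PredictionRecord",
    "PredictionSet",
    "combine_avg",
    "combine_vote",
]

MODE_AVG = "avg"
MODE_VOTE = "vote"

#: absolute tolerance for the inclusive threshold comparison
RHO_ATOL = 1e-12


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble size, combination rule and thresholds."""

    n: int = 5
    mode: str = MODE_AVG
    x: int | None = None
    rho: float = 0.8
    p: float = 0.1
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("ensemble size n must be >= 1")
        if self.mode not in (MODE_AVG, MODE_VOTE):
            raise ValidationError(f"unknown ensemble mode {self.mode!r}")
        if self.mode == MODE_VOTE:
            if self.x is None or not 1 <= self.x <= self.n:
                raise ValidationError(
                    f"votes x must lie in [1, n={self.n}], got {self.x}"
                )
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("threshold rho must be in [0, 1]")


@dataclass(frozen=True)
class PredictionRecord:
    gene: str
    term: str
    likelihood: float
    votes: int | None = None


@dataclass
class PredictionSet:
    """Ranked novel (gene, term, likelihood) predictions.

    Records are sorted by likelihood descending (ties broken by gene then
    term for determinism).  ``masked_known`` counts the pairs that met the
    decision rule but were excluded because they are already annotated.
    """

    records: list[PredictionRecord]
    config_snapshot: EnsembleConfig | None = None
    masked_known: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.gene, r.term) for r in self.records}


def _check_congruent(
    mats: list[LikelihoodMatrix], known: AnnotationMatrix
) -> None:
    if not mats:
        raise ValidationError("need at least one likelihood matrix")
    ref = mats[0]
    for m in mats:
        if m.stage != STAGE_CALIBRATED:
            raise ValidationError(
                f"likelihood matrices must be calibrated, got stage {m.stage!r}"
            )
        if m.genes != ref.genes or m.terms != ref.terms:
            raise ValidationError("likelihood matrices are not congruent")
    if known.genes != ref.genes or known.terms != ref.terms:
        raise ValidationError(
            "known annotation matrix is not congruent with likelihoods"
        )


def _to_records(
    likelihood: np.ndarray,
    selected: np.ndarray,
    genes: list[str],
    terms: list[str],
    votes: np.ndarray | None,
) -> list[PredictionRecord]:
    gi, tj = np.nonzero(selected)
    recs = [
        PredictionRecord(
            gene=genes[i],
            term=terms[j],
            likelihood=float(likelihood[i, j]),
            votes=None if votes is None else int(votes[i, j]),
        )
        for i, j in zip(gi.tolist(), tj.tolist())
    ]
    recs.sort(key=lambda r: (-r.likelihood, r.gene, r.term))
    return recs


def combine_avg(
    mats: list[LikelihoodMatrix],
    known: AnnotationMatrix,
    rho: float,
    config: EnsembleConfig | None = None,
) -> PredictionSet:
    """Average the n likelihood matrices and threshold at rho."""
    _check_congruent(mats, known)
    mean = np.mean([m.values for m in mats], axis=0)
    passing = mean >= rho - RHO_ATOL
    unknown = known.values == 0
    cfg = config or EnsembleConfig(n=len(mats), mode=MODE_AVG, rho=rho)
    return PredictionSet(
        records=_to_records(mean, passing & unknown, known.genes, known.terms, None),
        config_snapshot=cfg,
        masked_known=int((passing & ~unknown).sum()),
    )


def combine_vote(
    mats: list[LikelihoodMatrix],
    known: AnnotationMatrix,
    x: int,
    rho: float,
    config: EnsembleConfig | None = None,
) -> PredictionSet:
    """Predict pairs for which at least x of the n models reach rho."""
    _check_congruent(mats, known)
    if not 1 <= x <= len(mats):
        raise ValidationError(f"votes x must lie in [1, {len(mats)}], got {x}")
    stack = np.stack([m.values for m in mats])
    passing = stack >= rho - RHO_ATOL
    votes = passing.sum(axis=0)
    selected_rule = votes >= x
    # mean of the likelihoods that passed the threshold (0 votes -> unused)
    with np.errstate(invalid="ignore"):
        passing_mean = np.where(
            votes > 0, (stack * passing).sum(axis=0) / np.maximum(votes, 1), 0.0
        )
    unknown = known.values == 0
    cfg = config or EnsembleConfig(
        n=len(mats), mode=MODE_VOTE, x=x, rho=rho
    )
    return PredictionSet(
        records=_to_records(
            passing_mean, selected_rule & unknown, known.genes, known.terms, votes
        ),
        config_snapshot=cfg,
        masked_known=int((selected_rule & ~unknown).sum()),
    )
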