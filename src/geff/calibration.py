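"""True-Path-Rule calibration of raw per-term likelihoods.

Per-term classifiers are trained independently, so their raw confidences
p(g, t) can violate the True Path Rule (a gene annotated to a term is
annotated to every ancestor of that term).  Calibration proceeds in two
stages:

1. *Ancestor averaging* — each raw likelihood is averaged with the mean raw
   likelihood of the term's ancestors::

       pH(g, t) = ( mean_{ta in ancestors(t)} p(g, ta) + p(g, t) ) / 2

   For a root term the ancestor set is empty and pH(g, t) = p(g, t): the
   empty mean contributes nothing, and the rule-violation fix below pushes
   roots toward the matrix maximum anyway.

2. *Rule-violation fix* — starting from the leaves, the final likelihood is
   the maximum averaged likelihood of the term or any of its descendants::

       l(g, t) = max( pH(g, t), max_{td in descendants(t)} pH(g, td) )

   computed in a single reverse-topological pass over children maxima, which
   is equivalent to the transitive-descendant form and costs O(edges).

After calibration l(g, ancestor) >= l(g, descendant) for every
ancestor/descendant pair, so thresholded prediction sets are themselves
hierarchy-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .ontology import OntologyDAG

__all__ = ["LikelihoodMatrix", "ancestor_average", "true_path_fix"]

STAGE_RAW = "raw"
STAGE_ANCESTOR_AVERAGED = "ancestor_averaged"
STAGE_CALIBRATED = "calibrated"


@dataclass
class LikelihoodMatrix:
    """Real-valued gene x term matrix of annotation likelihoods in [0, 1]."""

    genes: list[str]
    terms: list[str]
    values: np.ndarray
    stage: str = STAGE_RAW
    _term_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.terms)):
            raise ValidationError(
                f"likelihood shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.terms)} terms"
            )
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValidationError("likelihood values must lie in [0, 1]")
        self._term_index = {t: j for j, t in enumerate(self.terms)}

    def term_index(self, term: str) -> int:
        return self._term_index[term]

    def to_csv(self, path: str) -> None:
        """Sparse triplet CSV (gene, term, value, stage); zero cells omitted."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene", "term", "value", "stage"])
            for i, g in enumerate(self.genes):
                for j, t in enumerate(self.terms):
                    v = self.values[i, j]
                    if v != 0.0:
                        w.writerow([g, t, repr(float(v)), self.stage])

    @classmethod
    def from_csv(cls, path: str) -> "LikelihoodMatrix":
        import csv

        triplets: list[tuple[str, str, float]] = []
        stage = STAGE_RAW
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                triplets.append((row["gene"], row["term"], float(row["value"])))
                stage = row.get("stage", STAGE_RAW)
        genes = sorted({g for g, _, _ in triplets})
        terms = sorted({t for _, t, _ in triplets})
        values = np.zeros((len(genes), len(terms)))
        gi = {g: i for i, g in enumerate(genes)}
        tj = {t: j for j, t in enumerate(terms)}
        for g, t, v in triplets:
            values[gi[g], tj[t]] = v
        return cls(genes=genes, terms=terms, values=values, stage=stage)


def ancestor_average(
    raw: LikelihoodMatrix, dag: OntologyDAG, transitive: bool = True
) -> LikelihoodMatrix:
    """Average each raw likelihood with the mean over the term's ancestors.

    ``transitive`` selects the full transitive ancestor set (default); with
    it off only direct parents contribute.  Ancestors outside the matrix's
    term columns carry no likelihood and are ignored.
    """
    if raw.stage != STAGE_RAW:
        raise ValidationError(f"expected a raw-stage matrix, got {raw.stage!r}")
    out = np.empty_like(raw.values)
    for j, t in enumerate(raw.terms):
        if t not in dag:
            raise ValidationError(f"term {t!r} absent from ontology")
        anc = dag.ancestors(t) if transitive else dag.parents(t)
        cols = [raw.term_index(a) for a in anc if a in raw._term_index]
        if cols:
            out[:, j] = (raw.values[:, cols].mean(axis=1) + raw.values[:, j]) / 2.0
        else:
            out[:, j] = raw.values[:, j]
    return LikelihoodMatrix(
        genes=list(raw.genes),
        terms=list(raw.terms),
        values=out,
        stage=STAGE_ANCESTOR_AVERAGED,
    )


def true_path_fix(avg: LikelihoodMatrix, dag: OntologyDAG) -> LikelihoodMatrix:
    """Propagate descendant maxima upward so likelihoods obey the hierarchy.

    Runs leaf-to-root over the whole ontology so that descendants connected
    through terms absent from the matrix still contribute.  Idempotent, and
    independent of gene ordering and of tie order among siblings (max is
    associative and commutative).
    """
    if avg.stage != STAGE_ANCESTOR_AVERAGED:
        raise ValidationError(
            f"expected an ancestor_averaged-stage matrix, got {avg.stage!r}"
        )
    n_genes = len(avg.genes)
    # running[t] = max pH over ({t} union descendants(t)) restricted to matrix terms
    running: dict[str, np.ndarray] = {}
    for t in dag.topological_order():  # children before parents
        acc: np.ndarray | None = None
        if t in avg._term_index:
            acc = avg.values[:, avg.term_index(t)].copy()
        for child in dag.children(t):
            cv = running.get(child)
            if cv is not None:
                acc = cv.copy() if acc is None else np.maximum(acc, cv)
        if acc is not None:
            running[t] = acc
    out = np.empty((n_genes, len(avg.terms)))
    for j, t in enumerate(avg.terms):
        if t not in dag:
            raise ValidationError(f"term {t!r} absent from ontology")
        out[:, j] = running[t]
    return LikelihoodMatrix(
        genes=list(avg.genes),
        terms=list(avg.terms),
        values=out,
        stage=STAGE_CALIBRATED,
    )
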