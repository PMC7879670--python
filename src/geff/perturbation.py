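"""Seeded random perturbation of annotation matrices and consistency repair.

Perturbation emulates an artificial outdated snapshot of an annotation
matrix: every existing annotation (1 cell) is independently deleted with a
preset probability ``p``.  Deletions can leave a matrix inconsistent with the
term hierarchy (a gene annotated to a term but not to one of its ancestors);
*unfolding* repairs this by removing every annotation with a deleted
ancestor, yielding the maximal hierarchy-consistent submatrix.  Repair by
deletion (rather than re-adding ancestors) keeps the perturbation a strict
information-removal operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationMatrix
from .exceptions import ValidationError
from .ontology import OntologyDAG

__all__ = ["PerturbationConfig", "perturb", "unfold", "make_perturbation_set"]


@dataclass(frozen=True)
class PerturbationConfig:
    """Deletion probability and random seed for one perturbed copy."""

    deletion_probability: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.deletion_probability <= 1.0:
            raise ValidationError(
                f"deletion probability must be in [0, 1], got {self.deletion_probability}"
            )


def perturb(matrix: AnnotationMatrix, cfg: PerturbationConfig) -> AnnotationMatrix:
    """Delete each 1 cell independently with probability ``cfg.deletion_probability``.

    Uses one generator stream per (matrix, seed) pair with a uniform draw per
    cell in row-major order over the stored gene/term order, so identical
    inputs reproduce identical outputs across runs and platforms.  Zero cells
    are never touched.  The result is tagged ``source_perturbed`` and marked
    not closed (run :func:`unfold` to repair consistency).
    """
    rng = np.random.default_rng(cfg.seed)
    u = rng.random(matrix.values.shape)  # row-major fill
    deleted = (matrix.values == 1) & (u < cfg.deletion_probability)
    out = matrix.copy(role="source_perturbed", closed=False)
    out.values[deleted] = 0
    return out


def unfold(matrix: AnnotationMatrix, dag: OntologyDAG) -> AnnotationMatrix:
    """Remove annotations whose ancestors were deleted, to a fixed point.

    A 1 cell survives iff every ancestor of its term that is present in the
    matrix also holds a 1 for the same gene; this is the maximal consistent
    submatrix of the input.  Implemented as a single roots-first pass: each
    term's column is intersected with its (already repaired) parents'
    columns, which propagates deletions down every path.
    """
    for t in matrix.terms:
        if t not in dag:
            raise ValidationError(f"matrix term {t!r} absent from ontology")
    out = matrix.copy()
    present = set(matrix.terms)
    # children-before-parents order, reversed -> parents first
    order = [t for t in reversed(dag.topological_order()) if t in present]
    for t in order:
        j = out.term_index(t)
        for parent in dag.parents(t):
            if parent in present:
                out.values[:, j] &= out.values[:, out.term_index(parent)]
    out.closed = True
    return out


def make_perturbation_set(
    matrix: AnnotationMatrix,
    p: float,
    seeds: list[int],
    dag: OntologyDAG,
) -> list[AnnotationMatrix]:
    """n perturbed-then-unfolded copies of ``matrix``, one per seed.

    Seeds must be pairwise distinct — duplicate seeds would produce identical
    ensemble members and defeat model diversity.
    """
    if len(set(seeds)) != len(seeds):
        raise ValidationError("perturbation seeds must be pairwise distinct")
    return [
        unfold(perturb(matrix, PerturbationConfig(p, seed)), dag)
        for seed in seeds
    ]
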