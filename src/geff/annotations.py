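"""Annotation parsing, evidence filtering, and binary gene x term matrices.

An annotation asserts that a gene carries an ontology term, labelled with one
or more evidence codes.  Annotations tagged only with uncurated codes (IEA:
inferred from electronic annotation; ND: no biological data available) are
considered unreliable and excluded from model training by default.

The in-memory workhorse is :class:`AnnotationMatrix`, a binary m x n matrix
over an ordered gene list and term list.  A matrix is *closed* when every 1
cell implies 1 in all ancestor-term cells present in the matrix (the implicit
annotations mandated by the True Path Rule).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .ontology import OntologyDAG

__all__ = [
    "EvidenceTaggedAnnotation",
    "AnnotationMatrix",
    "load_gaf",
    "filter_reliable",
    "build_matrix",
    "close_matrix",
    "UNRELIABLE_CODES",
]

logger = logging.getLogger(__name__)

#: Evidence codes marking annotations produced without expert review.
UNRELIABLE_CODES = frozenset({"IEA", "ND"})


@dataclass(frozen=True)
class EvidenceTaggedAnnotation:
    """A gene-term association with the union of its evidence codes."""

    gene: str
    term: str
    evidence_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.evidence_codes:
            raise ValidationError(
                f"annotation ({self.gene}, {self.term}) has no evidence codes"
            )


@dataclass
class AnnotationMatrix:
    """Binary gene x term matrix with provenance role and consistency flag.

    ``values[i, j] == 1`` iff gene ``genes[i]`` is annotated to ``terms[j]``.
    ``closed`` records whether the matrix is known to satisfy ancestor
    closure with respect to the ontology it was built from (relative to the
    terms actually present in the matrix).
    """

    genes: list[str]
    terms: list[str]
    values: np.ndarray
    role: str = "source_original"
    closed: bool = False
    _gene_index: dict[str, int] = field(init=False, repr=False)
    _term_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.genes), len(self.terms)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.terms)} terms"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("annotation matrix entries must be 0 or 1")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._term_index = {t: j for j, t in enumerate(self.terms)}

    # -- lookups -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def term_index(self, term: str) -> int:
        return self._term_index[term]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def has_term(self, term: str) -> bool:
        return term in self._term_index

    def value(self, gene: str, term: str) -> int:
        return int(self.values[self._gene_index[gene], self._term_index[term]])

    def annotated_terms(self) -> set[str]:
        """Terms carried by at least one gene."""
        mask = self.values.any(axis=0)
        return {t for t, m in zip(self.terms, mask) if m}

    def copy(self, role: str | None = None, closed: bool | None = None):
        return AnnotationMatrix(
            genes=list(self.genes),
            terms=list(self.terms),
            values=self.values.copy(),
            role=self.role if role is None else role,
            closed=self.closed if closed is None else closed,
        )

    def restrict_terms(self, terms: list[str]) -> "AnnotationMatrix":
        """Column-subset the matrix to ``terms`` (order preserved)."""
        missing = [t for t in terms if t not in self._term_index]
        if missing:
            raise ValidationError(f"terms absent from matrix: {missing[:5]}")
        cols = [self._term_index[t] for t in terms]
        return AnnotationMatrix(
            genes=list(self.genes),
            terms=list(terms),
            values=self.values[:, cols].copy(),
            role=self.role,
            closed=False,  # restriction can break closure
        )

    def cells(self) -> set[tuple[str, str]]:
        """The set of annotated (gene, term) pairs."""
        gi, tj = np.nonzero(self.values)
        return {(self.genes[i], self.terms[j]) for i, j in zip(gi, tj)}

    # -- serialization (sparse triplet CSV) --------------------------------

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["gene", "term", "value"])
            gi, tj = np.nonzero(self.values)
            for i, j in zip(gi.tolist(), tj.tolist()):
                w.writerow([self.genes[i], self.terms[j], 1])

    @classmethod
    def from_csv(
        cls,
        path: str,
        genes: list[str] | None = None,
        terms: list[str] | None = None,
        role: str = "source_original",
        closed: bool = False,
    ) -> "AnnotationMatrix":
        triplets: list[tuple[str, str]] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if int(row["value"]) == 1:
                    triplets.append((row["gene"], row["term"]))
        if genes is None:
            genes = sorted({g for g, _ in triplets})
        if terms is None:
            terms = sorted({t for _, t in triplets})
        mat = cls(
            genes=genes,
            terms=terms,
            values=np.zeros((len(genes), len(terms)), dtype=np.uint8),
            role=role,
            closed=closed,
        )
        for g, t in triplets:
            mat.values[mat.gene_index(g), mat.term_index(t)] = 1
        return mat


# -- GAF / TSV reading -----------------------------------------------------

_GAF_MIN_COLUMNS = 15


def load_gaf(path: str) -> list[EvidenceTaggedAnnotation]:
    """Read gene annotations from a GAF 2.x file or a 3-column TSV dialect.

    GAF rows use columns 2 (object id), 4 (qualifier), 5 (term) and 7
    (evidence code); rows whose qualifier contains ``NOT`` are dropped.  The
    TSV dialect is ``gene <TAB> term <TAB> comma-separated-codes``.  Evidence
    codes are unioned per (gene, term) pair.  Malformed rows are logged and
    skipped; a file yielding no usable rows is an error.
    """
    pairs: dict[tuple[str, str], set[str]] = {}
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= _GAF_MIN_COLUMNS:
                    gene, qualifier, term, evidence = (
                        fields[1],
                        fields[3],
                        fields[4],
                        fields[6],
                    )
                    if "NOT" in qualifier.split("|"):
                        continue
                    codes = {evidence} if evidence else set()
                elif len(fields) == 3:
                    gene, term = fields[0], fields[1]
                    codes = {c.strip() for c in fields[2].split(",") if c.strip()}
                else:
                    raise ValueError(f"{len(fields)} columns")
                if not gene or not term or not codes:
                    raise ValueError("empty gene/term/evidence")
            except ValueError as exc:
                n_bad += 1
                logger.warning("skipping malformed row %d of %s: %s", lineno, path, exc)
                continue
            pairs.setdefault((gene, term), set()).update(codes)
    if not pairs:
        raise ValidationError(f"no usable annotation rows in {path!r} ({n_bad} malformed)")
    return [
        EvidenceTaggedAnnotation(gene=g, term=t, evidence_codes=frozenset(codes))
        for (g, t), codes in sorted(pairs.items())
    ]


def filter_reliable(
    annotations: list[EvidenceTaggedAnnotation],
    include_iea_only: bool = False,
    unreliable_codes: frozenset[str] = UNRELIABLE_CODES,
) -> list[EvidenceTaggedAnnotation]:
    """Drop annotations supported only by uncurated evidence codes.

    An annotation is kept iff it carries at least one code outside
    ``unreliable_codes``.  With ``include_iea_only`` set the filter is a
    no-op, reproducing the "with IEA-only annotations" training variant.
    """
    if include_iea_only:
        return list(annotations)
    return [a for a in annotations if a.evidence_codes - unreliable_codes]


# -- matrix construction ---------------------------------------------------

def build_matrix(
    annotations: list[EvidenceTaggedAnnotation],
    dag: OntologyDAG,
    term_universe: set[str] | None = None,
    role: str = "source_original",
) -> AnnotationMatrix:
    """Build the ancestor-closed binary matrix for a set of annotations.

    Each direct annotation sets its own cell and the cells of every ancestor
    term present in the matrix.  When ``term_universe`` is given the matrix
    columns are exactly that universe (restriction applied before closure, so
    ancestors outside the universe are dropped); otherwise columns cover the
    observed terms plus all their ancestors.  Annotations to terms unknown to
    the ontology are logged and skipped.
    """
    usable = []
    for a in annotations:
        if a.term in dag:
            usable.append(a)
        else:
            logger.warning("skipping annotation to unknown term %r", a.term)
    if term_universe is not None:
        usable = [a for a in usable if a.term in term_universe]
    if not usable:
        raise ValidationError("no annotations usable for matrix construction")

    genes = sorted({a.gene for a in usable})
    if term_universe is not None:
        terms = sorted(term_universe)
    else:
        term_set: set[str] = set()
        for a in usable:
            term_set.add(a.term)
            term_set |= dag.ancestors(a.term)
        terms = sorted(term_set)

    mat = AnnotationMatrix(
        genes=genes,
        terms=terms,
        values=np.zeros((len(genes), len(terms)), dtype=np.uint8),
        role=role,
        closed=False,
    )
    for a in usable:
        i = mat.gene_index(a.gene)
        mat.values[i, mat.term_index(a.term)] = 1
        for anc in dag.ancestors(a.term):
            if mat.has_term(anc):
                mat.values[i, mat.term_index(anc)] = 1
    mat.closed = True
    return mat


def close_matrix(matrix: AnnotationMatrix, dag: OntologyDAG) -> AnnotationMatrix:
    """Return the ancestor closure of ``matrix`` over its own term columns.

    Idempotent: closing a closed matrix returns an identical matrix.
    """
    out = matrix.copy()
    for j, t in enumerate(matrix.terms):
        if t not in dag:
            raise ValidationError(f"matrix term {t!r} absent from ontology")
        rows = np.nonzero(matrix.values[:, j])[0]
        if rows.size == 0:
            continue
        for anc in dag.ancestors(t):
            if out.has_term(anc):
                out.values[rows, out.term_index(anc)] = 1
    out.closed = True
    return out
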