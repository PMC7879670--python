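# Methods

## Problem and model

`geff` addresses annotation discovery: given the known gene–term
annotations of two organisms over a shared ontology, predict which
currently-missing (gene, term) pairs of the less-studied *target* organism
are real annotations that have simply not been recorded yet. The method is
supervised despite the task having no labelled negatives: an artificial
"outdated" copy of the well-annotated *source* organism's matrix is created
by random deletion, and per-term classifiers learn to rebuild the original
from the depleted version. Whatever term co-occurrence structure lets a
model rebuild deleted source annotations is then applied, unchanged, to the
target's known annotation rows — the transfer requires no gene orthology,
only the shared vocabulary *T = T_S ∩ T_T*.

Key assumptions:

- Annotation matrices are ancestor-closed (True Path Rule), so implicit
  annotations to ancestors are part of the signal.
- Term co-occurrence patterns are comparable between source and target
  organisms over the shared vocabulary.
- Annotations supported only by uncurated evidence (IEA/ND) are less
  reliable; training uses curated-supported annotations by default, with a
  switch to include IEA-only annotations.

## Pipeline stages and numerical choices

**Perturbation.** Each 1-cell of the closed source matrix is independently
deleted with probability *p* (default 0.1), using one RNG stream per
(matrix, seed) with a uniform draw per cell in row-major order over the
stored gene/term order — reproducible across platforms. *Unfolding* then
removes every annotation with a deleted ancestor (computed roots-first in a
single pass, equal to the maximal hierarchy-consistent submatrix). Repair
deletes descendants rather than re-adding ancestors: re-adding would undo
the information removal the perturbation exists to create. Perturbation is
applied to the closed matrix and then unfolded.

**Per-term classifiers.** Binary relevance over *T*: features are the
perturbed columns *T*∖{*t*꜀}, labels the original column *t*꜀, training
rows the source genes with ≥ 5 annotations inside *T* (configurable
`min_gene_annotations`). Base learners: random forest (100 trees;
confidence = fraction of trees voting positive) or k-nearest neighbours
(k = 5; confidence = fraction of positive neighbours); the learners' other
hyperparameters are scikit-learn defaults. A label column containing a
single class yields a degenerate constant model emitting that class's value
— the output any calibrated learner converges to — rather than a failed
fit. Every fit is seeded from (base seed, perturbation seed, term index)
through a `SeedSequence`, making whole runs reproducible. Target genes with
an all-zero feature row are scored like any other row.

**Calibration.** Ancestor averaging uses the full transitive ancestor set
by default (a parents-only variant is available via the `transitive` flag;
the choice is exposed because either reading of "ancestors" is defensible).
For a root term the ancestor set is empty: the averaged value is defined as
the raw value, since an empty mean contributes nothing and the subsequent
fix pushes roots toward the column maximum anyway. The True-Path fix is a
single leaf-to-root pass propagating children maxima, algebraically equal
to the max over the full transitive descendant set but O(edges); it runs
over the whole ontology so descendants connected through terms outside the
likelihood matrix still contribute. Both stages map [0,1] into [0,1]; the
fix is idempotent and independent of gene order and sibling tie order.

**Ensemble.** n = 5 members by default, one per perturbation seed.
Threshold comparison is inclusive (≥ ρ) so ρ = 1 remains satisfiable, with
an absolute tolerance of 1e-12 absorbing float representation error in
averaged likelihoods. For voted predictions the reported likelihood is the
mean of the member likelihoods that passed ρ — a ranking convenience; the
voting rule itself is the decision. Known target annotations are always
masked out of the output; the count of masked pairs is reported.

**Evaluation.** N, precision and mean predicted-term level against a later
snapshot. Precision with N = 0 is reported as undefined (null), never 0 or
1, to keep threshold-sweep tables honest at extreme ρ. Measured precision
is a lower bound on true precision (unconfirmed predictions may be
undiscovered annotations); this caveat is carried in report metadata, not
corrected for. "Term level" is the minimum root-to-term depth within the
term's namespace (a term on several levels is counted at its lowest);
minimum rather than maximum depth is the package's reading of a term's
reported level.

## Synthetic worlds

The fixture generator emulates the two-snapshot evaluation protocol with no
external data. A random rooted DAG (default 100 terms, ~1.3 parents per
non-root term) carries co-occurrence *blocks*: the term set shared by both
organisms (60% of terms by default) is partitioned into 8 blocks. Each gene
is drawn into 1–3 blocks and, per block, carries the block's full term set
with probability `block_coherence` (default 0.95) — carriage is decided at
the gene–block level, so the marginal per-term carriage probability equals
the coherence while misses stay correlated within a gene, as they are when
curation records a gene's role in a process wholesale. Independent noise
annotations are added at rate 0.02 per (gene, term). Matrices are
ancestor-closed; the *known* snapshot drops each direct annotation with
probability `holdout_fraction` (default 0.2) and the *updated* snapshot
restores them; genes left without any known annotation are dropped from
both snapshots, since an annotation database has no record of such genes
and evaluation covers only genes present in both versions. The
updated∖known cell set is returned as the planted-annotation ledger.

Default scale — 100 terms, 200 source and 80 target genes — keeps the
end-to-end benchmark (≈300 random-forest fits per run) at about a minute on
one CPU while leaving enough planted structure for precision estimates on
dozens-to-hundreds of predictions.

What passing the synthetic benchmark shows: the pipeline recovers planted
co-occurrence structure, the ensemble orderings hold (N non-increasing in x
and ρ; the n-of-n intersection at least as precise as the 1-of-n union),
and a permuted-label control collapses precision to near the chance base
rate. What it does not show: performance on real GO annotations, whose
topology, depth distribution, annotation bias and inter-organism
evolutionary distance the generator deliberately does not mimic.

## Known limitations

- Binary relevance ignores correlations between class-terms beyond what
  calibration reinstates.
- The shared-vocabulary transfer cannot predict terms absent from the
  source organism.
- Very sparse shared vocabularies make many label columns single-class,
  degrading the ensemble toward constants.
- Ensemble members differ only through perturbation seeds; with p → 0 the
  members coincide and voting adds nothing.
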