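"""Fully synthetic, seeded test worlds for the annotation-transfer pipeline.

A *world* consists of a random rooted term DAG, two organisms (a
well-annotated source and a sparser target) whose annotations share planted
term co-occurrence blocks, and for each organism a *known* (older) and an
*updated* (later) annotation snapshot.  The updated snapshot restores a
held-out fraction of annotations, emulating discoveries made between two
database versions; the held-out pairs form the planted-annotation ledger the
recovery benchmark is scored against.

Planted structure
-----------------
Terms shared by both organisms are partitioned into co-occurrence blocks.
Each gene is drawn into 1-3 blocks and, per block, carries the block's whole
term set with probability ``block_coherence`` (a gene either participates in
the emulated process — acquiring all its terms — or does not; the marginal
per-term carriage probability equals ``block_coherence``).  Carriage misses
are therefore correlated within a gene, as they are when curation events
record a gene's role in a process wholesale.  ``noise_rate`` adds
independent random annotations on top.  All matrices are ancestor-closed.

This generator emulates the co-occurrence signal the per-term classifiers
exploit; it does not mimic real GO topology, annotation depth distributions,
or evolutionary distance between organisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix, EvidenceTaggedAnnotation, build_matrix
from .calibration import LikelihoodMatrix, ancestor_average, true_path_fix
from .ensemble import EnsembleConfig
from .evaluation import sweep
from .exceptions import ValidationError
from .models import CrossOrganismConfig, predict_raw, select_terms, train_models
from .ontology import OntologyDAG
from .perturbation import make_perturbation_set

__all__ = [
    "FixtureSpec",
    "World",
    "make_world",
    "run_transfer",
    "recovery_benchmark",
    "write_obo",
    "write_annotation_tsv",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic world; defaults give the desk-scale benchmark."""

    n_terms: int = 100
    dag_density: float = 1.3  # mean parents per non-root term
    n_blocks: int = 8
    n_source_genes: int = 200
    n_target_genes: int = 80
    term_overlap_fraction: float = 0.6
    block_coherence: float = 0.95
    noise_rate: float = 0.02
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValidationError("need at least 2 terms")
        if not 0.0 < self.term_overlap_fraction <= 1.0:
            raise ValidationError("term_overlap_fraction must be in (0, 1]")
        if not 0.0 < self.block_coherence <= 1.0:
            raise ValidationError("block_coherence must be in (0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError("noise_rate must be in [0, 1]")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValidationError("holdout_fraction must be in [0, 1)")
        if self.n_blocks < 1 or self.n_blocks > self.n_terms:
            raise ValidationError("n_blocks must be in [1, n_terms]")
        if self.dag_density < 1.0:
            raise ValidationError("dag_density must be >= 1")


@dataclass
class World:
    """A generated ontology plus paired known/updated matrices per organism."""

    dag: OntologyDAG
    source_known: AnnotationMatrix
    source_updated: AnnotationMatrix
    target_known: AnnotationMatrix
    target_updated: AnnotationMatrix
    blocks: list[list[str]]
    ledger: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    block_members: dict[str, dict[str, set[int]]] = field(default_factory=dict)
    spec: FixtureSpec | None = None


def _make_dag(spec: FixtureSpec, rng: np.random.Generator) -> OntologyDAG:
    terms = [f"T{i:04d}" for i in range(spec.n_terms)]
    edges: list[tuple[str, str, str]] = []
    extra_p = min(1.0, spec.dag_density - 1.0)
    for i in range(1, spec.n_terms):
        parent = terms[int(rng.integers(0, i))]
        edges.append((terms[i], parent, "is_a"))
        if i > 1 and rng.random() < extra_p:
            second = terms[int(rng.integers(0, i))]
            if second != parent:
                edges.append((terms[i], second, "is_a"))
    return OntologyDAG(edges, terms=terms)


def _organism_annotations(
    genes: list[str],
    blocks: list[list[str]],
    universe: list[str],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Direct annotations for one organism plus each gene's carried blocks."""
    universe_arr = np.array(universe)
    known_direct: list[tuple[str, str]] = []
    updated_direct: list[tuple[str, str]] = []
    carried: dict[str, set[int]] = {}
    for g in genes:
        n_b = int(rng.integers(1, 4))
        chosen = rng.choice(len(blocks), size=min(n_b, len(blocks)), replace=False)
        direct: set[str] = set()
        carried[g] = set()
        for b in chosen:
            if rng.random() < spec.block_coherence:
                direct |= set(blocks[int(b)])
                carried[g].add(int(b))
        noise_mask = rng.random(len(universe_arr)) < spec.noise_rate
        direct |= set(universe_arr[noise_mask].tolist())
        for t in sorted(direct):
            updated_direct.append((g, t))
            if rng.random() >= spec.holdout_fraction:
                known_direct.append((g, t))
    return known_direct, updated_direct, carried


def _build(
    direct: list[tuple[str, str]],
    dag: OntologyDAG,
    universe: set[str],
    genes: list[str],
    role: str,
) -> AnnotationMatrix:
    annos = [
        EvidenceTaggedAnnotation(g, t, frozenset({"IDA"})) for g, t in direct
    ]
    mat = build_matrix(annos, dag, term_universe=universe, role=role)
    # pad to the full gene roster so known/updated stay congruent
    missing = [g for g in genes if not mat.has_gene(g)]
    if missing:
        all_genes = sorted(set(mat.genes) | set(missing))
        padded = AnnotationMatrix(
            genes=all_genes,
            terms=list(mat.terms),
            values=np.zeros((len(all_genes), len(mat.terms)), dtype=np.uint8),
            role=role,
            closed=True,
        )
        for g in mat.genes:
            padded.values[padded.gene_index(g), :] = mat.values[mat.gene_index(g), :]
        return padded
    return mat


def make_world(spec: FixtureSpec) -> World:
    """Generate a reproducible synthetic world from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    dag = _make_dag(spec, rng)
    terms = sorted(dag.terms)
    root = sorted(dag.roots)[0]

    non_root = [t for t in terms if t != root]
    n_shared = max(spec.n_blocks, round(spec.term_overlap_fraction * spec.n_terms) - 1)
    if n_shared > len(non_root):
        n_shared = len(non_root)
    shared = sorted(
        rng.choice(non_root, size=n_shared, replace=False).tolist()
    )
    if len(shared) < spec.n_blocks:
        raise ValidationError("not enough shared terms to populate the blocks")

    shuffled = list(shared)
    rng.shuffle(shuffled)
    blocks = [sorted(b.tolist()) for b in np.array_split(np.array(shuffled), spec.n_blocks)]
    if any(len(b) == 0 for b in blocks):
        raise ValidationError("degenerate fixture: empty co-occurrence block")

    leftover = [t for t in non_root if t not in set(shared)]
    rng.shuffle(leftover)
    half = len(leftover) // 2
    source_universe = set(shared) | {root} | set(leftover[:half])
    target_universe = set(shared) | {root} | set(leftover[half:])

    source_genes = [f"SG{i:04d}" for i in range(spec.n_source_genes)]
    target_genes = [f"TG{i:04d}" for i in range(spec.n_target_genes)]

    src_known_d, src_updated_d, src_carried = _organism_annotations(
        source_genes, blocks, sorted(source_universe - {root}), spec, rng
    )
    tgt_known_d, tgt_updated_d, tgt_carried = _organism_annotations(
        target_genes, blocks, sorted(target_universe - {root}), spec, rng
    )

    # An annotation database has no record of a gene without annotations, and
    # evaluation covers only genes present in both snapshot versions; keep
    # exactly the genes with at least one known-snapshot annotation.
    def _with_known(known_d, updated_d, carried):
        keep = {g for g, _ in known_d}
        return (
            known_d,
            [(g, t) for g, t in updated_d if g in keep],
            {g: b for g, b in carried.items() if g in keep},
            sorted(keep),
        )

    src_known_d, src_updated_d, src_carried, source_genes = _with_known(
        src_known_d, src_updated_d, src_carried
    )
    tgt_known_d, tgt_updated_d, tgt_carried, target_genes = _with_known(
        tgt_known_d, tgt_updated_d, tgt_carried
    )

    source_known = _build(src_known_d, dag, source_universe, source_genes, "source_original")
    source_updated = _build(src_updated_d, dag, source_universe, source_genes, "updated_validation")
    target_known = _build(tgt_known_d, dag, target_universe, target_genes, "target_known")
    target_updated = _build(tgt_updated_d, dag, target_universe, target_genes, "updated_validation")

    ledger = {
        "source": source_updated.cells() - source_known.cells(),
        "target": target_updated.cells() - target_known.cells(),
    }
    return World(
        dag=dag,
        source_known=source_known,
        source_updated=source_updated,
        target_known=target_known,
        target_updated=target_updated,
        blocks=blocks,
        ledger=ledger,
        block_members={"source": src_carried, "target": tgt_carried},
        spec=spec,
    )


# -- pipeline driver -------------------------------------------------------

@dataclass
class TransferRun:
    """Trained-and-calibrated state reusable across ensemble configurations."""

    calibrated: list[LikelihoodMatrix]
    known: AnnotationMatrix  # target known, restricted to the shared terms
    updated: AnnotationMatrix
    dag: OntologyDAG
    terms: list[str]


def run_transfer(
    world: World,
    p: float,
    seeds: Iterable[int],
    cross: CrossOrganismConfig | None = None,
    permute_labels_seed: int | None = None,
) -> TransferRun:
    """Train the n-model ensemble on the source and calibrate target likelihoods.

    ``permute_labels_seed``, when set, independently permutes each term
    column of the target's known matrix across genes before scoring — a
    shuffled-label control that destroys the gene-level co-occurrence signal
    while preserving per-term annotation frequencies.
    """
    shared = select_terms(
        world.source_known.annotated_terms(),
        world.target_known.annotated_terms(),
    )
    if cross is None:
        cross = CrossOrganismConfig(term_set=shared)
    elif cross.term_set is None:
        cross = replace(cross, term_set=shared)
    else:
        cross = replace(cross, term_set=shared & cross.term_set)
    terms = sorted(cross.term_set)

    seeds = list(seeds)
    perturbed_set = make_perturbation_set(world.source_known, p, seeds, world.dag)

    target_features = world.target_known
    if permute_labels_seed is not None:
        prng = np.random.default_rng(permute_labels_seed)
        target_features = world.target_known.copy()
        for j in range(target_features.values.shape[1]):
            target_features.values[:, j] = prng.permutation(
                target_features.values[:, j]
            )
        target_features.closed = False

    calibrated = []
    for seed, perturbed in zip(seeds, perturbed_set):
        ms = train_models(
            perturbed, world.source_known, cross, perturbation_seed=seed
        )
        raw = predict_raw(ms, target_features)
        calibrated.append(true_path_fix(ancestor_average(raw, world.dag), world.dag))

    return TransferRun(
        calibrated=calibrated,
        known=world.target_known.restrict_terms(terms),
        updated=world.target_updated,
        dag=world.dag,
        terms=terms,
    )


def recovery_benchmark(
    spec: FixtureSpec,
    configs: EnsembleConfig | Iterable[EnsembleConfig],
    cross: CrossOrganismConfig | None = None,
    permute_labels_seed: int | None = None,
) -> pd.DataFrame:
    """End-to-end synthetic benchmark: source-trained models scored on the target.

    Generates a world, runs the full pipeline once, and evaluates every
    ensemble configuration against the target's updated matrix.  All
    configurations must share p and seeds (models are trained once).
    """
    if isinstance(configs, EnsembleConfig):
        configs = [configs]
    configs = list(configs)
    first = configs[0]
    if any(c.p != first.p or c.seeds != first.seeds for c in configs):
        raise ValidationError(
            "all swept configurations must share p and the seed list"
        )
    seeds = first.seeds or tuple(range(1, first.n + 1))
    world = make_world(spec)
    run = run_transfer(
        world, first.p, seeds, cross, permute_labels_seed=permute_labels_seed
    )
    return sweep(
        configs, run.calibrated, run.known, run.updated, run.dag,
        target="synthetic_target",
    )


# -- text-format writers (fixture interchange) -----------------------------

def write_obo(dag: OntologyDAG, path: str) -> None:
    """Write the DAG as a minimal OBO 1.2 file (id, name, is_a tags)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for t in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.name(t) or t}\n")
            for parent in sorted(dag.parents(t)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def write_annotation_tsv(
    matrix: AnnotationMatrix, path: str, evidence: str = "IDA"
) -> None:
    """Write a matrix's annotations in the 3-column TSV dialect."""
    with open(path, "w") as fh:
        for g, t in sorted(matrix.cells()):
            fh.write(f"{g}\t{t}\t{evidence}\n")
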