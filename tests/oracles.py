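"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from a plain child->parents dict and deliberately
avoids the package's graph code paths (and networkx), so oracle and
implementation can only agree by computing the same mathematical object.
"""

from __future__ import annotations

import numpy as np

from geff.ontology import OntologyDAG


def random_dag(
    rng: np.random.Generator, n_terms: int, extra_edge_p: float = 0.3
) -> tuple[OntologyDAG, dict[str, list[str]]]:
    """A random rooted DAG plus its child->parents dict (term 0 is the root)."""
    terms = [f"t{i}" for i in range(n_terms)]
    parents: dict[str, list[str]] = {t: [] for t in terms}
    edges = []
    for i in range(1, n_terms):
        p = terms[int(rng.integers(0, i))]
        parents[terms[i]].append(p)
        edges.append((terms[i], p, "is_a"))
        if i > 1 and rng.random() < extra_edge_p:
            q = terms[int(rng.integers(0, i))]
            if q not in parents[terms[i]]:
                parents[terms[i]].append(q)
                edges.append((terms[i], q, "is_a"))
    return OntologyDAG(edges, terms=terms), parents


def ancestors_bf(parents: dict[str, list[str]], term: str) -> set[str]:
    """Transitive closure of parent links by explicit DFS."""
    seen: set[str] = set()
    stack = list(parents[term])
    while stack:
        t = stack.pop()
        if t not in seen:
            seen.add(t)
            stack.extend(parents[t])
    return seen


def descendants_bf(parents: dict[str, list[str]], term: str) -> set[str]:
    return {u for u in parents if term in ancestors_bf(parents, u)}


def level_bf(parents: dict[str, list[str]], term: str) -> int:
    """Minimum root-to-term path length by enumerating all upward paths."""
    best: list[int] = []

    def walk(t: str, depth: int) -> None:
        if not parents[t]:
            best.append(depth)
            return
        for p in parents[t]:
            walk(p, depth + 1)

    walk(term, 0)
    return min(best)


def ancestor_average_bf(
    values: np.ndarray, terms: list[str], parents: dict[str, list[str]]
) -> np.ndarray:
    """Eq-by-definition ancestor averaging over the transitive ancestor set."""
    out = np.empty_like(values, dtype=float)
    index = {t: j for j, t in enumerate(terms)}
    for j, t in enumerate(terms):
        anc = [a for a in ancestors_bf(parents, t) if a in index]
        for i in range(values.shape[0]):
            if anc:
                mean = sum(values[i, index[a]] for a in anc) / len(anc)
                out[i, j] = (mean + values[i, j]) / 2.0
            else:
                out[i, j] = values[i, j]
    return out


def true_path_fix_bf(
    values: np.ndarray, terms: list[str], parents: dict[str, list[str]]
) -> np.ndarray:
    """Max over the full transitive descendant set, cell by cell."""
    out = np.empty_like(values, dtype=float)
    index = {t: j for j, t in enumerate(terms)}
    for j, t in enumerate(terms):
        desc = [d for d in descendants_bf(parents, t) if d in index]
        cols = [j] + [index[d] for d in desc]
        out[:, j] = values[:, cols].max(axis=1)
    return out


def unfold_bf(
    values: np.ndarray, terms: list[str], parents: dict[str, list[str]]
) -> np.ndarray:
    """Maximal consistent submatrix: keep a 1 iff all its in-matrix ancestors are 1."""
    index = {t: j for j, t in enumerate(terms)}
    out = values.copy()
    for j, t in enumerate(terms):
        anc_cols = [index[a] for a in ancestors_bf(parents, t) if a in index]
        for i in range(values.shape[0]):
            if values[i, j] == 1 and any(values[i, c] == 0 for c in anc_cols):
                out[i, j] = 0
    return out


def closure_bf(
    values: np.ndarray, terms: list[str], parents: dict[str, list[str]]
) -> np.ndarray:
    """Ancestor closure by brute-force reachability."""
    index = {t: j for j, t in enumerate(terms)}
    out = values.copy()
    for j, t in enumerate(terms):
        anc_cols = [index[a] for a in ancestors_bf(parents, t) if a in index]
        for i in range(values.shape[0]):
            if values[i, j] == 1:
                for c in anc_cols:
                    out[i, c] = 1
    return out


def is_closed(
    values: np.ndarray, terms: list[str], parents: dict[str, list[str]]
) -> bool:
    return bool((closure_bf(values, terms, parents) == values).all())
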