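"""Ontology term graph: loading, ancestor/descendant queries, and term levels.

The controlled vocabulary is a rooted directed acyclic graph.  Edges point
from child to parent (the ``is_a`` direction), so "ancestors" of a term are
the nodes reachable by following edges, and "descendants" are the nodes from
which the term is reachable.  Term *level* is the minimum number of edges on
any path from a root of the term's namespace down to the term; roots have
level 0 and deeper terms denote more specific functions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import obonet

from .exceptions import ValidationError

__all__ = ["OntologyDAG", "load_obo", "load_edge_tsv"]


class OntologyDAG:
    """A rooted DAG of ontology terms with child-to-parent edges.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent, relation)`` triples.  ``relation`` is a
        free-form label such as ``"is_a"`` or ``"part_of"``.
    namespaces
        Optional mapping from term id to a namespace label (e.g. BP/MF/CC).
        Terms sharing a namespace share the roots used for level computation.
    names
        Optional mapping from term id to a human-readable name.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] | None = None,
        namespaces: Mapping[str, str] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> None:
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for child, parent, relation in edges:
            g.add_edge(child, parent, relation=relation)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(
                f"ontology graph contains a cycle through term {cycle[0][0]!r}"
            )
        self._graph = g
        self._namespaces = dict(namespaces or {})
        self._names = dict(names or {})
        self._levels: dict[str, int] | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def roots(self) -> set[str]:
        """Terms with no parent."""
        return {t for t in self._graph.nodes if self._graph.out_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def namespace(self, term: str) -> str | None:
        return self._namespaces.get(term)

    def name(self, term: str) -> str | None:
        return self._names.get(term)

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        self._check(term)
        return set(self._graph.predecessors(term))

    # -- transitive queries ------------------------------------------------

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via parent links, excluding it."""
        self._check(term)
        return nx.descendants(self._graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms from which ``term`` is reachable, excluding it."""
        self._check(term)
        return nx.ancestors(self._graph, term)

    def topological_order(self) -> list[str]:
        """Terms ordered children before parents (leaf-to-root)."""
        return list(nx.topological_sort(self._graph))

    def term_level(self, term: str) -> int:
        """Minimum root-to-term path length within the term's namespace."""
        self._check(term)
        if self._levels is None:
            self._levels = self._compute_levels()
        try:
            return self._levels[term]
        except KeyError:
            raise ValidationError(
                f"term {term!r} is not reachable from any root of its namespace"
            ) from None

    def _compute_levels(self) -> dict[str, int]:
        # BFS from roots along parent->child edges, one namespace at a time
        # so multi-namespace ontologies get per-namespace depths.
        levels: dict[str, int] = {}
        roots_by_ns: dict[str | None, set[str]] = {}
        for r in self.roots:
            roots_by_ns.setdefault(self._namespaces.get(r), set()).add(r)
        for ns, roots in roots_by_ns.items():
            frontier = list(roots)
            depth = 0
            seen = set(roots)
            while frontier:
                nxt: list[str] = []
                for term in frontier:
                    if self._namespaces.get(term) == ns and (
                        term not in levels or depth < levels[term]
                    ):
                        levels[term] = depth
                    for child in self._graph.predecessors(term):
                        if child not in seen:
                            seen.add(child)
                            nxt.append(child)
                frontier = nxt
                depth += 1
        return levels

    def _check(self, term: str) -> None:
        if term not in self._graph:
            raise KeyError(f"unknown ontology term: {term!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OntologyDAG({len(self)} terms, "
            f"{self._graph.number_of_edges()} edges, {len(self.roots)} roots)"
        )


def load_obo(path: str, include_part_of: bool = False) -> OntologyDAG:
    """Read an OBO 1.2-style file into an :class:`OntologyDAG`.

    ``is_a`` edges always contribute to the hierarchy; ``part_of``
    relationships only when ``include_part_of`` is set.  Obsolete terms are
    dropped.  A cyclic hierarchy is rejected.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except OSError:
        raise
    except Exception as exc:  # malformed stanza structure
        raise ValidationError(f"cannot parse OBO file {path!r}: {exc}") from exc
    wanted = {"is_a"}
    if include_part_of:
        wanted.add("part_of")
    edges = [
        (child, parent, key)
        for child, parent, key in graph.edges(keys=True)
        if key in wanted
    ]
    namespaces = {
        t: d["namespace"] for t, d in graph.nodes(data=True) if "namespace" in d
    }
    names = {t: d["name"] for t, d in graph.nodes(data=True) if "name" in d}
    return OntologyDAG(
        edges, terms=graph.nodes, namespaces=namespaces, names=names
    )


def load_edge_tsv(path: str) -> OntologyDAG:
    """Read a ``child <TAB> parent <TAB> relation`` edge list (fixture dialect).

    The relation column is optional and defaults to ``is_a``.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"bad edge line in {path!r}: {line!r}")
            relation = parts[2] if len(parts) > 2 else "is_a"
            edges.append((parts[0], parts[1], relation))
    return OntologyDAG(edges)
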