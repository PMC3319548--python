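"""Hierarchical taxonomy of functional terms.

A taxonomy is a rooted directed tree or DAG whose nodes are functional
annotation terms (e.g. Gene Ontology terms) and whose edges point from a
parent term to its more specific child terms.  Every query the rest of the
package needs — levels, term specificity, ancestor relations, shortest-path
distances, maximum unrelated (antichain) subsets — lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Taxonomy",
    "TermSet",
    "TaxonomyError",
    "load_taxonomy",
    "load_taxonomy_edges",
    "level_specificity",
    "term_specificity",
    "is_related",
    "ancestor_term_set",
    "max_unrelated_subset",
    "term_distance",
]


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies or unknown terms."""


# A TermSet is simply a frozenset of term IDs.  Unrelatedness (no member is
# an ancestor of another) is enforced where annotations are installed, via
# :func:`max_unrelated_subset` / :meth:`Taxonomy.reduce_to_unrelated`.
TermSet = frozenset


@dataclass
class Taxonomy:
    """A rooted DAG of functional terms with precomputed level sets.

    Parameters
    ----------
    graph:
        Directed graph with parent→child edges.  Must be acyclic with a
        single in-degree-0 node (the root).
    specificity_aggregation:
        How to collapse a term's (possibly multiple) occurrence levels into
        one specificity score: ``"mean"`` (default), ``"min"`` or ``"max"``.

    Notes
    -----
    A term's *level set* is the set of lengths of all directed root-to-term
    paths; in a DAG a term can occur at several levels.  The taxonomy depth
    ``L`` is the largest level of any term.  The level specificity score is
    ``zeta(l) = l / L`` and a term's specificity is the aggregate of
    ``zeta`` over its occurrence levels, so the root scores 0 and terms
    found only at the deepest level score 1.
    """

    graph: nx.DiGraph
    specificity_aggregation: str = "mean"
    root: str = field(init=False)
    levels: dict[str, frozenset[int]] = field(init=False, repr=False)
    depth: int = field(init=False)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise TaxonomyError("empty taxonomy")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise TaxonomyError(f"cycle detected: {cycle[0][0]} -> {cycle[0][1]}")
        roots = [n for n in self.graph if self.graph.in_degree(n) == 0]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        if self.specificity_aggregation not in ("mean", "min", "max"):
            raise TaxonomyError(
                f"unknown specificity aggregation {self.specificity_aggregation!r}"
            )
        self.root = roots[0]
        self.levels = self._compute_levels()
        self.depth = max(max(ls) for ls in self.levels.values())
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    def _compute_levels(self) -> dict[str, frozenset[int]]:
        # In a DAG every directed path is simple, so the set of root-to-term
        # path lengths propagates along topological order.
        levels: dict[str, set[int]] = {self.root: {0}}
        for node in nx.topological_sort(self.graph):
            if node == self.root:
                continue
            acc: set[int] = set()
            for parent in self.graph.predecessors(node):
                acc.update(l + 1 for l in levels[parent])
            levels[node] = acc
        return {t: frozenset(ls) for t, ls in levels.items()}

    # -- basic queries ----------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def _check(self, *terms: str) -> None:
        for t in terms:
            if t not in self.graph:
                raise TaxonomyError(f"unknown term {t!r}")

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of *term* (all terms with a directed path to it)."""
        self._check(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, term))
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        self._check(term)
        cached = self._descendant_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._descendant_cache[term] = cached
        return cached

    def term_specificity(self, term: str) -> float:
        return term_specificity(term, self)

    def reduce_to_unrelated(self, terms: Iterable[str]) -> TermSet:
        """Drop every term that has a strict descendant in the set.

        This is the canonical reduction applied to raw gene annotations:
        redundant ancestors carry no extra information, so only the most
        specific members are kept.  The result is always an unrelated set.
        """
        ts = set(terms)
        self._check(*ts)
        keep = {t for t in ts if not (self.descendants(t) & ts)}
        return TermSet(keep)

    def is_unrelated_set(self, terms: Iterable[str]) -> bool:
        ts = list(terms)
        self._check(*ts)
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if is_related(a, b, self):
                    return False
        return True


def level_specificity(level: int, depth: int) -> float:
    """Level specificity score zeta(l) = l / L, linear from root (0) to depth (1)."""
    if depth < 1:
        raise TaxonomyError(f"taxonomy depth must be >= 1, got {depth}")
    if not 0 <= level <= depth:
        raise TaxonomyError(f"level {level} outside [0, {depth}]")
    return level / depth


def term_specificity(term: str, taxonomy: Taxonomy) -> float:
    """Functional term specificity in [0, 1].

    Aggregates the level specificity score over every level at which the
    term occurs (mean by default; see ``Taxonomy.specificity_aggregation``).
    """
    taxonomy._check(term)
    zetas = [level_specificity(l, taxonomy.depth) for l in taxonomy.levels[term]]
    agg = taxonomy.specificity_aggregation
    if agg == "mean":
        return sum(zetas) / len(zetas)
    if agg == "min":
        return min(zetas)
    return max(zetas)


def is_related(t_a: str, t_b: str, taxonomy: Taxonomy) -> bool:
    """True iff one term is an ancestor of the other (or they are equal)."""
    taxonomy._check(t_a, t_b)
    if t_a == t_b:
        return True
    return t_b in taxonomy.descendants(t_a) or t_a in taxonomy.descendants(t_b)


def ancestor_term_set(terms: Iterable[str], taxonomy: Taxonomy) -> frozenset[str]:
    """Closure of *terms* under "every term on any simple path to the root".

    Always contains the input terms and the root.
    """
    result: set[str] = set()
    for t in terms:
        result.add(t)
        result |= taxonomy.ancestors(t)
    if result:
        result.add(taxonomy.root)
    return frozenset(result)


def max_unrelated_subset(terms: Iterable[str], taxonomy: Taxonomy) -> TermSet:
    """Maximum-cardinality unrelated subset (maximum antichain) of *terms*.

    Ties are broken deterministically: prefer the subset with the larger
    summed term specificity, then the lexicographically smallest sorted
    tuple of term IDs.  Exact branch-and-bound search; the candidate sets
    arising in hierarchical annotation (intersections of ancestor closures)
    are small, so exhaustive optimality is affordable.
    """
    candidates = sorted(set(terms))
    if not candidates:
        raise TaxonomyError("max_unrelated_subset: empty input")
    taxonomy._check(*candidates)

    sigma = {t: term_specificity(t, taxonomy) for t in candidates}
    related: dict[str, set[str]] = {t: set() for t in candidates}
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if is_related(a, b, taxonomy):
                related[a].add(b)
                related[b].add(a)

    # best = (size, sigma_sum, neg-lexicographic key, members)
    best: list = [0, -math.inf, None, ()]

    def key_tuple(members: tuple[str, ...]):
        return tuple(sorted(members))

    def better(size: int, ssum: float, members: tuple[str, ...]) -> bool:
        if size != best[0]:
            return size > best[0]
        if not math.isclose(ssum, best[1], rel_tol=1e-12, abs_tol=1e-12):
            return ssum > best[1]
        return key_tuple(members) < best[2]

    def search(idx: int, chosen: tuple[str, ...], ssum: float, excluded: set[str]) -> None:
        remaining = [t for t in candidates[idx:] if t not in excluded]
        if len(chosen) + len(remaining) < best[0]:
            return
        if not remaining:
            if better(len(chosen), ssum, chosen):
                best[0], best[1], best[2] = len(chosen), ssum, key_tuple(chosen)
                best[3] = chosen
            return
        v = remaining[0]
        v_idx = candidates.index(v) + 1
        # include v
        search(v_idx, chosen + (v,), ssum + sigma[v], excluded | related[v])
        # exclude v
        search(v_idx, chosen, ssum, excluded | {v})

    search(0, (), 0.0, set())
    return TermSet(best[3])


def term_distance(t_a: str, t_b: str, taxonomy: Taxonomy) -> float:
    """Shortest directed-path length between a related pair; inf if unrelated.

    Symmetric: the path is measured in whichever direction the ancestor
    relation holds.  Equal terms are at distance 0.
    """
    taxonomy._check(t_a, t_b)
    if t_a == t_b:
        return 0
    if t_b in taxonomy.descendants(t_a):
        return nx.shortest_path_length(taxonomy.graph, t_a, t_b)
    if t_a in taxonomy.descendants(t_b):
        return nx.shortest_path_length(taxonomy.graph, t_b, t_a)
    return math.inf


# -- loading ---------------------------------------------------------------


def load_taxonomy_edges(
    edges: Iterable[tuple[str, str]],
    *,
    virtual_root: bool = False,
    specificity_aggregation: str = "mean",
) -> Taxonomy:
    """Build a Taxonomy from (child, parent) pairs.

    With ``virtual_root=True``, multiple top-level terms are joined under a
    synthetic root node named ``"ROOT"``.
    """
    g = nx.DiGraph()
    for child, parent in edges:
        g.add_edge(parent, child)
    if g.number_of_nodes() == 0:
        raise TaxonomyError("no edges: empty taxonomy")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise TaxonomyError(f"cycle detected: {cycle[0][0]} -> {cycle[0][1]}")
    roots = [n for n in g if g.in_degree(n) == 0]
    if len(roots) > 1:
        if not virtual_root:
            raise TaxonomyError(
                f"multiple roots {sorted(roots)}; enable virtual_root to join them"
            )
        for r in roots:
            g.add_edge("ROOT", r)
    return Taxonomy(g, specificity_aggregation=specificity_aggregation)


def load_taxonomy(
    path: str,
    *,
    namespace: str | None = None,
    include_part_of: bool = False,
    virtual_root: bool = False,
    specificity_aggregation: str = "mean",
) -> Taxonomy:
    """Load a taxonomy from an OBO file or an edge-list TSV.

    OBO files (detected by content) keep only ``is_a`` edges by default
    (``part_of`` optionally), drop obsolete terms, and may be restricted to
    one namespace (e.g. ``biological_process``).  TSV files carry one
    ``child<TAB>parent`` pair per line; a ``child``/``parent`` header row and
    ``#`` comments are skipped.
    """
    with open(path) as fh:
        head = fh.read(4096)
    if "format-version" in head or "[Term]" in head:
        return _load_obo(
            path,
            namespace=namespace,
            include_part_of=include_part_of,
            virtual_root=virtual_root,
            specificity_aggregation=specificity_aggregation,
        )
    return _load_tsv(
        path, virtual_root=virtual_root, specificity_aggregation=specificity_aggregation
    )


def _load_tsv(path: str, **kwargs) -> Taxonomy:
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TaxonomyError(f"{path}:{i + 1}: expected two tab-separated columns")
            child, parent = parts[0].strip(), parts[1].strip()
            if i == 0 and child.lower() in ("child", "term"):
                continue
            edges.append((child, parent))
    return load_taxonomy_edges(edges, **kwargs)


def _load_obo(
    path: str,
    *,
    namespace: str | None,
    include_part_of: bool,
    virtual_root: bool,
    specificity_aggregation: str,
) -> Taxonomy:
    import obonet

    raw = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    keep_nodes = set()
    alt: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        if namespace and data.get("namespace") != namespace:
            continue
        keep_nodes.add(node)
        for a in data.get("alt_id", []):
            alt[a] = node
    for node in keep_nodes:
        g.add_node(node)
    for child, parent, key in raw.edges(keys=True):
        if key != "is_a" and not (include_part_of and key == "part_of"):
            continue
        if child in keep_nodes and parent in keep_nodes:
            g.add_edge(parent, child)  # obonet edges point child -> parent
    if g.number_of_nodes() == 0:
        raise TaxonomyError(f"no terms left after filtering {path}")
    roots = [n for n in g if g.in_degree(n) == 0]
    if len(roots) > 1:
        if not virtual_root:
            raise TaxonomyError(
                f"multiple roots {sorted(roots)[:5]}; enable virtual_root"
            )
        for r in roots:
            g.add_edge("ROOT", r)
    tax = Taxonomy(g, specificity_aggregation=specificity_aggregation)
    tax.alt_ids = alt  # type: ignore[attr-defined]
    return tax
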