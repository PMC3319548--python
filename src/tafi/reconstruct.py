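"""TAFI: taxonomy-driven agglomerative fuzzy inference of gene hierarchies.

Starting from one singleton cluster per gene, each iteration scores every
cluster pair by the HMS of the hypothetical module obtained by joining the
two clusters under a fresh root, finds the best similarity S_max, and
merges *every* pair within the multiplicative band ``alpha * S_max`` —
this is the fuzziness: a cluster that joins several admissible merges
appears as a subtree in each of them, so multi-functional genes can end up
in several subtrees of the final forest.  Merging stops once S_max drops
below the stopping criterion ``beta``.

A merge is pruned when the resulting leaf set has already been formed
(redundancy) or when the two clusters share genes (a gene may recur across
subtrees of the forest, never inside one tree).  Since the hypothetical-
merge HMS is a semi-metric, the score itself serves as the linkage; no
Ward-style update rule is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .modules import AnnotatedModule, ModuleError, ModuleTree, annotate_hierarchy, annotate_leaves
from .scoring import ScoringConfig, hms, penalization
from .taxonomy import Taxonomy, TermSet, ancestor_term_set, max_unrelated_subset, term_specificity

__all__ = ["TafiConfig", "TafiResult", "cluster_similarity", "tafi_build", "cut_hierarchy", "forest_hms"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TafiConfig:
    """TAFI parameters.

    alpha:
        Merging factor in (0, 1]: pairs with similarity >= alpha * S_max
        merge in the same iteration.  alpha = 1 recovers classic
        best-pair-only agglomerative clustering (fuzziness off).
    beta:
        Stopping criterion in [0, 1]: agglomeration halts when the best
        pairwise similarity falls below beta.
    scoring:
        The HMS configuration used as the inter-cluster similarity.
    missing:
        Policy for unannotated genes (see ``annotate_leaves``).
    """

    alpha: float = 0.9
    beta: float = 0.1
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    missing: str = "root"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")


@dataclass
class _Cluster:
    """Active cluster with cached scoring state for O(1) merge similarity."""

    module: AnnotatedModule
    score_sum: float        # sum of P(v) * sigma*(F(v)) over internal nodes
    n_internal: int
    root_terms: TermSet
    root_closure: frozenset[str]
    key: tuple[str, ...]    # sorted leaf genes; deterministic ordering handle

    @property
    def leafset(self) -> frozenset[str]:
        return frozenset(self.key)


def _sigma_star(terms: TermSet, taxonomy: Taxonomy, config: ScoringConfig) -> float:
    sigmas = [term_specificity(t, taxonomy) for t in terms]
    if config.term_specificity_aggregation == "max":
        return max(sigmas)
    return sum(sigmas) / len(sigmas)


def _make_singleton(gene: str, module: AnnotatedModule, taxonomy: Taxonomy) -> _Cluster:
    leaf = module.tree.root
    terms = module.annotation[leaf]
    return _Cluster(
        module=module,
        score_sum=0.0,
        n_internal=0,
        root_terms=terms,
        root_closure=ancestor_term_set(terms, taxonomy),
        key=(gene,),
    )


def _merge_annotation(
    a: _Cluster, b: _Cluster, taxonomy: Taxonomy
) -> tuple[TermSet, frozenset[str]]:
    common = a.root_closure & b.root_closure
    terms = max_unrelated_subset(common, taxonomy)
    return terms, ancestor_term_set(terms, taxonomy)


def _pair_similarity(
    a: _Cluster, b: _Cluster, taxonomy: Taxonomy, config: ScoringConfig
) -> tuple[float, TermSet, frozenset[str], float]:
    """Hypothetical-merge HMS, computed incrementally.

    Joining a and b under a fresh root changes nothing inside either
    subtree, so the merged score is the two cached internal-node sums plus
    the new root's P * sigma*, averaged over all internal nodes.
    """
    terms, closure = _merge_annotation(a, b, taxonomy)
    p_new = penalization(terms, [a.root_terms, b.root_terms], taxonomy, config)
    contrib = p_new * _sigma_star(terms, taxonomy, config)
    n_int = a.n_internal + b.n_internal + 1
    total = a.score_sum + b.score_sum + contrib
    sim = total / n_int if config.node_aggregation == "mean" else total
    return sim, terms, closure, contrib


def cluster_similarity(
    a: AnnotatedModule,
    b: AnnotatedModule,
    taxonomy: Taxonomy,
    config: TafiConfig = TafiConfig(),
) -> float:
    """HMS of the hypothetical module joining *a* and *b* under a new root.

    Definitionally identical to building the merged tree explicitly and
    scoring it; this entry point recomputes from the full modules rather
    than cached cluster state.
    """
    merged = ModuleTree.join([a.tree, b.tree])
    module = AnnotatedModule(tree=merged)
    module.annotation.update(a.annotation)
    module.annotation.update(b.annotation)
    annotate_hierarchy(module, taxonomy)
    return hms(module, taxonomy, config.scoring)


@dataclass
class TafiResult:
    """Forest produced by TAFI plus the iteration trace."""

    forest: list[AnnotatedModule]
    s_max_history: list[float]
    n_iterations: int

    @property
    def trees(self) -> list[ModuleTree]:
        return [m.tree for m in self.forest]


def tafi_build(
    genes: Iterable[str],
    gene_annotations: Mapping[str, Iterable[str]],
    taxonomy: Taxonomy,
    config: TafiConfig = TafiConfig(),
    *,
    force_single_root: bool = False,
) -> TafiResult:
    """Reconstruct an (overlapping) functional hierarchy from a bag of genes.

    Returns a forest: one tree if agglomeration completes, several if the
    stopping criterion fires first or fuzzy duplication leaves overlapping
    subtrees.  With ``force_single_root`` the remaining (disjoint) trees
    are joined under a final virtual root.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ModuleError("tafi_build: empty gene set")

    active: list[_Cluster] = []
    for g in gene_list:
        tree = ModuleTree.leaf(g)
        module = annotate_leaves(tree, gene_annotations, taxonomy, missing=config.missing)
        active.append(_make_singleton(g, module, taxonomy))

    registry: set[frozenset[str]] = {c.leafset for c in active}
    history: list[float] = []
    iteration = 0

    while len(active) > 1:
        iteration += 1
        active.sort(key=lambda c: c.key)
        sims: dict[tuple[int, int], tuple[float, TermSet, frozenset[str], float]] = {}
        admissible: list[tuple[float, tuple[str, ...], tuple[str, ...], int, int]] = []
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                sims[(i, j)] = _pair_similarity(
                    active[i], active[j], taxonomy, config.scoring
                )
                a, b = active[i], active[j]
                # a gene may not recur inside one tree; repeated subtrees
                # are redundant — such pairs can never merge
                if not (a.leafset & b.leafset) and (a.leafset | b.leafset) not in registry:
                    admissible.append((sims[(i, j)][0], a.key, b.key, i, j))
        if not admissible:
            logger.info("TAFI iteration %d: no admissible merge left; stopping", iteration)
            break
        s_max = max(t[0] for t in admissible)
        history.append(s_max)
        logger.info("TAFI iteration %d: %d clusters, S_max=%.4f", iteration, len(active), s_max)
        if s_max < config.beta:
            break

        threshold = config.alpha * s_max - 1e-12
        candidates = sorted(admissible, key=lambda t: (-t[0], t[1], t[2]))
        if config.alpha == 1.0:
            # fuzziness off: classic AHC merges only the single best pair
            candidates = candidates[:1]
        merged_clusters: list[_Cluster] = []
        consumed: set[int] = set()
        for sim, _, _, i, j in candidates:
            if sim < threshold:
                break
            a, b = active[i], active[j]
            union = a.leafset | b.leafset
            if union in registry:
                continue  # formed earlier in this very iteration
            terms, closure, contrib = sims[(i, j)][1], sims[(i, j)][2], sims[(i, j)][3]
            tree = ModuleTree.join([a.module.tree, b.module.tree])
            module = AnnotatedModule(tree=tree)
            module.annotation.update(a.module.annotation)
            module.annotation.update(b.module.annotation)
            module.annotation[tree.root] = terms
            merge_order = dict(a.module.tree.merge_order or {})
            merge_order.update(b.module.tree.merge_order or {})
            merge_order[tree.root] = iteration
            tree.merge_order = merge_order
            merged_clusters.append(
                _Cluster(
                    module=module,
                    score_sum=a.score_sum + b.score_sum + contrib,
                    n_internal=a.n_internal + b.n_internal + 1,
                    root_terms=terms,
                    root_closure=closure,
                    key=tuple(sorted(union)),
                )
            )
            registry.add(union)
            consumed.add(i)
            consumed.add(j)
        if not merged_clusters:
            logger.info("TAFI iteration %d: every admissible merge pruned; stopping", iteration)
            break
        active = [c for k, c in enumerate(active) if k not in consumed]
        active.extend(merged_clusters)

    active.sort(key=lambda c: c.key)
    forest = [c.module for c in active]
    if force_single_root and len(forest) > 1:
        all_genes = [g for c in active for g in c.key]
        if len(all_genes) != len(set(all_genes)):
            raise ModuleError(
                "force_single_root: overlapping subtrees cannot share one tree"
            )
        tree = ModuleTree.join([m.tree for m in forest])
        order: dict[str, int] = {}
        for m in forest:
            order.update(m.tree.merge_order or {})
        order[tree.root] = iteration + 1
        tree.merge_order = order
        module = AnnotatedModule(tree=tree)
        for m in forest:
            module.annotation.update(m.annotation)
        annotate_hierarchy(module, taxonomy)
        forest = [module]
    else:
        for m in forest:
            if not m.is_fully_annotated():
                annotate_hierarchy(m, taxonomy)
    return TafiResult(forest=forest, s_max_history=history, n_iterations=iteration)


def forest_hms(result: TafiResult, taxonomy: Taxonomy, config: ScoringConfig = ScoringConfig()) -> float:
    """HMS pooled over a forest: mean P*sigma* across all internal nodes.

    Reduces to plain HMS for a single tree; 0 for a forest of singletons
    (no internal structure to reward).
    """
    total = 0.0
    n_internal = 0
    for module in result.forest:
        internal = module.tree.internal_nodes()
        if not internal:
            continue
        sub = hms(module, taxonomy, replace(config, node_aggregation="sum"))
        total += sub
        n_internal += len(internal)
    if n_internal == 0:
        return 0.0
    return total / n_internal if config.node_aggregation == "mean" else total


def cut_hierarchy(
    forest: Iterable[ModuleTree | AnnotatedModule], k: int
) -> list[frozenset[str]]:
    """Cut the highest merges until exactly *k* subtrees remain; return leaf sets.

    The highest merge is removed first, exposing its children as new
    subtree roots; "highest" means the latest agglomeration step for trees
    built by TAFI (which record their merge order) and the node of
    greatest topological height otherwise (ties: smaller subtree, then
    lexicographically smallest leaf set).  A fuzzy gene appears in every
    subtree that contains it.
    """
    roots: list[tuple[ModuleTree, str]] = []
    for item in forest:
        tree = item.tree if isinstance(item, AnnotatedModule) else item
        roots.append((tree, tree.root))
    if k < 1:
        raise ModuleError(f"k must be >= 1, got {k}")
    total_leaves = sum(t.n_leaves for t, r in roots)
    if k > total_leaves:
        raise ModuleError(f"k={k} exceeds total leaf count {total_leaves}")
    if len(roots) > k:
        raise ModuleError(f"forest already has {len(roots)} > k={k} subtrees")

    def leafset(tree: ModuleTree, node: str) -> frozenset[str]:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            kids = tree.children[n]
            if kids:
                stack.extend(kids)
            else:
                out.add(tree.leaf_genes[n])
        return frozenset(out)

    while len(roots) < k:
        splittable = [(t, n) for t, n in roots if t.children[n]]
        if not splittable:
            raise ModuleError("no internal nodes left to cut")
        def cut_key(tn):
            t, n = tn
            order = (t.merge_order or {}).get(n, -1)
            return (-order, -t.height(n), len(leafset(t, n)), tuple(sorted(leafset(t, n))))

        t, n = min(splittable, key=cut_key)
        roots.remove((t, n))
        new = [(t, c) for c in t.children[n]]
        if len(roots) + len(new) > k:
            raise ModuleError(
                f"cut cannot reach exactly k={k}: splitting a {len(new)}-way node overshoots"
            )
        roots.extend(new)
    return [leafset(t, n) for t, n in roots]
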