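"""Hierarchical gene modules and their hierarchical functional annotation.

A hierarchical gene module (HGM) is a rooted tree whose leaves are genes.
Annotation assigns every node an unrelated set of taxonomy terms F(v):
leaves carry the gene's own annotation; each internal node receives the
set of most specific functional terms common to all of its children —
the maximum unrelated subset of the intersection of the children's
ancestor term closures.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .taxonomy import (
    Taxonomy,
    TermSet,
    ancestor_term_set,
    max_unrelated_subset,
    term_specificity,
)

__all__ = ["ModuleTree", "AnnotatedModule", "ModuleError", "annotate_leaves", "annotate_hierarchy"]

logger = logging.getLogger(__name__)

_counter = itertools.count()


def _fresh_id() -> str:
    return f"_n{next(_counter)}"


class ModuleError(ValueError):
    """Raised for malformed module trees or missing annotations."""


@dataclass
class ModuleTree:
    """Rooted tree over genes: leaves carry gene IDs, internal nodes are synthetic.

    ``children`` maps every node ID to the tuple of its child node IDs
    (empty for leaves); ``leaf_genes`` maps leaf node IDs to gene IDs.
    """

    root: str
    children: dict[str, tuple[str, ...]]
    leaf_genes: dict[str, str]
    # agglomeration bookkeeping: internal node -> iteration at which the
    # merge was executed (None for trees not built agglomeratively)
    merge_order: dict[str, int] | None = None

    def __post_init__(self) -> None:
        reachable = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in reachable:
                raise ModuleError(f"node {n!r} reached twice: not a tree")
            reachable.add(n)
            stack.extend(self.children.get(n, ()))
        if reachable != set(self.children):
            raise ModuleError("children map contains nodes unreachable from root")
        leaves = {n for n, c in self.children.items() if not c}
        if leaves != set(self.leaf_genes):
            raise ModuleError("leaf_genes must cover exactly the childless nodes")
        genes = list(self.leaf_genes.values())
        if len(genes) != len(set(genes)):
            raise ModuleError("duplicate gene IDs among the leaves of one tree")

    @classmethod
    def leaf(cls, gene: str) -> "ModuleTree":
        nid = _fresh_id()
        return cls(root=nid, children={nid: ()}, leaf_genes={nid: gene})

    @classmethod
    def join(cls, subtrees: Iterable["ModuleTree"]) -> "ModuleTree":
        """New tree with a fresh root above the roots of *subtrees*."""
        subtrees = list(subtrees)
        if not subtrees:
            raise ModuleError("join of zero subtrees")
        root = _fresh_id()
        children: dict[str, tuple[str, ...]] = {root: tuple(t.root for t in subtrees)}
        leaf_genes: dict[str, str] = {}
        for t in subtrees:
            overlap = set(children) & set(t.children)
            if overlap:
                raise ModuleError(f"node ID collision: {sorted(overlap)[:3]}")
            children.update(t.children)
            leaf_genes.update(t.leaf_genes)
        return cls(root=root, children=children, leaf_genes=leaf_genes)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.leaf_genes.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_genes)

    def internal_nodes(self) -> list[str]:
        return [n for n, c in self.children.items() if c]

    def postorder(self) -> list[str]:
        order: list[str] = []
        stack: list[tuple[str, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        return order

    def height(self, node: str | None = None) -> int:
        node = node if node is not None else self.root
        kids = self.children[node]
        if not kids:
            return 0
        return 1 + max(self.height(c) for c in kids)


@dataclass
class AnnotatedModule:
    """A ModuleTree together with per-node annotation F(v) and penalization P(v)."""

    tree: ModuleTree
    annotation: dict[str, TermSet] = field(default_factory=dict)
    penalization: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)

    def is_fully_annotated(self) -> bool:
        return set(self.annotation) == set(self.tree.children)


def annotate_leaves(
    tree: ModuleTree,
    gene_annotations: Mapping[str, Iterable[str]],
    taxonomy: Taxonomy,
    *,
    missing: str = "error",
) -> AnnotatedModule:
    """Install leaf annotations, reducing each gene's term set to unrelated form.

    ``missing`` controls what happens to genes absent from
    *gene_annotations* (or annotated with an empty set): ``"error"`` raises,
    ``"root"`` annotates them with the taxonomy root so downstream scoring
    stays total (an unannotated gene contributes no specificity).
    """
    if missing not in ("error", "root"):
        raise ModuleError(f"unknown missing-gene policy {missing!r}")
    annotated = AnnotatedModule(tree=tree)
    for node, gene in tree.leaf_genes.items():
        terms = frozenset(gene_annotations.get(gene, ()))
        if not terms:
            if missing == "error":
                raise ModuleError(f"gene {gene!r} has no annotation")
            annotated.annotation[node] = TermSet({taxonomy.root})
            continue
        reduced = taxonomy.reduce_to_unrelated(terms)
        if reduced != terms:
            logger.warning(
                "annotation of gene %s contains related terms; reduced %d -> %d",
                gene, len(terms), len(reduced),
            )
        annotated.annotation[node] = TermSet(reduced)
    return annotated


def annotate_hierarchy(module: AnnotatedModule, taxonomy: Taxonomy) -> AnnotatedModule:
    """Fill in F(v) for every internal node by post-order traversal.

    F(v) = max_unrelated_subset( ∩_c ancestor_term_set(F(c)) ) over the
    children c of v.  The intersection always contains the taxonomy root,
    so F(v) is never empty.  A single-child node copies its child's
    annotation unchanged.
    """
    tree = module.tree
    ann = module.annotation
    closures: dict[str, frozenset[str]] = {}
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            if node not in ann:
                raise ModuleError(f"leaf {node!r} is not annotated")
            closures[node] = ancestor_term_set(ann[node], taxonomy)
            continue
        if len(kids) == 1:
            ann[node] = ann[kids[0]]
            closures[node] = closures[kids[0]]
            continue
        common = frozenset.intersection(*(closures[c] for c in kids))
        ann[node] = max_unrelated_subset(common, taxonomy)
        closures[node] = ancestor_term_set(ann[node], taxonomy)
    for node in tree.children:
        module.specificity[node] = max(
            term_specificity(t, taxonomy) for t in ann[node]
        )
    return module
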