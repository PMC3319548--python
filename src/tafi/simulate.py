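"""Seeded generators: random taxonomies, annotations, planted modular gene sets.

The generators emulate the statistical shape of the real inputs — a GO-like
term DAG, per-gene unrelated term sets, and "bags of genes" drawn from
known functional groups — so every pipeline stage can be exercised without
downloads.  Planted modules live in disjoint branches of the taxonomy
(extra DAG parents are only ever drawn from the same branch), so at zero
annotation noise genes from different modules share no functional ancestor
below the root: within-module coherence is strictly separated from
between-module coherence by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .taxonomy import Taxonomy, TermSet, load_taxonomy_edges

__all__ = ["GeneratorSpec", "GeneratorError", "generate_taxonomy", "generate_planted_modules", "generate_background"]

_MAX_WIDTH = 60  # cap on terms per level, keeps random taxonomies desk-sized


class GeneratorError(ValueError):
    """Raised for infeasible generator specifications."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic experiment.

    seed:
        RNG seed; identical specs produce identical outputs.
    depth:
        Taxonomy depth L (>= 2): every branch of the generated taxonomy
        reaches exactly this depth.
    branching:
        (min, max) children per internal term.
    dag_extra_parent_prob:
        Probability that a term gains one extra parent (drawn from
        strictly shallower terms of its own root branch, so the DAG stays
        acyclic, keeps depth L, and branches stay disjoint).
    n_modules:
        Number m of planted gene modules, one per root branch.
    genes_per_module:
        Genes in each planted module.
    terms_per_gene:
        (min, max) terms annotated to each gene.
    multi_function_prob:
        Probability that a gene is additionally annotated from (and listed
        in) a second planted module.
    annotation_noise:
        Probability that each annotated term is replaced by a uniformly
        random taxonomy term.
    """

    seed: int = 0
    depth: int = 5
    branching: tuple[int, int] = (2, 3)
    dag_extra_parent_prob: float = 0.0
    n_modules: int = 3
    genes_per_module: int = 8
    terms_per_gene: tuple[int, int] = (1, 3)
    multi_function_prob: float = 0.0
    annotation_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise GeneratorError(f"depth must be >= 2, got {self.depth}")
        if not 1 <= self.branching[0] <= self.branching[1]:
            raise GeneratorError(f"invalid branching range {self.branching}")
        for name in ("dag_extra_parent_prob", "multi_function_prob", "annotation_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise GeneratorError(f"{name} must be in [0, 1], got {v}")
        if self.n_modules < 1 or self.genes_per_module < 1:
            raise GeneratorError("need at least one module and one gene per module")


def generate_taxonomy(spec: GeneratorSpec) -> Taxonomy:
    """Random rooted taxonomy of depth exactly ``spec.depth``.

    The root has ``max(n_modules, branching[0])`` children, each heading
    its own branch grown level by level; with ``dag_extra_parent_prob`` > 0
    terms acquire extra parents within their branch, turning the tree into
    a DAG without changing its depth.
    """
    rng = random.Random(spec.seed)
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"T{counter[0]:04d}"

    root = "T0000"
    edges: list[tuple[str, str]] = []  # (child, parent)
    branch_of: dict[str, str] = {}
    n_branches = max(spec.n_modules, spec.branching[0])
    level_nodes: dict[int, list[str]] = {0: [root]}
    branches = []
    for _ in range(n_branches):
        b = fresh()
        edges.append((b, root))
        branch_of[b] = b
        branches.append(b)
    level_nodes[1] = list(branches)

    for level in range(1, spec.depth):
        nxt: list[str] = []
        width = len(level_nodes[level])
        for node in level_nodes[level]:
            if width >= _MAX_WIDTH:
                n_children = 1
            else:
                n_children = rng.randint(*spec.branching)
            for _ in range(n_children):
                c = fresh()
                edges.append((c, node))
                branch_of[c] = branch_of[node]
                nxt.append(c)
            width += n_children - 1
        level_nodes[level + 1] = nxt

    if spec.dag_extra_parent_prob > 0:
        min_level = {root: 0}
        for lvl, nodes in level_nodes.items():
            for n in nodes:
                min_level.setdefault(n, lvl)
        existing = {(c, p) for c, p in edges}
        for lvl in range(2, spec.depth + 1):
            for node in level_nodes[lvl]:
                if rng.random() >= spec.dag_extra_parent_prob:
                    continue
                candidates = [
                    u
                    for ul in range(1, lvl)
                    for u in level_nodes[ul]
                    if branch_of[u] == branch_of[node] and (node, u) not in existing
                ]
                if candidates:
                    parent = rng.choice(candidates)
                    edges.append((node, parent))
                    existing.add((node, parent))

    tax = load_taxonomy_edges(edges)
    tax.branch_of = branch_of  # type: ignore[attr-defined]
    return tax


def _branch_members(taxonomy: Taxonomy, branch: str) -> list[str]:
    return sorted(taxonomy.descendants(branch) | {branch})


def generate_planted_modules(
    spec: GeneratorSpec, taxonomy: Taxonomy
) -> tuple[dict[str, TermSet], list[set[str]]]:
    """Gene annotations plus the m reference gene sets they were drawn from.

    Each module lives in its own child branch of the taxonomy root (the
    branch must reach depth >= 2 below the root) and is organized around a
    *core term*: a deep term of that branch carried by every module gene —
    the way all members of a real pathway share the pathway's specific
    annotation — plus up to ``terms_per_gene[1] - 1`` accessory terms from
    the same branch, unrelated to the core.  Multi-functional genes
    additionally carry a second module's core term and join that
    reference set.  Noise is applied last and never changes reference
    membership.
    """
    rng = random.Random(spec.seed + 1)
    root = taxonomy.root
    branch_heads = sorted(taxonomy.graph.successors(root))
    deep_enough = [
        b
        for b in branch_heads
        if any(max(taxonomy.levels[d]) - min(taxonomy.levels[b]) >= 2
               for d in taxonomy.descendants(b))
    ]
    if len(deep_enough) < spec.n_modules:
        raise GeneratorError(
            f"taxonomy offers {len(deep_enough)} depth->=2 root branches, "
            f"need {spec.n_modules}"
        )
    anchors = deep_enough[: spec.n_modules]
    all_terms = sorted(taxonomy.terms - {root})

    def deepest_terms(branch: str) -> list[str]:
        members = _branch_members(taxonomy, branch)
        top = max(max(taxonomy.levels[t]) for t in members)
        return [t for t in members if max(taxonomy.levels[t]) == top]

    cores = [rng.choice(deepest_terms(b)) for b in anchors]
    accessory_pools = []
    for b, core in zip(anchors, cores):
        pool = [
            t
            for t in _branch_members(taxonomy, b)
            if t != b and t != core
            and t not in taxonomy.ancestors(core)
            and t not in taxonomy.descendants(core)
        ]
        accessory_pools.append(pool)

    annotations: dict[str, TermSet] = {}
    reference: list[set[str]] = [set() for _ in range(spec.n_modules)]

    def module_terms(mi: int) -> set[str]:
        terms = {cores[mi]}
        n_accessory = rng.randint(*spec.terms_per_gene) - 1
        pool = accessory_pools[mi]
        if n_accessory > 0 and pool:
            terms |= set(rng.sample(pool, min(n_accessory, len(pool))))
        return terms

    for mi in range(spec.n_modules):
        for gi in range(spec.genes_per_module):
            gene = f"M{mi + 1}G{gi + 1:02d}"
            terms = module_terms(mi)
            reference[mi].add(gene)
            if spec.n_modules > 1 and rng.random() < spec.multi_function_prob:
                other = rng.choice([j for j in range(spec.n_modules) if j != mi])
                terms.add(cores[other])
                reference[other].add(gene)
            if spec.annotation_noise > 0:
                terms = {
                    rng.choice(all_terms) if rng.random() < spec.annotation_noise else t
                    for t in terms
                }
            annotations[gene] = taxonomy.reduce_to_unrelated(terms)
    return annotations, reference


def generate_background(
    spec: GeneratorSpec,
    taxonomy: Taxonomy,
    n_genes: int,
    *,
    branch: str | None = None,
    prefix: str = "BG",
) -> dict[str, TermSet]:
    """Annotate *n_genes* background genes with random unrelated term sets.

    With ``branch`` set, terms are confined to that root branch (useful
    when a null distribution should not be degenerate at zero coherence).
    """
    rng = random.Random(spec.seed + 2)
    if branch is None:
        pool = sorted(taxonomy.terms - {taxonomy.root})
    else:
        pool = [t for t in _branch_members(taxonomy, branch) if t != branch]
    if not pool:
        raise GeneratorError("no terms available for background annotation")
    out: dict[str, TermSet] = {}
    for i in range(n_genes):
        k = rng.randint(*spec.terms_per_gene)
        terms = set(rng.sample(pool, min(k, len(pool))))
        out[f"{prefix}{i + 1:04d}"] = taxonomy.reduce_to_unrelated(terms)
    return out
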