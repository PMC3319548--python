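import random

import pytest

from tafi import (
    ModuleError,
    ModuleTree,
    ScoringConfig,
    TafiConfig,
    cluster_similarity,
    cut_hierarchy,
    hms,
    tafi_build,
)
from tafi.modules import annotate_hierarchy, annotate_leaves
from tafi.scoring import score_tree
from tafi.simulate import GeneratorSpec, generate_planted_modules, generate_taxonomy

from conftest import random_dag


def make_cluster(genes, annotations, tax):
    tree = ModuleTree.leaf(genes[0])
    for g in genes[1:]:
        tree = ModuleTree.join([tree, ModuleTree.leaf(g)])
    mod = annotate_leaves(tree, annotations, tax)
    return annotate_hierarchy(mod, tax)


class TestClusterSimilarity:
    def test_identical_deep_singletons_score_one(self, chain_taxonomy):
        ann = {"g1": {"b"}, "g2": {"b"}}
        a = make_cluster(["g1"], ann, chain_taxonomy)
        b = make_cluster(["g2"], ann, chain_taxonomy)
        assert cluster_similarity(a, b, chain_taxonomy) == 1.0

    def test_root_only_overlap_scores_zero(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"b1"}}
        a = make_cluster(["g1"], ann, fork_taxonomy)
        b = make_cluster(["g2"], ann, fork_taxonomy)
        assert cluster_similarity(a, b, fork_taxonomy) == 0.0

    def test_equals_hms_of_explicitly_merged_tree(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a2"}, "g3": {"b1"}, "g4": {"b2"}}
        a = make_cluster(["g1", "g2"], ann, fork_taxonomy)
        b = make_cluster(["g3", "g4"], ann, fork_taxonomy)
        cfg = TafiConfig(scoring=ScoringConfig(theta=2))
        merged = ModuleTree.join([a.tree, b.tree])
        expected, _ = score_tree(merged, ann, fork_taxonomy, cfg.scoring)
        assert cluster_similarity(a, b, fork_taxonomy, cfg) == pytest.approx(expected)

    def test_symmetric(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a2"}}
        a = make_cluster(["g1"], ann, fork_taxonomy)
        b = make_cluster(["g2"], ann, fork_taxonomy)
        assert cluster_similarity(a, b, fork_taxonomy) == pytest.approx(
            cluster_similarity(b, a, fork_taxonomy)
        )


def classic_ahc_oracle(genes, annotations, tax, scoring):
    """Best-pair-per-iteration agglomeration with the same similarity."""
    cfg = TafiConfig(alpha=1.0, beta=0.0, scoring=scoring)
    clusters = {g: make_cluster([g], annotations, tax) for g in sorted(genes)}
    keys = {g: (g,) for g in clusters}
    while len(clusters) > 1:
        best = None
        for x in sorted(clusters):
            for y in sorted(clusters):
                if x >= y:
                    continue
                s = cluster_similarity(clusters[x], clusters[y], tax, cfg)
                cand = (-s, keys[x], keys[y], x, y)
                if best is None or cand < best:
                    best = cand
        _, kx, ky, x, y = best
        merged_tree = ModuleTree.join([clusters[x].tree, clusters[y].tree])
        mod = annotate_leaves(merged_tree, annotations, tax)
        annotate_hierarchy(mod, tax)
        new_key = tuple(sorted(kx + ky))
        del clusters[x], clusters[y]
        name = "|".join(new_key)
        clusters[name] = mod
        keys[name] = new_key
    return next(iter(clusters.values()))


def tree_shape(tree: ModuleTree, node=None):
    """Canonical nested-frozenset encoding of the leaf partition structure."""
    node = node if node is not None else tree.root
    kids = tree.children[node]
    if not kids:
        return tree.leaf_genes[node]
    return frozenset(tree_shape(tree, c) for c in kids)


class TestTafiBuild:
    def test_empty_gene_set_rejected(self, fork_taxonomy):
        with pytest.raises(ModuleError):
            tafi_build([], {}, fork_taxonomy)

    def test_single_gene_yields_one_leaf(self, fork_taxonomy):
        res = tafi_build(["g1"], {"g1": {"a1"}}, fork_taxonomy)
        assert len(res.forest) == 1
        assert res.forest[0].tree.genes == {"g1"}

    @pytest.mark.parametrize("seed", range(10))
    def test_alpha_one_matches_classic_ahc_oracle(self, seed):
        rng = random.Random(seed)
        tax = random_dag(rng, rng.randint(6, 12))
        terms = sorted(tax.terms)
        n = rng.randint(3, 8)
        ann = {
            f"g{i}": set(rng.sample(terms, rng.randint(1, 2))) for i in range(n)
        }
        scoring = ScoringConfig(theta=rng.choice([1, 5, 10]))
        cfg = TafiConfig(alpha=1.0, beta=0.0, scoring=scoring)
        res = tafi_build(set(ann), ann, tax, cfg)
        assert len(res.forest) == 1
        oracle = classic_ahc_oracle(set(ann), ann, tax, scoring)
        assert tree_shape(res.forest[0].tree) == tree_shape(oracle.tree)

    def test_alpha_one_gives_binary_tree_each_gene_once(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a2"}, "g3": {"b1"}, "g4": {"b2"}}
        res = tafi_build(set(ann), ann, fork_taxonomy, TafiConfig(alpha=1.0, beta=0.0))
        assert len(res.forest) == 1
        tree = res.forest[0].tree
        assert sorted(tree.leaf_genes.values()) == ["g1", "g2", "g3", "g4"]
        for v in tree.internal_nodes():
            assert len(tree.children[v]) == 2

    def test_bridge_gene_appears_under_both_subtrees(self):
        # two planted groups; g4 carries both cores -> fuzzy duplication
        spec = GeneratorSpec(seed=3, n_modules=2, genes_per_module=4)
        tax = generate_taxonomy(spec)
        ann, ref = generate_planted_modules(spec, tax)
        bridge = "M1G04"
        ann[bridge] = frozenset(ann[bridge] | ann["M2G01"])
        res = tafi_build(set(ann), ann, tax, TafiConfig(alpha=0.9, beta=0.95))
        with_a = [
            m for m in res.forest
            if bridge in m.tree.genes and (m.tree.genes - {bridge}) <= ref[0]
            and len(m.tree.genes) > 1
        ]
        with_b = [
            m for m in res.forest
            if bridge in m.tree.genes and (m.tree.genes - {bridge}) <= ref[1]
            and len(m.tree.genes) > 1
        ]
        assert with_a and with_b

    def test_no_two_formed_subtrees_share_leafsets(self):
        spec = GeneratorSpec(seed=5, n_modules=2, genes_per_module=4)
        tax = generate_taxonomy(spec)
        ann, _ = generate_planted_modules(spec, tax)
        res = tafi_build(set(ann), ann, tax, TafiConfig(alpha=0.9, beta=0.5))
        leafsets = [frozenset(m.tree.genes) for m in res.forest]
        assert len(leafsets) == len(set(leafsets))

    def test_stopping_criterion_leaves_forest(self, fork_taxonomy):
        # joining the two coherent pairs dilutes HMS to 2/3 < beta: stop first
        ann = {"g1": {"a1"}, "g2": {"a1"}, "g3": {"b1"}, "g4": {"b1"}}
        res = tafi_build(set(ann), ann, fork_taxonomy, TafiConfig(alpha=1.0, beta=0.7))
        leafsets = {frozenset(m.tree.genes) for m in res.forest}
        assert leafsets == {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})}

    def test_force_single_root_joins_forest(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a1"}, "g3": {"b1"}, "g4": {"b1"}}
        res = tafi_build(
            set(ann), ann, fork_taxonomy,
            TafiConfig(alpha=1.0, beta=0.7), force_single_root=True,
        )
        assert len(res.forest) == 1
        assert res.forest[0].tree.genes == {"g1", "g2", "g3", "g4"}

    def test_cached_scores_match_fresh_recomputation(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a2"}, "g3": {"b1"}, "g4": {"b2"}}
        cfg = TafiConfig(alpha=1.0, beta=0.0, scoring=ScoringConfig(theta=7))
        res = tafi_build(set(ann), ann, fork_taxonomy, cfg)
        mod = res.forest[0]
        fresh, _ = score_tree(mod.tree, ann, fork_taxonomy, cfg.scoring)
        assert hms(mod, fork_taxonomy, cfg.scoring) == pytest.approx(fresh)


class TestCutHierarchy:
    def make_balanced(self):
        a = ModuleTree.join([ModuleTree.leaf("g1"), ModuleTree.leaf("g2")])
        b = ModuleTree.join([ModuleTree.leaf("g3"), ModuleTree.leaf("g4")])
        return ModuleTree.join([a, b])

    def test_k_one_returns_all_leaves(self):
        assert cut_hierarchy([self.make_balanced()], 1) == [
            frozenset({"g1", "g2", "g3", "g4"})
        ]

    def test_k_equals_leaf_count_gives_singletons(self):
        result = cut_hierarchy([self.make_balanced()], 4)
        assert sorted(result, key=sorted) == [
            frozenset({"g1"}), frozenset({"g2"}), frozenset({"g3"}), frozenset({"g4"})
        ]

    def test_balanced_tree_k_two_gives_the_two_clades(self):
        result = cut_hierarchy([self.make_balanced()], 2)
        assert set(result) == {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})}

    def test_k_beyond_leaves_rejected(self):
        with pytest.raises(ModuleError):
            cut_hierarchy([self.make_balanced()], 5)

    def test_merge_order_cut_undoes_latest_merges(self, fork_taxonomy):
        ann = {"g1": {"a1"}, "g2": {"a1"}, "g3": {"b1"}, "g4": {"b1"}}
        res = tafi_build(set(ann), ann, fork_taxonomy, TafiConfig(alpha=1.0, beta=0.0))
        result = cut_hierarchy(res.forest, 2)
        assert set(result) == {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})}
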