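import itertools
import random

import networkx as nx
import pytest

from tafi import Taxonomy, load_taxonomy_edges


@pytest.fixture
def chain_taxonomy():
    """root <- a <- b: depth 2, strictly nested."""
    return load_taxonomy_edges([("a", "root"), ("b", "a")])


@pytest.fixture
def fork_taxonomy():
    """Depth-2 tree: root -> {A, B}; A -> {a1, a2}; B -> {b1, b2}."""
    return load_taxonomy_edges(
        [("A", "root"), ("B", "root"), ("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]
    )


@pytest.fixture
def diamond_taxonomy():
    """DAG: x has two parents p1 (level 1) and p2 (level 2, child of p1)."""
    return load_taxonomy_edges(
        [("p1", "root"), ("p2", "p1"), ("x", "p1"), ("x", "p2")]
    )


def random_dag(rng: random.Random, n_terms: int, extra_edge_prob: float = 0.3) -> Taxonomy:
    """Random rooted DAG on n_terms+1 nodes, each non-root with >=1 earlier parent."""
    names = ["root"] + [f"t{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, len(names)):
        parent = names[rng.randrange(i)]
        edges.append((names[i], parent))
        for j in range(i):
            if names[j] != parent and rng.random() < extra_edge_prob / i:
                edges.append((names[i], names[j]))
    return load_taxonomy_edges(edges)


def brute_force_levels(tax: Taxonomy, term: str) -> set[int]:
    """Level set by explicit enumeration of all simple root-to-term paths."""
    if term == tax.root:
        return {0}
    return {
        len(p) - 1 for p in nx.all_simple_paths(tax.graph, tax.root, term)
    }


def brute_force_max_unrelated(terms, tax: Taxonomy):
    """Power-set oracle: best unrelated subset under the documented tie-break."""
    from tafi import is_related, term_specificity

    terms = sorted(terms)
    best = None
    for r in range(len(terms), 0, -1):
        for combo in itertools.combinations(terms, r):
            if all(
                not is_related(a, b, tax)
                for a, b in itertools.combinations(combo, 2)
            ):
                key = (len(combo), sum(term_specificity(t, tax) for t in combo))
                neg = tuple(sorted(combo))
                if best is None or (key[0], key[1]) > (best[0][0], best[0][1]) or (
                    key[0] == best[0][0]
                    and abs(key[1] - best[0][1]) < 1e-12
                    and neg < best[1]
                ):
                    best = (key, neg, frozenset(combo))
        if best is not None and best[0][0] == r:
            break
    return best[2]
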