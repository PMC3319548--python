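# Methods

## Model

`tafi` treats functional annotation as a two-level structure: a
**taxonomy** *T* of functional terms (rooted tree or DAG; edges point from
general to specific terms) and a **hierarchical gene module** *M* (a
rooted tree whose leaves are genes). The taxonomy is the semantic space;
the module tree is the object being scored or inferred.

### Levels and term specificity

Each term's *level set* is the set of lengths of all directed
root-to-term paths; in a DAG a term may occur at several levels. With *L*
the taxonomy depth, the level specificity score is ζ(l) = l/L and a
term's specificity σ(t) aggregates ζ over its occurrence levels — the
mean by default, min/max selectable via `Taxonomy.specificity_aggregation`.
The root always scores 0; only terms occurring exclusively at the deepest
level score 1. This linear-in-depth form is one deliberate rendering of
"specificity grows with depth"; it is isolated behind a single
configuration point so alternatives (e.g. min-level) can be swapped
without touching any other formula. No background term-frequency
(information content) enters anywhere: coherence is scored against the
taxonomy's shape alone, by design.

### Annotations as unrelated sets

Every annotation — a gene's term set, or an internal node's F(v) — is
kept in *unrelated* form: no member is an ancestor of another. Raw inputs
(GAF files routinely list a term together with its ancestors) are reduced
to their most specific members with a warning rather than rejected.
Internal nodes receive the set of **most specific common terms** of their
children: the maximum-cardinality unrelated subset (maximum antichain) of
the intersection of the children's ancestor closures. Because every
closure contains the root, F(v) is never empty. The antichain is found by
exact branch-and-bound with a deterministic tie-break (largest summed
specificity, then lexicographically smallest ID tuple); the candidate
sets arising in practice are intersections of small closures, so
exhaustive optimality is cheap, and the implementation is unit-tested
against a power-set oracle on hundreds of random DAGs.

### Coherence: the hierarchical modularity score

For a parent v and child c, the annotation distance D is the largest (by
default; mean selectable) over terms in F(v) of the shortest taxonomy
distance to a related term in F(c); D = ∞ if some parent term has no
related partner. The dissimilarity is d = D/(D + θ), and the node's
penalization factor is P(v) = 1 − max over children of d. HMS is the mean
over internal nodes of P(v)·σ*(F(v)), with σ* the maximum specificity in
F(v). The mean (rather than sum) keeps scores comparable across module
sizes; a single-child node (possible after hierarchy cuts) inherits its
child's annotation with P = 1.

Two alternative penalty shapes are provided for comparison —
`exponential` (P = exp(−D/θ)) and `linear` (P = max(0, 1 − D/L)) — but
`reciprocal` is the default and the one pinned by the anchor values: at
θ = 1 a distance-1 annotation shift costs exactly 50 % of a node's score,
and at θ = 100 a 15-level shift costs 13 % (rounded).

### θ: meaning and default

θ (dimensionless, in taxonomy-edge units) sets how quickly penalty
accrues with annotation distance; HMS is non-decreasing in θ. The package
default is θ = 10, a middle ground at which a one-edge shift costs ~9 %.
`calibrate_theta` implements the principled choice: given validation
modules known to be coherent, pick the largest grid θ for which at least
a target fraction (default 90 %) remain significant at the chosen level
(default 0.05). Larger θ is preferred because it is the most permissive
setting that still separates known-coherent modules from the null.

### Significance

`monte_carlo_pvalue` draws N (default 1000) same-size gene sets from a
background universe, scores each with the *same* hierarchy builder as the
observed module, and reports p = (r+1)/(N+1) with r the number of null
scores ≥ the observed. The +1 correction keeps p in (0, 1] and makes it
exactly uniform under the null for a continuous statistic. Two builder
modes exist: **rebuild** (TAFI re-run per sample — the mode matching the
bag-of-genes workflow) and **fixed-topology** (null genes permuted onto
the observed tree shape — appropriate when the hierarchy itself is given
and much cheaper). Ties in the statistic (e.g. many null sets scoring
exactly 0 when the universe spans disjoint branches) make the p-value
conservative; the uniformity test therefore uses a one-branch universe
where the statistic is effectively continuous.

### TAFI

TAFI starts from singleton clusters and iterates: score every cluster
pair by the HMS of the hypothetical module formed by joining the two
trees under a fresh root (computed incrementally — a merge changes no
interior node, so only the new root's P·σ* term is new); let S_max be the
best similarity among *admissible* pairs; merge every admissible pair
within the multiplicative band α·S_max; stop when S_max < β or no
admissible pair remains. A pair is inadmissible when the union of its
leaf sets has already been formed (pruning of redundant subtrees) or when
the two clusters share genes (a gene may recur across subtrees of the
forest, never inside one tree). Constituents of executed merges retire at
the end of the iteration, living on inside every merge they joined —
this is the fuzziness that lets a multi-functional gene surface in
several subtrees. The multiplicative band (rather than an additive
margin) keeps the admission criterion proportionally scaled as S_max
shrinks. The hypothetical-merge HMS is itself the linkage; since it is a
semi-metric (no triangle inequality), variance-based linkages like Ward's
would not be valid, and none is used.

At α = 1 the band degenerates and the builder merges only the single best
admissible pair per iteration — classic agglomerative clustering with
fuzziness off, the mode used for partition-style validation. (Merging
*all* exact ties at α = 1 would duplicate genes, which is fuzzy
behaviour; it is reserved for α < 1.)

`cut_hierarchy` produces k subtrees by undoing the highest merges first:
for TAFI-built trees "highest" is the latest agglomeration step (the
merge order is recorded on the tree), which is the dendrogram's own level
structure; trees read from Newick fall back to topological height, which
can misorder cuts when subtrees have very unequal depths.

### Consistency evaluation

Predicted subtrees are compared with reference modules through a k×k
contingency table (cell = intersection size; fuzzy genes counted once per
predicted set). Columns are assigned to rows by maximum-weight bipartite
matching (greedy matching available for comparison) so a perfect
prediction is a diagonal table. Three chance-corrected skill scores are
reported: Heidke ((PC−E)/(1−E) with E from both marginals), Peirce (same
numerator, normalized by reference marginals only), and Gerrity (the
standard equitable reward matrix built from the reference marginals'
cumulative distribution). All equal 1 exactly on a positive diagonal;
Heidke and Peirce are invariant under simultaneous row/column
permutation, Gerrity is not (its weights depend on category order through
the cumulative marginals) — an inherent property of the standard formula.

## Synthetic data: what it emulates, and what it does not

The generators produce (a) random taxonomies of exact depth L with
configurable branching, optionally DAG-ified by giving terms extra
parents drawn from strictly shallower terms of the *same* root branch (so
depth, acyclicity, and branch disjointness are preserved); (b) planted
gene modules, one per root branch, each organized around a **core term**
— a deepest-level term of the branch carried by every module gene, plus
unrelated accessory terms from the same branch — mirroring how members of
a real pathway share the pathway's specific annotation; (c) multi-
functional genes carrying a second module's core and belonging to both
reference sets; (d) annotation noise that replaces terms uniformly at
random, applied last.

Defaults: depth 5, branching 2–3, 3 modules × 8 genes, 1–3 terms per
gene, noise 0. At noise 0 the construction guarantees a separation the
recovery analysis relies on: within-module similarities are uniformly
high while any merge across modules is diluted toward
(n−1)/n of the within level (the new root contributes zero specificity),
so within-module merges strictly precede cross-module ones and cutting
at k recovers the planted partition exactly.

What the generator does **not** emulate: the heavy-tailed term-usage
frequencies of real GO corpora, evidence codes, annotation
incompleteness, or correlated noise. Passing the planted-recovery tests
therefore demonstrates the machinery is correct under ideal annotation
structure, not that real KEGG/MIPS-scale results are reproduced; on real
data, within-module annotation dispersion narrows the separation margin
and recovery degrades with noise (which the noise dial makes visible).

## Numerical choices and degenerate inputs

- All orderings are made deterministic: merge candidates sort by
  (descending similarity, lexicographic leaf sets), antichain ties break
  by summed specificity then ID order, generators use one seeded RNG
  stream per call. Identical seeds give byte-identical outputs.
- Similarity band admission uses a 1e-12 tolerance so exact ties at
  α·S_max are admitted regardless of floating-point noise.
- d = 1 is assigned when D = ∞ (no related partner); P = 0/exp(−∞)
  conventions follow the same limit.
- A module with fewer than two leaves has no internal node and HMS is
  rejected rather than defaulted.
- Forest-level HMS (used when a null sample fragments) pools P·σ* over
  all internal nodes of all trees; a forest of singletons scores 0.
- Genes missing from the annotation map either raise or receive {root}
  (configurable); {root} contributes zero specificity, so unannotated
  genes dilute but never inflate coherence.

## Known limitations

- The exact branch-and-bound antichain search is exponential in the
  worst case; it is intended for the small candidate sets produced by
  closure intersections, not for arbitrary thousand-term inputs.
- With α < 1 on data containing many *exactly tied* similarities (e.g.
  several genes annotated with one identical term set), the fuzzy band
  admits every tied pair and the forest can grow combinatorially. Real
  annotation profiles rarely tie exactly; for partition-style analyses
  use α = 1, as the consistency protocol does.
- Monte-Carlo p-values inherit the discreteness of (r+1)/(N+1) and are
  conservative under ties in the statistic.
- Gerrity's score requires every reference category non-empty and k ≥ 2.
- OBO support covers `is_a` (and optionally `part_of`) relations only;
  cross-ontology relations are out of scope.
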