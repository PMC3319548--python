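"""Monte-Carlo significance of HMS scores and theta calibration.

The empirical p-value of an observed module compares its HMS against N
random gene sets of the same size drawn from a background universe, each
scored by the *same* hierarchy builder as the observed module.  The
estimator (r+1)/(N+1) — with r the number of null scores at or above the
observed one — never reports zero and is exactly uniform under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .modules import ModuleError, ModuleTree
from .reconstruct import TafiConfig, forest_hms, tafi_build
from .scoring import ScoringConfig, score_tree
from .taxonomy import Taxonomy

__all__ = [
    "CoherenceReport",
    "monte_carlo_pvalue",
    "calibrate_theta",
    "tafi_scorer",
    "fixed_tree_scorer",
]

logger = logging.getLogger(__name__)

# A hierarchy builder maps (gene tuple, numpy Generator) -> HMS score.
Builder = Callable[[tuple[str, ...], np.random.Generator], float]


@dataclass(frozen=True)
class CoherenceReport:
    """Outcome of a Monte-Carlo coherence test."""

    hms: float
    p_value: float
    n_samples: int
    n_exceed: int
    seed: int

    def __post_init__(self) -> None:
        expected = (self.n_exceed + 1) / (self.n_samples + 1)
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("inconsistent p-value bookkeeping")


def tafi_scorer(
    gene_annotations: Mapping[str, Iterable[str]],
    taxonomy: Taxonomy,
    config: TafiConfig = TafiConfig(),
) -> Builder:
    """Builder that reconstructs each sample's hierarchy with TAFI.

    Scores the resulting forest by pooling P * sigma* over all internal
    nodes, so a sample that fragments (stopping criterion fires early) is
    scored on whatever structure it did form.
    """

    def build(genes: tuple[str, ...], rng: np.random.Generator) -> float:
        result = tafi_build(genes, gene_annotations, taxonomy, config)
        return forest_hms(result, taxonomy, config.scoring)

    return build


def fixed_tree_scorer(
    topology: ModuleTree,
    gene_annotations: Mapping[str, Iterable[str]],
    taxonomy: Taxonomy,
    config: ScoringConfig = ScoringConfig(),
    *,
    missing: str = "root",
) -> Builder:
    """Builder that permutes sampled genes onto a fixed tree topology.

    The null hypothesis keeps the observed tree shape and asks only
    whether the observed leaf labelling is unusually coherent.
    """
    leaf_nodes = sorted(topology.leaf_genes)

    def build(genes: tuple[str, ...], rng: np.random.Generator) -> float:
        if len(genes) != len(leaf_nodes):
            raise ModuleError(
                f"sample size {len(genes)} != topology leaf count {len(leaf_nodes)}"
            )
        order = rng.permutation(len(genes))
        relabelled = ModuleTree(
            root=topology.root,
            children=dict(topology.children),
            leaf_genes={n: genes[order[i]] for i, n in enumerate(leaf_nodes)},
        )
        score, _ = score_tree(relabelled, gene_annotations, taxonomy, config, missing=missing)
        return score

    return build


def monte_carlo_pvalue(
    genes: Iterable[str],
    background: Iterable[str],
    hierarchy_builder: Builder,
    *,
    n_samples: int = 1000,
    seed: int = 0,
    observed_hms: float | None = None,
) -> CoherenceReport:
    """Empirical p-value for the coherence of *genes* against *background*.

    Draws ``n_samples`` uniform subsets of size ``len(genes)`` without
    replacement from the background, scores each with the same builder,
    and returns p = (r+1)/(N+1).  If ``observed_hms`` is given it is used
    as the test statistic; otherwise the builder scores the observed set.
    """
    gene_list = sorted(set(genes))
    bg = sorted(set(background))
    if len(gene_list) < 2:
        raise ModuleError("module must contain at least 2 genes")
    if n_samples < 1:
        raise ModuleError("n_samples must be >= 1")
    if len(bg) < len(gene_list):
        raise ModuleError(
            f"background ({len(bg)} genes) smaller than module ({len(gene_list)})"
        )
    if not set(gene_list) <= set(bg):
        warnings.warn("module contains genes outside the background universe")

    rng = np.random.default_rng(seed)
    if observed_hms is None:
        observed_hms = hierarchy_builder(tuple(gene_list), rng)
    bg_arr = np.array(bg, dtype=object)
    r = 0
    for _ in range(n_samples):
        sample = tuple(rng.choice(bg_arr, size=len(gene_list), replace=False))
        null_score = hierarchy_builder(sample, rng)
        if null_score >= observed_hms - 1e-12:
            r += 1
    return CoherenceReport(
        hms=observed_hms,
        p_value=(r + 1) / (n_samples + 1),
        n_samples=n_samples,
        n_exceed=r,
        seed=seed,
    )


def calibrate_theta(
    validation_modules: Sequence[Iterable[str]],
    background: Iterable[str],
    gene_annotations: Mapping[str, Iterable[str]],
    taxonomy: Taxonomy,
    theta_grid: Sequence[float],
    *,
    alpha_level: float = 0.05,
    coverage_target: float = 0.9,
    n_samples: int = 1000,
    seed: int = 0,
    tafi_config: TafiConfig = TafiConfig(),
) -> float:
    """Largest theta whose significant-module coverage meets the target.

    For each theta in the (ascending) grid, every validation module gets a
    Monte-Carlo p-value under a TAFI rebuild with that theta; coverage is
    the fraction with p <= alpha_level.  Returns the largest qualifying
    theta (larger theta penalizes less, so this is the most permissive
    setting that still recovers the validation set); if none qualifies,
    warns and returns the coverage-maximizing theta.
    """
    if not validation_modules:
        raise ModuleError("empty validation set")
    if not theta_grid:
        raise ModuleError("empty theta grid")
    if not 0 < coverage_target <= 1:
        raise ModuleError(f"coverage target must be in (0, 1], got {coverage_target}")
    grid = sorted(theta_grid)
    coverages: dict[float, float] = {}
    for gi, theta in enumerate(grid):
        cfg = replace(tafi_config, scoring=replace(tafi_config.scoring, theta=theta))
        builder = tafi_scorer(gene_annotations, taxonomy, cfg)
        n_sig = 0
        for mi, module in enumerate(validation_modules):
            sub_seed = (seed * 100003 + gi * 1009 + mi) % (2**31)
            report = monte_carlo_pvalue(
                module, background, builder, n_samples=n_samples, seed=sub_seed
            )
            if report.p_value <= alpha_level:
                n_sig += 1
        coverages[theta] = n_sig / len(validation_modules)
        logger.info("theta=%g: coverage %.3f", theta, coverages[theta])
    qualifying = [t for t in grid if coverages[t] >= coverage_target]
    if qualifying:
        return max(qualifying)
    best_cov = max(coverages.values())
    fallback = max(t for t in grid if coverages[t] == best_cov)
    warnings.warn(
        f"no theta reaches coverage {coverage_target:.2f}; "
        f"returning theta={fallback} with coverage {best_cov:.2f}"
    )
    return fallback
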