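import warnings

import numpy as np
import pytest

import tafi.significance as sig
from tafi import (
    CoherenceReport,
    ModuleError,
    ModuleTree,
    ScoringConfig,
    TafiConfig,
    calibrate_theta,
    fixed_tree_scorer,
    monte_carlo_pvalue,
    tafi_scorer,
)
from tafi.simulate import (
    GeneratorSpec,
    generate_background,
    generate_planted_modules,
    generate_taxonomy,
)


@pytest.fixture(scope="module")
def planted_world():
    spec = GeneratorSpec(seed=11)
    tax = generate_taxonomy(spec)
    ann, ref = generate_planted_modules(spec, tax)
    bg_ann = generate_background(spec, tax, 40)
    all_ann = {**ann, **bg_ann}
    return spec, tax, all_ann, ref, sorted(all_ann)


class TestCoherenceReport:
    def test_estimator_bookkeeping_enforced(self):
        with pytest.raises(ValueError):
            CoherenceReport(hms=0.5, p_value=0.1, n_samples=10, n_exceed=5, seed=0)
        rep = CoherenceReport(hms=0.5, p_value=6 / 11, n_samples=10, n_exceed=5, seed=0)
        assert 0 < rep.p_value <= 1


class TestMonteCarloPvalue:
    def test_observed_above_all_nulls_gives_minimum_p(self):
        builder = lambda genes, rng: 0.0
        rep = monte_carlo_pvalue(
            ["a", "b"], ["a", "b", "c", "d"], builder, n_samples=9, seed=1,
            observed_hms=1.0,
        )
        assert rep.p_value == pytest.approx(1 / 10)
        assert rep.n_exceed == 0

    def test_observed_below_all_nulls_gives_p_one(self):
        builder = lambda genes, rng: 1.0
        rep = monte_carlo_pvalue(
            ["a", "b"], ["a", "b", "c", "d"], builder, n_samples=9, seed=1,
            observed_hms=0.0,
        )
        assert rep.p_value == 1.0

    def test_background_smaller_than_module_rejected(self):
        with pytest.raises(ModuleError, match="background"):
            monte_carlo_pvalue(["a", "b", "c"], ["a", "b"], lambda g, r: 0.0)

    def test_zero_samples_rejected(self):
        with pytest.raises(ModuleError):
            monte_carlo_pvalue(["a", "b"], ["a", "b", "c"], lambda g, r: 0.0, n_samples=0)

    def test_module_outside_background_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            monte_carlo_pvalue(
                ["a", "x"], ["a", "b", "c"], lambda g, r: 0.0,
                n_samples=5, observed_hms=1.0,
            )

    def test_planted_module_significant_and_reproducible(self, planted_world):
        spec, tax, ann, ref, background = planted_world
        builder = tafi_scorer(ann, tax, TafiConfig(alpha=1.0, beta=0.0))
        reps = [
            monte_carlo_pvalue(ref[0], background, builder, n_samples=99, seed=21)
            for _ in range(2)
        ]
        assert reps[0].p_value <= 0.05
        assert reps[0] == reps[1]  # identical seed + inputs => identical report

    def test_p_monotone_nonincreasing_in_observed_statistic(self):
        # frozen null sample set, replayed identically for every observed value
        frozen = [0.3, 0.6, 0.1, 0.9, 0.5, 0.2, 0.8, 0.4, 0.7]

        def make_builder():
            it = iter(frozen)
            return lambda genes, rng: next(it)

        ps = []
        for observed in (0.0, 0.25, 0.45, 0.65, 0.95):
            rep = monte_carlo_pvalue(
                ["a", "b"], ["a", "b", "c", "d"], make_builder(),
                n_samples=len(frozen), seed=3, observed_hms=observed,
            )
            ps.append(rep.p_value)
        assert ps == sorted(ps, reverse=True)


class TestFixedTreeScorer:
    def test_size_mismatch_rejected(self, fork_taxonomy):
        topo = ModuleTree.join([ModuleTree.leaf("x"), ModuleTree.leaf("y")])
        builder = fixed_tree_scorer(topo, {"a": {"a1"}}, fork_taxonomy)
        with pytest.raises(ModuleError):
            builder(("a", "b", "c"), np.random.default_rng(0))

    def test_scores_permuted_labels_on_same_topology(self, fork_taxonomy):
        topo = ModuleTree.join([ModuleTree.leaf("x"), ModuleTree.leaf("y")])
        ann = {"a": {"a1"}, "b": {"a1"}}
        builder = fixed_tree_scorer(topo, ann, fork_taxonomy)
        assert builder(("a", "b"), np.random.default_rng(0)) == 1.0


class TestNullCalibration:
    def test_null_pvalues_approximately_uniform(self):
        """Module drawn from the background itself: p should be ~Uniform(0,1].

        The background universe is annotated within a single taxonomy
        branch so the null statistic has a near-continuous distribution
        (genes from disjoint branches would pile scores up at exactly 0).
        """
        from scipy.stats import kstest

        spec = GeneratorSpec(seed=11)
        tax = generate_taxonomy(spec)
        branch = sorted(tax.graph.successors(tax.root))[0]
        bg_ann = generate_background(spec, tax, 60, branch=branch)
        background = sorted(bg_ann)
        topo = ModuleTree.leaf("x0")
        for i in range(1, 6):
            topo = ModuleTree.join([topo, ModuleTree.leaf(f"x{i}")])
        builder = fixed_tree_scorer(topo, bg_ann, tax)
        master = np.random.default_rng(77)
        pvals = []
        for _ in range(100):
            genes = tuple(master.choice(background, size=6, replace=False))
            rep = monte_carlo_pvalue(
                genes, background, builder, n_samples=49,
                seed=int(master.integers(2**31)),
            )
            pvals.append(rep.p_value)
        stat, p = kstest(pvals, "uniform")
        assert p > 0.01


class TestCalibrateTheta:
    def test_all_significant_returns_largest_theta(self, planted_world, monkeypatch):
        spec, tax, ann, ref, background = planted_world

        def always_small(genes, background, builder, *, n_samples=0, seed=0, observed_hms=None):
            return CoherenceReport(
                hms=1.0, p_value=1 / (n_samples + 1), n_samples=n_samples,
                n_exceed=0, seed=seed,
            )

        monkeypatch.setattr(sig, "monte_carlo_pvalue", always_small)
        theta = calibrate_theta(
            ref, background, ann, tax, [1, 5, 10, 50], n_samples=99, seed=0
        )
        assert theta == 50

    def test_none_significant_warns_and_returns_argmax(self, planted_world, monkeypatch):
        spec, tax, ann, ref, background = planted_world

        def never_small(genes, background, builder, *, n_samples=0, seed=0, observed_hms=None):
            return CoherenceReport(
                hms=0.0, p_value=1.0, n_samples=n_samples, n_exceed=n_samples,
                seed=seed,
            )

        monkeypatch.setattr(sig, "monte_carlo_pvalue", never_small)
        with pytest.warns(UserWarning, match="coverage"):
            theta = calibrate_theta(
                ref, background, ann, tax, [1, 10], n_samples=9, seed=0
            )
        assert theta == 10

    def test_coverage_crossing_selects_last_qualifying_theta(self, planted_world, monkeypatch):
        spec, tax, ann, ref, background = planted_world
        # significant for theta <= 10 only: coverage crosses between 10 and 50
        def threshold_fake(genes, background, builder, *, n_samples=0, seed=0, observed_hms=None):
            theta = threshold_fake.current_theta
            p = 1 / (n_samples + 1) if theta <= 10 else 1.0
            r = 0 if theta <= 10 else n_samples
            return CoherenceReport(
                hms=0.0, p_value=p, n_samples=n_samples, n_exceed=r, seed=seed
            )

        real_scorer = sig.tafi_scorer

        def spy_scorer(annotations, taxonomy, config):
            threshold_fake.current_theta = config.scoring.theta
            return real_scorer(annotations, taxonomy, config)

        monkeypatch.setattr(sig, "monte_carlo_pvalue", threshold_fake)
        monkeypatch.setattr(sig, "tafi_scorer", spy_scorer)
        theta = calibrate_theta(
            ref, background, ann, tax, [1, 5, 10, 50, 100], n_samples=99, seed=0
        )
        assert theta == 10

    def test_empty_validation_set_rejected(self, planted_world):
        spec, tax, ann, ref, background = planted_world
        with pytest.raises(ModuleError):
            calibrate_theta([], background, ann, tax, [1.0])
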