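"""TPE proposals, optimization loop, baselines and diagnostics.

Synthetic (simulation-free) objectives with known minima serve as oracles so
optimizer behavior is checked independently of the pathway models.
"""

import numpy as np
import pytest

from circuitbo import (
    ArchitectureSpec,
    ConfigurationError,
    OptimizerConfig,
    SearchSpace,
    Trial,
    TrialHistory,
    baseline_optimize,
    bayesopt_minimize,
    exploration_stats,
    landscape_grid,
    tpe_propose,
)

ARCH_A = ArchitectureSpec("categorical", categorical_label="A", name="A")
ARCH_B = ArchitectureSpec("categorical", categorical_label="B", name="B")


def quadratic_space(n_dims=1, archs=(ARCH_A,)):
    return SearchSpace(bounds=((0.0, 10.0),) * n_dims, architectures=tuple(archs))


def quadratic(arch, x, minimum=3.7):
    return float(np.sum((np.asarray(x) - minimum) ** 2))


class TestSearchSpace:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(bounds=((1.0, 0.0),), architectures=(ARCH_A,))
        with pytest.raises(ConfigurationError):
            SearchSpace(bounds=((0.0, np.inf),), architectures=(ARCH_A,))

    def test_empty_architectures_rejected(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(bounds=((0.0, 1.0),), architectures=())

    def test_from_model_matches_enumeration(self, toy_model):
        space = SearchSpace.from_model(toy_model)
        assert len(space.architectures) == 4
        assert space.n_continuous == 4

    def test_prior_samples_within_bounds(self):
        space = quadratic_space(3, (ARCH_A, ARCH_B))
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, x = space.sample_prior(rng)
            assert 0 <= a < 2
            assert np.all(x >= space.lo) and np.all(x <= space.hi)


class TestTpePropose:
    def test_empty_history_draws_from_prior(self):
        space = quadratic_space()
        a, x = tpe_propose(TrialHistory(), space, OptimizerConfig(), np.random.default_rng(1))
        assert a == 0 and 0 <= x[0] <= 10

    def test_degenerate_history_falls_back_to_prior(self):
        space = quadratic_space()
        hist = TrialHistory()
        for i in range(50):
            hist.append(Trial(i, 0, "A", np.array([5.0]), 1.0))
        a, x = tpe_propose(hist, space, OptimizerConfig(), np.random.default_rng(2))
        assert 0 <= x[0] <= 10

    def test_proposals_respect_bounds_and_architectures(self):
        # fuzz: proposals always feasible at any history size
        space = quadratic_space(2, (ARCH_A, ARCH_B))
        rng = np.random.default_rng(3)
        hist = TrialHistory()
        cfg = OptimizerConfig(n_startup=5)
        for i in range(120):
            a, x = tpe_propose(hist, space, cfg, rng)
            assert a in (0, 1)
            assert np.all(x >= space.lo - 1e-12) and np.all(x <= space.hi + 1e-12)
            hist.append(Trial(i, a, "AB"[a], x, quadratic(None, x) + 0.01 * a))

    def test_finds_quadratic_minimum_across_seeds(self):
        # 1-D convex loss: best found within 5% of the span in >= 18/20 seeds
        space = quadratic_space()
        hits = 0
        for seed in range(20):
            hist = bayesopt_minimize(
                quadratic, space, OptimizerConfig(n_iterations=100, seed=seed)
            )
            if abs(hist.best_trial().p_c[0] - 3.7) <= 0.5:
                hits += 1
        assert hits >= 18

    def test_categorical_reweighting_favors_better_architecture(self):
        # arch A always loss 0.0(+noise-free continuous), B always 1.0
        space = quadratic_space(1, (ARCH_A, ARCH_B))

        def objective(arch, x):
            return 0.0 if arch.name == "A" else 1.0

        late_fracs = []
        for seed in range(5):
            hist = bayesopt_minimize(
                objective, space, OptimizerConfig(n_iterations=120, seed=seed)
            )
            names = [t.arch_name for t in hist.trials]
            early = names[:40].count("A") / 40
            late = names[-40:].count("A") / 40
            late_fracs.append(late - early)
        assert np.mean(late_fracs) > 0.2


class TestBayesoptLoop:
    def test_best_trace_monotone_and_seeded_determinism(self, toy_model):
        from circuitbo import default_objective_spec, make_objective

        obj = make_objective(toy_model, default_objective_spec(toy_model))
        space = SearchSpace.from_model(toy_model)
        cfg = OptimizerConfig(n_iterations=40, seed=7)
        h1 = bayesopt_minimize(obj, space, cfg)
        h2 = bayesopt_minimize(obj, space, cfg)
        trace = h1.best_trace()
        assert np.all(np.diff(trace) <= 0)
        assert np.array_equal(h1.losses, h2.losses)
        assert all(
            np.array_equal(a.p_c, b.p_c) and a.arch_index == b.arch_index
            for a, b in zip(h1.trials, h2.trials)
        )

    def test_constant_objective_explores_uniformly(self):
        space = quadratic_space(1, (ARCH_A, ARCH_B))
        hist = bayesopt_minimize(
            lambda arch, x: 1.0, space, OptimizerConfig(n_iterations=400, seed=0)
        )
        assert np.ptp(hist.best_trace()) == 0.0
        fracs = hist.architecture_fractions()
        assert abs(fracs["A"] - 0.5) < 0.15

    def test_exploration_persists_on_glucaric_model(self, glucaric_model):
        # non-majority architectures keep being sampled in every run quarter
        from circuitbo import default_objective_spec, make_objective

        obj = make_objective(glucaric_model, default_objective_spec(glucaric_model))
        space = SearchSpace.from_model(glucaric_model)
        hist = bayesopt_minimize(obj, space, OptimizerConfig(n_iterations=200, seed=0))
        stats = exploration_stats(hist, 4)
        for b in range(4):
            sub = stats[stats["bin"] == b]
            majority = sub["fraction"].max()
            assert majority < 1.0  # non-majority fraction stays above zero


class TestBaselines:
    def test_random_search_within_bounds_and_reproducible(self):
        space = quadratic_space(2, (ARCH_A, ARCH_B))
        h1 = baseline_optimize("random", quadratic, space, {"n": 50, "seed": 1})
        h2 = baseline_optimize("random", quadratic, space, {"n": 50, "seed": 1})
        assert len(h1) == 50
        assert np.array_equal(h1.losses, h2.losses)

    def test_grid_hits_separable_quadratic_minimum(self):
        space = quadratic_space(2)
        hist = baseline_optimize("grid", quadratic, space, {"n": 121})
        best = hist.best_trial()
        axis = np.linspace(0, 10, 11)
        nearest = axis[np.argmin(np.abs(axis - 3.7))]
        assert np.allclose(best.p_c, nearest)

    def test_grid_warns_on_nonfactorizable_budget(self):
        space = quadratic_space(2)
        with pytest.warns(UserWarning):
            baseline_optimize("grid", quadratic, space, {"n": 120})

    def test_ga_elitism_keeps_best_fitness_monotone(self):
        space = quadratic_space(3, (ARCH_A, ARCH_B))
        hist = baseline_optimize(
            "ga", quadratic, space,
            {"population": 12, "generations": 10, "seed": 2},
        )
        per_gen_best = hist.losses.reshape(10, 12).min(axis=1)
        running = np.minimum.accumulate(per_gen_best)
        assert np.all(per_gen_best == running)

    def test_gradient_finds_smooth_minimum_and_reports_failures(self):
        space = quadratic_space(2)
        hist = baseline_optimize("gradient", quadratic, space, {"n_starts": 2, "seed": 0})
        assert hist.best_trial().loss < 1e-6
        assert "convergence_failures" in hist.meta

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            baseline_optimize("annealing", quadratic, quadratic_space(), {})


class TestDiagnostics:
    def test_landscape_constant_objective(self):
        space = quadratic_space(2)
        xs, ys, Z = landscape_grid(lambda a, x: 2.5, ARCH_A, (0, 1), 5, space)
        assert Z.shape == (5, 5)
        assert np.all(Z == 2.5)

    def test_landscape_minimum_beats_random_interior_points(self):
        space = quadratic_space(2)
        xs, ys, Z = landscape_grid(quadratic, ARCH_A, (0, 1), 30, space)
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(space.lo, space.hi)
            # compare against the grid-restricted objective at fixed dims
            assert Z.min() <= quadratic(ARCH_A, p) + 0.25

    def test_landscape_reproducible(self):
        space = quadratic_space(2)
        a = landscape_grid(quadratic, ARCH_A, (0, 1), 7, space)[2]
        b = landscape_grid(quadratic, ARCH_A, (0, 1), 7, space)[2]
        assert np.array_equal(a, b)

    def test_landscape_needs_two_dims(self):
        with pytest.raises(ConfigurationError):
            landscape_grid(quadratic, ARCH_A, (0, 1, 2), 5, quadratic_space(3))

    def test_exploration_stats_partition_and_sums(self):
        hist = TrialHistory()
        rng = np.random.default_rng(0)
        names = ["A", "B", "C", "D"]
        for i in range(103):
            a = int(rng.integers(4))
            hist.append(Trial(i, a, names[a], np.array([0.0]), 1.0))
        stats = exploration_stats(hist, 4)
        sizes = []
        for b in range(4):
            sub = stats[stats["bin"] == b]
            assert sub["fraction"].sum() == pytest.approx(1.0)
        # bins partition trials with sizes differing by <= 1
        chunks = np.array_split(np.arange(103), 4)
        assert max(len(c) for c in chunks) - min(len(c) for c in chunks) <= 1

    def test_exploration_stats_single_architecture(self):
        hist = TrialHistory()
        for i in range(10):
            hist.append(Trial(i, 0, "A", np.array([0.0]), 1.0))
        stats = exploration_stats(hist, 2)
        assert np.all(stats["fraction"] == 1.0)

    def test_exploration_more_bins_than_trials_rejected(self):
        hist = TrialHistory()
        hist.append(Trial(0, 0, "A", np.array([0.0]), 1.0))
        with pytest.raises(ConfigurationError):
            exploration_stats(hist, 2)


class TestTrialHistory:
    def test_nonfinite_loss_rejected(self):
        with pytest.raises(ConfigurationError):
            Trial(0, 0, "A", np.array([0.0]), np.nan)

    def test_argmin_tie_first_encountered(self):
        hist = TrialHistory()
        hist.append(Trial(0, 0, "A", np.array([1.0]), 5.0))
        hist.append(Trial(1, 1, "B", np.array([2.0]), 5.0))
        assert hist.best_trial().index == 0

    def test_dict_round_trip(self):
        hist = TrialHistory(meta={"seed": 4})
        hist.append(Trial(0, 0, "A", np.array([1.0, 2.0]), 0.5))
        again = TrialHistory.from_dict(hist.to_dict())
        assert again.meta["seed"] == 4
        assert np.array_equal(again.trials[0].p_c, hist.trials[0].p_c)
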