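"""Greedy initializer and genetic algorithm for the balance factors."""

import numpy as np
import pytest

from nucfuse.balance_search import (
    SearchConfig,
    SearchResult,
    ga_optimize,
    greedy_init,
    make_cv_fitness,
    optimize_balance,
    select_final_R,
)
from nucfuse.classify import BalancedFusionKNN
from nucfuse.evaluate import stratified_kfold
from nucfuse.fusion import BalanceVector
from nucfuse.synthetic import SyntheticSpec, generate
from nucfuse.encoders import encode_all


def quadratic_fitness(R):
    """Separable synthetic fitness with analytic minimum at (0.8, 0.3)."""
    return (R[0] - 0.8) ** 2 + (R[1] - 0.3) ** 2


class TestGreedyInit:
    def test_emits_exactly_the_configured_number_of_vectors(self):
        cfg = SearchConfig(init_restarts=7, seed=0)
        pop = greedy_init(quadratic_fitness, n=2, config=cfg)
        assert len(pop) == 7
        assert all(isinstance(bv, BalanceVector) for bv in pop)
        assert all(bv.provenance == "greedy-init" for bv in pop)

    def test_default_restart_count_is_fifty(self):
        assert SearchConfig().init_restarts == 50

    def test_lands_within_one_grid_step_of_separable_optimum(self):
        cfg = SearchConfig(init_restarts=5, seed=1)
        for bv in greedy_init(quadratic_fitness, n=2, config=cfg):
            assert abs(bv.r[0] - 0.8) <= 0.01 + 1e-6
            assert abs(bv.r[1] - 0.3) <= 0.01 + 1e-6

    def test_scan_starts_from_half_everywhere(self):
        seen = []

        def recording(R):
            seen.append(R.copy())
            return quadratic_fitness(R)

        greedy_init(recording, n=3, config=SearchConfig(init_restarts=1, seed=2))
        # first call: one coordinate is on the grid, the others still 0.5
        assert np.sum(seen[0] == 0.5) == 2

    def test_grid_endpoints_clamped_into_open_interval(self):
        cfg = SearchConfig(init_restarts=1, seed=0)
        # minimum at r=0 is clamped, never emitted as exactly 0
        (bv,) = greedy_init(lambda R: float(np.sum(R**2)), n=2, config=cfg)
        assert np.all(bv.r > 0) and np.all(bv.r < 1)
        assert np.all(bv.r <= 1e-6 + 1e-12)

    def test_deterministic_given_seed(self):
        cfg = SearchConfig(init_restarts=3, seed=5)
        a = greedy_init(quadratic_fitness, n=2, config=cfg)
        b = greedy_init(quadratic_fitness, n=2, config=cfg)
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x.r, z.r)


class TestGA:
    def _population(self, n=2, size=6, seed=0):
        rng = np.random.default_rng(seed)
        return [BalanceVector(r=rng.uniform(0.1, 0.9, n)) for _ in range(size)]

    def test_no_variation_keeps_best_constant(self):
        pop = [BalanceVector(r=np.array([0.4, 0.6]))] * 5
        cfg = SearchConfig(mutation_rate=0.0, crossover_rate=0.0, generations=10, seed=0)
        res = ga_optimize(pop, quadratic_fitness, cfg)
        bests = [h[1] for h in res.history]
        assert len(set(bests)) == 1

    def test_best_so_far_is_monotone_non_increasing(self):
        cfg = SearchConfig(generations=30, seed=3)
        res = ga_optimize(self._population(), quadratic_fitness, cfg)
        bests = [h[1] for h in res.history]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(bests, bests[1:]))

    def test_converges_near_separable_optimum_across_seeds(self):
        hits = 0
        for seed in range(20):
            cfg = SearchConfig(generations=30, population_size=20, seed=seed)
            res = ga_optimize(self._population(seed=seed, size=20),
                              quadratic_fitness, cfg)
            if np.all(np.abs(res.best_R.r - [0.8, 0.3]) <= 0.02):
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeded runs

    def test_final_best_never_worse_than_initial_best(self):
        pop = self._population(size=10, seed=7)
        init_best = min(quadratic_fitness(bv.r) for bv in pop)
        cfg = SearchConfig(generations=15, seed=7)
        res = ga_optimize(pop, quadratic_fitness, cfg)
        assert res.best_fitness <= init_best + 1e-15

    def test_offspring_respect_open_interval(self):
        cfg = SearchConfig(generations=20, mutation_rate=1.0, mutation_sd=0.5, seed=1)
        res = ga_optimize(self._population(), quadratic_fitness, cfg)
        assert np.all(res.best_R.r > 0) and np.all(res.best_R.r < 1)

    def test_deterministic_given_seed(self):
        cfg = SearchConfig(generations=10, seed=11)
        a = ga_optimize(self._population(seed=2), quadratic_fitness, cfg)
        b = ga_optimize(self._population(seed=2), quadratic_fitness, cfg)
        np.testing.assert_array_equal(a.best_R.r, b.best_R.r)
        assert a.history == b.history

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ga_optimize([], quadratic_fitness, SearchConfig())


class TestSelectFinalR:
    def _result(self, fitness, r, evals=10):
        return SearchResult(
            best_R=BalanceVector(r=np.asarray(r)), best_fitness=fitness,
            evaluations=evals,
        )

    def test_minimum_fitness_wins(self):
        results = [
            self._result(0.3, [0.5, 0.5]),
            self._result(0.2, [0.6, 0.4]),
            self._result(0.25, [0.7, 0.3]),
        ]
        np.testing.assert_array_equal(select_final_R(results).r, [0.6, 0.4])

    def test_single_result_returned_as_is(self):
        res = self._result(0.4, [0.2, 0.8])
        assert select_final_R([res]) is res.best_R

    def test_ties_break_by_evaluations_then_lexicographic(self):
        a = self._result(0.2, [0.6, 0.1], evals=5)
        b = self._result(0.2, [0.3, 0.9], evals=5)
        c = self._result(0.2, [0.1, 0.1], evals=9)
        np.testing.assert_array_equal(select_final_R([a, b, c]).r, [0.3, 0.9])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_final_R([])


class TestCVFitness:
    def _blocks(self, seed=0):
        ds = generate(SyntheticSpec(n_classes=3, per_class=6, seed=seed))
        ids = ds.ids()
        A = np.vstack([encode_all(ds, "dipc")[i] for i in ids])
        B = np.vstack([encode_all(ds, "pssm")[i] for i in ids])
        return A, B, ds.y()

    def test_gram_fast_path_matches_explicit_classifier(self):
        # the closed-form fused cosine must agree with literally fusing
        # and classifying fold by fold
        A, B, y = self._blocks()
        R = np.array([0.7, 0.4, 0.2])
        fitness = make_cv_fitness(A, B, y, K=3, k=1, seed=5)
        folds = stratified_kfold(y, K=3, repeats=1, seed=5)[0]
        X = np.hstack([A, B])
        correct = 0
        for test_idx in folds:
            mask = np.ones(y.size, dtype=bool)
            mask[test_idx] = False
            model = BalancedFusionKNN(split=A.shape[1], R=R, k=1)
            model.fit(X[mask], y[mask])
            correct += int(np.sum(model.predict(X[test_idx]) == y[test_idx]))
        assert fitness(R) == pytest.approx(1.0 - correct / y.size, abs=1e-12)

    def test_fitness_is_deterministic_in_r(self):
        A, B, y = self._blocks()
        fitness = make_cv_fitness(A, B, y, K=3, k=1, seed=0)
        R = np.array([0.5, 0.5, 0.5])
        assert fitness(R) == fitness(R.copy())

    def test_true_label_mode_differs_and_stays_bounded(self):
        A, B, y = self._blocks()
        fit_tl = make_cv_fitness(A, B, y, K=3, k=1, seed=0, mode="true-label")
        for R in (np.array([0.5] * 3), np.array([0.9, 0.1, 0.5])):
            assert 0.0 <= fit_tl(R) <= 1.0


class TestRecoveryDirection:
    def test_composition_classes_get_larger_factors_than_pssm_classes(self):
        """Directional balance-factor recovery on an identifiable design.

        Four classes: two carry all their signal in residue composition
        (and share the background PSSM), two carry it all in the PSSM
        column profile (and share near-uniform composition).  The
        optimized factors should weight the composition block more for
        the composition classes than for the PSSM classes.
        """
        wins = 0
        for seed in range(3):
            ds = generate(
                SyntheticSpec(
                    n_classes=4,
                    per_class=12,
                    composition_concentration=0.4,
                    pssm_profile_shift=2.0,
                    pssm_noise_sd=1.5,
                    signal_split=(1.0, 1.0, 0.0, 0.0),
                    seed=seed,
                )
            )
            ids = ds.ids()
            A = np.vstack([encode_all(ds, "dipc")[i] for i in ids])
            B = np.vstack([encode_all(ds, "pssm")[i] for i in ids])
            for M in (A, B):
                sd = M.std(axis=0)
                sd[sd == 0] = 1.0
                M -= M.mean(axis=0)
                M /= sd
            fitness = make_cv_fitness(
                A, B, ds.y(), K=3, k=1, seed=seed, mode="true-label"
            )
            cfg = SearchConfig(init_restarts=4, generations=25, seed=seed)
            res = optimize_balance(fitness, 4, cfg)
            comp = res.best_R.r[:2].mean()
            pssm = res.best_R.r[2:].mean()
            if comp > pssm:
                wins += 1
        assert wins >= 2


def test_optimize_balance_not_worse_than_greedy_alone():
    cfg = SearchConfig(init_restarts=4, generations=10, seed=3)
    greedy_best = min(
        quadratic_fitness(bv.r)
        for bv in greedy_init(quadratic_fitness, n=2, config=cfg)
    )
    res = optimize_balance(quadratic_fitness, n=2, config=cfg)
    assert res.best_fitness <= greedy_best + 1e-15
    assert res.best_R.provenance == "ga-optimized"
    assert res.evaluations > 0
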