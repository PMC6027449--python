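import numpy as np
import pytest

from rfe_variants.rfe import (ClassifierConfig, _rank, run_rfe, train_and_rank,
                              evaluate_subset)
from .conftest import make_table


def label_plus_noise_table(seed, n=200, n_noise=2):
    """Feature A equals the label (+/-1); remaining features are pure noise."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2 == 0
    cols = [np.where(labels, 1.0, -1.0)]
    cols += [rng.standard_normal(n) for _ in range(n_noise)]
    names = ["A"] + [chr(ord("B") + j) for j in range(n_noise)]
    return make_table(np.column_stack(cols), labels, names=names)


class TestTrainAndRank:
    def test_label_copy_feature_ranked_first(self):
        wins = sum(
            train_and_rank(label_plus_noise_table(seed),
                           ClassifierConfig(n_trees=30, seed=seed)
                           ).feature_names[0] == "A"
            for seed in range(20))
        assert wins >= 19

    def test_single_feature_ranking(self):
        table = label_plus_noise_table(0, n=40, n_noise=0)
        ranking = train_and_rank(table, ClassifierConfig(n_trees=10, seed=0))
        assert ranking.feature_names == ("A",)

    def test_every_feature_appears_once(self):
        table = label_plus_noise_table(3, n=60, n_noise=4)
        ranking = train_and_rank(table, ClassifierConfig(n_trees=10, seed=1))
        assert sorted(ranking.feature_names) == sorted(table.feature_names)

    def test_exact_score_ties_break_lexicographically(self):
        ranking = _rank(["b", "a", "c"], np.array([0.5, 0.5, 0.9]))
        assert ranking.feature_names == ("c", "a", "b")

    def test_single_class_rejected(self):
        table = make_table([[1.0], [2.0]], [True, True])
        with pytest.raises(ValueError, match="single class"):
            train_and_rank(table, ClassifierConfig(n_trees=5))

    def test_bootstrap_reconstruction_matches_sklearn(self):
        # the OOB bookkeeping regenerates each tree's bootstrap draw; pin it
        # against the library's own private generator
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.ensemble._forest import _generate_sample_indices
        table = label_plus_noise_table(5, n=50)
        forest = RandomForestClassifier(n_estimators=8, random_state=9)
        forest.fit(table.values, table.labels)
        for tree in forest.estimators_:
            mine = np.random.RandomState(tree.random_state).randint(0, 50, 50)
            theirs = _generate_sample_indices(tree.random_state, 50, 50, None)
            assert np.array_equal(mine, theirs)


class TestEvaluateSubset:
    def test_resubstitution_on_separable_data(self, separable_table):
        report = evaluate_subset(separable_table, separable_table,
                                 ["signal", "noise_a", "noise_b"],
                                 ClassifierConfig(n_trees=30, seed=0))
        assert report.balanced_accuracy >= 95.0

    def test_noise_only_subset_is_chance_level(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.arange(80) % 2 == 0
            table = make_table(rng.standard_normal((80, 1)), labels)
            train, test = table.take(range(40)), table.take(range(40, 80))
            report = evaluate_subset(train, test, ["f0"],
                                     ClassifierConfig(n_trees=20, seed=seed))
            accs.append(report.balanced_accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_unknown_feature_rejected(self, separable_table):
        with pytest.raises(KeyError, match="ghost"):
            evaluate_subset(separable_table, separable_table, ["ghost"],
                            ClassifierConfig(n_trees=5))

    def test_empty_subset_rejected(self, separable_table):
        with pytest.raises(ValueError):
            evaluate_subset(separable_table, separable_table, [],
                            ClassifierConfig(n_trees=5))


@pytest.fixture(scope="module")
def split_tables():
    table = label_plus_noise_table(7, n=120, n_noise=4)
    return table.take(range(80)), table.take(range(80, 120))


class TestRunRfe:

    def test_step1_sizes_count_down_to_one(self, split_tables):
        train, ev = split_tables
        trace = run_rfe(train, ev, ClassifierConfig(n_trees=10, seed=0))
        assert trace.subset_sizes == (5, 4, 3, 2, 1)

    @pytest.mark.parametrize("step,expected", [
        (2, (5, 3, 1)),
        (3, (5, 2, 1)),
    ])
    def test_larger_steps_never_overshoot(self, split_tables, step, expected):
        train, ev = split_tables
        trace = run_rfe(train, ev, ClassifierConfig(n_trees=10, seed=0),
                        step=step)
        assert trace.subset_sizes == expected

    def test_subsets_strictly_nested(self, split_tables):
        train, ev = split_tables
        trace = run_rfe(train, ev, ClassifierConfig(n_trees=10, seed=1))
        for prev, cur in zip(trace, trace.steps[1:]):
            assert set(cur.subset) < set(prev.subset)

    def test_trace_induces_total_ranking(self, split_tables):
        train, ev = split_tables
        trace = run_rfe(train, ev, ClassifierConfig(n_trees=10, seed=2))
        assert sorted(trace.elimination_order()) == sorted(train.feature_names)

    def test_identical_seed_gives_identical_trace(self, split_tables):
        train, ev = split_tables
        cfg = ClassifierConfig(n_trees=10, seed=3)
        first = run_rfe(train, ev, cfg)
        second = run_rfe(train, ev, cfg)
        assert first == second

    def test_dropped_feature_matches_independent_ranking(self, split_tables):
        """At each step, the dropped feature is the argmin of a fresh
        importance call on the same subset, order, and derived seed."""
        train, ev = split_tables
        train4 = train.restrict(["A", "B", "C", "D"])
        ev4 = ev.restrict(["A", "B", "C", "D"])
        cfg = ClassifierConfig(n_trees=10, seed=4)
        trace = run_rfe(train4, ev4, cfg)
        current = list(train4.feature_names)
        for k, step in enumerate(trace.steps[:-1]):
            oracle = train_and_rank(train4.restrict(current),
                                    cfg.for_iteration(k))
            assert step.dropped == (oracle.feature_names[-1],)
            current = [f for f in step.subset if f != step.dropped[0]]

    def test_informative_features_survive_to_the_end(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 120
            labels = np.arange(n) % 2 == 0
            signal = np.where(labels, 0.75, -0.75)[:, None]
            values = np.column_stack([
                signal + rng.standard_normal((n, 3)) * 0.5,
                rng.standard_normal((n, 17)),
            ])
            names = [f"inf{j}" for j in range(3)] + [f"nz{j}" for j in range(17)]
            table = make_table(values, labels, names=names)
            train, ev = table.take(range(80)), table.take(range(80, 120))
            trace = run_rfe(train, ev, ClassifierConfig(n_trees=25, seed=seed))
            last3 = next(s.subset for s in trace if len(s.subset) == 3)
            if sum(f.startswith("inf") for f in last3) >= 2:
                hits += 1
        assert hits >= 18

    def test_trace_serializes_to_records(self, split_tables):
        train, ev = split_tables
        trace = run_rfe(train, ev, ClassifierConfig(n_trees=10, seed=5))
        records = trace.to_records()
        assert [r["subset_size"] for r in records] == [5, 4, 3, 2, 1]
        assert all(set(r) == {"subset_size", "features", "balanced_accuracy",
                              "dropped_feature"} for r in records)
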