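"""Random-forest training, out-of-bag permutation importance, and the
recursive elimination loop.

The elimination loop is the classic wrapper procedure: train a random forest
on the current feature subset, rank features by permutation importance, record
the subset's held-out balanced accuracy, drop the least important feature(s),
and repeat down to a single feature.  The full trace of (subset, accuracy)
pairs is returned; decision variants consume it downstream.

Importance is the mean decrease in out-of-bag accuracy: for each tree, the
samples left out of its bootstrap draw are scored once as-is and once with a
feature's values permuted among them; the drop in accuracy, averaged over
trees, is that feature's score.  scikit-learn grows the forest; the OOB
bookkeeping (bootstrap-draw reconstruction and permutation scoring) lives
here, since the library exposes no out-of-bag permutation importance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._utils import derive_seed
from .metrics import MetricsReport, compute_metrics
from .preprocess import FeatureTable

# cap on the scratch block built per tree when scoring permuted features
_MAX_BLOCK_BYTES = 64 * 2**20


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest hyperparameters.

    Defaults follow the R ``randomForest`` conventions for classification:
    500 trees and sqrt(p) candidate features per split.  ``metric`` selects
    the accuracy recorded along the elimination trace; balanced accuracy is
    the default because class-imbalanced data is the motivating use case.
    """

    n_trees: int = 500
    max_features: int | str = "sqrt"
    seed: int = 0
    metric: str = "balanced"  # or "plain"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.metric not in ("balanced", "plain"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def for_iteration(self, iteration: int) -> "ClassifierConfig":
        """Config with a per-iteration derived seed (used by the RFE loop)."""
        return replace(self, seed=derive_seed(self.seed, iteration))


@dataclass(frozen=True)
class ImportanceRanking:
    """Features sorted by descending importance; ties broken by name."""

    entries: tuple[tuple[str, float], ...]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(score for _, score in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TraceStep:
    """One elimination iteration: the subset evaluated and what was dropped."""

    subset: tuple[str, ...]
    accuracy: float
    importance: ImportanceRanking
    dropped: tuple[str, ...]
    metrics: MetricsReport


@dataclass(frozen=True)
class EliminationTrace:
    """Ordered record of every candidate subset with its held-out accuracy."""

    steps: tuple[TraceStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def __getitem__(self, i: int) -> TraceStep:
        return self.steps[i]

    @property
    def subset_sizes(self) -> tuple[int, ...]:
        return tuple(len(s.subset) for s in self.steps)

    @property
    def accuracies(self) -> tuple[float, ...]:
        return tuple(s.accuracy for s in self.steps)

    def elimination_order(self) -> list[str]:
        """Features in the order they were dropped, surviving feature(s) last.

        With step size 1 this is a total ranking of the feature universe from
        least to most important.
        """
        order: list[str] = []
        for step in self.steps:
            order.extend(step.dropped)
        order.extend(self.steps[-1].subset)
        return order

    def to_records(self) -> list[dict]:
        """JSON-ready rows: one per step."""
        return [
            {
                "subset_size": len(s.subset),
                "features": list(s.subset),
                "balanced_accuracy": s.accuracy,
                "dropped_feature": list(s.dropped),
            }
            for s in self.steps
        ]


def _fit_forest(X: np.ndarray, y: np.ndarray, config: ClassifierConfig) -> RandomForestClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean decrease in OOB accuracy per feature, averaged over trees.

    Each tree's bootstrap draw is reconstructed from its stored seed (the same
    uniform-with-replacement draw the forest made), giving the exact OOB rows.
    Permutations are drawn within each tree's OOB set, one per feature, and
    all permuted copies for a tree are scored in a single stacked predict call.
    """
    n, p = X.shape
    rng = np.random.RandomState(seed)
    y_enc = forest.classes_.searchsorted(y)
    totals = np.zeros(p)
    used = 0
    chunk = max(1, min(p, _MAX_BLOCK_BYTES // max(1, n * p * 8)))
    for tree in forest.estimators_:
        boot = np.random.RandomState(tree.random_state).randint(0, n, n)
        oob = np.flatnonzero(np.bincount(boot, minlength=n) == 0)
        m = oob.size
        if m == 0:
            continue
        X_oob = X[oob]
        y_oob = y_enc[oob]
        base_acc = (tree.predict(X_oob).astype(int) == y_oob).mean()
        for start in range(0, p, chunk):
            cols = range(start, min(start + chunk, p))
            blocks = np.repeat(X_oob[None, :, :], len(cols), axis=0)
            for b, j in enumerate(cols):
                blocks[b, :, j] = X_oob[rng.permutation(m), j]
            preds = tree.predict(blocks.reshape(-1, p)).astype(int)
            perm_acc = (preds.reshape(len(cols), m) == y_oob).mean(axis=1)
            totals[list(cols)] += base_acc - perm_acc
        used += 1
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples; cannot rank features")
    return totals / used


def _rank(feature_names: Sequence[str], scores: np.ndarray) -> ImportanceRanking:
    order = sorted(range(len(feature_names)),
                   key=lambda j: (-scores[j], feature_names[j]))
    return ImportanceRanking(
        entries=tuple((feature_names[j], float(scores[j])) for j in order))


def _forest_and_ranking(
    train: FeatureTable, config: ClassifierConfig
) -> tuple[RandomForestClassifier, ImportanceRanking]:
    if train.n_features == 0:
        raise ValueError("empty feature set")
    forest = _fit_forest(train.values, train.labels, config)
    scores = _oob_permutation_importance(
        forest, train.values, train.labels, derive_seed(config.seed, 1))
    return forest, _rank(train.feature_names, scores)


def train_and_rank(train: FeatureTable, config: ClassifierConfig) -> ImportanceRanking:
    """Fit a forest on ``train`` and return its OOB permutation-importance ranking."""
    _, ranking = _forest_and_ranking(train, config)
    return ranking


def _trace_accuracy(report: MetricsReport, predictions: np.ndarray,
                    truth: np.ndarray, metric: str) -> float:
    if metric == "balanced":
        return report.balanced_accuracy
    return 100.0 * float((predictions == truth).mean())


def evaluate_subset(
    train: FeatureTable, test: FeatureTable, subset: Sequence[str],
    config: ClassifierConfig,
) -> MetricsReport:
    """Train on ``train`` restricted to ``subset`` and score ``test``."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    tr = train.restrict(subset)
    te = test.restrict(subset)
    forest = _fit_forest(tr.values, tr.labels, config)
    return compute_metrics(forest.predict(te.values), te.labels)


def run_rfe(
    train: FeatureTable, eval: FeatureTable, config: ClassifierConfig,
    step: int = 1,
) -> EliminationTrace:
    """Run the elimination loop and return the full trace.

    Each iteration fits one forest on ``train`` restricted to the surviving
    subset; that forest supplies both the importance ranking and the
    predictions on ``eval`` recorded as the subset's accuracy.  ``step``
    features are dropped per iteration (fewer on the last drop, so the trace
    always ends at one feature).  With ``step=1`` and p features the trace
    has exactly p steps.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    subset = list(train.feature_names)
    steps: list[TraceStep] = []
    iteration = 0
    while True:
        cfg = config.for_iteration(iteration)
        tr = train.restrict(subset)
        forest, ranking = _forest_and_ranking(tr, cfg)
        ev = eval.restrict(subset)
        predictions = forest.predict(ev.values)
        report = compute_metrics(predictions, ev.labels)
        accuracy = _trace_accuracy(report, predictions, ev.labels, config.metric)
        if len(subset) == 1:
            steps.append(TraceStep(tuple(ranking.feature_names), accuracy,
                                   ranking, (), report))
            break
        n_drop = min(step, len(subset) - 1)
        dropped = tuple(ranking.feature_names[-n_drop:])
        steps.append(TraceStep(tuple(ranking.feature_names), accuracy,
                               ranking, dropped, report))
        keep = set(subset) - set(dropped)
        # keep the importance order for the next iteration's initial layout
        subset = [f for f in ranking.feature_names if f in keep]
        iteration += 1
    return EliminationTrace(steps=tuple(steps))
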