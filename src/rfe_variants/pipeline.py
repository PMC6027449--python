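"""Cross-validated selection pipeline: four-part splits, per-fold RFE with a
decision variant, cross-fold voting, and the automatic vote-threshold sweep.

Each of the ``n_folds`` folds holds out one tenth of the samples (X4) and
partitions the rest into three stratified parts: X1 and X2 train the forests
inside the elimination loop, X3 scores every candidate subset, and the fold's
decision variant picks one subset from the resulting trace.  Features are
then pooled across folds by vote count; candidate final subsets (votes
strictly above a threshold) are each scored by retraining on X1+X2+X3 and
predicting the untouched X4 of every fold, and the best-scoring threshold
wins.  Final metrics pool the X4 confusion counts across folds.

Normalization parameters are always fitted on the fold's training portion
(X1+X2+X3) and applied, unclipped, to X4, so no information leaks from the
reporting split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed, round_half_up
from .metrics import MetricsReport, compute_metrics, pool_reports
from .preprocess import FeatureTable, apply_normalization, fit_normalization
from .rfe import ClassifierConfig, EliminationTrace, _fit_forest, run_rfe
from .variants import VariantDecision, VariantSpec, select
from .voting import ThresholdSweepResult, VotePool, count_votes, sweep_threshold


@dataclass(frozen=True)
class SplitScheme:
    """One fold's four disjoint index sets; X4 is the held-out tenth."""

    fold_index: int
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    x4: np.ndarray

    def training_indices(self) -> np.ndarray:
        """X1 + X2 + X3 — everything except the reporting split."""
        return np.concatenate([self.x1, self.x2, self.x3])

    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.x1, self.x2, self.x3, self.x4])


def _proportional_chunks(m: int, proportions: Sequence[float]) -> list[int]:
    """Split m items into len(proportions) counts by largest remainder."""
    total = float(sum(proportions))
    raw = [m * p / total for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = m - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_splits(
    table: FeatureTable,
    n_folds: int = 10,
    seed: int = 0,
    proportions: Sequence[float] = (1.0, 1.0, 1.0),
    stratified: bool = True,
) -> list[SplitScheme]:
    """Build the per-fold X1/X2/X3/X4 index sets.

    X4 assignment is a stratified k-fold partition: every sample lands in
    exactly one fold's X4.  Within each fold the remaining samples are dealt
    into X1:X2:X3 by ``proportions`` (default equal thirds), stratified by
    label, all driven by ``seed``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = table.labels
    if stratified and min(labels.sum(), (~labels).sum()) < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds: smallest class has "
            f"{int(min(labels.sum(), (~labels).sum()))} samples")
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=n_folds, shuffle=True, random_state=seed)
    schemes = []
    for fold_index, (train_idx, test_idx) in enumerate(
            splitter.split(table.values, labels)):
        rng = np.random.RandomState(derive_seed(seed, fold_index))
        parts: list[list[int]] = [[], [], []]
        groups = ([train_idx[labels[train_idx]], train_idx[~labels[train_idx]]]
                  if stratified else [train_idx])
        for group in groups:
            group = np.array(group)
            rng.shuffle(group)
            counts = _proportional_chunks(len(group), proportions)
            offset = 0
            for part, c in zip(parts, counts):
                part.extend(group[offset:offset + c].tolist())
                offset += c
        schemes.append(SplitScheme(
            fold_index=fold_index,
            x1=np.sort(np.array(parts[0], dtype=int)),
            x2=np.sort(np.array(parts[1], dtype=int)),
            x3=np.sort(np.array(parts[2], dtype=int)),
            x4=np.sort(np.asarray(test_idx, dtype=int)),
        ))
    return schemes


def run_fold(
    fold: SplitScheme,
    table: FeatureTable,
    variant: VariantSpec,
    config: ClassifierConfig,
    step: int = 1,
    return_trace: bool = False,
) -> VariantDecision | tuple[VariantDecision, EliminationTrace]:
    """Run RFE on one fold and apply the decision variant to its trace.

    Normalization is fitted on X1+X2+X3; the elimination loop trains on
    X1+X2 and scores each subset on X3.
    """
    params = fit_normalization(table.take(fold.training_indices()))
    train = apply_normalization(
        table.take(np.concatenate([fold.x1, fold.x2])), params)
    evaluation = apply_normalization(table.take(fold.x3), params)
    trace = run_rfe(train, evaluation, config, step=step)
    decision = select(trace, variant)
    return (decision, trace) if return_trace else decision


@dataclass(frozen=True)
class PipelineReport:
    """Everything a selection run produced, plus the config that determines it."""

    variant: VariantSpec
    config: dict
    fold_decisions: tuple[VariantDecision, ...]
    pool: VotePool
    sweep: ThresholdSweepResult
    sweep_fold_metrics: dict[int, MetricsReport]  # pooled X4 counts per v0
    final_metrics: MetricsReport
    baseline_metrics: MetricsReport

    @property
    def final_subset(self) -> tuple[str, ...]:
        return self.sweep.final_subset

    @property
    def chosen_v0(self) -> int:
        return self.sweep.chosen_v0

    def sweep_table(self, include_baseline: bool = True) -> pd.DataFrame:
        """Threshold-sweep summary, largest threshold first.

        Columns: v0, number of features, balanced accuracy, sensitivity,
        specificity — plus a no-selection baseline row.
        """
        rows = []
        for row in sorted(self.sweep.rows, key=lambda r: -r.v0):
            m = self.sweep_fold_metrics[row.v0].rounded()
            rows.append({"v0": row.v0, "n_features": row.n_features,
                         "balanced_accuracy": m["balanced_accuracy"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"]})
        if include_baseline:
            m = self.baseline_metrics.rounded()
            rows.append({"v0": "without FS",
                         "n_features": len(self.config["feature_names"]),
                         "balanced_accuracy": m["balanced_accuracy"],
                         "sensitivity": m["sensitivity"],
                         "specificity": m["specificity"]})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "variant": {"kind": self.variant.kind.value,
                        "pct": self.variant.pct,
                        "prenum": self.variant.prenum},
            "config": self.config,
            "fold_decisions": [
                {"subset": list(d.subset),
                 "achieved_accuracy": d.achieved_accuracy,
                 "trace_index": d.trace_index,
                 "threshold": d.threshold}
                for d in self.fold_decisions
            ],
            "votes": dict(sorted(self.pool.votes.items())),
            "sweep": self.sweep.to_records(),
            "chosen_v0": self.chosen_v0,
            "final_subset": list(self.final_subset),
            "final_metrics": self.final_metrics.to_dict(),
            "baseline_metrics": self.baseline_metrics.to_dict(),
        }


def run_pipeline(
    table: FeatureTable,
    variant: VariantSpec,
    config: ClassifierConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    step: int = 1,
    proportions: Sequence[float] = (1.0, 1.0, 1.0),
) -> PipelineReport:
    """Run the full cross-validated selection and threshold sweep.

    ``seed`` is the single master seed: fold assignment, every forest inside
    the elimination loops, and the sweep's scoring forests all draw derived
    seeds from it, so two runs with identical arguments produce identical
    reports.
    """
    config = config or ClassifierConfig()
    folds = make_splits(table, n_folds=n_folds, seed=derive_seed(seed, 0),
                        proportions=proportions)

    decisions = []
    for fold in folds:
        cfg = replace(config, seed=derive_seed(seed, 1, fold.fold_index))
        decisions.append(run_fold(fold, table, variant, cfg, step=step))
    pool = count_votes(decisions, n_folds)

    # per-fold normalization params and splits, reused across candidate sets
    fold_norm = []
    for fold in folds:
        train123 = table.take(fold.training_indices())
        params = fit_normalization(train123)
        fold_norm.append((
            apply_normalization(train123, params),
            apply_normalization(table.take(fold.x4), params),
        ))

    def score_set(features: Sequence[str]) -> tuple[float, MetricsReport]:
        per_fold = []
        for fold, (train, held_out) in zip(folds, fold_norm):
            cfg = replace(config, seed=derive_seed(seed, 2, fold.fold_index))
            tr = train.restrict(features)
            forest = _fit_forest(tr.values, tr.labels, cfg)
            predictions = forest.predict(held_out.restrict(features).values)
            per_fold.append(compute_metrics(predictions, held_out.labels))
        mean_ba = float(np.mean([m.balanced_accuracy for m in per_fold]))
        return mean_ba, pool_reports(per_fold)

    metrics_cache: dict[tuple[str, ...], tuple[float, MetricsReport]] = {}

    def evaluator(features: Sequence[str]) -> float:
        key = tuple(features)
        if key not in metrics_cache:
            metrics_cache[key] = score_set(key)
        return metrics_cache[key][0]

    sweep = sweep_threshold(pool, evaluator)
    sweep_fold_metrics = {row.v0: metrics_cache[row.candidate_set][1]
                          for row in sweep.rows}
    final_metrics = metrics_cache[sweep.final_subset][1]
    _, baseline_metrics = score_set(table.feature_names)

    return PipelineReport(
        variant=variant,
        config={
            "seed": seed,
            "n_folds": n_folds,
            "step": step,
            "n_trees": config.n_trees,
            "max_features": config.max_features,
            "metric": config.metric,
            "proportions": list(proportions),
            "feature_names": list(table.feature_names),
        },
        fold_decisions=tuple(decisions),
        pool=pool,
        sweep=sweep,
        sweep_fold_metrics=sweep_fold_metrics,
        final_metrics=final_metrics,
        baseline_metrics=baseline_metrics,
    )
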