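"""Cross-fold voting: pool per-fold selections and sweep the vote threshold.

Each cross-validation fold selects one subset; a feature's vote v_f is the
number of folds that selected it.  Candidate final subsets are the features
with v_f strictly greater than a threshold v0; sweeping v0 from 0 to
n_folds - 1 yields a nested family of candidates, and the one with the
highest evaluated balanced accuracy becomes the final subset — choosing the
threshold automatically.  Accuracy ties go to the larger threshold (the more
compact candidate set).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .variants import VariantDecision


@dataclass(frozen=True)
class VotePool:
    """Per-feature vote counts over the folds; zero-vote features are absent."""

    votes: dict[str, int]
    n_folds: int

    def __post_init__(self) -> None:
        for name, v in self.votes.items():
            if not 0 < v <= self.n_folds:
                raise ValueError(
                    f"vote for {name!r} is {v}, outside 1..{self.n_folds}")

    @property
    def max_vote(self) -> int:
        return max(self.votes.values(), default=0)

    def total_votes(self) -> int:
        return sum(self.votes.values())


@dataclass(frozen=True)
class SweepRow:
    """One evaluated threshold setting."""

    v0: int
    candidate_set: tuple[str, ...]
    balanced_accuracy: float
    n_features: int


@dataclass(frozen=True)
class ThresholdSweepResult:
    """All sweep rows plus the winning threshold and its candidate set."""

    rows: tuple[SweepRow, ...]
    chosen_v0: int
    final_subset: tuple[str, ...]

    @property
    def chosen_row(self) -> SweepRow:
        return next(r for r in self.rows if r.v0 == self.chosen_v0)

    def to_records(self) -> list[dict]:
        return [
            {"v0": r.v0, "n_features": r.n_features,
             "balanced_accuracy": r.balanced_accuracy,
             "features": list(r.candidate_set)}
            for r in self.rows
        ]


def count_votes(decisions: Sequence[VariantDecision], n_folds: int) -> VotePool:
    """Count, for each feature, how many folds selected it."""
    if len(decisions) != n_folds:
        raise ValueError(f"expected {n_folds} decisions, got {len(decisions)}")
    votes: dict[str, int] = {}
    for decision in decisions:
        for name in decision.subset:
            votes[name] = votes.get(name, 0) + 1
    return VotePool(votes=votes, n_folds=n_folds)


def candidate_set(pool: VotePool, v0: int) -> tuple[str, ...]:
    """Features with votes strictly greater than ``v0``.

    Ordered by descending vote, then name, so the list is stable and reads as
    a ranking.
    """
    if not 0 <= v0 <= pool.n_folds - 1:
        raise ValueError(f"v0 must lie in 0..{pool.n_folds - 1}, got {v0}")
    chosen = [(name, v) for name, v in pool.votes.items() if v > v0]
    chosen.sort(key=lambda item: (-item[1], item[0]))
    return tuple(name for name, _ in chosen)


def sweep_threshold(
    pool: VotePool,
    evaluator: Callable[[Sequence[str]], float],
    v0_range: Iterable[int] | None = None,
) -> ThresholdSweepResult:
    """Evaluate every distinct non-empty candidate set and pick the best.

    ``evaluator`` maps a feature list to a balanced accuracy (the pipeline
    supplies a cross-fold one).  Identical candidate sets across adjacent
    thresholds are evaluated once and the score reused.  The winning row
    maximizes balanced accuracy; ties go to the larger threshold.
    """
    if v0_range is None:
        v0_range = range(pool.n_folds)
    cache: dict[tuple[str, ...], float] = {}
    rows: list[SweepRow] = []
    for v0 in v0_range:
        cand = candidate_set(pool, v0)
        if not cand:
            continue
        if cand not in cache:
            cache[cand] = float(evaluator(cand))
        rows.append(SweepRow(v0=v0, candidate_set=cand,
                             balanced_accuracy=cache[cand],
                             n_features=len(cand)))
    if not rows:
        raise ValueError("every candidate set in the sweep range is empty")
    best = max(rows, key=lambda r: (r.balanced_accuracy, r.v0))
    return ThresholdSweepResult(rows=tuple(rows), chosen_v0=best.v0,
                                final_subset=best.candidate_set)
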