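"""Confusion-matrix metrics: sensitivity, specificity, balanced accuracy.

All three are percentages.  Balanced accuracy is the arithmetic mean of
sensitivity (true-positive rate) and specificity (true-negative rate), which
keeps the score honest under the class imbalance typical of toxicogenomic
screens.  Values are held unrounded internally; tables report them half-up to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import round_half_up


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived percentage metrics."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def rounded(self) -> dict[str, float]:
        """Metrics at reporting precision (2 decimals, half-up)."""
        return {
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "balanced_accuracy": round_half_up(self.balanced_accuracy),
        }

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "balanced_accuracy": self.balanced_accuracy}


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy from already-computed percentage rates."""
    return (sensitivity + specificity) / 2.0


def compute_metrics(predictions: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Build a :class:`MetricsReport` from boolean prediction/truth vectors.

    ``truth`` must contain at least one positive and one negative sample,
    otherwise sensitivity or specificity is undefined.
    """
    predictions = np.asarray(predictions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape[0]} predictions, "
            f"{truth.shape[0]} truth labels")
    if truth.all() or not truth.any():
        raise ValueError("truth labels contain a single class")
    return MetricsReport(
        tp=int((predictions & truth).sum()),
        tn=int((~predictions & ~truth).sum()),
        fp=int((predictions & ~truth).sum()),
        fn=int((~predictions & truth).sum()),
    )


def pool_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Pool confusion counts across folds (counts add; rates recomputed)."""
    return MetricsReport(
        tp=sum(r.tp for r in reports),
        tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports),
    )
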