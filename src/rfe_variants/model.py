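"""Model/Results surface over the cross-validated selection pipeline.

``RFEVoting`` is built from data (a :class:`~rfe_variants.preprocess.FeatureTable`,
a DataFrame, or a CSV/TSV file) plus the selection settings; ``fit`` runs the
whole procedure — per-fold recursive elimination, the decision variant,
cross-fold voting and the automatic vote-threshold sweep — and returns an
:class:`RFEVotingResults` carrying the selected features, their vote counts,
the sweep diagnostics and the held-out performance, with a ``summary()``
table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .pipeline import PipelineReport, run_pipeline
from .preprocess import FeatureTable, load_table
from .rfe import ClassifierConfig
from .variants import VariantSpec


class RFEVoting:
    """Cross-validated random-forest RFE with voting-based subset selection.

    Parameters
    ----------
    table
        The feature table being selected over.
    variant
        Decision rule applied to each fold's elimination trace ("ha",
        "pct-ha" or "prenum"); see :class:`~rfe_variants.variants.VariantSpec`.
    config
        Random-forest hyperparameters (500 trees, sqrt(p) splits by default).
    n_folds
        Cross-validation folds; each contributes one vote per selected feature.
    step
        Features eliminated per RFE iteration.
    """

    def __init__(
        self,
        table: FeatureTable,
        variant: VariantSpec | str = "ha",
        config: ClassifierConfig | None = None,
        n_folds: int = 10,
        step: int = 1,
        proportions: Sequence[float] = (1.0, 1.0, 1.0),
    ) -> None:
        if isinstance(variant, str):
            variant = VariantSpec(kind=variant)
        self.table = table
        self.variant = variant
        self.config = config or ClassifierConfig()
        self.n_folds = n_folds
        self.step = step
        self.proportions = tuple(proportions)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str, positive_label: str, **kwargs
    ) -> "RFEVoting":
        labels = df[label_column].astype(str) == str(positive_label)
        feat = df.drop(columns=[label_column])
        table = FeatureTable(
            sample_ids=tuple(str(i) for i in df.index),
            feature_names=tuple(str(c) for c in feat.columns),
            values=feat.to_numpy(dtype=float),
            labels=labels.to_numpy(),
        )
        return cls(table, **kwargs)

    @classmethod
    def from_csv(cls, path: str, label_column: str, positive_label: str,
                 delimiter: str | None = None, **kwargs) -> "RFEVoting":
        table = load_table(path, label_column, positive_label, delimiter=delimiter)
        return cls(table, **kwargs)

    def fit(self, seed: int = 0) -> "RFEVotingResults":
        """Run the full pipeline under one master seed."""
        report = run_pipeline(
            self.table, self.variant, self.config,
            n_folds=self.n_folds, seed=seed, step=self.step,
            proportions=self.proportions,
        )
        return RFEVotingResults(self, report)


class RFEVotingResults:
    """Fitted selection results: final subset, votes, sweep, held-out metrics."""

    def __init__(self, model: RFEVoting, report: PipelineReport) -> None:
        self.model = model
        self.report = report

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.report.final_subset

    @property
    def chosen_vote_threshold(self) -> int:
        return self.report.chosen_v0

    @property
    def votes(self) -> dict[str, int]:
        return dict(self.report.pool.votes)

    @property
    def metrics(self):
        """Pooled held-out (X4) confusion metrics for the final subset."""
        return self.report.final_metrics

    @property
    def baseline_metrics(self):
        """Same evaluation with no feature selection."""
        return self.report.baseline_metrics

    def sweep_table(self) -> pd.DataFrame:
        return self.report.sweep_table()

    def summary(self) -> str:
        """Human-readable account of the fit, one block per stage."""
        r = self.report
        m = r.final_metrics.rounded()
        b = r.baseline_metrics.rounded()
        fold_sizes = [len(d.subset) for d in r.fold_decisions]
        lines = [
            "Cross-validated RF-RFE feature selection",
            "=" * 48,
            f"Samples: {self.model.table.n_samples} "
            f"({self.model.table.n_positive} positive / "
            f"{self.model.table.n_negative} negative); "
            f"features: {self.model.table.n_features}",
            f"Variant: {r.variant.describe()};  folds: {len(r.fold_decisions)};  "
            f"trees: {r.config['n_trees']};  seed: {r.config['seed']}",
            "",
            f"Per-fold subset sizes: {fold_sizes}",
            f"Features in vote pool: {len(r.pool.votes)} "
            f"(max vote {r.pool.max_vote})",
            f"Chosen vote threshold v0: {r.chosen_v0}",
            f"Final subset ({len(r.final_subset)} features): "
            + ", ".join(r.final_subset),
            "",
            "Held-out performance (pooled X4 across folds):",
            f"  balanced accuracy {m['balanced_accuracy']:.2f}%   "
            f"sensitivity {m['sensitivity']:.2f}%   "
            f"specificity {m['specificity']:.2f}%",
            "Without feature selection:",
            f"  balanced accuracy {b['balanced_accuracy']:.2f}%   "
            f"sensitivity {b['sensitivity']:.2f}%   "
            f"specificity {b['specificity']:.2f}%",
        ]
        return "\n".join(lines)
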