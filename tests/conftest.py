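import numpy as np
import pytest

from rfe_variants.metrics import MetricsReport
from rfe_variants.preprocess import FeatureTable
from rfe_variants.rfe import EliminationTrace, ImportanceRanking, TraceStep


def make_table(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_names=tuple(names),
        values=values,
        labels=np.asarray(labels, dtype=bool),
    )


def make_trace(accuracies, n_features=None, feature_names=None):
    """Build a step-1 elimination trace with the given accuracies.

    Subsets are nested by dropping the alphabetically last surviving feature
    at each step; importance scores are descending placeholders.
    """
    n_features = n_features or len(accuracies)
    assert len(accuracies) == n_features
    names = list(feature_names or (f"g{j:03d}" for j in range(n_features)))
    steps = []
    current = sorted(names)
    dummy_metrics = MetricsReport(tp=1, tn=1, fp=1, fn=1)
    for acc in accuracies:
        ranking = ImportanceRanking(
            entries=tuple((f, float(len(current) - i))
                          for i, f in enumerate(current)))
        dropped = (current[-1],) if len(current) > 1 else ()
        steps.append(TraceStep(subset=tuple(current), accuracy=float(acc),
                               importance=ranking, dropped=dropped,
                               metrics=dummy_metrics))
        current = current[:-1]
    return EliminationTrace(steps=tuple(steps))


@pytest.fixture
def separable_table():
    """80 samples whose first feature tracks the label exactly; two noise."""
    rng = np.random.default_rng(42)
    labels = np.arange(80) % 2 == 0
    values = np.column_stack([
        np.where(labels, 1.0, -1.0),
        rng.standard_normal(80),
        rng.standard_normal(80),
    ])
    return make_table(values, labels, names=["signal", "noise_a", "noise_b"])
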