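"""Feature tables and min-max normalization to [-1, 1].

The central container is :class:`FeatureTable`: a samples x features numeric
matrix with named feature columns and a binary label per sample.  Tables are
read from CSV/TSV with one row per sample; every non-label column is a feature.

Normalization maps each feature column f to ``2*(f - f_min)/(f_max - f_min) - 1``
using the column minimum and maximum.  Parameters are fitted on training data
only and applied, unclipped, to held-out data, so held-out values may fall
outside [-1, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd


class TableError(ValueError):
    """A feature table violates a structural requirement."""


class MissingFileError(TableError):
    pass


class LabelColumnError(TableError):
    """The requested label column is absent."""


class NonNumericCellError(TableError):
    """A feature cell could not be parsed as a finite number."""


class TooFewSamplesError(TableError):
    pass


class SingleClassError(TableError):
    """Labels contain only one class."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features matrix with binary labels.

    Parameters
    ----------
    sample_ids
        Opaque per-row identifiers (length n).
    feature_names
        Unique feature column names (length p).
    values
        Finite float matrix of shape (n, p).
    labels
        Boolean vector of length n; True marks the positive class.
    """

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        n, p = values.shape
        if len(self.sample_ids) != n or len(labels) != n:
            raise TableError("sample_ids, labels and value rows must align")
        if len(self.feature_names) != p:
            raise TableError("feature_names must match value columns")
        if len(set(self.feature_names)) != p:
            raise TableError("feature names must be unique")
        if not np.isfinite(values).all():
            raise TableError("feature matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {name: j for j, name in enumerate(self.feature_names)}
        missing = [name for name in names if name not in lookup]
        if missing:
            raise KeyError(f"unknown feature name(s): {missing}")
        return np.array([lookup[name] for name in names], dtype=int)

    def restrict(self, features: Sequence[str]) -> "FeatureTable":
        """Return the table restricted to the given feature columns, in order."""
        idx = self.feature_index(features)
        return replace(
            self,
            feature_names=tuple(features),
            values=self.values[:, idx],
        )

    def take(self, indices: Sequence[int]) -> "FeatureTable":
        """Return the table restricted to the given sample rows."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            values=self.values[idx],
            labels=self.labels[idx],
        )

    def to_dataframe(self, label_column: str = "label",
                     positive_label: str = "pos",
                     negative_label: str = "neg") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names),
                          index=list(self.sample_ids))
        df.index.name = "sample_id"
        df[label_column] = np.where(self.labels, positive_label, negative_label)
        return df


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature column minimum and maximum, fitted on a training table."""

    feature_names: tuple[str, ...]
    f_min: np.ndarray
    f_max: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "f_min", np.asarray(self.f_min, dtype=float))
        object.__setattr__(self, "f_max", np.asarray(self.f_max, dtype=float))
        if not (self.f_min <= self.f_max).all():
            raise ValueError("f_min must not exceed f_max")


def _infer_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".tab") else ","


def load_table(path: str, label_column: str, positive_label: str,
               delimiter: str | None = None,
               index_column: str | None = None) -> FeatureTable:
    """Read a CSV/TSV with a header row into a :class:`FeatureTable`.

    Every column except ``label_column`` (and the optional ``index_column``)
    becomes a feature.  Label values equal to ``positive_label`` map to the
    positive class; every other value maps to negative.  Rows with missing or
    non-numeric feature cells are an error, never imputed.
    """
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter))
    if label_column not in df.columns:
        raise LabelColumnError(
            f"label column {label_column!r} not found; columns: {list(df.columns)}")
    if index_column is None and "sample_id" in df.columns:
        index_column = "sample_id"  # our own writer's identifier column
    if index_column is not None and index_column in df.columns:
        df = df.set_index(index_column)
        sample_ids = [str(s) for s in df.index]
    else:
        sample_ids = [str(i) for i in range(len(df))]
    labels = df[label_column].astype(str).to_numpy() == str(positive_label)
    feat = df.drop(columns=[label_column])
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise NonNumericCellError(
            f"non-numeric or missing value at row {sample_ids[row]!r}, "
            f"column {feat.columns[col]!r}: {feat.iat[row, col]!r}")
    if len(df) < 2:
        raise TooFewSamplesError(f"need at least 2 samples, got {len(df)}")
    if labels.all() or not labels.any():
        raise SingleClassError(
            "labels contain a single class; need both positive and negative samples")
    return FeatureTable(
        sample_ids=tuple(sample_ids),
        feature_names=tuple(str(c) for c in feat.columns),
        values=numeric.to_numpy(dtype=float),
        labels=labels,
    )


def write_table(table: FeatureTable, path: str, label_column: str = "label",
                positive_label: str = "pos", negative_label: str = "neg",
                delimiter: str | None = None) -> None:
    """Write a table back to CSV/TSV (delimiter inferred from extension)."""
    sep = _infer_delimiter(path, delimiter)
    table.to_dataframe(label_column, positive_label, negative_label).to_csv(path, sep=sep)


def fit_normalization(table: FeatureTable) -> NormalizationParams:
    """Record each feature's column minimum and maximum."""
    if table.n_features == 0:
        raise TableError("cannot fit normalization on an empty feature set")
    return NormalizationParams(
        feature_names=table.feature_names,
        f_min=table.values.min(axis=0),
        f_max=table.values.max(axis=0),
    )


def apply_normalization(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Map each feature through the affine [-1, 1] rescaling.

    Constant features (f_min == f_max) map to 0.  Values from a table other
    than the one the params were fitted on may leave [-1, 1]; they are not
    clipped.
    """
    lookup = {name: j for j, name in enumerate(params.feature_names)}
    missing = [name for name in table.feature_names if name not in lookup]
    if missing:
        raise KeyError(f"normalization params missing feature(s): {missing}")
    idx = np.array([lookup[name] for name in table.feature_names], dtype=int)
    fmin, fmax = params.f_min[idx], params.f_max[idx]
    span = fmax - fmin
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = 2.0 * (table.values - fmin) / safe_span - 1.0
    scaled[:, constant] = 0.0
    return replace(table, values=scaled)


def invert_normalization(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Inverse affine map; constant features recover their fitted f_min."""
    lookup = {name: j for j, name in enumerate(params.feature_names)}
    idx = np.array([lookup[name] for name in table.feature_names], dtype=int)
    fmin, fmax = params.f_min[idx], params.f_max[idx]
    span = fmax - fmin
    raw = (table.values + 1.0) / 2.0 * span + fmin
    raw[:, span == 0] = fmin[span == 0]
    return replace(table, values=raw)
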