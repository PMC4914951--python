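"""Data model shared by the selection engine, classifiers and evaluation code.

The central objects are :class:`FeatureTable` (a samples x features intensity
matrix, typically a log-transformed LC-MS peak table or a microarray
expression matrix), :class:`BinaryLabels` (a two-level class factor aligned to
the table's samples) and :class:`SelectionConfig` (the knobs of the selection
engine).  Tables are immutable: every subsetting operation returns a new
object, so bootstrap and permutation machinery can never corrupt the input.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "BinaryLabels",
    "SelectionConfig",
    "DataValidationError",
    "validate_dataset",
    "restrict_features",
    "encode_labels",
]


class DataValidationError(ValueError):
    """Raised when an input table or label vector violates the data contract."""


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features numeric intensity matrix with row/column names.

    Parameters
    ----------
    values
        2-D float array, one row per sample, one column per feature.
        Intensities are unitless here; upstream pipelines typically provide
        log10-scale values.
    sample_ids
        Ordered, unique sample names (length = number of rows).
    feature_ids
        Ordered, unique feature names (length = number of columns).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataValidationError("feature table must be 2-dimensional")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if len(self.sample_ids) != values.shape[0]:
            raise DataValidationError(
                f"{len(self.sample_ids)} sample ids for {values.shape[0]} rows"
            )
        if len(self.feature_ids) != values.shape[1]:
            raise DataValidationError(
                f"{len(self.feature_ids)} feature ids for {values.shape[1]} columns"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataValidationError("duplicate feature ids")

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[0]

    @property
    def p(self) -> int:
        """Number of features."""
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=tuple(str(i) for i in frame.index),
            feature_ids=tuple(str(c) for c in frame.columns),
        )

    def take_samples(self, indices: Sequence[int], ids: Sequence[str] | None = None) -> "FeatureTable":
        """Row subset/resample.  ``ids`` overrides names when rows repeat."""
        indices = np.asarray(indices, dtype=int)
        if ids is None:
            counts: dict[str, int] = {}
            names = []
            for i in indices:
                base = self.sample_ids[i]
                k = counts.get(base, 0)
                counts[base] = k + 1
                names.append(base if k == 0 else f"{base}.{k}")
            ids = names
        return FeatureTable(self.values[indices], tuple(ids), self.feature_ids)


@dataclass(frozen=True)
class BinaryLabels:
    """Two-level class factor over the samples of a :class:`FeatureTable`.

    ``positive_level`` fixes which class counts as "positive" for
    sensitivity/specificity; it defaults to the lexicographically larger
    level so runs are deterministic without user input.
    """

    labels: tuple[str, ...]
    positive_level: str = ""

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise DataValidationError(
                f"labels must have exactly two levels, got {levels!r}"
            )
        pos = self.positive_level or levels[-1]
        if pos not in levels:
            raise DataValidationError(
                f"positive_level {pos!r} is not one of the levels {levels!r}"
            )
        object.__setattr__(self, "positive_level", str(pos))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def levels(self) -> tuple[str, str]:
        """(negative level, positive level)."""
        return (self.negative_level, self.positive_level)

    @property
    def negative_level(self) -> str:
        a, b = sorted(set(self.labels))
        return a if b == self.positive_level else b

    def as_binary(self) -> np.ndarray:
        """0/1 indicator of the positive level."""
        return np.asarray([1 if x == self.positive_level else 0 for x in self.labels])

    def take(self, indices: Sequence[int]) -> "BinaryLabels":
        indices = np.asarray(indices, dtype=int)
        return BinaryLabels(
            tuple(self.labels[i] for i in indices), positive_level=self.positive_level
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for x in self.labels:
            out[x] = out.get(x, 0) + 1
        return out


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the selection engine.

    boot
        Number of bootstrap resamples per selection round (default 50).
    alpha
        Significance threshold on the proportion of bootstraps where the
        permuted-subset accuracy reaches the unpermuted one (default 0.05).
    methods
        Classifiers to wrap; any subset of {"plsda", "rf", "svm"}.
    seed
        Master seed; every downstream random draw derives from it.
    max_rounds
        Hard safeguard on the number of selection rounds.
    permutations_q2y
        Number of response permutations in the PLS-DA Q2Y significance test.
    n_trees, svm_cost
        Classifier hyperparameters (fixed defaults, overridable).
    """

    boot: int = 50
    alpha: float = 0.05
    methods: tuple[str, ...] = ("plsda", "rf", "svm")
    seed: int = 0
    max_rounds: int = 50
    permutations_q2y: int = 1000
    n_trees: int = 500
    svm_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.boot < 2:
            raise ValueError("boot must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be positive")
        if self.permutations_q2y < 1:
            raise ValueError("permutations_q2y must be positive")
        methods = tuple(self.methods)
        unknown = set(methods) - {"plsda", "rf", "svm"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        object.__setattr__(self, "methods", methods)

    def replace(self, **kwargs) -> "SelectionConfig":
        return dataclasses.replace(self, **kwargs)


def validate_dataset(
    table: FeatureTable, labels: BinaryLabels
) -> tuple[FeatureTable, BinaryLabels]:
    """Check table/label consistency; never mutates either input.

    Raises :class:`DataValidationError` on missing or non-finite cells
    (naming the offending sample and feature), dimension mismatch, fewer
    than 4 samples, or a class with fewer than 2 samples.  Constant-valued
    features are legal (classifiers guard their scaling) but reported with
    a warning.
    """
    if labels.n != table.n:
        raise DataValidationError(
            f"{labels.n} labels for {table.n} samples"
        )
    if table.n < 4:
        raise DataValidationError(f"need at least 4 samples, got {table.n}")
    if table.p < 1:
        raise DataValidationError("need at least 1 feature")
    bad = ~np.isfinite(table.values)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataValidationError(
            f"non-finite value at sample {table.sample_ids[i]!r} / feature "
            f"{table.feature_ids[j]!r}; impute or filter missing values upstream"
        )
    for level, count in labels.counts().items():
        if count < 2:
            raise DataValidationError(
                f"each class needs >= 2 samples; class {level!r} has {count}"
            )
    constant = [
        table.feature_ids[j]
        for j in range(table.p)
        if np.ptp(table.values[:, j]) == 0.0
    ]
    if constant:
        shown = ", ".join(constant[:5]) + ("..." if len(constant) > 5 else "")
        warnings.warn(
            f"{len(constant)} constant feature(s) retained: {shown}",
            stacklevel=2,
        )
    return table, labels


def restrict_features(table: FeatureTable, keep: Sequence[str]) -> FeatureTable:
    """Column subset in the order given by ``keep``."""
    keep = [str(k) for k in keep]
    index = {f: j for j, f in enumerate(table.feature_ids)}
    unknown = [k for k in keep if k not in index]
    if unknown:
        raise KeyError(f"unknown feature id(s): {unknown}")
    cols = [index[k] for k in keep]
    return FeatureTable(
        table.values[:, cols] if cols else np.empty((table.n, 0)),
        table.sample_ids,
        tuple(keep),
    )


def encode_labels(labels: BinaryLabels) -> np.ndarray:
    """Numeric response: positive level -> +0.5, the other level -> -0.5."""
    return np.where(labels.as_binary() == 1, 0.5, -0.5)
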