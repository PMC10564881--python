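"""Core tabular containers: participant-by-predictor matrices and binary targets.

A :class:`FeatureTable` couples the value matrix with an explicit observed-cell
mask so that downstream steps (sparsity filtering, masked imputation) can
distinguish "missing" from "imputed" long after the NaNs are gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "BinaryTarget"]


@dataclass
class FeatureTable:
    """Participants x predictors matrix with an explicit missingness mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, one row per subject, one column per candidate
        predictor.  Unobserved cells may hold NaN.
    mask : pandas.DataFrame
        Boolean, same shape/index/columns as ``values``; True = observed.
    feature_meta : pandas.DataFrame
        Indexed by feature name with at least columns ``domain`` and
        ``dtype`` (one of ``continuous``, ``binary``, ``ordinal``).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.values.notna()
        if self.values.shape != self.mask.shape:
            raise ValueError("mask shape must equal values shape")
        if not self.values.columns.equals(self.mask.columns):
            raise ValueError("mask columns must match values columns")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"domain": "unknown", "dtype": "continuous"},
                index=self.values.columns,
            )

    # -- convenience ------------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of unobserved cells."""
        return 1.0 - self.mask.mean(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.mask.copy(), self.feature_meta.copy()
        )

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(
            self.values[names], self.mask[names], self.feature_meta.loc[names]
        )

    def select_subjects(self, ids) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[ids], self.mask.loc[ids], self.feature_meta
        )

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- I/O (empty cell = missing) ---------------------------------------
    def to_csv(self, path) -> None:
        # values hold NaN at unobserved cells; imputed cells (mask=False but
        # finite value) are written as-is
        self.values.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, feature_meta: pd.DataFrame | None = None) -> "FeatureTable":
        values = pd.read_csv(path, index_col="subject_id")
        return cls(values, values.notna(), feature_meta)


@dataclass
class BinaryTarget:
    """Case / not-case vector for one condition.

    ``source_items`` records which symptom items were agglomerated into the
    score from which the labels were derived.
    """

    labels: pd.Series
    source_items: list[str] = field(default_factory=list)
    name: str = "target"

    def __post_init__(self) -> None:
        vals = set(pd.unique(self.labels))
        if not vals <= {0, 1}:
            raise ValueError("labels must be coded 0/1")
        self.labels = self.labels.astype(int)

    @property
    def positive_rate(self) -> float:
        return float(self.labels.mean())

    def as_array(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def select_subjects(self, ids) -> "BinaryTarget":
        return BinaryTarget(self.labels.loc[ids], list(self.source_items), self.name)

    def to_csv(self, path) -> None:
        self.labels.rename("label").to_csv(path, index_label="subject_id")
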