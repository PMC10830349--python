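"""Labelled symmetric distance matrices.

A :class:`DistanceMatrix` is the common currency of the pipeline: pairwise
abundance asynchrony, Gower trait dissimilarity and patristic distance are
all square, symmetric, nonnegative matrices with a zero diagonal and species
labels.  Undefined entries (e.g. pairs with too little time-series overlap)
are stored as NaN and excluded pairwise by downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, InvalidArgumentError

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Symmetric species-by-species distance matrix with NaN for undefined pairs.

    Parameters
    ----------
    labels
        Species identifiers, one per row/column, unique.
    values
        Square float array; ``values[i, j]`` is the distance between
        ``labels[i]`` and ``labels[j]``.  NaN marks an undefined pair.
    name
        Provenance tag ("asynchrony", "gower:combined", "patristic", ...).
    """

    labels: list[str]
    values: np.ndarray
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidArgumentError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise InvalidArgumentError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InvalidArgumentError("distance matrix must be symmetric")
        diag = np.diagonal(self.values)
        if not np.allclose(diag[~np.isnan(diag)], 0.0):
            raise InvalidArgumentError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise InvalidArgumentError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InvalidArgumentError(f"label {label!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def reindex(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Restrict/reorder to ``labels`` (all must be present)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise AlignmentError(f"labels absent from matrix {self.name!r}: {missing}")
        idx = np.array([self.labels.index(l) for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise FormatError(f"{path}: row and column labels differ")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
        return cls(list(df.index.astype(str)), values, name or str(path))

    def triangle(self) -> np.ndarray:
        """Strict lower-triangle entries in row-major pair order (may contain NaN)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]
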