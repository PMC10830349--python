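"""Interannual abundance change and pairwise asynchrony.

Monitoring schemes publish one *collated annual abundance index* per species
and year: a scheme-wide, standardised log10 estimate of the expected count on
a standardised transect walk or trapping event.  The analysis works not on
the indices themselves but on their year-to-year differences ("interannual
change"), and summarises how dissimilar two species' dynamics are with

    M_ij = (1 - K_ij) / 2

where K_ij is the Pearson correlation of the two change series over their
shared intervals.  M maps perfect synchrony (K = 1) to 0, independence to
0.5 and perfect anticorrelation (K = -1) to 1, putting asynchrony on the
same [0, 1] scale as Gower trait dissimilarity.

Panels are held wide (species rows, integer calendar-year columns) with NaN
for unmonitored years.  Changes are computed only across consecutive
calendar years where both endpoints are observed — never across gaps — and
correlations use pairwise-complete overlap, since different schemes span
different periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError, PipelineError
from .matrices import DistanceMatrix

logger = logging.getLogger("traitsync.abundance")

__all__ = [
    "AbundancePanel",
    "ChangePanel",
    "AsynchronyMatrix",
    "read_panel",
    "write_matrix",
    "interannual_change",
    "asynchrony_matrix",
]


@dataclass
class AbundancePanel:
    """Species x year table of collated annual indices (log10 scale).

    ``data`` is a wide DataFrame: index = species ids, columns = consecutive
    integer calendar years spanning the observed range, values = float
    indices with NaN for missing years.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(int)
        self.data = self.data.sort_index(axis=1)
        years = list(self.data.columns)
        if years:
            full = list(range(years[0], years[-1] + 1))
            if years != full:
                self.data = self.data.reindex(columns=full)
        self.data.index.name = "species"
        self.data.columns.name = "year"

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def years(self) -> list[int]:
        return list(self.data.columns)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.data.rename_axis("species")
            .reset_index()
            .melt(id_vars="species", var_name="year", value_name="index")
            .dropna(subset=["index"])
        )
        long["year"] = long["year"].astype(int)
        return long.sort_values(["species", "year"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


@dataclass
class ChangePanel:
    """Species x interval table of interannual changes.

    Columns are the *starting* calendar year of each one-year interval;
    ``data.loc[sp, t]`` is ``index(t+1) - index(t)``, NaN when either
    endpoint is unobserved.
    """

    data: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.data.index)


@dataclass
class AsynchronyMatrix:
    """Pairwise asynchrony M with the per-pair overlap counts behind it."""

    matrix: DistanceMatrix
    n_overlap: np.ndarray  # symmetric int matrix of shared intervals

    @property
    def labels(self) -> list[str]:
        return self.matrix.labels


def read_panel(path, log10: bool = False) -> AbundancePanel:
    """Read a long-format CSV (species, year, index) into a panel.

    Parameters
    ----------
    log10
        Apply a log10 transform, for inputs supplied on the raw count scale.
        Collated indices are published on the log scale already, so the
        default leaves values untouched.
    """
    df = pd.read_csv(path)
    required = {"species", "year", "index"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    dup = df.duplicated(subset=["species", "year"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header line and 1-basing
        raise FormatError(f"{path}: duplicate (species, year) at file line(s) {rows}")
    if not pd.api.types.is_numeric_dtype(df["index"]):
        bad = df.loc[pd.to_numeric(df["index"], errors="coerce").isna(), "index"]
        raise FormatError(f"{path}: non-numeric index values, e.g. {bad.iloc[0]!r}")
    values = df["index"].astype(float)
    if log10:
        if (values <= 0).any():
            raise FormatError(f"{path}: nonpositive values cannot be log10-transformed")
        values = np.log10(values)
    wide = (
        df.assign(index=values)
        .pivot(index="species", columns="year", values="index")
    )
    return AbundancePanel(wide)


def write_matrix(matrix: DistanceMatrix, path) -> None:
    """Write a labelled square CSV (inverse of DistanceMatrix.from_csv)."""
    matrix.to_csv(path)


def interannual_change(panel: AbundancePanel, min_years: int = 2) -> ChangePanel:
    """Difference each species' index series across consecutive observed years.

    Species with fewer than ``min_years`` non-missing values (< 2 means no
    change can be formed at all) are dropped with a logged warning.
    """
    if min_years < 2:
        raise InvalidArgumentError("min_years must be >= 2")
    data = panel.data
    keep = data.notna().sum(axis=1) >= min_years
    dropped = data.index[~keep].tolist()
    if dropped:
        logger.warning(
            "dropping %d species with < %d observed years: %s",
            len(dropped), min_years, dropped,
        )
    data = data.loc[keep]
    if data.shape[1] < 2:
        return ChangePanel(pd.DataFrame(index=data.index))
    arr = data.to_numpy(dtype=float)
    deltas = arr[:, 1:] - arr[:, :-1]  # NaN propagates across gaps
    cols = data.columns[:-1]  # interval labelled by starting year
    return ChangePanel(pd.DataFrame(deltas, index=data.index, columns=cols))


def asynchrony_matrix(changes: ChangePanel, min_overlap: int = 5) -> AsynchronyMatrix:
    """Pairwise asynchrony M = (1 - K)/2 from interannual change series.

    K is the pairwise-complete Pearson correlation over shared intervals.
    Pairs with fewer than ``min_overlap`` shared intervals, or with zero
    variance in either series over the shared intervals, are undefined (NaN).
    """
    if min_overlap < 3:
        raise InvalidArgumentError("min_overlap must be >= 3")
    X = changes.data.to_numpy(dtype=float)
    species = changes.species
    n = len(species)
    valid = ~np.isnan(X)
    Xz = np.where(valid, X, 0.0)
    V = valid.astype(float)

    # Pairwise-complete moments via masked outer products.
    n_ov = V @ V.T
    s_x = Xz @ V.T          # sum of x_i over intervals shared with j
    s_y = s_x.T
    s_xx = (Xz * Xz) @ V.T
    s_yy = s_xx.T
    s_xy = Xz @ Xz.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n_ov * s_xy - s_x * s_y
        var_x = n_ov * s_xx - s_x**2
        var_y = n_ov * s_yy - s_y**2
        K = cov / np.sqrt(var_x * var_y)

    tol = 1e-12
    undef = (n_ov < min_overlap) | (var_x <= tol) | (var_y <= tol)
    K = np.where(undef, np.nan, K)
    K = np.clip(K, -1.0, 1.0)
    M = (1.0 - K) / 2.0
    np.fill_diagonal(M, 0.0)
    M = (M + M.T) / 2.0  # enforce exact symmetry against float noise

    off = ~np.eye(n, dtype=bool)
    n_undef = int(np.isnan(M[off]).sum() // 2)
    if n > 1 and n_undef == n * (n - 1) // 2:
        raise PipelineError("insufficient overlap: every species pair is undefined")
    if n_undef:
        logger.info("asynchrony: %d pair(s) undefined (overlap/variance)", n_undef)

    return AsynchronyMatrix(
        DistanceMatrix(species, M, name="asynchrony"),
        n_overlap=n_ov.astype(int),
    )
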