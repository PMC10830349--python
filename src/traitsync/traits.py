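"""Gower trait dissimilarity with equal-group-contribution weighting.

Species traits come in two codings: continuous measurements (forewing length
in mm, dry mass in mg, hostplant number) and categorical traits expanded
into multiple binary presence/absence *dimensions* (e.g. twelve monthly
columns for the adult flight period, eight habitat columns).  Gower distance
handles the mix: continuous traits are range-normalised absolute differences
over the analysis species set, and a multi-dimension binary trait is the
mean mismatch over mutually observed dimensions rescaled by the maximum
observed mismatch so every single-trait matrix spans [0, 1] (the gawdis
convention).

For the combined matrix, traits are organised into five functional groups —
nesting habits, body size, phenology, diet, habitat — and weighted so each
*group* contributes equally regardless of how many correlated traits it
contains: a group weight (default 1/6) is split evenly among the group's
member traits, which reproduces the published per-trait weighting scheme
(1-trait habitat group 0.167; 3-trait body-size group 0.0556 per trait;
6-trait phenology group 0.0278 per trait).  The combined distance is the
weighted mean of single-trait distances over the traits defined for each
pair, renormalised by the sum of their weights, so the overall scale of the
weights is immaterial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .matrices import DistanceMatrix

logger = logging.getLogger("traitsync.traits")

__all__ = [
    "TraitTable",
    "TraitGrouping",
    "read_traits",
    "single_trait_distance",
    "group_weights",
    "combined_trait_distance",
]

_TYPES = {"binary", "continuous"}


@dataclass
class TraitTable:
    """Species x trait-dimension values; NaN marks missing data.

    Binary dimensions contain only {0, 1, NaN}; continuous dimensions any
    real.  A species with every dimension missing carries no information and
    is rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise InvalidArgumentError("duplicate species in trait table")
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            raise InvalidArgumentError(
                f"species with all trait dimensions missing: {list(self.data.index[all_missing])}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def restrict(self, species) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise InvalidArgumentError(f"species absent from trait table: {missing}")
        return TraitTable(self.data.loc[list(species)])

    def to_csv(self, path) -> None:
        self.data.rename_axis("species").to_csv(path)


@dataclass
class TraitGrouping:
    """Dimension -> trait -> group mapping with per-trait types and weights.

    ``meta`` has one row per dimension with columns ``dimension``, ``trait``,
    ``group``, ``type``; every dimension belongs to exactly one trait and
    every trait to exactly one group.
    """

    meta: pd.DataFrame
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"dimension", "trait", "group", "type"}
        if not required.issubset(self.meta.columns):
            raise InvalidArgumentError(
                f"trait metadata needs columns {sorted(required)}, got {list(self.meta.columns)}"
            )
        self.meta = self.meta.copy()
        if self.meta["dimension"].duplicated().any():
            raise InvalidArgumentError("a dimension may belong to only one trait")
        bad = set(self.meta["type"]) - _TYPES
        if bad:
            raise InvalidArgumentError(f"unknown trait type(s): {sorted(bad)}")
        per_trait = self.meta.groupby("trait")[["group", "type"]].nunique()
        if (per_trait > 1).any().any():
            raise InvalidArgumentError("a trait must have a single group and type")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.meta["trait"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.meta["group"]))

    def dimensions_of(self, trait: str) -> list[str]:
        dims = self.meta.loc[self.meta["trait"] == trait, "dimension"].tolist()
        if not dims:
            raise InvalidArgumentError(f"unknown trait {trait!r}")
        return dims

    def type_of(self, trait: str) -> str:
        return str(self.meta.loc[self.meta["trait"] == trait, "type"].iloc[0])

    def group_of(self, trait: str) -> str:
        return str(self.meta.loc[self.meta["trait"] == trait, "group"].iloc[0])

    def traits_in(self, group: str) -> list[str]:
        sub = self.meta.loc[self.meta["group"] == group, "trait"]
        if sub.empty:
            raise InvalidArgumentError(f"unknown or empty group {group!r}")
        return list(dict.fromkeys(sub))

    def to_csv(self, path) -> None:
        out = self.meta.copy()
        if self.weights:
            out["weight"] = out["trait"].map(self.weights)
        out.to_csv(path, index=False)


def read_traits(traits_path: str | Path, meta_path: str | Path) -> tuple[TraitTable, TraitGrouping]:
    """Read a species x dimension CSV plus its dimension metadata CSV."""
    df = pd.read_csv(traits_path, index_col="species")
    meta = pd.read_csv(meta_path)
    grouping = TraitGrouping(meta)
    known = set(meta["dimension"])
    extra = [c for c in df.columns if c not in known]
    if extra:
        raise FormatError(f"{traits_path}: dimensions missing from metadata: {extra}")
    absent = [d for d in known if d not in df.columns]
    if absent:
        raise FormatError(f"{traits_path}: metadata dimensions absent from table: {absent}")
    for trait in grouping.traits:
        if grouping.type_of(trait) == "binary":
            vals = df[grouping.dimensions_of(trait)].to_numpy(dtype=float)
            ok = np.isnan(vals) | (vals == 0) | (vals == 1)
            if not ok.all():
                raise FormatError(f"{traits_path}: non-binary value in binary trait {trait!r}")
    return TraitTable(df), grouping


def single_trait_distance(
    table: TraitTable, grouping: TraitGrouping, trait_id: str
) -> DistanceMatrix:
    """Gower distance matrix for one trait.

    Continuous: ``|x_i - x_j| / range(x)`` with the range taken over the
    included species (all-equal values give distance 0 with a warning).
    Multi-dimension binary: mean mismatch over mutually non-missing
    dimensions, rescaled by the maximum observed value so the trait spans
    [0, 1]; pairs sharing no observed dimension are undefined (NaN).
    """
    dims = grouping.dimensions_of(trait_id)
    ttype = grouping.type_of(trait_id)
    X = table.data[dims].to_numpy(dtype=float)
    n = X.shape[0]
    species = table.species
    n_obs_per_species = (~np.isnan(X)).sum(axis=1)
    if (n_obs_per_species > 0).sum() < 2:
        raise InvalidArgumentError(f"trait {trait_id!r}: fewer than 2 species with data")

    if ttype == "continuous":
        # Per-dimension range scaling; nearly always a single dimension.
        D = np.zeros((n, n))
        W = np.zeros((n, n))
        for k in range(dims.__len__()):
            x = X[:, k]
            obs = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if obs.any() else np.nan
            diff = np.abs(x[:, None] - x[None, :])
            if not np.isfinite(rng) or rng == 0:
                logger.warning("trait %s: zero range, distances set to 0", trait_id)
                diff = np.where(np.isnan(diff), np.nan, 0.0)
            else:
                diff = diff / rng
            ok = ~np.isnan(diff)
            D += np.where(ok, diff, 0.0)
            W += ok
        with np.errstate(invalid="ignore", divide="ignore"):
            D = D / W
    elif ttype == "binary":
        valid = ~np.isnan(X)
        Xz = np.where(valid, X, 0.0)
        V = valid.astype(float)
        shared = V @ V.T
        # binary mismatch |x_i - x_j| = x_i + x_j - 2 x_i x_j, summed over shared dims
        mism = (Xz @ V.T) + (V @ Xz.T) - 2.0 * (Xz @ Xz.T)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(shared > 0, mism / np.maximum(shared, 1), np.nan)
        off = ~np.eye(n, dtype=bool)
        dmax = np.nanmax(D[off]) if np.any(~np.isnan(D[off])) else np.nan
        if np.isfinite(dmax) and dmax > 0:
            D = D / dmax
    else:  # pragma: no cover - grouping validation blocks this
        raise InvalidArgumentError(f"unknown trait type {ttype!r}")

    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(species, D, name=f"gower:{trait_id}")


def group_weights(grouping: TraitGrouping, group_weight: float = 1.0 / 6.0) -> dict[str, float]:
    """Per-trait weights giving each trait group an equal total weight.

    Each group receives ``group_weight`` split evenly among its member
    traits; only relative weights matter after the combined-distance
    renormalisation, so the default 1/6 is kept for agreement with the
    published per-trait values.
    """
    if group_weight <= 0:
        raise InvalidArgumentError("group_weight must be positive")
    weights: dict[str, float] = {}
    for group in grouping.groups:
        members = grouping.traits_in(group)
        if not members:
            raise InvalidArgumentError(f"empty trait group {group!r}")
        for trait in members:
            weights[trait] = group_weight / len(members)
    return weights


def combined_trait_distance(
    table: TraitTable,
    grouping: TraitGrouping,
    weights: Mapping[str, float] | None = None,
) -> DistanceMatrix:
    """Weighted-mean Gower distance across all traits.

    ``D_ij = sum_t w_t d_ij(t) / sum_t w_t`` over the traits *defined* for
    the pair (pairwise deletion with weight renormalisation); a pair with no
    defined trait is undefined.
    """
    if weights is None:
        weights = group_weights(grouping)
    missing = [t for t in grouping.traits if t not in weights]
    if missing:
        raise InvalidArgumentError(f"weights missing for traits: {missing}")
    n = len(table.species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in grouping.traits:
        w = float(weights[trait])
        if w < 0:
            raise InvalidArgumentError(f"negative weight for trait {trait!r}")
        if w == 0:
            continue
        d = single_trait_distance(table, grouping, trait).values
        ok = ~np.isnan(d)
        num += np.where(ok, w * d, 0.0)
        den += np.where(ok, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    undefined = int(np.isnan(D[~np.eye(n, dtype=bool)]).sum() // 2)
    if undefined:
        logger.info("combined distance: %d pair(s) with no defined trait", undefined)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(table.species, D, name="gower:combined")
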