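"""Gower distances and equal-group-contribution weighting."""

import numpy as np
import pandas as pd
import pytest

from traitsync import (
    InvalidArgumentError,
    TraitGrouping,
    TraitTable,
    combined_trait_distance,
    group_weights,
    single_trait_distance,
)


def brute_force_gower(data: pd.DataFrame, meta: pd.DataFrame, weights: dict) -> np.ndarray:
    """Independent double-loop Gower oracle (single-trait + weighted combine)."""
    species = list(data.index)
    n = len(species)
    traits = list(dict.fromkeys(meta["trait"]))
    per_trait = {}
    for t in traits:
        dims = meta.loc[meta["trait"] == t, "dimension"].tolist()
        ttype = meta.loc[meta["trait"] == t, "type"].iloc[0]
        d = np.full((n, n), np.nan)
        if ttype == "continuous":
            for k in dims:
                x = data[k].to_numpy(float)
                rng_ = np.nanmax(x) - np.nanmin(x)
                for i in range(n):
                    for j in range(n):
                        if np.isnan(x[i]) or np.isnan(x[j]):
                            continue
                        val = 0.0 if rng_ == 0 else abs(x[i] - x[j]) / rng_
                        d[i, j] = val if np.isnan(d[i, j]) else d[i, j] + val
                # mean over dims handled implicitly for 1-dim traits
        else:
            for i in range(n):
                for j in range(n):
                    vals = []
                    for k in dims:
                        xi, xj = data.at[species[i], k], data.at[species[j], k]
                        if np.isnan(xi) or np.isnan(xj):
                            continue
                        vals.append(abs(xi - xj))
                    if vals:
                        d[i, j] = np.mean(vals)
            off = ~np.eye(n, dtype=bool)
            dmax = np.nanmax(d[off]) if np.any(~np.isnan(d[off])) else np.nan
            if np.isfinite(dmax) and dmax > 0:
                d = d / dmax
        np.fill_diagonal(d, 0.0)
        per_trait[t] = d
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for t, d in per_trait.items():
        ok = ~np.isnan(d)
        num += np.where(ok, weights[t] * d, 0.0)
        den += np.where(ok, weights[t], 0.0)
    with np.errstate(invalid="ignore"):
        D = num / den
    np.fill_diagonal(D, 0.0)
    return per_trait, D


class TestGroupWeights:
    def test_published_weight_scheme(self, table1_grouping):
        """1/6 per group split among members reproduces the printed weights."""
        w = group_weights(table1_grouping)
        assert round(w["H"], 3) == 0.167          # habitat: single-trait group
        assert round(w["PH"], 3) == 0.167         # nesting: single-trait group
        for t in ("FMI", "FMA", "EDM"):           # body size: three traits
            assert round(w[t], 4) == 0.0556
        for t in ("V", "ES", "PS", "LS", "AS", "OS"):  # phenology: six traits
            assert round(w[t], 4) == 0.0278
        for t in ("HN", "HS", "HC"):              # diet: three traits
            assert round(w[t], 4) == 0.0556

    def test_bad_group_weight_rejected(self, table1_grouping):
        with pytest.raises(InvalidArgumentError):
            group_weights(table1_grouping, group_weight=0.0)


class TestSingleTraitDistance:
    def test_binary_mismatch_rescaled_to_observed_max(self, small_trait_table):
        """(1,0,...) vs (0,1,...) mismatch 2/8 = 0.25 is the max -> rescaled to 1."""
        table, grouping = small_trait_table
        D = single_trait_distance(table, grouping, "H")
        assert D.get("spA", "spB") == pytest.approx(1.0)
        assert D.get("spA", "spC") == pytest.approx(0.0)   # identical vectors
        assert D.get("spB", "spC") == pytest.approx(1.0)

    def test_continuous_range_endpoints(self, small_trait_table):
        table, grouping = small_trait_table
        D = single_trait_distance(table, grouping, "FMA")
        assert D.get("spA", "spB") == pytest.approx(1.0)   # 10 vs 20 over range [10, 20]
        assert D.get("spA", "spC") == pytest.approx(0.5)

    def test_zero_range_warns_and_zeroes(self, small_trait_table, caplog):
        table, grouping = small_trait_table
        flat = TraitTable(table.data.assign(FMA=12.0))
        with caplog.at_level("WARNING", logger="traitsync.traits"):
            D = single_trait_distance(flat, grouping, "FMA")
        assert np.allclose(D.values, 0.0)
        assert "zero range" in caplog.text

    def test_unknown_trait_rejected(self, small_trait_table):
        table, grouping = small_trait_table
        with pytest.raises(InvalidArgumentError, match="unknown trait"):
            single_trait_distance(table, grouping, "nope")

    def test_pair_with_no_shared_dimension_undefined(self):
        meta = pd.DataFrame(
            [{"dimension": f"B_{k}", "trait": "B", "group": "g", "type": "binary"}
             for k in (1, 2)]
        )
        data = pd.DataFrame(
            {"B_1": [1.0, np.nan, 1.0], "B_2": [np.nan, 0.0, 1.0]},
            index=["x", "y", "z"],
        )
        D = single_trait_distance(TraitTable(data), TraitGrouping(meta), "B")
        assert np.isnan(D.get("x", "y"))
        assert not np.isnan(D.get("x", "z"))


class TestCombinedDistance:
    def test_weighted_mean_arithmetic(self):
        """Two traits, weights (0.167, 0.0278), distances (0, 1) -> 0.0278/0.1948."""
        meta = pd.DataFrame(
            [
                {"dimension": "A", "trait": "A", "group": "g1", "type": "continuous"},
                {"dimension": "B", "trait": "B", "group": "g2", "type": "continuous"},
            ]
        )
        # trait A identical (distance 0), trait B at range endpoints (distance 1)
        data = pd.DataFrame({"A": [5.0, 5.0], "B": [0.0, 1.0]}, index=["x", "y"])
        D = combined_trait_distance(
            TraitTable(data), TraitGrouping(meta), {"A": 0.167, "B": 0.0278}
        )
        assert D.get("x", "y") == pytest.approx(0.0278 / (0.167 + 0.0278), rel=1e-9)

    def test_all_zero_and_all_one_limits(self, rng):
        meta = pd.DataFrame(
            [
                {"dimension": "A", "trait": "A", "group": "g1", "type": "continuous"},
                {"dimension": "B", "trait": "B", "group": "g2", "type": "continuous"},
            ]
        )
        same = pd.DataFrame({"A": [1.0, 1.0], "B": [2.0, 2.0]}, index=["x", "y"])
        D0 = combined_trait_distance(TraitTable(same), TraitGrouping(meta),
                                     {"A": 0.7, "B": 0.1})
        assert D0.get("x", "y") == 0.0
        ends = pd.DataFrame({"A": [0.0, 1.0], "B": [5.0, 9.0]}, index=["x", "y"])
        D1 = combined_trait_distance(TraitTable(ends), TraitGrouping(meta),
                                     {"A": 0.7, "B": 0.1})
        assert D1.get("x", "y") == pytest.approx(1.0)

    def test_agrees_with_bruteforce_oracle(self, rng, table1_grouping):
        """Vectorised implementation == double-loop oracle on a 10-species table."""
        meta = table1_grouping.meta
        species = [f"s{i:02d}" for i in range(10)]
        cols = {}
        for _, row in meta.iterrows():
            if row["type"] == "binary":
                col = rng.integers(0, 2, size=10).astype(float)
            else:
                col = rng.normal(10, 3, size=10)
            col[rng.random(10) < 0.1] = np.nan
            cols[row["dimension"]] = col
        data = pd.DataFrame(cols, index=species)
        data.iloc[0, :] = np.where(np.isnan(data.iloc[0, :]), 1.0, data.iloc[0, :])
        table = TraitTable(data)
        weights = group_weights(table1_grouping)
        per_trait, D_oracle = brute_force_gower(data, meta, weights)
        for t in table1_grouping.traits:
            got = single_trait_distance(table, table1_grouping, t).values
            np.testing.assert_allclose(got, per_trait[t], atol=1e-12, equal_nan=True)
        got_combined = combined_trait_distance(table, table1_grouping, weights).values
        np.testing.assert_allclose(got_combined, D_oracle, atol=1e-12, equal_nan=True)

    def test_convex_combination_bounds(self, rng, table1_grouping):
        """Combined distance lies within [min, max] of the single-trait distances."""
        species = [f"s{i:02d}" for i in range(8)]
        cols = {}
        for _, row in table1_grouping.meta.iterrows():
            cols[row["dimension"]] = (
                rng.integers(0, 2, 8).astype(float)
                if row["type"] == "binary"
                else rng.normal(0, 1, 8)
            )
        table = TraitTable(pd.DataFrame(cols, index=species))
        singles = np.stack(
            [single_trait_distance(table, table1_grouping, t).values
             for t in table1_grouping.traits]
        )
        combined = combined_trait_distance(table, table1_grouping).values
        assert np.all(combined <= np.nanmax(singles, axis=0) + 1e-12)
        assert np.all(combined >= np.nanmin(singles, axis=0) - 1e-12)
        assert np.all((combined >= 0) & (combined <= 1))

    def test_balanced_groups_contribute_equally(self, rng):
        """With one comparably-dispersed trait per group, each group's distance
        matrix correlates with the combined matrix to within 0.1 of the others."""
        n = 40
        groups = ["g1", "g2", "g3", "g4", "g5"]
        meta = pd.DataFrame(
            [{"dimension": f"{g}_{k}", "trait": g, "group": g, "type": "binary"}
             for g in groups for k in range(6)]
        )
        data = pd.DataFrame(
            {f"{g}_{k}": rng.integers(0, 2, n).astype(float)
             for g in groups for k in range(6)},
            index=[f"s{i:02d}" for i in range(n)],
        )
        table = TraitTable(data)
        grouping = TraitGrouping(meta)
        combined = combined_trait_distance(table, grouping).triangle()
        cors = []
        for g in groups:
            tri = single_trait_distance(table, grouping, g).triangle()
            cors.append(np.corrcoef(tri, combined)[0, 1])
        assert max(cors) - min(cors) < 0.1

    def test_all_missing_species_rejected(self):
        with pytest.raises(InvalidArgumentError, match="all trait dimensions missing"):
            TraitTable(pd.DataFrame({"A": [1.0, np.nan]}, index=["x", "y"]))
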