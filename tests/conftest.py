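import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from traitsync import AbundancePanel, DistanceMatrix, TraitGrouping, TraitTable


def euclidean_dm(rng: np.random.Generator, n: int, name: str = "", dim: int = 3) -> DistanceMatrix:
    """Distance matrix of iid Gaussian points (a generic non-degenerate input)."""
    pts = rng.standard_normal((n, dim))
    labels = [f"s{i:02d}" for i in range(n)]
    return DistanceMatrix(labels, squareform(pdist(pts)), name=name)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240131)


@pytest.fixture
def toy_panel() -> AbundancePanel:
    """Three species, five years, one gap."""
    data = pd.DataFrame(
        {
            2001: [2.0, 1.5, 3.0],
            2002: [2.3, np.nan, 3.1],
            2003: [2.1, 2.4, 2.9],
            2004: [2.6, 2.2, 3.3],
            2005: [2.4, 2.5, 3.0],
        },
        index=["spA", "spB", "spC"],
    )
    return AbundancePanel(data)


@pytest.fixture
def table1_grouping() -> TraitGrouping:
    """The five-group/fourteen-trait scheme of the published weighting table."""
    rows = []
    scheme = [
        ("PH", "nesting", "binary", 8),
        ("FMI", "body size", "continuous", 1),
        ("FMA", "body size", "continuous", 1),
        ("EDM", "body size", "continuous", 1),
        ("V", "phenology", "binary", 3),
        ("ES", "phenology", "binary", 12),
        ("PS", "phenology", "binary", 12),
        ("LS", "phenology", "binary", 12),
        ("AS", "phenology", "binary", 12),
        ("OS", "phenology", "binary", 4),
        ("HN", "diet", "continuous", 1),
        ("HS", "diet", "binary", 4),
        ("HC", "diet", "binary", 18),
        ("H", "habitat", "binary", 8),
    ]
    for trait, group, ttype, ndim in scheme:
        dims = [trait] if ndim == 1 else [f"{trait}_{k+1}" for k in range(ndim)]
        for d in dims:
            rows.append({"dimension": d, "trait": trait, "group": group, "type": ttype})
    return TraitGrouping(pd.DataFrame(rows))


@pytest.fixture
def small_trait_table() -> tuple[TraitTable, TraitGrouping]:
    """Three species, one 8-dim binary habitat trait and one continuous trait."""
    meta = pd.DataFrame(
        [{"dimension": f"H_{k+1}", "trait": "H", "group": "habitat", "type": "binary"}
         for k in range(8)]
        + [{"dimension": "FMA", "trait": "FMA", "group": "body size", "type": "continuous"}]
    )
    habitat = np.zeros((3, 8))
    habitat[0, 0] = 1  # spA: first habitat only
    habitat[1, 1] = 1  # spB: second habitat only
    habitat[2, 0] = 1  # spC: same as spA
    data = pd.DataFrame(
        {f"H_{k+1}": habitat[:, k] for k in range(8)} | {"FMA": [10.0, 20.0, 15.0]},
        index=["spA", "spB", "spC"],
    )
    return TraitTable(data), TraitGrouping(meta)
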