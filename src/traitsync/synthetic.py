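"""Synthetic phylogenies, traits and abundance panels with known ground truth.

The generative model mirrors the statistical structure the downstream
analysis assumes:

1. A pure-birth (Yule) tree supplies the phylogeny.
2. Traits evolve on that tree — continuous traits by Brownian motion,
   binary dimensions by a symmetric two-state Mk process — so trait
   distance carries phylogenetic signal, as real life-history traits do.
3. Each year t, a small number of shared environmental drivers take iid
   standard-normal values e_{t,d}.  Species i responds through a loading
   vector

       w_i = beta * g(traits_i) + (1 - beta) * u_i,

   where g is a fixed deterministic map from trait dimensions to driver
   loadings (documented below) and u_i is iid standard-normal species
   noise.  beta in [0, 1] controls how strongly traits determine the
   response: beta = 0 severs the trait-asynchrony link entirely (the null),
   large beta makes similar species respond similarly (synchronously).
4. The interannual change is Delta_{i,t} = w_i . e_t + eps_{i,t} with
   eps ~ N(0, sigma^2); the published-index analogue is the cumulative sum
   of changes on top of a species baseline, with a fraction of
   (species, year) cells deleted completely at random.

Because changes are jointly Gaussian, the population Pearson correlation of
two species' change series has the closed form

    corr_ij = (w_i . w_j) / sqrt((|w_i|^2 + sigma^2)(|w_j|^2 + sigma^2)),

so the *expected* asynchrony matrix M = (1 - corr)/2 is known analytically
and serves as the oracle for parameter-recovery tests.

The trait->loading map g: trait dimensions are enumerated in table order
and dimension k is assigned to driver k mod n_drivers.  A continuous
dimension contributes its z-scored value to its driver; a binary dimension
contributes +1/-1 (state 1/0).  Each driver's summed loading is then
z-scored across species so g and the unit-normal noise loadings u are on
the same scale.  The map is monotone: species with more similar traits get
more similar loadings, hence more synchronous dynamics.

All randomness derives from one root seed via named ``SeedSequence``
streams, so each stage (tree / traits / loadings / weather / missingness)
is independently reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .matrices import DistanceMatrix
from .phylo import PhyloTree
from .traits import TraitGrouping, TraitTable

__all__ = [
    "TraitSpec",
    "SimConfig",
    "GroundTruth",
    "default_trait_spec",
    "simulate_tree",
    "simulate_traits",
    "simulate_abundance",
    "expected_asynchrony",
    "simulate_dataset",
]


@dataclass(frozen=True)
class TraitSpec:
    """One trait to evolve: id, functional group, coding and rate.

    ``rate`` is the Brownian-motion variance per unit branch length for
    continuous traits, or the per-unit-length Mk flip rate for binary
    dimensions.
    """

    trait_id: str
    group: str
    type: str  # "binary" | "continuous"
    n_dimensions: int = 1
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in {"binary", "continuous"}:
            raise InvalidArgumentError(f"unknown trait type {self.type!r}")
        if self.n_dimensions < 1:
            raise InvalidArgumentError("n_dimensions must be >= 1")
        if self.rate < 0:
            raise InvalidArgumentError("evolution rate must be >= 0")


def default_trait_spec() -> list[TraitSpec]:
    """Trait scheme emulating the published mixed binary/continuous tables.

    Five functional groups — nesting, body size, phenology, diet, habitat —
    with the published dimension counts: monthly life-stage windows (12
    binary dimensions each), multi-category habitat/nesting/hostplant
    codings, and continuous size/mass measurements.
    """
    return [
        TraitSpec("PH", "nesting", "binary", 8, 0.5),
        TraitSpec("FMI", "body size", "continuous", 1, 1.0),
        TraitSpec("FMA", "body size", "continuous", 1, 1.0),
        TraitSpec("EDM", "body size", "continuous", 1, 1.0),
        TraitSpec("V", "phenology", "binary", 3, 0.5),
        TraitSpec("ES", "phenology", "binary", 12, 0.5),
        TraitSpec("PS", "phenology", "binary", 12, 0.5),
        TraitSpec("LS", "phenology", "binary", 12, 0.5),
        TraitSpec("AS", "phenology", "binary", 12, 0.5),
        TraitSpec("OS", "phenology", "binary", 4, 0.5),
        TraitSpec("HN", "diet", "continuous", 1, 1.0),
        TraitSpec("HS", "diet", "binary", 4, 0.5),
        TraitSpec("HC", "diet", "binary", 18, 0.5),
        TraitSpec("H", "habitat", "binary", 8, 0.5),
    ]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults match the parameter-recovery conditions exercised throughout
    the test suite: a 60-species community observed for 40 years, three
    shared environmental drivers, trait effect beta = 0.8, change noise
    sigma = 0.5 and 5% of cells missing at random.
    """

    n_species: int = 60
    n_years: int = 40
    n_drivers: int = 3
    beta: float = 0.8
    noise_sd: float = 0.5
    birth_rate: float = 1.0
    trait_spec: list[TraitSpec] = field(default_factory=default_trait_spec)
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise InvalidArgumentError("n_species must be >= 3")
        if self.n_years < 3:
            raise InvalidArgumentError("n_years must be >= 3")
        if self.n_drivers < 1:
            raise InvalidArgumentError("n_drivers must be >= 1")
        if self.beta < 0:
            raise InvalidArgumentError("beta must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be > 0")
        if not (0 <= self.missing_fraction < 1):
            raise InvalidArgumentError("missing_fraction must be in [0, 1)")
        if self.birth_rate <= 0:
            raise InvalidArgumentError("birth_rate must be > 0")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    loadings: pd.DataFrame            # species x driver loading matrix w
    expected_asynchrony: DistanceMatrix
    trait_table: TraitTable
    tree: PhyloTree


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named per-stage stream derived from the root seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "big") % (2**31)])
    return np.random.default_rng(ss)


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree with tips sp001..spN."""
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    if birth_rate <= 0:
        raise InvalidArgumentError("birth_rate must be > 0")
    stage = _stage_rng(seed, "tree")
    rng = random.Random(int(stage.integers(2**31)))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    # The process stops at the n-th speciation, leaving a zero-length cherry;
    # run the clock on for the waiting time to the (unrealised) next event so
    # every terminal branch is positive.  The tree stays ultrametric.
    extra = stage.exponential(1.0 / (n_species * birth_rate))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = max(3, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return PhyloTree(tree)


def _dimension_columns(spec: TraitSpec) -> list[str]:
    if spec.n_dimensions == 1:
        return [spec.trait_id]
    return [f"{spec.trait_id}_{k + 1}" for k in range(spec.n_dimensions)]


def simulate_traits(
    tree: PhyloTree, trait_spec: list[TraitSpec], seed: int = 0
) -> tuple[TraitTable, TraitGrouping]:
    """Evolve traits along the tree.

    Continuous dimensions follow Brownian motion from a root value of 0
    with variance ``rate`` per unit branch length; binary dimensions follow
    a symmetric two-state Mk process with flip rate ``rate`` and a uniform
    root state, giving flip probability (1 - exp(-2*rate*L))/2 along a
    branch of length L.  Closer tips are therefore more similar in
    expectation (phylogenetic signal).
    """
    if not trait_spec:
        raise InvalidArgumentError("trait_spec must be non-empty")
    rng = _stage_rng(seed, "traits")
    nodes = list(tree.tree.preorder_node_iter())
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    tip_labels = []
    for spec in trait_spec:
        for dim_name in _dimension_columns(spec):
            states: dict[int, float] = {}
            for node in nodes:
                if node.parent_node is None:
                    if spec.type == "continuous":
                        states[id(node)] = 0.0
                    else:
                        states[id(node)] = float(rng.integers(2))
                    continue
                parent = states[id(node.parent_node)]
                length = node.edge.length or 0.0
                if spec.type == "continuous":
                    states[id(node)] = parent + rng.normal(
                        0.0, np.sqrt(spec.rate * length)
                    )
                else:
                    p_flip = 0.5 * (1.0 - np.exp(-2.0 * spec.rate * length))
                    flip = rng.random() < p_flip
                    states[id(node)] = 1.0 - parent if flip else parent
            tip_values = {
                leaf.taxon.label: states[id(leaf)]
                for leaf in tree.tree.leaf_node_iter()
            }
            columns[dim_name] = tip_values
            meta_rows.append(
                {
                    "dimension": dim_name,
                    "trait": spec.trait_id,
                    "group": spec.group,
                    "type": spec.type,
                }
            )
    tip_labels = sorted(tree.tip_labels)
    data = pd.DataFrame(
        {name: [vals[t] for t in tip_labels] for name, vals in columns.items()},
        index=tip_labels,
    )
    return TraitTable(data), TraitGrouping(pd.DataFrame(meta_rows))


def _trait_loading_map(table: TraitTable, grouping: TraitGrouping, n_drivers: int) -> np.ndarray:
    """Deterministic map g from trait dimensions to species x driver loadings."""
    X = table.data.to_numpy(dtype=float)
    n, k = X.shape
    types = dict(zip(grouping.meta["dimension"], grouping.meta["type"]))
    G = np.zeros((n, n_drivers))
    for j, dim in enumerate(table.data.columns):
        x = X[:, j].copy()
        x = np.where(np.isnan(x), np.nanmean(x) if np.any(~np.isnan(x)) else 0.0, x)
        if types[dim] == "continuous":
            sd = x.std()
            contrib = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        else:
            contrib = 2.0 * x - 1.0
        G[:, j % n_drivers] += contrib
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    return (G - G.mean(axis=0)) / sd


def expected_asynchrony(loadings: np.ndarray, noise_sd: float, labels=None) -> DistanceMatrix:
    """Analytic expected asynchrony M from loadings and change-noise SD.

    corr_ij = (w_i . w_j)/sqrt((|w_i|^2 + sigma^2)(|w_j|^2 + sigma^2));
    M = (1 - corr)/2, diagonal forced to 0.
    """
    if noise_sd <= 0:
        raise InvalidArgumentError("noise_sd must be > 0")
    W = np.asarray(loadings, dtype=float)
    gram = W @ W.T
    scale = np.sqrt(np.diag(gram) + noise_sd**2)
    corr = gram / np.outer(scale, scale)
    M = (1.0 - np.clip(corr, -1.0, 1.0)) / 2.0
    np.fill_diagonal(M, 0.0)
    M = (M + M.T) / 2.0
    if labels is None:
        labels = [f"sp{i + 1:03d}" for i in range(W.shape[0])]
    return DistanceMatrix(list(labels), M, name="expected-asynchrony")


def simulate_abundance(
    traits: TraitTable, cfg: SimConfig, grouping: TraitGrouping | None = None
):
    """Trait-driven abundance panel plus its generating ground truth.

    Returns ``(AbundancePanel, GroundTruth)``.  See the module docstring
    for the generative model.  ``grouping`` is needed to distinguish binary
    from continuous dimensions in the trait->loading map; omitted, all
    dimensions are treated as continuous z-scores.
    """
    from .abundance import AbundancePanel  # local import to avoid cycle

    species = traits.species
    n = len(species)
    if n != cfg.n_species:
        cfg = SimConfig(**{**cfg.__dict__, "n_species": n})
    if grouping is None:
        meta = pd.DataFrame(
            {
                "dimension": traits.data.columns,
                "trait": traits.data.columns,
                "group": "all",
                "type": "continuous",
            }
        )
        grouping = TraitGrouping(meta)

    G = _trait_loading_map(traits, grouping, cfg.n_drivers)
    rng_load = _stage_rng(cfg.seed, "loadings")
    U = rng_load.standard_normal((n, cfg.n_drivers))
    W = cfg.beta * G + (1.0 - cfg.beta) * U

    rng_env = _stage_rng(cfg.seed, "weather")
    E = rng_env.standard_normal((cfg.n_years - 1, cfg.n_drivers))
    eps = rng_env.normal(0.0, cfg.noise_sd, size=(n, cfg.n_years - 1))
    deltas = W @ E.T + eps  # species x (n_years - 1)

    baselines = rng_load.normal(2.0, 0.5, size=n)
    index = np.concatenate(
        [baselines[:, None], baselines[:, None] + np.cumsum(deltas, axis=1)], axis=1
    )

    if cfg.missing_fraction > 0:
        rng_miss = _stage_rng(cfg.seed, "missing")
        mask = rng_miss.random(index.shape) < cfg.missing_fraction
        index = np.where(mask, np.nan, index)

    years = list(range(2000, 2000 + cfg.n_years))
    panel = AbundancePanel(pd.DataFrame(index, index=species, columns=years))
    truth = GroundTruth(
        loadings=pd.DataFrame(W, index=species, columns=[f"driver{d+1}" for d in range(cfg.n_drivers)]),
        expected_asynchrony=expected_asynchrony(W, cfg.noise_sd, labels=species),
        trait_table=traits,
        tree=None,  # filled by simulate_dataset when a tree exists
    )
    return panel, truth


def simulate_confounded_dataset(
    n_species: int = 60,
    n_years: int = 300,
    seed: int = 0,
    hidden_dims: int = 3,
    beta: float = 0.95,
    noise_sd: float = 0.5,
    birth_rate: float = 1.0,
):
    """Phylogeny-confounded study for exercising the partial Mantel test.

    Abundance dynamics are driven *only* by an unobserved trait evolved by
    Brownian motion on the tree; a second, "measured" trait evolves neutrally
    on the same tree and never enters the abundance model.  Any association
    between measured-trait distance and asynchrony therefore flows entirely
    through shared ancestry, and partialling out patristic distance should
    pull the Mantel r toward zero.

    Returns ``(tree, traits, grouping, panel)`` where ``traits`` contains
    both the hidden and the measured trait (trait ids "hidden", "measured").
    """
    tree = simulate_tree(n_species, birth_rate, seed=seed)
    spec = [
        TraitSpec("hidden", "hidden", "continuous", hidden_dims, 1.0),
        TraitSpec("measured", "measured", "continuous", 1, 1.0),
    ]
    traits, grouping = simulate_traits(tree, spec, seed=seed)
    hidden_cols = [c for c in traits.data.columns if c.startswith("hidden")]
    hidden_tbl = TraitTable(traits.data[hidden_cols])
    cfg = SimConfig(
        n_species=n_species, n_years=n_years, n_drivers=hidden_dims,
        beta=beta, noise_sd=noise_sd, missing_fraction=0.0, seed=seed,
    )
    panel, _ = simulate_abundance(hidden_tbl, cfg)
    return tree, traits, grouping, panel


def simulate_dataset(cfg: SimConfig):
    """Full synthetic study: tree, traits, grouping, panel and ground truth."""
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=cfg.seed)
    traits, grouping = simulate_traits(tree, cfg.trait_spec, seed=cfg.seed)
    panel, truth = simulate_abundance(traits, cfg, grouping=grouping)
    truth.tree = tree
    return tree, traits, grouping, panel, truth


def write_dataset(outdir: str | Path, cfg: SimConfig) -> None:
    """Simulate and write panel/traits/metadata/tree/ground-truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, traits, grouping, panel, truth = simulate_dataset(cfg)
    panel.to_csv(outdir / "panel.csv")
    traits.to_csv(outdir / "traits.csv")
    grouping.to_csv(outdir / "trait_meta.csv")
    tree.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    truth.loadings.rename_axis("species").to_csv(outdir / "loadings.csv")
    truth.expected_asynchrony.to_csv(outdir / "expected_asynchrony.csv")
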