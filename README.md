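# traitsync

Tools for asking whether species with different functional traits have
*asynchronous* population dynamics — the pattern that underpins the
stabilising effect of trait diversity in ecological communities.  The
package is built for analyses of insect monitoring data (butterfly,
macro-moth and bumblebee schemes publish annual collated abundance indices
per species), but any long-format species × year index table works.

## What it computes

**Abundance asynchrony.** For each species, the collated annual index
(standardised log₁₀ abundance) is differenced across consecutive years to
give interannual changes Δᵢₜ. For each species pair, with K the Pearson
correlation of the two change series over their shared intervals,

    M = (1 − K) / 2

maps perfect synchrony (K = 1) to 0, independence to 0.5 and perfect
anticorrelation (K = −1) to 1, so asynchrony lives on the same [0, 1] scale
as trait dissimilarity. Pairs with too few shared intervals (default < 5)
are left undefined and excluded pairwise downstream.

**Trait dissimilarity.** Gower distances on mixed trait tables: continuous
traits (forewing length, dry mass, …) as range-normalised absolute
differences; categorical traits coded as multi-column binary dimensions
(e.g. twelve monthly columns for a flight period) as mean mismatch rescaled
to span [0, 1]. A combined matrix weights traits so that each functional
*group* — nesting habits, body size, phenology, diet, habitat — contributes
equally: a group weight of 1/6 is split evenly among a group's traits
(habitat 0.167; body-size traits 0.0556 each; phenology traits 0.0278 each),
and the per-pair weighted mean is renormalised over the traits defined for
that pair.

**Phylogenetic distance.** Patristic (sum of branch lengths) distances from
Newick trees, with species complexes (e.g. *Bombus lucorum/terrestris*)
collapsed to the mean distance over their member tips.

**Inference.** Simple Mantel tests (Pearson r between vectorised lower
triangles; joint row/column permutation of one matrix; one-tailed
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1)) and partial Mantel tests
controlling phylogenetic distance through the first-order partial
correlation r_AB·C. 95% confidence intervals come from subsampling 90% of
species without replacement. An exact enumeration oracle (all n! joint
permutations, n ≤ 8) validates the Monte-Carlo p-values.

**Synthetic data.** A generator produces pure-birth trees, traits evolved on
them (Brownian motion / two-state Mk), and abundance panels whose
year-to-year changes load on shared environmental drivers with
trait-dependent loadings — so the expected asynchrony matrix is known in
closed form and every stage of the pipeline is testable without any data
download. See `docs/methods.md` for the model.

## Worked example

Simulate a 60-species, 40-year community in which traits partly determine
how species respond to shared environmental drivers, then run the full
analysis:

```bash
traitsync simulate --outdir demo --seed 11
cat > demo/config.yaml <<EOF
panel: demo/panel.csv
traits: demo/traits.csv
trait_meta: demo/trait_meta.csv
tree: demo/tree.nwk
outdir: demo/results
n_perm: 10000
n_boot: 1000
seed: 1
trait_list: [H, AS, FMA]
label: demo
EOF
traitsync run-all --config demo/config.yaml
```

which prints:

```
label                trait    test     r_obs  p_one_tailed    ci_low   ci_high  n_species
 demo             combined  simple  0.178765      0.000100  0.150357  0.210097         60
 demo             combined partial  0.164330      0.000100  0.134647  0.194652         60
 demo                    H  simple  0.091562      0.001400  0.059347  0.129016         60
 demo                    H partial  0.083608      0.003100  0.051746  0.120570         60
 demo                   AS  simple  0.020656      0.176082  0.000403  0.047542         60
 demo                   AS partial  0.011185      0.282272 -0.010601  0.033756         60
 demo                  FMA  simple -0.017366      0.828617 -0.032169  0.001466         60
 demo                  FMA partial -0.045755      1.000000 -0.057357 -0.033888         60
 demo phylogeny~asynchrony  simple  0.073376      0.004100  0.040933  0.113914         60
 demo   phylogeny~combined  simple  0.320838      0.000100  0.290480  0.348007         60
```

Read it as: combined-trait dissimilarity is positively associated with
abundance asynchrony (Mantel r ≈ 0.18, one-tailed p = 1/(n_perm+1), the
smallest attainable), and the association survives controlling for
phylogenetic distance (partial r ≈ 0.16) — the expected outcome on data
where trait-driven dynamics are true by construction. Individual traits
vary: habitat use carries signal here, flight period little, forewing
length none. The last two rows test phylogenetic distance itself against
asynchrony and against combined trait distance.

Every stage is also available separately (`traitsync asynchrony`,
`trait-dist`, `phylo-dist`, `mantel`, `experiment-length`) and as library
functions (`traitsync.asynchrony_matrix`, `combined_trait_distance`,
`patristic_matrix`, `mantel`, `partial_mantel`, …).

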