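# Methods

This note documents the statistical models and procedures implemented in
`traitsync`, the design choices that were genuinely open, and what the
synthetic-data tests do and do not establish about real monitoring data.

## Asynchrony from collated indices

Inputs are *collated annual abundance indices*: per-species, scheme-wide
standardised log₁₀ estimates of expected count on a standardised survey.
The pipeline consumes these directly; fitting them from raw counts (the
Generalised Abundance Index) is out of scope. Interannual change is the
first difference of the index across consecutive calendar years; a change
is only defined when both bounding years are observed, never across gaps.
Species with fewer than two observed years are dropped with a warning.

Pairwise asynchrony is

    M_ij = (1 − K_ij) / 2,   K_ij = Pearson corr(Δ_i, Δ_j) over shared intervals.

This maps K = 1 → 0, K = 0 → 0.5, K = −1 → 1, which is the only affine map
of K onto [0, 1] consistent with "0 = completely synchronous, 1 =
completely asynchronous". Correlations are pairwise-complete: the schemes
span different periods, so listwise deletion would discard most data. Pairs
with fewer than `min_overlap` shared intervals (default 5 — a Pearson r on
fewer points is uninformative; configurable) or zero variance in either
change series are undefined (NaN) and excluded pairwise by all downstream
statistics, with counts logged. Indices are assumed to be on the log scale
already; a `log10` switch exists for raw-scale inputs.

## Gower trait dissimilarity

Traits come in two codings. A continuous trait contributes
|x_i − x_j| / range(x), the range taken over the analysis species set (so
distances are relative to the community at hand, per Gower's definition; a
zero range yields all-zero distances with a warning). A categorical trait
is expanded into binary presence/absence *dimensions*; its distance is the
mean mismatch over mutually observed dimensions, rescaled by the maximum
observed value so each single-trait matrix spans [0, 1] (the convention of
the gawdis R package). Pairs sharing no observed dimension are undefined.
Missing data are handled by pairwise deletion at the dimension level with
weight renormalisation — standard Gower practice.

The combined matrix uses fixed *equal-group-contribution* weights: each of
the five functional groups (nesting habits, body size, phenology, diet,
habitat) receives weight 1/6, split evenly among its member traits. This
reproduces the published per-trait weights (0.167 for the single-trait
habitat and nesting groups, 0.0556 for each of three body-size and diet
traits, 0.0278 for each of six phenology traits). Five groups at 1/6 sum
to 5/6 rather than 1, but the combined distance renormalises by the summed
weights of the traits defined for each pair, so only relative weights
matter. The analytic fixed-weight scheme was chosen over gawdis's iterative
contribution-optimisation because the fixed weights are the documented
scheme; the optimisation variant is a possible extension. No log-transform
is applied to mass or length traits by default (a config switch is the
right place for that choice, not a hidden default).

## Patristic distance and species complexes

Patristic distance is the sum of branch lengths on the unique tip-to-tip
path, computed through dendropy from Newick input. Trees must carry branch
lengths on every non-root edge; polytomies are accepted; tip labels are
normalised (trimmed, underscores → spaces) and must be unique. A species
complex is collapsed at the *distance-matrix* level: the complex's distance
to every other species is the arithmetic mean of its members' distances.
(The alternative — pruning the tree and re-deriving — is not what "mean of
the branch lengths between each species and the members" describes.) The
mean can break ultrametricity, so only symmetry, nonnegativity and the zero
diagonal are guaranteed afterwards.

## Mantel inference

The Mantel statistic is the Pearson correlation of the vectorised strict
lower triangles of two matrices aligned to one species ordering; undefined
entries in any participating matrix are excluded pairwise, consistently.
The null distribution permutes rows and columns of the second matrix (B)
jointly. The one-tailed p-value against H₀: r ≤ 0 uses the add-one
convention p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1) (never zero; default
n_perm = 10,000). Permuting B rather than A matches the scientific
question — whether traits could explain asynchrony — though the two choices
are identical in distribution for the simple test.

The partial test computes the first-order partial correlation

    r_AB·C = (r_AB − r_AC·r_BC) / √((1 − r_AC²)(1 − r_BC²)),

permuting B and recomputing r_AB and r_BC each round with r_AC held fixed
(raw-matrix permutation in the Smouse–Long–Sokal style). A
residual-permutation variant (regress the A and B triangles on C, permute
B's residuals) is available via `method="residual"`; the two are
asymptotically similar. |r_AC| = 1 or |r_BC| = 1 raises a collinearity
error rather than dividing by zero.

Confidence intervals (95%) subsample ⌈0.9·n⌉ species *without* replacement
for each of n_boot = 10,000 repeats and take the 2.5th/97.5th percentiles
of the recomputed r. With-replacement resampling was rejected because
duplicated species create artificial zero distances; the subsampling
fraction is exposed. Degenerate repeats are discarded and logged; more than
50% discarded is an error. `n_boot=0` skips the CI (NaN bounds), which
large simulation studies use for speed.

An exact oracle enumerates all n! joint permutations for n ≤ 8 and is used
in tests to calibrate the Monte-Carlo p-value; permutation internals are
vectorised in chunks of 2,000 permutations with NaN-aware row-wise Pearson
computation, so masks follow the permuted matrix correctly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

1. **Tree** — pure-birth (Yule) process conditioned on n tips, via
   dendropy, with the waiting time to the next (unrealised) speciation
   appended to every terminal branch so no branch is zero; the tree stays
   ultrametric.
2. **Traits** — continuous traits evolve by Brownian motion (variance =
   rate × branch length, root value 0); binary dimensions by a symmetric
   two-state Mk process (flip probability (1 − e^{−2qL})/2 on a branch of
   length L, uniform root state). Both give closer tips more similar trait
   values — the phylogenetic signal real life-history traits show. The
   default trait scheme mirrors the published table: five groups, fourteen
   traits, with the published dimension counts (12 monthly columns per life
   stage, 8 habitat classes, …).
3. **Abundance** — each year, d shared environmental drivers take iid
   N(0,1) values e_t. Species i's loading vector is
   w_i = β·g(traits_i) + (1−β)·u_i with u_i iid N(0,1). The map g assigns
   trait dimension k to driver k mod d; a continuous dimension contributes
   its z-score, a binary dimension ±1; each driver's summed loading is then
   z-scored across species so the trait part and the noise part are on the
   same scale, making β ∈ [0,1] an interpretable trait-effect dial (β = 0
   is the exact null). Changes are Δ_{i,t} = w_i·e_t + ε_{i,t},
   ε ~ N(0, σ²); the index is a species baseline (N(2, 0.5), the scale of
   log₁₀ collated indices) plus the cumulative change. Missingness is
   applied completely at random (the testable default; real schemes'
   missingness is certainly not MCAR, which is a stated limitation).

Because changes are jointly Gaussian, the population correlation of two
change series is

    corr_ij = (w_i · w_j) / √((‖w_i‖² + σ²)(‖w_j‖² + σ²)),

giving a closed-form expected asynchrony matrix (1 − corr)/2 used as the
recovery oracle.

Default study conditions: 60 species, 40 years, 3 drivers, β = 0.8,
σ = 0.5, 5% missing cells, birth rate 1. These give per-pair overlap and
effect sizes comparable to a well-sampled monitoring scheme and are the
conditions under which the suite's parameter-recovery and null-calibration
checks run. The confounded variant (`simulate_confounded_dataset`) drives
abundance only through an *unobserved* tree-evolved trait while a measured
trait evolves neutrally on the same tree, so the measured trait's
association with asynchrony is pure shared ancestry — the scenario the
partial Mantel test exists to catch; it uses 300 years and β = 0.95 so the
confounded signal is estimated cleanly.

All randomness derives from one root seed through named SeedSequence
streams per stage (tree / traits / loadings / weather / missingness), so a
fixed seed gives bit-identical outputs and stages are independently
reproducible.

### What passing synthetic tests does not show

The generator has linear Gaussian driver structure, MCAR missingness, no
density dependence, no observation error beyond additive noise on changes,
and traits whose effect on dynamics is monotone in trait distance by
construction. Real monitoring data violate all of these to unknown
degrees. The tests therefore establish that the *pipeline* is correct and
calibrated (type-I error, oracle agreement, recovery when the signal
exists), not that any particular ecological effect size is detectable in a
given real scheme.

## Numerical choices and degenerate inputs

- Correlations use pairwise-complete moment formulas; K is clipped to
  [−1, 1] before mapping to M, and matrices are symmetrised against float
  noise.
- Permutation comparisons use r_perm ≥ r_obs − 1e-12 so exact ties (e.g.
  the identity permutation when A = B) count as exceedances.
- Degenerate permutations (zero variance after masking) are excluded from
  the exceedance count but kept in the denominator — conservative — and
  logged.
- Zero-variance distance matrices, collinear covariates, sub-3-pair
  vectorisations, and all-undefined asynchrony matrices raise typed errors
  rather than producing NaN results.
- Species alignment is the sorted intersection across sources; dropping is
  logged per source, and fewer than three common species is an error.

## Test scale

The suite's simulation studies use the sizes at which their statistical
guarantees are sharp but cheap: 500 replicates at n_perm = 199 for type-I
error (binomial SE ≈ 1%), 20 seeds for recovery power, 300 replicates for
null calibration, 100,000 permutations against exact enumeration on 6×6
matrices, 2,000-year panels for closed-form convergence, and 10 seeds for
confounding attenuation. The whole suite runs in well under a minute.

## Known limitations

- The equal-group weighting is the fixed analytic scheme; gawdis-style
  iterative contribution balancing is not implemented.
- No multiple-testing correction across per-trait rows (deliberate, to
  mirror per-trait reporting conventions); users comparing many traits
  should apply their own.
- Change series are used as-is: no detrending or autocorrelation
  correction.
- The bootstrap subsampling scheme is one reasonable choice among several;
  CIs should be read as stability summaries, not exact frequentist
  intervals.
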