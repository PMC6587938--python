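# Methods

`microgeostat` implements the statistical workflow used in landscape-scale
surveys of soil prokaryotic communities along short transects: alpha
diversity from OTU count tables, geostatistical description of soil
properties (semivariograms, ordinary kriging, cross-validation), per-class
spatial autocorrelation tests, and taxa–environment association (Spearman
tables, collinearity screening, BIOENV).  This note records the models, the
conventions chosen where the field admits several, and what the synthetic
data generator does and does not emulate.

## Alpha diversity and richness

All indices operate on a single sample's count vector after rarefaction.

- **Shannon** `H = -Σ p_i log_b p_i` with **base 2 by default**.  The base
  is configurable; base 2 is the default because it is the only base under
  which the typical reported values for rarefied soil samples (H up to
  ~5.9 at depths near 139 reads) are feasible — `2^5.9 ≈ 60` effective
  taxa fits inside such a sample, `e^5.9 ≈ 365` does not.
- **Simpson family** with `D = Σ p_i²`: "Simpson" is reported as the
  Gini–Simpson index `1 − D`, "Simpson reciprocal" as `1/D` (effective
  species number), and "Simpson E" as `(1/D)/S_obs`.
- **Good's coverage** `1 − F₁/N`, the probability that the next read
  belongs to an already observed taxon (`F₁` singletons, `N` reads).
- **Chao1**, bias-corrected by default:
  `S_obs + F₁(F₁−1)/(2(F₂+1))`, which stays defined when `F₂ = 0`; the
  classic `S_obs + F₁²/(2F₂)` is available by flag.
- **ACE** with the standard rare/abundant split at 10 reads (configurable).
  When every rare taxon is a singleton the coverage estimate is zero and
  ACE is undefined; this raises rather than returning infinity.
- **Faith's PD**: total branch length of the union of root-to-tip paths of
  the observed taxa on a rooted tree with branch lengths (scikit-bio
  `TreeNode`).  The root's own length, when present, is excluded.

Rarefaction subsamples each sample **without replacement** to exactly the
requested depth (multivariate hypergeometric draw); samples shallower than
the depth are dropped and logged, and every downstream per-sample product
(diversity tables, domain ratios, taxon kriging responses) excludes them.
The seed is a required argument — there is no hidden default stream.

## Semivariograms

The empirical semivariogram is the method-of-moments estimator
`γ̂(h) = (1/2N(h)) Σ (z_i − z_j)²` over pairs at lag `h`.  Cloud values are
stored as `(h_ij, (z_i − z_j)²/2)` so that bin means equal `γ̂` directly.
Defaults: 12 equal-width bins up to half the maximum pairwise distance
(both configurable); bin centres are reported as the mean pair distance in
the bin; empty bins are dropped.

Five model families are supported, all with `γ(0) = 0` exactly and
`lim_{h→0⁺} γ(h) = c₀`:

| family       | structured part (h > 0)                    | `a` means |
|--------------|--------------------------------------------|-----------|
| nugget       | 0                                          | —         |
| spherical    | `c(1.5 h/a − 0.5 (h/a)³)`, plateau at `a`  | range     |
| exponential  | `c(1 − e^{−3h/a})`                         | practical range |
| gaussian     | `c(1 − e^{−3h²/a²})`                       | practical range |
| periodic     | `c(1 − cos(2πh/a))` (hole-effect cosine)   | period    |

The "periodic" family models patchy terrain whose semivariance returns to
the nugget level once per period.  Because it is non-monotone, its "sill"
for the nugget/sill ratio is taken as `c₀ + c`, i.e. the plateau the other
families reach; the cosine form is one documented choice among several
hole-effect variants in use.

Fitting is weighted least squares over `(c₀, c, a)` with box constraints
(`c₀, c ≥ 0`, `a > 0`), a deterministic multi-start grid (2 nugget × 2
partial-sill × 8 range starts spanning 0.15–2 × the maximum lag), and
`scipy.optimize.least_squares` (trust-region reflective).  Default weights
are `N(h)/h²` (the gstat default); Cressie weights `N(h)/γ_model(h)²`
(iterated three times) and OLS are available.  The best family minimises
the weighted residual sum of squares; ties resolve to the first family in
the candidate list.  On noise-free model-generated bins every family is
recovered to well under 1% relative error.

Spatial dependence is classified from the nugget/sill ratio `c₀/(c₀+c)`:
**high** below 0.25, **medium** in [0.25, 0.75], **low** above 0.75.  A
zero sill (constant attribute) has no defined class and raises.

## Mantel correlograms

For each of `k` equal-width geographic distance classes (default 6,
covering all pairwise distances), the statistic is the Pearson correlation
between the class-membership indicator and the attribute-dissimilarity
vectors over all sample pairs, **negated** so that positive values read as
positive autocorrelation (similar values at that distance), matching the
plotting convention of the vegan/ncf correlograms.  Significance is
two-sided on `|statistic|` by permuting sample labels of the dissimilarity
matrix (rows and columns together), with `p = (exceedances + 1)/(n_perm + 1)`
and 1,000 permutations by default.  The test is exact under
exchangeability; with 200 null simulations the per-class rejection rate at
α = 0.05 sits inside the binomial 95% interval around 0.05 (ties make it,
if anything, slightly conservative).  Value dissimilarity defaults to
Euclidean distance on the attribute; a precomputed symmetric matrix is
accepted for community data.

## Ordinary kriging and cross-validation

Predictions solve the `(n+1)×(n+1)` semivariance system with the
unbiasedness constraint `Σw = 1` via a Lagrange multiplier; the kriging
variance is `w·γ₀ + λ`.  All samples enter every system (global
neighbourhood — appropriate at n ≈ 13; no search-radius truncation).
Consequences verified in the tests: weights sum to one everywhere; with
zero nugget the predictor interpolates exactly with zero variance; under a
pure-nugget model every weight is `1/n` and the prediction is the sample
mean.  Negative weights are permitted (they arise from screening with
monotone models), so predictions can leave the data range except in the
convex pure-nugget case.

Co-located samples with equal values are deduplicated with a warning;
with conflicting values the system is singular and the constructor raises,
naming the pair.

Leave-one-out cross-validation re-predicts each sample from the others
using the **same** fitted variogram (no refit per fold, matching gstat's
`krige.cv`).  Summary statistics:

- `ASE = sqrt(mean((Z'_j − mean(Z'))²))` — the spread of the LOO estimates;
- `RMSE = sqrt(mean((Z_j − Z'_j)²))`;
- `RMSE_r = RMSE / S_z` with `S_z` the standard deviation (ddof = 1) of the
  observations.

The square root is taken over the full mean of squares (the standard
definition); a published typesetting variant placing the root over `1/N`
alone is not reproduced.  Accuracy flags: ASE and RMSE "similar" when
`|ASE − RMSE|/max(ASE, RMSE) ≤ 0.2`, and `RMSE_r` "accurate" when at or
below 0.40·(1 + 0.2), operationalising the conventional "RMSE_r close to
40%" rule.

The prediction grid tiles the polygon's bounding box with square cells of
the configured pixel area (default 2.38 m²), anchored at the lower-left
corner, keeping cells whose centre falls strictly inside the polygon
(row-major order).  The reported `expected_cells = round(area/pixel_area)`
is the area-ratio count; the kept-cell count can differ by a few percent
through boundary cells.

## Taxa–environment association

Spearman correlations use average ranks with the two-sided t
approximation on n−2 degrees of freedom (scipy); an exact permutation
p-value is not needed at the tier thresholds used (0.05 / 0.01).  Constant
vectors yield an undefined correlation, reported as NA with tier "ns".

Collinearity screening is greedy: while any pair of environmental
variables exceeds `|r| > 0.8` (Pearson), the member of the worst pair with
the larger mean absolute correlation to the remaining variables is
dropped, ties breaking by variable name.  This is a deterministic screen
serving the same role as corSelect/multicol-style filtering; it does not
reproduce any particular package's ranking criterion.

BIOENV standardizes the environmental variables (zero mean, unit sd,
ddof = 1), computes the community dissimilarity once — Bray–Curtis on
relative abundances by default, Euclidean available; which metric the
community side of such analyses used is often unstated, so it is left
configurable — and exhaustively evaluates every non-empty variable subset
up to the requested size, Spearman-correlating Euclidean environmental
distances with the community dissimilarities.  The search is genuinely
exhaustive (asserted against brute-force enumeration in the tests), and
`skbio.stats.distance.bioenv` serves as an independent cross-check there.

## Synthetic data generator

Soil properties are Gaussian random fields over the transect coordinates
with covariance `C(h) = sill − γ(h)`, factorized by Cholesky with a small
diagonal jitter (1e-8·sill for the periodic family, whose cosine
covariance is only conditionally valid off a line; 1e-10·sill otherwise).
Defaults emulate the study system the analysis is designed for: 13 samples
over a 211 m NW–SE transect with irregular spacing; near-constant alkaline
pH around 10.45; log-normal EC spanning roughly 7–180 dS/m; patchy
(periodic) structure in water content (~13–56%), organic C (~4.5–26 g/kg)
and inorganic C; sand/silt/clay drawn as three positive fields closed to
sum exactly 100.  Clipping to physical ranges is post-hoc truncation —
acceptable for fixtures, but it slightly distorts the marginal
distributions near the bounds.

Communities follow a log-linear response: per-sample taxon intensity
`exp(baseline + effects · standardized covariates)`, normalized to
proportions and drawn multinomially at a per-sample depth uniform on
[100, 1500] reads, so rarefaction thresholds in the low hundreds can drop
samples and exercise the omission path.  Default effects put most signal
on EC and WC (sd 0.8) and little elsewhere (sd 0.2), mirroring the
salinity/moisture-driven structure such surveys report.  Two-domain
taxonomy lineages (Archaea/Bacteria, a handful of realistic phylum names)
are attached for the collapsing and ratio machinery.

What the generator does **not** emulate: sequencing error and chimeras,
compositional zero-inflation beyond multinomial sampling, phylogenetic
signal in the effect structure (trees for PD tests are arbitrary), and
cross-correlation between soil properties (fields are independent).
Passing tests on this generator therefore demonstrate the correctness of
the estimators and the recoverability of planted structure under the
model's own assumptions — not robustness to real-data violations of them.

## Problem sizes and numerical choices

The statistical suites run at sizes chosen to make Monte-Carlo noise small
relative to the assertions while staying quick on a laptop: 200-point
transects and 20 seeds for variogram recovery (median fitted range within
±30% of truth), 200 null simulations × 999 permutations for Mantel
calibration, 100 seeds for planted-signal BIOENV recovery, 1,000 random
targets for the weight-sum invariant, and 50 random 5-point
configurations against the naive kriging solver.  Linear systems are
solved densely (`numpy.linalg.solve`); kriging right-hand sides are
batched across targets.  Degenerate inputs fail loudly: all-zero count
vectors, zero-total samples, constant attributes where a class or ratio is
undefined, empty distance classes (dropped with a warning), and
non-factorizable covariances.

## Known limitations

- Omnidirectional variograms only; no anisotropy or trend (universal)
  kriging.
- The hole-effect "periodic" family is one parametric choice; fitted
  periods are only as identifiable as the lag coverage allows.
- Greedy collinearity screening can differ from exhaustive subset
  selection on adversarial correlation structures.
- The BIOENV search is exponential in the variable count; it is intended
  for the ≤ 10 environmental variables typical of soil surveys.
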