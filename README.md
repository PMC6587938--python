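# microgeostat

Geostatistics for soil microbiome transects: who lives where in the soil,
and which measured soil properties explain it.

Landscape-scale surveys of soil prokaryotes sample a handful of
georeferenced points along a transect, sequence 16S amplicons into OTU
tables, and measure soil properties (pH, electrolytic conductivity EC,
water content WC, carbon fractions, texture) at the same points.
`microgeostat` implements the statistical core of such studies as a
tested, reusable library:

- **OTU tables** — TSV and BIOM 1.0 JSON I/O, validation, taxonomic
  collapsing, relative abundance, rarefaction without replacement with an
  explicit drop rule for shallow samples;
- **alpha diversity** — Shannon (base 2 default), Gini–Simpson, reciprocal
  Simpson, Simpson evenness, Good's coverage, bias-corrected Chao1, ACE,
  Faith's PD, plus per-sample Archaea/Bacteria ratios;
- **spatial structure** — empirical semivariograms
  γ̂(h) = (1/2N(h)) Σ (z_i − z_j)², weighted-least-squares fits of the
  nugget / spherical / exponential / gaussian / periodic (hole-effect)
  families, nugget/sill spatial-dependence classes (high < 0.25 ≤ medium
  ≤ 0.75 < low), and Mantel autocorrelograms with permutation tests;
- **ordinary kriging** — Ẑ(s₀) = Σ wᵢ z(sᵢ) with Σ wᵢ = 1 via a Lagrange
  multiplier, rasterized polygon prediction grids, and leave-one-out
  cross-validation reporting ASE, RMSE and RMSE_r = RMSE/S_z with the
  "RMSE_r near 40%" accuracy rule;
- **taxa–environment association** — Spearman correlation tables with
  p < 0.05 / p < 0.01 tiers, greedy collinearity screening, and the
  exhaustive BIOENV best-subset search (Bray–Curtis community
  dissimilarity vs. Euclidean distances of scaled environmental subsets,
  rank-correlated);
- **synthetic transects** — Gaussian random fields with variogram-derived
  covariance, compositional texture closure, and log-linear multinomial
  communities, so every stage is testable with planted ground truth.

The geostatistical core follows a model/results idiom:
`Variogram(data, ...).fit()` returns a results object with the fitted
parameters, per-family diagnostics and a `summary()` table, and
`OrdinaryKriging(...)` exposes `.predict()` and `.cross_validate()`.
See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a 13-sample, 211 m saline-alkaline transect, describe the spatial
structure of EC, krige it over a polygon, and ask which soil variables
best explain the community:

```python
from microgeostat import (SimulationConfig, simulate_transect, simulate_community,
                          Variogram, OrdinaryKriging, build_prediction_grid,
                          bioenv, transect_polygon)

cfg = SimulationConfig(seed=1)
soil = simulate_transect(cfg)
print(soil[["EC", "WC", "pH"]].describe().loc[["min", "max"]].round(2))

fit = Variogram(soil, attribute="EC").fit()
print(fit.summary()[["family", "nugget", "psill", "range",
                     "nugget_sill_ratio", "best"]].round(3).head(3))
print("dependence class:", fit.dependence_class)

ok = OrdinaryKriging(soil, attribute="EC", model=fit.model)
print(ok.cross_validate().summary())

ring = transect_polygon(soil[["easting", "northing"]].to_numpy())
grid = build_prediction_grid(ring, pixel_area=2.38)
maps = ok.predict(grid.centers)
print(f"{grid.n_cells} cells; predicted EC range "
      f"{maps.predictions.min():.1f}-{maps.predictions.max():.1f} dS/m")

otus = simulate_community(soil, cfg)
env = soil[["pH", "EC", "WC", "org_C", "inorg_C", "sand", "silt", "clay"]]
res = bioenv(otus, env, max_subset_size=3)
print(res.best_per_size.to_string(index=False))
```

Output:

```
         EC     WC     pH
min   11.86  10.81  10.24
max  155.96  55.50  10.63
      family    nugget     psill    range  nugget_sill_ratio   best
0   periodic  1385.569   693.782  104.628              0.666   True
1  spherical  1002.490  1435.723   46.201              0.411  False
2   gaussian  1317.754  1133.081   42.195              0.538  False
dependence class: medium
n                          13
ASE                 28.199163
RMSE                31.749422
RMSE_r               0.656847
S_z                 48.336074
ase_rmse_similar         True
rmse_r_accurate         False
dtype: object
14161 cells; predicted EC range 15.1-108.9 dS/m
 size       subset        r
    1        (EC,) 0.658898
    2     (EC, WC) 0.845243
    3 (pH, EC, WC) 0.781181
```

Reading it: for this realization, EC is best described by a hole-effect
("periodic", patchy) variogram with a 105 m period, but its nugget/sill
ratio of 0.67 means only medium spatial dependence, and cross-validation
agrees — ASE and RMSE are similar (the variance model is honest about
itself) while RMSE_r = 0.66 is well above the 40% rule, so the kriged EC
map is indicative rather than accurate at 13 samples.  BIOENV ranks EC as
the single variable most correlated with community dissimilarities and
EC + WC as the best subset overall (Spearman r = 0.85) — recovering the
planted salinity/moisture drivers of the simulated community.

A thin CLI mirrors the library for shell use
(`microgeostat simulate | diversity | variogram | krige | crossval |
correlate | bioenv | pipeline`); `microgeostat pipeline --config run.yaml`
executes the full workflow (diversity → variograms → kriging maps +
cross-validation → correlation tables → BIOENV) into an output directory
with a checksummed manifest, byte-reproducible for a fixed seed.

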