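# spatepi

Spatial epidemiology of cluster surveys: from individual survey records to
cluster-level prevalence maps, spatial cluster detection and spatially
varying regression.

`spatepi` is aimed at analysts working with DHS-style household surveys —
a few hundred GPS-located enumeration-area clusters, a handful of
respondents per cluster, sampling weights — who want to answer two
questions about a binary outcome such as teenage pregnancy: *where* does
prevalence cluster geographically, and *which community characteristics
drive that variation*. It bundles the standard desk-GIS workflow into one
tested, scriptable Python package:

- **Aggregation** — composite outcome per respondent, survey-weighted
  proportion per cluster `p_g = Σ w_i x_i / Σ w_i`, regional summary
  tables.
- **Spatial weights** — haversine distances, k-nearest-neighbour or
  fixed-distance-band matrices over cluster points, optional
  row-standardization and self-inclusion.
- **Global Moran's I** —
  `I = (n/S0) · Σ_ij w_ij (y_i − ȳ)(y_j − ȳ) / Σ_i (y_i − ȳ)²`, with
  analytic (normality) and permutation inference.
- **Getis-Ord Gi\*** — self-inclusive local z-scores binned into
  hot/cold classes at 90/95/99% confidence, optional FDR gating.
- **Bernoulli spatial scan** — circular windows up to 50% of the
  population, Kulldorff-style log-likelihood ratio, relative risk, and
  Monte Carlo p-values conditioning on the total case count; ranked
  non-overlapping primary/secondary clusters.
- **OLS with a spatial diagnostic battery** — classical and HC1-robust
  inference, VIF, Jarque–Bera, Koenker's studentized Breusch–Pagan,
  joint F and robust Wald, AICc, residual Moran's I, and an exhaustive
  exploratory subset search gated on all assumptions.
- **Geographically weighted regression** —
  `y_i = β_0(u_i,v_i) + Σ_k β_k(u_i,v_i) x_ik + ε_i`, adaptive bisquare or
  gaussian kernels, golden-section AICc bandwidth selection, hat-matrix
  effective parameters tr(S), and GeoJSON coefficient-surface export.
- **Synthetic surveys** — a DHS-like generator with known spatial risk
  surfaces, sampling weights and confidentiality displacement (≤ 2 km
  urban, ≤ 5 km rural), so every method can be validated against ground
  truth.

## Worked example

Cluster prevalence from a synthetic survey, spatial clustering, then the
global-vs-local model comparison (`examples/03_moran_hotspots.py` and
`examples/06_gwr.py`):

```python
import spatepi as sp

config = sp.dhs_like_config(seed=3, n_clusters=250)
individuals, locations = sp.simulate_survey(config)
feats = sp.build_cluster_features(individuals, locations)
y = feats["outcome_proportion"].to_numpy()

W = sp.build_weights(feats["lon"], feats["lat"], row_standardize=True)
moran = sp.morans_i(y, W)
```

```
Moran's I = 0.148  (E[I] = -0.0040, z = 4.53, analytic p = 5.9e-06, permutation p = 0.001)
```

Prevalence is spatially clustered: I is well above its null expectation
−1/(n−1), and none of 999 value permutations reached the observed I. The
GWR stage then asks whether covariate effects vary over space:

```
selected adaptive bandwidth: 200 neighbours
effective number of parameters tr(S) = 17.79
sigma = 0.195, residual squares = 11.428
GWR  AICc = -88.71, R2 = 0.331, adj R2 = 0.289
OLS  AICc = -48.73, adj R2 = 0.150
preferred model: gwr
community_poverty coefficient surface: min 0.113, max 0.345
```

The AICc gap far exceeds the Δ > 3 preference rule, so the spatially
varying model wins; the poverty coefficient surface shows the effect
strengthening across the domain (these numbers are what the example
scripts print for their fixed seeds).

Each script in `examples/` demonstrates one capability; the `spatepi`
command exposes the same stages as subcommands (`spatepi run --config
cfg.yaml --json` runs the whole chain reproducibly).

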