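"""Global spatial autocorrelation and Gi* hotspots of cluster prevalence.

Builds cluster-level weighted prevalence from a synthetic survey, a
distance-band spatial weight matrix, then global Moran's I (analytic and
permutation inference) and the Getis-Ord Gi* hot/cold classification.
"""

import pandas as pd

import spatepi as sp

config = sp.dhs_like_config(seed=3, n_clusters=250)
individuals, locations = sp.simulate_survey(config)
feats = sp.build_cluster_features(individuals, locations)
y = feats["outcome_proportion"].to_numpy()

W = sp.build_weights(feats["lon"], feats["lat"], row_standardize=True)
moran = sp.morans_i(y, W)
p_perm = sp.moran_permutation(y, W, n_perm=999, seed=3)
print(f"Moran's I = {moran.I:.3f}  (E[I] = {moran.expected_I:.4f}, "
      f"z = {moran.z:.2f}, analytic p = {moran.p_analytic:.2g}, "
      f"permutation p = {p_perm:.3f})")

W_star = sp.build_weights(feats["lon"], feats["lat"], include_self=True)
gi = sp.getis_ord_gistar(y, W_star)
print(pd.Series(gi.category).value_counts().to_string())

# A positive I with small p says prevalence is spatially clustered; the
# category counts show how many clusters sit in significant hot (high
# prevalence) or cold (low prevalence) neighbourhoods.
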