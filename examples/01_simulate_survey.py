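"""Generate a synthetic DHS-like teenage-pregnancy survey.

Draws cluster GPS points over an Ethiopia-like bounding box, teenagers per
cluster with sampling weights, community covariates, and a binary outcome
whose risk is elevated in the south-east of the domain; cluster coordinates
are then displaced for confidentiality exactly as DHS does (<= 2 km urban,
<= 5 km rural).
"""

import spatepi as sp

config = sp.dhs_like_config(seed=1, n_clusters=200)
individuals, locations = sp.simulate_survey(config)

print(f"clusters:    {len(locations)}  (urban share "
      f"{locations['urban'].mean():.2f})")
print(f"teenagers:   {len(individuals)}")
print(f"outcome prevalence: {individuals['outcome'].mean():.3f}")
print(individuals.head())

# The prevalence is the share of simulated teenagers with a pregnancy
# before age 19; the urban share mirrors the 202/645 urban enumeration
# areas of the emulated sampling frame.
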