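"""Regional prevalence table from the built-in 2016 EDHS regional counts.

Expands the published weighted regional counts into unit-weight records and
recomputes the per-region percentage of teenagers with a pregnancy, plus
each region's share of the national weighted sample of 3381.
"""

import spatepi as sp
from spatepi.datasets import edhs2016_regional_records

records = edhs2016_regional_records()
summary = sp.regional_summary(records)
print(summary.to_string(index=False))
print(f"\nweighted sample total: {summary['total'].sum()}")

# pct_yes is the percentage of the region's weighted sample with teenage
# pregnancy (e.g. Oromia 16.94%); pct_of_total is the region's share of
# the national weighted sample.
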