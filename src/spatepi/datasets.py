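"""Small built-in study inputs.

Regional teenage-pregnancy counts by region from the 2016 Ethiopian
Demographic and Health Survey (weighted counts as published): for each
region, (count without pregnancy, count with pregnancy).  The weighted
national sample totals 3381 teenagers aged 15-19.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EDHS2016_REGIONAL_COUNTS = {
    "Tigray": (243, 33),
    "Afar": (23, 7),
    "Amhara": (703, 64),
    "Oromia": (1025, 209),
    "Somali": (85, 20),
    "Benishangul Gumuz": (29, 5),
    "SNNP": (608, 73),
    "Gambela": (8, 1),
    "Harari": (7, 1),
    "Addis Ababa": (211, 6),
    "Dire Dawa": (18, 2),
}


def edhs2016_regional_records() -> pd.DataFrame:
    """Expand the regional counts into unit-weight individual records.

    One row per (weighted) teenager with region, weight 1, and the two
    outcome source flags (positives recorded as births before 19).
    """
    rows = []
    for region, (n_no, n_yes) in EDHS2016_REGIONAL_COUNTS.items():
        rows.append(pd.DataFrame({
            "region": region,
            "weight": 1.0,
            "births_before_19": np.repeat([0, 1], [n_no, n_yes]),
            "currently_pregnant": 0,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["outcome"] = ((df["births_before_19"] == 1)
                     | (df["currently_pregnant"] == 1)).astype(int)
    return df
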