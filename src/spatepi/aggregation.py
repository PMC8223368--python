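"""From individual survey records to the cluster-level analysis table.

The outcome is composite at the individual level (a birth before age 19 OR
a current pregnancy); the spatial stages all operate on survey-weighted
proportions per cluster, p_g = sum_i(w_i x_i) / sum_i(w_i).  This module
builds those proportions, the community covariate shares, and the regional
summary table (weighted counts and percentages by region).
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class MissingDataError(ValueError):
    pass


def round_half_away(x, ndigits: int = 2):
    """Round half away from zero (display convention for summary tables)."""
    q = Decimal(1).scaleb(-ndigits)
    if np.ndim(x) == 0:
        return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return np.array([round_half_away(v, ndigits) for v in np.asarray(x)])


def define_outcome(records: pd.DataFrame) -> pd.Series:
    """Composite outcome: 1 iff births_before_19 == 1 or currently_pregnant == 1.

    Missing flags raise; nothing is silently imputed.
    """
    for col in ("births_before_19", "currently_pregnant"):
        if col not in records.columns:
            raise MissingDataError(f"column {col!r} absent")
        if records[col].isna().any():
            n_bad = int(records[col].isna().sum())
            raise MissingDataError(f"{n_bad} missing value(s) in {col!r}")
    b = records["births_before_19"].astype(int)
    c = records["currently_pregnant"].astype(int)
    if not ((b.isin((0, 1))).all() and (c.isin((0, 1))).all()):
        raise ValueError("outcome flags must be 0/1")
    return ((b == 1) | (c == 1)).astype(int)


def weighted_proportion(
    records: pd.DataFrame,
    group_key: str,
    variable: str,
    weight: str = "weight",
) -> pd.DataFrame:
    """Per-group weighted proportion sum(w x) / sum(w).

    Missing values of ``variable`` are excluded pairwise (with a logged
    count); a group whose weights sum to zero raises.
    """
    df = records[[group_key, variable, weight]]
    if (df[weight] <= 0).any():
        raise ValueError("weights must be positive")
    n_miss = int(df[variable].isna().sum())
    if n_miss:
        log.warning("weighted_proportion(%s): excluding %d missing value(s)",
                    variable, n_miss)
        df = df.dropna(subset=[variable])
    if df.empty:
        raise ValueError("no records to aggregate")
    g = df.groupby(group_key, sort=True)
    num = g.apply(lambda d: float((d[weight] * d[variable]).sum()),
                  include_groups=False)
    den = g[weight].sum()
    if (den <= 0).any():
        bad = den.index[den <= 0].tolist()
        raise ValueError(f"zero total weight in group(s) {bad}")
    out = pd.DataFrame({
        group_key: den.index,
        "proportion": (num / den).to_numpy(),
        "n": g.size().to_numpy(),
        "sum_weight": den.to_numpy(),
    }).reset_index(drop=True)
    return out


def regional_summary(records: pd.DataFrame, region: str = "region",
                     outcome: str = "outcome",
                     weight: str = "weight") -> pd.DataFrame:
    """Regional summary: weighted no/yes counts, percentages, total shares.

    Counts are weighted sums rounded to integers for display; within-region
    percentages and grand-total shares are rounded half-away-from-zero to
    two decimals.
    """
    if records.empty:
        raise ValueError("empty input")
    df = records[[region, outcome, weight]]
    g = df.groupby(region, sort=True)
    w_yes = g.apply(lambda d: float((d[weight] * d[outcome]).sum()),
                    include_groups=False)
    w_tot = g[weight].sum()
    w_no = w_tot - w_yes
    grand = float(w_tot.sum())
    out = pd.DataFrame({
        "region": w_tot.index,
        "count_no": round_half_away(w_no.to_numpy(), 0).astype(int),
        "pct_no": round_half_away(100.0 * w_no.to_numpy() / w_tot.to_numpy()),
        "count_yes": round_half_away(w_yes.to_numpy(), 0).astype(int),
        "pct_yes": round_half_away(100.0 * w_yes.to_numpy() / w_tot.to_numpy()),
        "total": round_half_away(w_tot.to_numpy(), 0).astype(int),
        "pct_of_total": round_half_away(100.0 * w_tot.to_numpy() / grand),
    }).reset_index(drop=True)
    return out


def community_covariates(records: pd.DataFrame, covariates,
                         cluster_key: str = "cluster_id",
                         weight: str = "weight") -> pd.DataFrame:
    """Per-cluster weighted proportion of each named 0/1 covariate."""
    missing = [c for c in covariates if c not in records.columns]
    if missing:
        raise KeyError(f"covariate(s) not in records: {missing}")
    out = None
    for name in covariates:
        wp = weighted_proportion(records, cluster_key, name, weight)
        wp = wp[[cluster_key, "proportion"]].rename(columns={"proportion": name})
        out = wp if out is None else out.merge(wp, on=cluster_key, how="outer")
    return out


def build_cluster_features(
    individuals: pd.DataFrame,
    locations: pd.DataFrame,
    covariates=None,
    weight: str = "weight",
) -> pd.DataFrame:
    """Cluster analysis table: location, counts, weighted proportions.

    ``cases``/``population`` are unweighted head counts (the scan statistic
    needs integers); ``outcome_proportion`` is the survey-weighted share.
    """
    df = individuals.copy()
    if "outcome" not in df.columns:
        df["outcome"] = define_outcome(df)
    wp = weighted_proportion(df, "cluster_id", "outcome", weight)
    wp = wp.rename(columns={"proportion": "outcome_proportion",
                            "n": "n_teens"})[
        ["cluster_id", "outcome_proportion", "n_teens"]]
    counts = df.groupby("cluster_id", sort=True).agg(
        cases=("outcome", "sum"), population=("outcome", "size")).reset_index()
    feats = locations[[c for c in ("cluster_id", "lon", "lat", "urban")
                       if c in locations.columns]].merge(
        wp, on="cluster_id", how="inner").merge(counts, on="cluster_id")
    if covariates:
        cc = community_covariates(df, covariates, weight=weight)
        feats = feats.merge(cc, on="cluster_id", how="left")
    return feats
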