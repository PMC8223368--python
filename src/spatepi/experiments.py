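"""Calibration and recovery experiments on synthetic ground truth.

Each function runs a seeded simulation study against the package's own
methods and returns the operating characteristic it measures: type-I error
of the Moran permutation test and of the Bernoulli scan, OLS confidence
coverage, GWR coefficient-surface recovery, planted-cluster recovery of the
scan, and predictor-set recovery of the exploratory search.  These back both
the test suite and the reproducibility script; sizes default to the study
conditions described in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster_stats import moran_permutation
from .gwr import fit_gwr, select_bandwidth
from .regression import exploratory_search, fit_ols
from .scan import scan_mc
from .weights import build_weights


def _spawn(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def moran_permutation_type1(n_runs: int = 200, n_perm: int = 99,
                            n_clusters: int = 40, alpha: float = 0.05,
                            seed: int = 0) -> float:
    """Rejection rate of the Moran permutation test on exchangeable data."""
    rng = np.random.default_rng(seed)
    lon = rng.uniform(34, 46, n_clusters)
    lat = rng.uniform(4, 14, n_clusters)
    W = build_weights(lon, lat, method="knn", param=5, row_standardize=True)
    rej = 0
    for r, g in enumerate(_spawn(seed + 1, n_runs)):
        y = g.normal(size=n_clusters)
        p = moran_permutation(y, W, n_perm=n_perm,
                              seed=int(g.integers(2 ** 31)))
        rej += int(p <= alpha)
    return rej / n_runs


def scan_type1(n_runs: int = 200, n_reps: int = 99, n_clusters: int = 20,
               alpha: float = 0.05, seed: int = 0) -> float:
    """Primary-cluster rejection rate of the scan under uniform risk."""
    rng = np.random.default_rng(seed)
    lon = rng.uniform(34, 46, n_clusters)
    lat = rng.uniform(4, 14, n_clusters)
    pop = np.full(n_clusters, 30)
    rej = 0
    for g in _spawn(seed + 1, n_runs):
        cases = g.binomial(pop, 0.12)
        if cases.sum() == 0 or cases.sum() >= pop.sum():
            continue
        out = scan_mc(lon, lat, cases, pop, n_reps=n_reps,
                      seed=int(g.integers(2 ** 31)), p_threshold=1.0)
        rej += int(bool(out) and out[0].p_mc <= alpha)
    return rej / n_runs


def ols_coverage(n_runs: int = 100, n: int = 617, k: int = 4,
                 seed: int = 0) -> dict:
    """Confidence coverage of OLS slopes under Gaussian errors.

    Returns per-coefficient 95% (1.96 SE) coverage and the share of runs
    where every slope lies within 3 classical SEs of the truth.
    """
    beta = np.array([0.5, -0.3, 0.8, 0.2])[:k]
    hits95 = 0
    joint3 = 0
    for g in _spawn(seed, n_runs):
        X = pd.DataFrame(g.normal(size=(n, k)),
                         columns=[f"x{j}" for j in range(k)])
        y = 1.0 + X.to_numpy() @ beta + g.normal(size=n)
        res = fit_ols(X, y)
        dev = np.abs(res.params[1:] - beta)
        hits95 += int(np.sum(dev <= 1.96 * res.bse[1:]))
        joint3 += int(np.all(dev <= 3 * res.bse[1:]))
    return {"coverage95": hits95 / (n_runs * k),
            "joint_within_3se": joint3 / n_runs}


def gwr_gradient_recovery(n_clusters: int = 400, seed: int = 0) -> float:
    """Correlation between the estimated and true slope surface.

    The slope of a single covariate follows a west-east linear gradient;
    GWR is fitted with an AICc-selected adaptive bisquare bandwidth.
    """
    rng = np.random.default_rng(seed)
    lon = rng.uniform(34, 46, n_clusters)
    lat = rng.uniform(4, 14, n_clusters)
    x1 = rng.uniform(0, 1, n_clusters)
    b1 = 0.05 * (lon - 40.0) + 0.3
    y = 0.2 + b1 * x1 + rng.normal(scale=0.03, size=n_clusters)
    X = pd.DataFrame({"x1": x1})
    bw, _ = select_bandwidth(X, y, lon, lat)
    res = fit_gwr(X, y, lon, lat, bw)
    return float(np.corrcoef(res.params[:, 1], b1)[0, 1])


def scan_planted_recovery(n_seeds: int = 20, n_clusters: int = 50,
                          rr: float = 3.0, base_rate: float = 0.1,
                          n_reps: int = 99, seed: int = 0) -> float:
    """Share of seeds where the primary cluster overlaps the planted
    circular high-risk zone with Jaccard index above 0.5."""
    from .weights import haversine_km

    success = 0
    for g in _spawn(seed, n_seeds):
        lon = g.uniform(34, 46, n_clusters)
        lat = g.uniform(4, 14, n_clusters)
        pop = np.full(n_clusters, 30)
        inside = haversine_km(lon, lat, 37.0, 7.0) <= 300.0
        cases = g.binomial(pop, np.where(inside, base_rate * rr, base_rate))
        if cases.sum() == 0 or not inside.any():
            continue
        out = scan_mc(lon, lat, cases, pop, n_reps=n_reps,
                      seed=int(g.integers(2 ** 31)), p_threshold=1.0)
        if not out:
            continue
        found = set(out[0].member_ids)
        truth = set(np.flatnonzero(inside).tolist())
        jac = len(found & truth) / len(found | truth)
        success += int(jac > 0.5)
    return success / n_seeds


def exploratory_recovery(n_seeds: int = 20, n: int = 617, n_pool: int = 8,
                         seed: int = 0) -> float:
    """Share of seeds where the top-ranked passing model equals the
    generating predictor set (4 true predictors among ``n_pool``)."""
    true = ["v0", "v1", "v2", "v3"]
    beta = np.array([0.15, 0.12, -0.10, 0.08])
    success = 0
    for g in _spawn(seed, n_seeds):
        lon = g.uniform(34, 46, n)
        lat = g.uniform(4, 14, n)
        W = build_weights(lon, lat, method="knn", param=6,
                          row_standardize=True)
        X = pd.DataFrame(g.uniform(0, 1, size=(n, n_pool)),
                         columns=[f"v{j}" for j in range(n_pool)])
        y = 0.3 + X[true].to_numpy() @ beta + g.normal(scale=0.05, size=n)
        out = exploratory_search(X, y, W, max_size=4)
        if len(out) and set(out.iloc[0]["predictors"]) == set(true):
            success += 1
    return success / n_seeds
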