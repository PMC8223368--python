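"""Kulldorff-style Bernoulli circular spatial scan statistic.

Cases (e.g. pregnant teenagers) and controls are counted per cluster point.
Circular windows grow around every cluster centre by absorbing clusters in
increasing great-circle distance, up to a maximum fraction of the total
population.  Each window is scored by the Bernoulli log-likelihood ratio

    LLR = c ln(c/n) + (n-c) ln((n-c)/n)
        + (C-c) ln((C-c)/(N-n)) + ((N-n)-(C-c)) ln(((N-n)-(C-c))/(N-n))
        - [C ln(C/N) + (N-C) ln((N-C)/N)]        (0 ln 0 := 0)

one-sided towards elevated risk (LLR = 0 whenever the inside rate does not
exceed the outside rate).  Significance comes from Monte Carlo replication
conditioning on the total case count C: cases are redistributed over the N
individuals by simple random sampling without replacement (multivariate
hypergeometric over cluster populations), and each observed cluster's LLR is
ranked against the distribution of replicate maxima.  Secondary clusters are
reported greedily by LLR among windows sharing no member with any
higher-ranked reported cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .weights import pairwise_distances_km


@dataclass
class ScanCluster:
    center_id: object
    radius_km: float
    member_ids: list
    cases_in: int
    pop_in: int
    llr: float
    relative_risk: float
    p_mc: float
    rank: int


def bernoulli_llr(c, n, C, N, mode: str = "high"):
    """Bernoulli log-likelihood ratio of a window (one-sided).

    In the default high-rate scan the LLR is 0 whenever the window rate
    c/n does not exceed the outside rate; ``mode="low"`` scans for
    depressed rates instead (0 unless the window rate is below the outside
    rate).  Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(c < 0) or np.any(c > n) or np.any(n > N) or np.any(c > C) \
            or np.any(C > N) or np.any(n < 1) or np.any(N - n < 1) \
            or np.any(C - c > N - n):
        raise ValueError("LLR arguments violate 0 <= c <= n <= N, c <= C <= N, "
                         "C - c <= N - n, n >= 1, N - n >= 1")
    n_out = N - n
    c_out = C - c
    ll_alt = (xlogy(c, c / n) + xlogy(n - c, (n - c) / n)
              + xlogy(c_out, c_out / n_out)
              + xlogy(n_out - c_out, (n_out - c_out) / n_out))
    ll_null = xlogy(C, C / N) + xlogy(N - C, (N - C) / N)
    llr = ll_alt - ll_null
    if mode == "high":
        keep = c / n > c_out / n_out
    elif mode == "low":
        keep = c / n < c_out / n_out
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.where(keep, np.maximum(llr, 0.0), 0.0)
    return float(out) if out.ndim == 0 else out


def relative_risk(c, n, C, N):
    """Rate inside a window over the rate outside: (c/n) / ((C-c)/(N-n)).

    Returns +inf when every case lies inside (C == c).
    """
    c, n, C, N = float(c), float(n), float(C), float(N)
    if n <= 0 or N - n <= 0:
        raise ValueError("window and its complement must both be nonempty")
    if not (0 <= c <= n and c <= C <= N):
        raise ValueError("counts violate 0 <= c <= n, c <= C <= N")
    inside = c / n
    if C - c == 0:
        return float("inf")
    return inside / ((C - c) / (N - n))


@dataclass
class _WindowGrid:
    """Prefix representation of all circular windows.

    For centre i, ``order[i]`` lists cluster indices by increasing distance
    (self first); the window with k members is the first k entries.  A prefix
    is a valid window iff its population respects ``max_fraction`` and it
    does not split a distance tie (tied clusters enter together).
    """

    order: np.ndarray          # (n, n) int
    radius: np.ndarray         # (n, n) distance to k-th member (col k-1)
    pop_prefix: np.ndarray     # (n, n) cumulative population
    valid: np.ndarray          # (n, n) bool
    pop: np.ndarray = field(repr=False, default=None)


def enumerate_windows(lon, lat, population, max_fraction: float = 0.5) -> _WindowGrid:
    """Enumerate every candidate circular window as distance-ordered prefixes."""
    pop = np.asarray(population)
    n = pop.size
    if n == 0:
        raise ValueError("empty input")
    if not 0 < max_fraction <= 0.5:
        raise ValueError("max_fraction must be in (0, 0.5]")
    D = pairwise_distances_km(lon, lat)
    # stable sort keeps index order within distance ties
    order = np.argsort(D, axis=1, kind="stable")
    dist_sorted = np.take_along_axis(D, order, axis=1)
    pop_prefix = np.cumsum(np.take_along_axis(
        np.broadcast_to(pop, (n, n)), order, axis=1), axis=1)
    pop_cap = np.floor(max_fraction * pop.sum())
    # a prefix of length k (column k-1) is a tie boundary iff d_k < d_{k+1}
    boundary = np.ones((n, n), dtype=bool)
    boundary[:, :-1] = dist_sorted[:, 1:] > dist_sorted[:, :-1]
    valid = boundary & (pop_prefix <= pop_cap)
    return _WindowGrid(order=order, radius=dist_sorted, pop_prefix=pop_prefix,
                       valid=valid, pop=pop)


def window_member_sets(grid: _WindowGrid):
    """All (center_index, frozenset-of-member-indices) valid windows."""
    out = []
    n = grid.order.shape[0]
    for i in range(n):
        for k in np.flatnonzero(grid.valid[i]) + 1:
            out.append((i, frozenset(grid.order[i, :k].tolist())))
    return out


def _llr_grid(grid: _WindowGrid, cases: np.ndarray) -> np.ndarray:
    """LLR of every valid prefix window for one case vector; invalid -> 0."""
    n = cases.size
    C = float(cases.sum())
    N = float(grid.pop.sum())
    case_prefix = np.cumsum(np.take_along_axis(
        np.broadcast_to(cases, (n, n)), grid.order, axis=1), axis=1)
    llr = np.zeros((n, n))
    m = grid.valid & (grid.pop_prefix < N)  # complement must be nonempty
    c = case_prefix[m].astype(float)
    npop = grid.pop_prefix[m].astype(float)
    llr[m] = bernoulli_llr(c, npop, C, N)
    return llr


def _replicate_maxima(grid, C, n_reps, rng):
    n = grid.pop.size
    maxima = np.empty(n_reps)
    reps = rng.multivariate_hypergeometric(
        np.asarray(grid.pop, dtype=np.int64), int(C), size=n_reps)
    for b in range(n_reps):
        maxima[b] = _llr_grid(grid, reps[b]).max()
    return maxima


def scan_mc(
    lon,
    lat,
    cases,
    population,
    ids=None,
    max_fraction: float = 0.5,
    n_reps: int = 999,
    seed: int | None = None,
    p_threshold: float = 0.05,
    max_clusters: int = 10,
) -> list[ScanCluster]:
    """Full Bernoulli scan: ranked non-overlapping clusters with Monte Carlo p.

    ``p_mc = (1 + #{replicate max LLR >= cluster LLR}) / (1 + n_reps)``; at
    most ``max_clusters`` clusters with ``p_mc <= p_threshold`` are reported
    (the primary cluster is always reported, whatever its p).
    """
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99")
    cases = np.asarray(cases, dtype=np.int64)
    pop = np.asarray(population, dtype=np.int64)
    if np.any(cases < 0) or np.any(cases > pop):
        raise ValueError("need 0 <= cases <= population per cluster")
    C = int(cases.sum())
    N = int(pop.sum())
    if C < 1 or N <= C:
        raise ValueError("need total cases >= 1 and some controls")
    if ids is None:
        ids = np.arange(pop.size)
    ids = np.asarray(ids)

    grid = enumerate_windows(lon, lat, pop, max_fraction)
    llr = _llr_grid(grid, cases)
    maxima = _replicate_maxima(grid, C, n_reps, np.random.default_rng(seed))

    # rank windows by LLR desc, greedy member-set disjointness
    flat = np.argsort(llr, axis=None, kind="stable")[::-1]
    reported: list[ScanCluster] = []
    covered = np.zeros(pop.size, dtype=bool)
    for f in flat:
        i, km1 = divmod(int(f), pop.size)
        if not grid.valid[i, km1]:
            continue
        if llr[i, km1] <= 0:
            break
        k = km1 + 1
        members = grid.order[i, :k]
        if covered[members].any():
            continue
        p_mc = (1 + int(np.sum(maxima >= llr[i, km1]))) / (1 + n_reps)
        # LLR is descending, so p_mc only grows: once a secondary candidate
        # misses the significance gate, nothing later can pass it
        if reported and p_mc > p_threshold:
            break
        c_in = int(cases[members].sum())
        n_in = int(pop[members].sum())
        reported.append(ScanCluster(
            center_id=ids[i],
            radius_km=float(grid.radius[i, km1]),
            member_ids=ids[members].tolist(),
            cases_in=c_in,
            pop_in=n_in,
            llr=float(llr[i, km1]),
            relative_risk=relative_risk(c_in, n_in, C, N),
            p_mc=p_mc,
            rank=len(reported) + 1,
        ))
        covered[members] = True
        if len(reported) >= max_clusters:
            break
    return reported
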