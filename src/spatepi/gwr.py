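"""Geographically weighted regression over survey cluster points.

At every cluster location (u_i, v_i) a weighted least-squares fit

    beta_hat(u_i, v_i) = (X' W_i X)^-1 X' W_i y

is computed with diagonal kernel weights W_i that decay with great-circle
distance from the regression point, so each location gets its own
coefficient vector.  Kernels: gaussian exp(-(d/b)^2 / 2) or bisquare
(1 - (d/b)^2)^2 for d < b (0 beyond); with an adaptive kernel the local
bandwidth b_i is the distance to the N-th nearest neighbour of the
regression point.  Model fit is summarised through the hat matrix rows
s_i = x_i (X' W_i X)^-1 X' W_i: the effective number of parameters is
tr(S) = sum_i s_ii, and the corrected AIC is

    AICc = 2 n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S)

with sigma_hat^2 = RSS / n.  Bandwidth is selected by golden-section
minimisation of AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weights import pairwise_distances_km


class LocalSingularityError(ValueError):
    def __init__(self, location_index, covariates):
        self.location_index = int(location_index)
        self.covariates = list(covariates)
        msg = (f"local design singular at location {self.location_index}")
        if self.covariates:
            msg += (f": covariate(s) {self.covariates} locally constant under "
                    f"the kernel; widen the bandwidth")
        super().__init__(msg)


@dataclass
class GWRResult:
    names: list
    params: np.ndarray               # n x (k+1), intercept first
    local_r2: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    bandwidth: float
    kernel: str
    adaptive: bool
    trace_S: float
    sigma: float
    rss: float
    aicc: float
    r2: float
    adj_r2: float
    n: int = 0
    k: int = 0

    def summary(self) -> dict:
        """Table-3-style global metrics block."""
        return {
            "bandwidth": self.bandwidth,
            "kernel": self.kernel,
            "adaptive": self.adaptive,
            "effective_number": self.trace_S,
            "sigma": self.sigma,
            "aicc": self.aicc,
            "residual_squares": self.rss,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
        }


def kernel_weight(d_km, bandwidth, kernel: str = "bisquare"):
    """Kernel weight in [0, 1] at distance d for a given bandwidth (km)."""
    if np.any(np.asarray(bandwidth) <= 0):
        raise ValueError("bandwidth must be positive")
    d = np.asarray(d_km, dtype=float)
    r = d / bandwidth
    if kernel == "gaussian":
        return np.exp(-0.5 * r ** 2)
    if kernel == "bisquare":
        return np.where(r < 1.0, (1.0 - r ** 2) ** 2, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


def _weight_matrix(D, bandwidth, kernel, adaptive):
    if adaptive:
        nn = int(round(bandwidth))
        n = D.shape[0]
        if not 1 <= nn <= n:
            raise ValueError(f"adaptive bandwidth {nn} outside 1..{n}")
        # local bandwidth: distance to the nn-th nearest neighbour (self incl.)
        b = np.sort(D, axis=1)[:, nn - 1]
        b = np.maximum(b, 1e-12)
        return kernel_weight(D, b[:, None], kernel)
    return kernel_weight(D, float(bandwidth), kernel)


def fit_gwr(
    X: pd.DataFrame,
    y,
    lon,
    lat,
    bandwidth,
    kernel: str = "bisquare",
    adaptive: bool = True,
) -> GWRResult:
    """Kernel-weighted local least squares at every cluster location."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = ["intercept"] + list(X.columns)
    Xd = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p = k + 1
    D = pairwise_distances_km(lon, lat)
    Wm = _weight_matrix(D, bandwidth, kernel, adaptive)   # n x n, row i = W_i

    support = (Wm > 0).sum(axis=1)
    if np.any(support < p + 1):
        i = int(np.argmin(support))
        raise LocalSingularityError(i, [])

    # batched X' W_i X and X' W_i y over all locations
    XtWX = np.einsum("in,np,nq->ipq", Wm, Xd, Xd)
    XtWy = np.einsum("in,np,n->ip", Wm, Xd, y)
    try:
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]   # n x p
    except np.linalg.LinAlgError:
        for i in range(n):
            if np.linalg.matrix_rank(XtWX[i]) < p:
                w = Wm[i]
                var = ((Xd - (w @ Xd) / w.sum()) ** 2 * w[:, None]).sum(axis=0)
                bad = [names[j] for j in range(1, p) if var[j] < 1e-12]
                raise LocalSingularityError(i, bad)
        raise

    fitted = np.einsum("ip,ip->i", Xd, beta)
    resid = y - fitted
    rss = float(resid @ resid)

    # hat diagonal: s_ii = w_ii * x_i (X'W_iX)^-1 x_i'
    sol = np.linalg.solve(XtWX, Xd[..., None])           # n x p x 1
    s_ii = np.einsum("ip,ip->i", Xd, sol[..., 0]) * np.diag(Wm)
    trace_S = float(s_ii.sum())

    # local weighted R^2 at each regression point
    wsum = Wm.sum(axis=1)
    ybar_w = (Wm @ y) / wsum
    pred_all = Xd @ beta.T                                # pred_all[j, i]: x_j beta_i
    res2 = (y[:, None] - pred_all) ** 2                   # j x i
    local_rss = np.einsum("in,ni->i", Wm, res2)
    local_tss = np.einsum("in,ni->i", Wm, (y[:, None] - ybar_w[None, :]) ** 2)
    local_r2 = 1.0 - local_rss / local_tss

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - trace_S - 1.0)
    return GWRResult(
        names=names, params=beta, local_r2=local_r2, residuals=resid,
        fitted=fitted, bandwidth=float(bandwidth), kernel=kernel,
        adaptive=adaptive, trace_S=trace_S,
        sigma=float(np.sqrt(rss / n)), rss=rss,
        aicc=gwr_aicc(n, rss, trace_S), r2=r2, adj_r2=adj, n=n, k=k,
    )


def gwr_aicc(n: int, rss: float, trace_s: float) -> float:
    """Corrected AIC for a GWR fit (hat-matrix trace as parameter count)."""
    if n - 2.0 - trace_s <= 0:
        raise ValueError(
            f"AICc undefined: n - 2 - tr(S) = {n - 2.0 - trace_s:.3f} <= 0; "
            f"increase the bandwidth")
    sigma2 = rss / n
    return float(n * np.log(sigma2) + n * np.log(2.0 * np.pi)
                 + n * (n + trace_s) / (n - 2.0 - trace_s))


def select_bandwidth(
    X,
    y,
    lon,
    lat,
    kernel: str = "bisquare",
    adaptive: bool = True,
    interval: tuple | None = None,
    tol_frac: float = 1e-2,
):
    """Golden-section minimisation of AICc over the bandwidth.

    Returns ``(bandwidth, trace)`` where ``trace`` is a DataFrame of every
    (bandwidth, AICc) pair evaluated.  Adaptive bandwidths are integer
    neighbour counts; candidates are rounded and memoised.
    """
    X = pd.DataFrame(X)
    n = len(X)
    p = X.shape[1] + 1
    if interval is None:
        if adaptive:
            interval = (max(p + 2, 10), n)
        else:
            D = pairwise_distances_km(lon, lat)
            pos = D[D > 0]
            interval = (float(np.median(np.sort(D, axis=1)[:, min(p + 2, n - 1)])),
                        float(pos.max()))
    lo, hi = float(interval[0]), float(interval[1])
    if lo > hi:
        raise ValueError(f"inverted search interval ({lo} > {hi})")

    cache: dict = {}

    def f(b):
        key = int(round(b)) if adaptive else round(b, 9)
        if key not in cache:
            try:
                cache[key] = fit_gwr(X, y, lon, lat, key, kernel, adaptive).aicc
            except (ValueError, np.linalg.LinAlgError):
                cache[key] = np.inf
        return cache[key]

    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = f(c), f(d)
    tol = tol_frac * (hi - lo)
    while (b - a) > max(tol, 1.0 if adaptive else 0.0):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = f(d)
    # also probe the interval ends; golden section can stall near a boundary
    for edge in (lo, hi):
        f(edge)
    if not np.isfinite(min(cache.values())):
        raise ValueError("AICc non-finite across the whole search interval")
    best = min(cache, key=lambda kk: (cache[kk], kk))
    trace = pd.DataFrame(sorted(cache.items()), columns=["bandwidth", "aicc"])
    return (float(best), trace)


def compare_models(aicc_a: float, aicc_b: float, threshold: float = 3.0,
                   labels: tuple = ("a", "b")) -> str:
    """AICc model preference: lower wins only if |delta| exceeds threshold."""
    if not (np.isfinite(aicc_a) and np.isfinite(aicc_b)):
        raise ValueError("AICc values must be finite")
    if abs(aicc_a - aicc_b) <= threshold:
        return "indistinguishable"
    return labels[0] if aicc_a < aicc_b else labels[1]


def quantile_breaks(values, n_classes: int = 5):
    """Quantile class breaks for mapping; duplicate breaks collapse."""
    qs = np.quantile(np.asarray(values, dtype=float),
                     np.linspace(0, 1, n_classes + 1))
    return np.unique(qs).tolist()


def coefficient_surfaces(result: GWRResult, lon, lat, ids=None) -> dict:
    """One GeoJSON point layer per covariate: coefficient + local R2.

    Layer metadata carries 5-class quantile breaks for choropleth mapping
    (degenerate constant fields collapse to fewer breaks).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if ids is None:
        ids = np.arange(result.n)
    layers = {}
    for j, name in enumerate(result.names):
        coef = result.params[:, j]
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(lon[i]), float(lat[i])]},
                "properties": {
                    "cluster_id": _jsonable(ids[i]),
                    "coefficient": float(coef[i]),
                    "local_r2": float(result.local_r2[i]),
                },
            }
            for i in range(result.n)
        ]
        layers[name] = {
            "type": "FeatureCollection",
            "features": features,
            "metadata": {"variable": name,
                         "quantile_breaks": quantile_breaks(coef)},
        }
    return layers


def _jsonable(v):
    return v.item() if hasattr(v, "item") else v
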