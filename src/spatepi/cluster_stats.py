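"""Global spatial autocorrelation (Moran's I) and Getis-Ord Gi* hotspots.

Moran's I is the cross-product statistic

    I = (n / S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

with expectation -1/(n-1) under spatial randomness.  Inference is offered
both analytically (normality assumption, as ArcGIS reports) and by random
permutation of the values over locations.

Gi* is the self-inclusive local statistic whose z-score flags clusters of
high values (hot spots) and low values (cold spots); z-scores are binned at
the conventional 90/95/99% thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import SpatialWeights

HOT_CATEGORIES = ("cold99", "cold95", "cold90", "not-significant",
                  "hot90", "hot95", "hot99")


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z: float
    p_analytic: float
    n: int
    p_permutation: float | None = None


@dataclass
class GiStarResult:
    ids: np.ndarray
    z: np.ndarray
    p: np.ndarray
    category: np.ndarray


def _moran_prepare(values, W: SpatialWeights):
    y = np.asarray(values, dtype=float)
    if y.size != W.n:
        raise ValueError(f"{y.size} values for {W.n} locations")
    if y.size < 3:
        raise ValueError("need at least 3 locations")
    if np.ptp(y) == 0:
        raise ValueError("values are constant: Moran's I undefined (zero variance)")
    if W.includes_self or any((nb == i).any() for i, nb in enumerate(W.neighbors)):
        raise ValueError("Moran's I requires weights without self-neighbours")
    z = y - y.mean()
    Wsp = W.to_sparse()
    return z, Wsp


def morans_i(values, W: SpatialWeights) -> MoranResult:
    """Global Moran's I with analytic z/p under the normality assumption."""
    z, Wsp = _moran_prepare(values, W)
    n = z.size
    S0 = Wsp.sum()
    num = float(z @ (Wsp @ z))
    I = (n / S0) * num / float(z @ z)

    # normality-assumption moments
    B = (Wsp + Wsp.T).tocsr()
    S1 = 0.5 * float(B.power(2).sum())
    row = np.asarray(Wsp.sum(axis=1)).ravel()
    col = np.asarray(Wsp.sum(axis=0)).ravel()
    S2 = float(((row + col) ** 2).sum())
    EI = -1.0 / (n - 1)
    EI2 = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / (S0 * S0 * (n * n - 1.0))
    var = max(EI2 - EI * EI, 0.0)
    zscore = (I - EI) / np.sqrt(var) if var > 0 else np.nan
    p = 2.0 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan
    return MoranResult(I=I, expected_I=EI, variance=var, z=zscore,
                       p_analytic=float(p), n=n)


def moran_permutation(
    values,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> float:
    """Permutation p-value for Moran's I: p = (r + 1) / (n_perm + 1).

    ``alternative="greater"`` counts permuted I >= observed (clustering);
    ``"two-sided"`` folds around the permutation mean.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    z, Wsp = _moran_prepare(values, W)
    n = z.size
    S0 = Wsp.sum()
    denom = float(z @ z)
    I_obs = (n / S0) * float(z @ (Wsp @ z)) / denom

    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    scale = n / (S0 * denom)
    for b in range(n_perm):
        zp = rng.permutation(z)
        perms[b] = scale * float(zp @ (Wsp @ zp))
    if alternative == "greater":
        r = int(np.sum(perms >= I_obs))
    elif alternative == "two-sided":
        center = perms.mean()
        r = int(np.sum(np.abs(perms - center) >= abs(I_obs - center)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (r + 1) / (n_perm + 1)


def getis_ord_gistar(values, W: SpatialWeights) -> GiStarResult:
    """Getis-Ord Gi* z-scores; weights must include self-neighbours.

    z_i = [sum_j w_ij x_j - Xbar sum_j w_ij] /
          (S * sqrt[(n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1)])

    with Xbar, S the global mean and (population) standard deviation.
    """
    x = np.asarray(values, dtype=float)
    if x.size != W.n:
        raise ValueError(f"{x.size} values for {W.n} locations")
    if not W.includes_self:
        raise ValueError("Gi* requires self-inclusive weights (include_self=True)")
    if np.ptp(x) == 0:
        raise ValueError("values are constant: Gi* undefined (zero variance)")
    n = x.size
    xbar = x.mean()
    S = np.sqrt((x ** 2).mean() - xbar ** 2)
    Wsp = W.to_sparse()
    wx = np.asarray(Wsp @ x).ravel()
    wsum = np.asarray(Wsp.sum(axis=1)).ravel()
    w2sum = np.asarray(Wsp.power(2).sum(axis=1)).ravel()
    spread = (n * w2sum - wsum ** 2) / (n - 1.0)
    if np.any(spread <= 0):
        bad = W.ids[spread <= 0].tolist()
        raise ValueError(
            f"Gi* undefined where the window spans the whole study area "
            f"(features {bad}); use a smaller band or k")
    z = (wx - xbar * wsum) / (S * np.sqrt(spread))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return GiStarResult(ids=W.ids.copy(), z=z, p=p,
                        category=classify_hotspots(z))


def classify_hotspots(
    z_scores,
    thresholds=(1.645, 1.96, 2.576),
    p_values=None,
    fdr: bool = False,
    alpha: float = 0.05,
):
    """Bin z-scores into hot/cold confidence classes.

    Symmetric by |z| and sign: |z| above the 1st/2nd/3rd threshold maps to
    the 90/95/99% class.  With ``fdr=True`` a Benjamini-Hochberg gate on
    ``p_values`` forces non-discoveries to "not-significant" first.
    """
    z = np.asarray(z_scores, dtype=float)
    t = tuple(float(v) for v in thresholds)
    if not (t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be strictly increasing")
    keep = np.ones(z.size, dtype=bool)
    if fdr:
        if p_values is None:
            raise ValueError("FDR gating requires p_values")
        from statsmodels.stats.multitest import multipletests
        keep = multipletests(np.asarray(p_values, float), alpha=alpha,
                             method="fdr_bh")[0]
    level = np.select(
        [np.abs(z) >= t[2], np.abs(z) >= t[1], np.abs(z) >= t[0]], [3, 2, 1], 0
    )
    level = np.where(keep, level, 0)
    names = {0: "not-significant"}
    for sgn, tag in ((1, "hot"), (-1, "cold")):
        for lv, pct in ((1, "90"), (2, "95"), (3, "99")):
            names[sgn * lv] = f"{tag}{pct}"
    signed = level * np.where(z >= 0, 1, -1)
    return np.array([names[int(v)] for v in signed], dtype=object)
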