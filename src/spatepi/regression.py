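"""OLS on cluster proportions with the full spatial-diagnostics battery.

The global model is ordinary least squares of the per-cluster outcome
proportion on community covariates, judged reliable only when it passes the
whole assumption battery: every coefficient significant under
heteroskedasticity-robust (HC1) inference, no collinearity (VIF < 7.5),
normal residuals (Jarque-Bera), homoskedastic residuals (Koenker's
studentized Breusch-Pagan), and residuals free of spatial autocorrelation
(Moran's I).  ``exploratory_search`` fits every predictor subset and returns
the ones passing all gates ranked by adjusted R-squared, mirroring the
exploratory-regression workflow of desktop GIS tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cluster_stats import morans_i
from .weights import SpatialWeights


class RankDeficiencyError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear or "
                         f"degenerate columns: {self.columns}")


@dataclass
class OLSResult:
    names: list                      # includes "intercept" first
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    robust_bse: np.ndarray
    robust_t: np.ndarray
    robust_p: np.ndarray
    vif: dict
    r2: float
    adj_r2: float
    f_stat: float
    f_df: tuple
    f_p: float
    wald_stat: float
    wald_df: int
    wald_p: float
    koenker_stat: float
    koenker_df: int
    koenker_p: float
    jb_stat: float
    jb_p: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    n: int = 0
    k: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.names,
            "coefficient": self.params,
            "se": self.bse,
            "t": self.tvalues,
            "p": self.pvalues,
            "robust_se": self.robust_bse,
            "robust_t": self.robust_t,
            "robust_p": self.robust_p,
            "vif": [np.nan] + [self.vif[v] for v in self.names[1:]],
        })


def _check_full_rank(Xd: np.ndarray, names):
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        # name the columns implicated via pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(Xd, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
        bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
        raise RankDeficiencyError(bad or names)


def fit_ols(X: pd.DataFrame, y) -> OLSResult:
    """Least-squares fit with classical and HC1-robust inference.

    ``X`` holds the predictors only; an intercept is always added.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    names = ["intercept"] + list(X.columns)
    Xd = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    _check_full_rank(Xd, names)

    fit = sm.OLS(y, Xd).fit()
    rob = fit.get_robustcov_results(cov_type="HC1")

    resid = np.asarray(fit.resid)
    rss = float(resid @ resid)
    r2 = float(fit.rsquared)
    adj = float(fit.rsquared_adj)

    if k >= 2:
        vifs = vif(X)
    elif k == 1:
        vifs = {names[1]: 1.0}
    else:
        vifs = {}

    if k >= 1:
        f_stat, f_df, f_p = _joint_f(r2, n, k)
        V = np.asarray(rob.cov_params())[1:, 1:]
        beta_s = fit.params[1:]
        wald = float(beta_s @ np.linalg.solve(V, beta_s))
        wald_p = float(stats.chi2.sf(wald, k))
        ko_stat, ko_p = koenker_bp(X, resid)
    else:
        f_stat = f_p = wald = wald_p = np.nan
        f_df = (0, n - 1)
        ko_stat, ko_p = np.nan, np.nan

    jb_stat, jb_p = jarque_bera(resid)

    return OLSResult(
        names=names,
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        robust_bse=np.asarray(rob.bse),
        robust_t=np.asarray(rob.tvalues),
        robust_p=np.asarray(rob.pvalues),
        vif=vifs,
        r2=r2,
        adj_r2=adj,
        f_stat=f_stat, f_df=f_df, f_p=f_p,
        wald_stat=wald, wald_df=k, wald_p=wald_p,
        koenker_stat=ko_stat, koenker_df=k, koenker_p=ko_p,
        jb_stat=jb_stat, jb_p=jb_p,
        aicc=aicc(n, k + 1, rss),
        residuals=resid,
        fitted=np.asarray(fit.fittedvalues),
        n=n, k=k,
    )


def vif(X: pd.DataFrame) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing predictor j on the remaining predictors plus
    an intercept.  Perfect collinearity is flagged as +inf, not raised.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(A, j, axis=1)])
        r2j = sm.OLS(A[:, j], others).fit().rsquared
        out[name] = float("inf") if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return out


def jarque_bera(residuals) -> tuple:
    """JB = n/6 * (S^2 + (K-3)^2 / 4); p from chi-square with 2 df."""
    e = np.asarray(residuals, dtype=float)
    n = e.size
    if n < 8:
        raise ValueError("Jarque-Bera needs n >= 8")
    if np.ptp(e) == 0:
        raise ValueError("zero-variance residuals")
    S = stats.skew(e, bias=True)
    K = stats.kurtosis(e, fisher=False, bias=True)
    jb = n / 6.0 * (S ** 2 + (K - 3.0) ** 2 / 4.0)
    return float(jb), float(stats.chi2.sf(jb, 2))


def koenker_bp(X: pd.DataFrame, residuals) -> tuple:
    """Koenker's studentized Breusch-Pagan: n * R2 of e^2 on X; chi2(k) p."""
    X = pd.DataFrame(X)
    e2 = np.asarray(residuals, dtype=float) ** 2
    n, k = X.shape
    if np.ptp(e2) == 0:
        return 0.0, 1.0
    Xd = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    r2_aux = sm.OLS(e2, Xd).fit().rsquared
    stat = n * float(r2_aux)
    return stat, float(stats.chi2.sf(stat, k))


def _joint_f(r2, n, k):
    if r2 >= 1.0:
        return float("inf"), (k, n - k - 1), 0.0
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return float(f), (k, n - k - 1), float(stats.f.sf(f, k, n - k - 1))


def joint_tests(result: OLSResult) -> dict:
    """Joint F (classical) and robust joint Wald on the slope coefficients."""
    if result.k == 0:
        raise ValueError("intercept-only model: no slopes to test jointly")
    return {
        "f_stat": result.f_stat, "f_df": result.f_df, "f_p": result.f_p,
        "wald_stat": result.wald_stat, "wald_df": result.wald_df,
        "wald_p": result.wald_p,
    }


def aicc(n: int, k_params: int, rss: float) -> float:
    """Gaussian-likelihood corrected AIC.

    K = k_params + 1 counts the residual variance as a parameter:
    AICc = n ln(2 pi RSS / n) + n + 2K + 2K(K+1)/(n - K - 1).
    """
    if rss <= 0:
        raise ValueError("RSS must be positive")
    K = k_params + 1
    if n <= K + 1:
        raise ValueError("n too small for AICc correction")
    return float(n * np.log(2.0 * np.pi * rss / n) + n + 2 * K
                 + 2.0 * K * (K + 1) / (n - K - 1))


@dataclass
class AssumptionReport:
    coefficients_significant: bool
    vif_ok: bool
    jb_p: float
    koenker_p: float
    residual_moran_I: float
    residual_moran_p: float
    passed: bool


def check_ols_assumptions(
    result: OLSResult,
    W: SpatialWeights,
    alpha: float = 0.05,
    vif_threshold: float = 7.5,
) -> AssumptionReport:
    """Gate an OLS fit on the full assumption battery.

    Pass requires: all coefficients significant at ``alpha`` under robust
    inference; every VIF strictly below ``vif_threshold``; Jarque-Bera,
    Koenker BP and residual Moran's I all non-significant at ``alpha``.
    """
    sig = bool(np.all(result.robust_p < alpha))
    vif_ok = all(v < vif_threshold for v in result.vif.values()) if result.vif else True
    mor = morans_i(result.residuals, W)
    passed = (sig and vif_ok and result.jb_p >= alpha
              and result.koenker_p >= alpha and mor.p_analytic >= alpha)
    return AssumptionReport(
        coefficients_significant=sig,
        vif_ok=vif_ok,
        jb_p=result.jb_p,
        koenker_p=result.koenker_p,
        residual_moran_I=mor.I,
        residual_moran_p=mor.p_analytic,
        passed=passed,
    )


def exploratory_search(
    X_pool: pd.DataFrame,
    y,
    W: SpatialWeights,
    max_size: int | None = None,
    alpha: float = 0.05,
    vif_threshold: float = 7.5,
) -> pd.DataFrame:
    """Exhaustive subset search keeping only models passing every gate.

    Fits all predictor subsets of size 1..max_size and returns the passing
    ones ranked by adjusted R-squared (descending), with their diagnostics.
    Deterministic: ties broken by subset order of enumeration.
    """
    X_pool = pd.DataFrame(X_pool)
    cols = list(X_pool.columns)
    if not cols:
        raise ValueError("empty candidate predictor list")
    if len(cols) > 12:
        raise ValueError("exhaustive search limited to <= 12 candidates")
    if max_size is None:
        max_size = len(cols)
    rows = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(cols, size):
            res = fit_ols(X_pool[list(subset)], y)
            rep = check_ols_assumptions(res, W, alpha=alpha,
                                        vif_threshold=vif_threshold)
            if rep.passed:
                rows.append({
                    "predictors": subset,
                    "adj_r2": res.adj_r2,
                    "r2": res.r2,
                    "aicc": res.aicc,
                    "jb_p": rep.jb_p,
                    "koenker_p": rep.koenker_p,
                    "residual_moran_p": rep.residual_moran_p,
                })
    out = pd.DataFrame(rows, columns=["predictors", "adj_r2", "r2", "aicc",
                                      "jb_p", "koenker_p", "residual_moran_p"])
    if len(out):
        out = out.sort_values("adj_r2", ascending=False, kind="stable")
        out.index = np.arange(1, len(out) + 1)
        out.index.name = "rank"
    return out
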