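"""Pre-analysis screening: parcel construction, descriptives, reliability,
multivariate normality, and the missing-completely-at-random test.

Skewness and kurtosis default to the small-sample-adjusted formulas common in
social-science software (the pandas/SPSS convention: bias-corrected skewness
and excess kurtosis); the plain moment definitions are available via
``adjusted=False``.  Correlations are pairwise-complete by default, matching
descriptive tables built on data with posttest attrition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, skew as _moment_skew, kurtosis as _moment_kurt

from .estimation import em_mvn

__all__ = [
    "make_parcels",
    "descriptives",
    "cronbach_alpha",
    "mardia_tests",
    "little_mcar_test",
    "MardiaResult",
    "LittleResult",
]


# ---------------------------------------------------------------------------
# parcels
# ---------------------------------------------------------------------------

def make_parcels(items: pd.DataFrame, n_parcels: int = 2, seed: int = 0,
                 prefix: str = "parcel") -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Randomly partition items into near-equal parcels (parallel forms).

    Each parcel score is the mean of its items over the case's non-missing
    items.  Returns the parcel score table and the item assignment, which
    should be persisted for reproducibility.
    """
    cols = list(items.columns)
    k = len(cols)
    if n_parcels < 1 or n_parcels > k:
        raise ValueError(f"cannot split {k} items into {n_parcels} parcels")
    rng = np.random.default_rng(seed)
    order = [cols[i] for i in rng.permutation(k)]
    assignment = {f"{prefix}{j + 1}": order[j::n_parcels] for j in range(n_parcels)}
    scores = pd.DataFrame({
        name: items[members].mean(axis=1, skipna=True)
        for name, members in assignment.items()
    }, index=items.index)
    return scores, assignment


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def _skew_kurt(x: np.ndarray, adjusted: bool) -> tuple[float, float]:
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        return np.nan, np.nan
    if adjusted:
        s = pd.Series(x)
        return float(s.skew()), float(s.kurt())
    return float(_moment_skew(x)), float(_moment_kurt(x))


@dataclass
class Descriptives:
    """Per-variable summary statistics plus a correlation matrix."""

    table: pd.DataFrame          # columns: n, mean, sd, skewness, kurtosis
    correlations: pd.DataFrame

    def __str__(self) -> str:
        return (self.table.to_string(float_format=lambda v: f"{v:.3f}")
                + "\n\nCorrelations (pairwise complete):\n"
                + self.correlations.to_string(float_format=lambda v: f"{v:.3f}"))


def descriptives(table: pd.DataFrame, *, adjusted: bool = True,
                 listwise: bool = False) -> Descriptives:
    """Means, SDs, adjusted skewness/kurtosis, per-variable n, correlations."""
    df = table.dropna() if listwise else table
    zero_var = [c for c in df.columns if np.nanvar(df[c].to_numpy(float)) == 0]
    if zero_var:
        raise ValueError(f"zero-variance variable(s): {zero_var}; "
                         "correlations undefined")
    rows = {}
    for c in df.columns:
        x = df[c].to_numpy(dtype=float)
        sk, ku = _skew_kurt(x, adjusted)
        rows[c] = {"n": int(np.sum(~np.isnan(x))),
                   "mean": float(np.nanmean(x)),
                   "sd": float(np.nanstd(x, ddof=1)),
                   "skewness": sk, "kurtosis": ku}
    corr = df.corr(method="pearson")   # pairwise-complete by construction
    return Descriptives(table=pd.DataFrame(rows).T, correlations=corr)


def descriptives_by_group(table: pd.DataFrame, group_col: str = "group",
                          **kwargs) -> dict[str, Descriptives]:
    return {gid: descriptives(sub.drop(columns=[group_col]), **kwargs)
            for gid, sub in table.groupby(group_col, sort=False)}


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha on listwise-complete cases.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))``.
    """
    df = items.dropna()
    k = df.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least two items")
    if df.shape[0] < 3:
        raise ValueError("alpha needs at least three complete cases")
    item_vars = df.var(axis=0, ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Mardia's multivariate normality tests
# ---------------------------------------------------------------------------

@dataclass
class MardiaResult:
    b1p: float
    skew_statistic: float
    skew_df: int
    skew_p: float
    b2p: float
    kurtosis_statistic: float
    kurtosis_p: float
    n: int
    alpha: float
    skew_normal: bool
    kurtosis_normal: bool


def mardia_tests(table: pd.DataFrame | np.ndarray, *,
                 alpha: float = 0.001) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests (listwise complete).

    Skewness: ``n * b1p / 6`` against chi-square with ``p(p+1)(p+2)/6`` df.
    Kurtosis: two-sided normal test of ``b2p`` against ``p(p+2)``.  The
    default decision level is 0.001 — the usual guard against this test's
    tendency to over-reject at conventional levels.
    """
    arr = (table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame)
           else np.asarray(table, dtype=float))
    arr = arr[~np.isnan(arr).any(axis=1)]
    n, p = arr.shape
    if n <= p:
        raise ValueError("need more complete cases than variables")
    z = arr - arr.mean(axis=0)
    s = z.T @ z / n                      # ML covariance
    try:
        chol = np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        raise ValueError("singular sample covariance matrix") from None
    from scipy.linalg import solve_triangular
    w = solve_triangular(chol, z.T, lower=True).T       # whitened data
    # b1p = (1/n^2) sum_ij (w_i . w_j)^3 = ||T||^2 / n^2 with the third-moment
    # tensor T_abc = sum_i w_ia w_ib w_ic (exact, avoids the n x n matrix)
    t = np.einsum("ia,ib,ic->abc", w, w, w)
    b1p = float((t ** 2).sum() / n ** 2)
    skew_stat = n * b1p / 6.0
    skew_df = p * (p + 1) * (p + 2) // 6
    skew_p = float(chi2_dist.sf(skew_stat, skew_df))
    d2 = (w ** 2).sum(axis=1)
    b2p = float((d2 ** 2).mean())
    kz = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2.0 * norm.sf(abs(kz)))
    return MardiaResult(
        b1p=b1p, skew_statistic=float(skew_stat), skew_df=skew_df,
        skew_p=skew_p, b2p=b2p, kurtosis_statistic=float(kz),
        kurtosis_p=kurt_p, n=n, alpha=alpha,
        skew_normal=skew_p >= alpha, kurtosis_normal=kurt_p >= alpha)


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

@dataclass
class LittleResult:
    chi_square: float
    df: int
    p_value: float
    n_patterns: int
    applicable: bool


def little_mcar_test(table: pd.DataFrame | np.ndarray) -> LittleResult:
    """Little's test of missing completely at random.

    With grand mean and covariance estimated by EM (homogeneous covariance
    across patterns, the classic statistic), sums over missingness patterns
    ``n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j)`` on each pattern's
    observed coordinates; df is ``sum_j p_j - p``.  With a single pattern
    (no missingness) the test is not applicable.
    """
    arr = (table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame)
           else np.asarray(table, dtype=float))
    arr = arr[~np.isnan(arr).all(axis=1)]
    n, p = arr.shape
    obs = ~np.isnan(arr)
    uniq, inv = np.unique(obs, axis=0, return_inverse=True)
    if uniq.shape[0] < 2:
        return LittleResult(np.nan, 0, np.nan, int(uniq.shape[0]), False)
    mu, sigma, _, _ = em_mvn(arr)
    stat = 0.0
    df = -p
    for j in range(uniq.shape[0]):
        idx = np.flatnonzero(uniq[j])
        rows = arr[inv == j][:, idx]
        n_j = rows.shape[0]
        df += idx.size
        ybar = rows.mean(axis=0)
        diff = ybar - mu[idx]
        sig = sigma[np.ix_(idx, idx)]
        stat += n_j * float(diff @ np.linalg.solve(sig, diff))
    pval = float(chi2_dist.sf(stat, df))
    return LittleResult(chi_square=float(stat), df=int(df), p_value=pval,
                        n_patterns=int(uniq.shape[0]), applicable=True)
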