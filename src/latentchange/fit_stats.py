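"""Fit indices and model-selection statistics for multi-group SEM fits.

Covers the battery conventional in intervention SEM reporting: the
likelihood-ratio chi-square with per-group contributions, CFI/TLI against a
per-group independence baseline, RMSEA with a 90% confidence interval from
inverting the noncentral chi-square distribution, SRMR over standardized mean
and covariance residuals, AIC with Burnham-Anderson delta-AIC rescaling and
support labels, and the nested-model chi-square difference test.

Multi-group RMSEA convention: the point estimate is
``sqrt(max((chi2 - df) / (df * N), 0)) * sqrt(G)`` with ``N`` the total sample
size and ``G`` the number of groups; the ``sqrt(G)`` factor is the convention
that reproduces standard software output for multiple-group models and can be
switched off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from .estimation import FitResult, GroupData, CompiledSpec, _split_patterns, _pattern_loglik
from .model_core import ModelSpec

__all__ = [
    "FitIndexSet",
    "ComparisonResult",
    "rmsea_point",
    "rmsea_ci",
    "cfi_tli",
    "srmr",
    "aic",
    "delta_aic",
    "support_label",
    "chi_square_difference",
    "baseline_chi_square",
    "fit_indices",
]


@dataclass
class FitIndexSet:
    """The fit-index battery for one fitted model."""

    chi_square: float
    df: int
    p_value: float
    cfi: float
    tli: float
    tli_raw: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    aic: float
    delta_aic: float | None = None
    support: str | None = None

    def as_dict(self) -> dict:
        d = {
            "chi_square": self.chi_square, "df": self.df, "p_value": self.p_value,
            "cfi": self.cfi, "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_ci_low": self.rmsea_ci90[0], "rmsea_ci_high": self.rmsea_ci90[1],
            "srmr": self.srmr, "aic": self.aic,
        }
        if self.delta_aic is not None:
            d["delta_aic"] = self.delta_aic
            d["support"] = self.support
        return d


@dataclass
class ComparisonResult:
    """Nested-model likelihood-ratio (chi-square difference) test."""

    delta_chi_square: float
    delta_df: int
    p_value: float
    preferred: str  # "constrained" | "unconstrained"


# ---------------------------------------------------------------------------
# RMSEA
# ---------------------------------------------------------------------------

def rmsea_point(chi_square: float, df: int, total_n: int,
                n_groups: int = 1, multigroup_scale: bool = True) -> float:
    """RMSEA point estimate; ``None``-df models are not admissible here."""
    if df < 1:
        raise ValueError("RMSEA undefined for df < 1")
    if total_n <= 0:
        raise ValueError("total_n must be positive")
    val = np.sqrt(max((chi_square - df) / (df * total_n), 0.0))
    if multigroup_scale:
        val *= np.sqrt(n_groups)
    return float(val)


def _ncp_root(chi_square: float, df: int, target: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi_square; df, lambda) = target."""
    f = lambda lam: ncx2.cdf(chi_square, df, lam) - target
    if f(0.0) < 0.0:       # even lambda = 0 gives too little mass: no root
        return 0.0
    hi = max(chi_square, 1.0)
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > 1e8:
            return hi
    return brentq(f, 0.0, hi, xtol=1e-10)


def rmsea_ci(chi_square: float, df: int, total_n: int, n_groups: int = 1,
             level: float = 0.90, multigroup_scale: bool = True
             ) -> tuple[float, float]:
    """Confidence interval by inverting the noncentral chi-square CDF."""
    if df < 1:
        raise ValueError("RMSEA CI undefined for df < 1")
    tail = (1.0 - level) / 2.0
    lam_lo = _ncp_root(chi_square, df, 1.0 - tail)   # lower endpoint
    lam_hi = _ncp_root(chi_square, df, tail)         # upper endpoint
    scale = np.sqrt(n_groups) if multigroup_scale else 1.0
    low = scale * np.sqrt(lam_lo / (df * total_n))
    high = scale * np.sqrt(lam_hi / (df * total_n))
    return float(low), float(high)


# ---------------------------------------------------------------------------
# incremental indices
# ---------------------------------------------------------------------------

def cfi_tli(chi_model: float, df_model: int, chi_baseline: float,
            df_baseline: int) -> tuple[float, float, float]:
    """CFI and TLI against the independence baseline.

    Returns ``(cfi, tli_clamped, tli_raw)``; TLI is clamped to [0, 1] for
    reporting but the raw value is kept.
    """
    if df_baseline <= 0:
        raise ValueError("baseline model must have positive df")
    d_m = max(chi_model - df_model, 0.0)
    d_b = max(chi_baseline - df_baseline, d_m, 0.0)
    cfi = 1.0 if d_b == 0.0 else 1.0 - d_m / d_b
    rb = chi_baseline / df_baseline
    rm = chi_model / df_model if df_model > 0 else np.nan
    tli_raw = (rb - rm) / (rb - 1.0) if rb != 1.0 else np.nan
    tli = float(np.clip(tli_raw, 0.0, 1.0)) if np.isfinite(tli_raw) else np.nan
    return float(cfi), tli, float(tli_raw)


def baseline_chi_square(data: Mapping[str, GroupData], *,
                        n_convention: str = "n") -> tuple[float, int]:
    """Independence-baseline chi-square and df.

    Baseline: per group, free means and variances, all covariances zero, no
    cross-group constraints.  For summary moments the ML solution is closed
    form (chi2 = sum_k n_k * (-ln det R_k) with R the correlation matrix).
    For raw data with missingness the diagonal model is fitted by direct
    FIML optimization.
    """
    chi = 0.0
    df = 0
    for gid, gd in data.items():
        if gd.is_raw and np.isnan(gd.raw).any():
            chi += _baseline_fiml(gd.raw)
            p = gd.raw.shape[1]
        else:
            m, s, n = gd.moments()
            p = m.size
            sd = np.sqrt(np.diag(s))
            corr = s / np.outer(sd, sd)
            sign, logdet_r = np.linalg.slogdet(corr)
            if sign <= 0:
                raise ValueError(f"group {gid}: singular correlation matrix")
            eff = n if n_convention == "n" else n - 1
            chi += eff * (-logdet_r)
        df += p * (p - 1) // 2
    return float(chi), df


def _baseline_fiml(arr: np.ndarray) -> float:
    """2*(saturated - diagonal-model) FIML loglik for one group's raw data."""
    from .estimation import em_mvn
    from scipy.optimize import minimize

    patterns = _split_patterns(arr)
    _, _, ll_sat, _ = em_mvn(arr)
    p = arr.shape[1]
    mu0 = np.nanmean(arr, axis=0)
    logv0 = np.log(np.nanvar(arr, axis=0))

    def nll(x):
        mu = x[:p]
        sigma = np.diag(np.exp(x[p:]))
        ll = _pattern_loglik(mu, sigma, patterns)
        return -ll if np.isfinite(ll) else np.inf

    res = minimize(nll, np.concatenate([mu0, logv0]), method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    return 2.0 * (ll_sat - (-res.fun))


# ---------------------------------------------------------------------------
# SRMR
# ---------------------------------------------------------------------------

def srmr(sample: Mapping[str, tuple[np.ndarray, np.ndarray]],
         implied: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> float:
    """Standardized root mean square residual over means and covariances.

    Per group, squared standardized residuals are accumulated over the
    nonredundant covariance elements ``(s_ij - sig_ij)/(sd_i sd_j)`` and the
    mean elements ``(m_i - mu_i)/sd_i``; groups are pooled weighted by their
    element counts before the square root.
    """
    total = 0.0
    count = 0
    for gid in sample:
        m, s = sample[gid]
        mu, sig = implied[gid]
        sd = np.sqrt(np.diag(s))
        if np.any(sd <= 0):
            bad = int(np.argmax(sd <= 0))
            raise ValueError(f"group {gid}: zero sample variance for variable {bad}")
        p = m.size
        for i in range(p):
            for j in range(i + 1):
                r = (s[i, j] - sig[i, j]) / (sd[i] * sd[j])
                total += r * r
                count += 1
            r = (m[i] - mu[i]) / sd[i]
            total += r * r
            count += 1
    return float(np.sqrt(total / count))


# ---------------------------------------------------------------------------
# AIC machinery
# ---------------------------------------------------------------------------

def aic(loglik: float, n_free_params: int) -> float:
    """Akaike information criterion, ``-2 ln L + 2 q``."""
    return -2.0 * loglik + 2.0 * n_free_params


def delta_aic(aics: Sequence[float]) -> np.ndarray:
    """Burnham-Anderson rescaling: each AIC minus the minimum."""
    a = np.asarray(list(aics), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AIC value")
    return a - a.min()


def support_label(delta: float) -> str:
    """Evidential support bin for a delta-AIC value.

    The published guidance leaves gaps (2-4 and 7-10); values there are
    labelled explicitly rather than silently assigned to a bin.
    """
    if delta < 0:
        raise ValueError("delta-AIC cannot be negative")
    if delta < 2.0:
        return "strong support"
    if 4.0 <= delta <= 7.0:
        return "considerably less support"
    if delta > 10.0:
        return "essentially no support"
    return "intermediate (guidance gap)"


# ---------------------------------------------------------------------------
# nested comparison
# ---------------------------------------------------------------------------

def _free_coords(spec: ModelSpec) -> dict[tuple, str]:
    out = {}
    for gid, pms in spec.groups.items():
        for mat, idx, lab in pms.free_entries():
            key = lab if lab is not None else f"{gid}.{mat}{list(idx)}"
            out[(gid, mat, idx)] = key
    return out


def _is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    """Structural nesting check.

    True when every coordinate free in the nested spec is free in the full
    spec and the nested label partition is a coarsening of the full one, OR
    when the only violation is the documented no-change/latent-change
    reparameterization: a group whose nested form frees the first-order
    disturbance variances (psi diagonal) while the full form instead frees
    the curve-factor covariance block — an exact reparameterization of a
    restriction, hence valid for the likelihood-ratio test.
    """
    nc = _free_coords(nested)
    fc = _free_coords(full)
    violating = []
    split: dict[str, set[str]] = {}   # full label -> nested labels it covers
    for coord, nlab in nc.items():
        if coord in fc:
            split.setdefault(fc[coord], set()).add(nlab)
        else:
            violating.append(coord)
    # a full label covering several distinct nested labels means the nested
    # spec frees what the full spec ties: not a restriction
    if any(len(v) > 1 for v in split.values()):
        return False
    if not violating:
        return True
    # allow the A-form (psi diag free, slope fixed) vs B-form (Phi block free)
    by_group: dict[str, list] = {}
    for gid, mat, idx in violating:
        by_group.setdefault(gid, []).append((mat, idx))
    for gid, coords in by_group.items():
        if not all(mat == "psi" and idx[0] == idx[1] for mat, idx in coords):
            return False
        full_pms = full.groups[gid]
        phi_free = full_pms.free["phi"]
        if not (phi_free[1, 1] and phi_free[1, 0]):
            return False
    return True


def chi_square_difference(fit_nested: FitResult, fit_full: FitResult, *,
                          alpha: float = 0.05, force: bool = False
                          ) -> ComparisonResult:
    """Likelihood-ratio test between nested fits.

    ``preferred`` is ``"constrained"`` (the nested, more parsimonious model)
    when the test is nonsignificant at ``alpha``.
    """
    if not force and not _is_nested(fit_nested.spec, fit_full.spec):
        raise ValueError("models are not nested (pass force=True to override)")
    d_chi = fit_nested.chi_square - fit_full.chi_square
    d_df = fit_nested.df - fit_full.df
    if d_df < 0:
        raise ValueError("nested model must have more df than the full model")
    if d_chi < -1e-6:
        raise ValueError(
            f"negative chi-square difference ({d_chi:.3g}); check convergence")
    d_chi = max(d_chi, 0.0)
    p = 1.0 if d_df == 0 else float(chi2_dist.sf(d_chi, d_df))
    return ComparisonResult(
        delta_chi_square=float(d_chi), delta_df=int(d_df), p_value=p,
        preferred="constrained" if p > alpha else "unconstrained")


# ---------------------------------------------------------------------------
# assembled battery
# ---------------------------------------------------------------------------

def fit_indices(fit: FitResult, data: Mapping[str, GroupData], *,
                n_convention: str = "n",
                multigroup_scale: bool = True) -> FitIndexSet:
    """Compute the full index battery for one fitted model."""
    chi_b, df_b = baseline_chi_square(data, n_convention=n_convention)
    cfi, tli, tli_raw = cfi_tli(fit.chi_square, fit.df, chi_b, df_b)
    total_n = fit.total_n
    g = len(fit.spec.groups)
    if fit.df >= 1:
        rp = rmsea_point(fit.chi_square, fit.df, total_n, g, multigroup_scale)
        ci = rmsea_ci(fit.chi_square, fit.df, total_n, g, multigroup_scale=multigroup_scale)
        pval = float(chi2_dist.sf(fit.chi_square, fit.df))
    else:
        rp, ci, pval = np.nan, (np.nan, np.nan), np.nan
    implied = {gid: fit.implied_moments(gid) for gid in fit.spec.groups}
    sample = fit.sample_moments
    if sample is None:
        sample = {gid: data[gid].moments()[:2] for gid in fit.spec.groups}
    return FitIndexSet(
        chi_square=fit.chi_square, df=fit.df, p_value=pval,
        cfi=cfi, tli=tli, tli_raw=tli_raw,
        rmsea=rp, rmsea_ci90=ci,
        srmr=srmr(sample, implied),
        aic=fit.aic,
    )
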