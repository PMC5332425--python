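"""Maximum-likelihood estimation of multiple-group latent curve models.

Two fitting routes are provided:

``fit_ml_summary``
    Mean-and-covariance-structure (MACS) maximum likelihood from per-group
    summary moments (mean vector, covariance matrix, n).  The discrepancy per
    group is the normal-theory ML fit function

    .. math::

        F = \\ln|\\Sigma| + \\mathrm{tr}(S\\Sigma^{-1}) - \\ln|S| - p
            + (\\bar y - \\mu)'\\Sigma^{-1}(\\bar y - \\mu),

    minimized as :math:`\\sum_k n_k F_k`; the likelihood-ratio statistic is
    :math:`\\chi^2 = \\sum_k n_k \\hat F_k` with per-group contributions
    :math:`n_k \\hat F_k`.

``fit_fiml_raw``
    Full-information maximum likelihood from raw case-level data with missing
    values: the casewise log-likelihood sums, over cases, the multivariate
    normal log-density restricted to each case's observed coordinates.  The
    saturated (unstructured per-group mean/covariance) model is fitted by EM
    and :math:`\\chi^2 = 2(\\ell_{sat} - \\ell_{model})`.

On complete data the two routes coincide (with the ``n`` covariance
denominator convention), which is used as an internal consistency check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_core import ModelSpec, implied_moments, per_group_df, degrees_of_freedom

__all__ = [
    "GroupData",
    "FitResult",
    "ml_discrepancy",
    "fit_ml_summary",
    "fit_fiml_raw",
    "fiml_casewise_loglik",
    "standard_errors",
    "em_mvn",
]

_LN2PI = np.log(2.0 * np.pi)
_PENALTY = 1e6
DEFAULT_SEED = 20170302


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GroupData:
    """Data for one group: raw cases (with missingness) or summary moments."""

    group: str
    names: list[str]
    raw: np.ndarray | None = None          # cases x variables, NaN = missing
    mean: np.ndarray | None = None
    cov: np.ndarray | None = None
    n: int | None = None

    @classmethod
    def from_raw(cls, group: str, table: pd.DataFrame | np.ndarray,
                 names: Sequence[str] | None = None) -> "GroupData":
        if isinstance(table, pd.DataFrame):
            names = list(table.columns) if names is None else list(names)
            arr = table.to_numpy(dtype=float)
        else:
            arr = np.asarray(table, dtype=float)
            names = [f"y{i+1}" for i in range(arr.shape[1])] if names is None else list(names)
        keep = ~np.all(np.isnan(arr), axis=1)
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"group {group}: excluded {dropped} all-missing case(s)")
        arr = arr[keep]
        if arr.shape[0] == 0:
            raise ValueError(f"group {group}: no usable cases")
        return cls(group=group, names=names, raw=arr, n=arr.shape[0])

    @classmethod
    def from_moments(cls, group: str, mean, cov, n: int,
                     names: Sequence[str] | None = None) -> "GroupData":
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance matrix is not symmetric")
        if n < mean.size + 1:
            raise ValueError("n must exceed the number of observed variables")
        names = [f"y{i+1}" for i in range(mean.size)] if names is None else list(names)
        return cls(group=group, names=names, mean=mean, cov=cov, n=int(n))

    @classmethod
    def from_summary(cls, group: str, n: int, means, sds, corr,
                     names: Sequence[str] | None = None) -> "GroupData":
        """Build moments from printed means, SDs and a correlation matrix."""
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        corr = np.asarray(corr, dtype=float)
        cov = corr * np.outer(sds, sds)
        return cls.from_moments(group, means, cov, n, names=names)

    @property
    def is_raw(self) -> bool:
        return self.raw is not None

    def moments(self, ddof: int = 0) -> tuple[np.ndarray, np.ndarray, int]:
        """(mean, covariance, n).  Raw data must be complete cases."""
        if not self.is_raw:
            return self.mean, self.cov, self.n
        if np.isnan(self.raw).any():
            raise ValueError(
                f"group {self.group}: raw data contain missing values; "
                "use the FIML route or drop incomplete cases explicitly")
        m = self.raw.mean(axis=0)
        c = np.cov(self.raw, rowvar=False, ddof=ddof)
        return m, np.atleast_2d(c), self.raw.shape[0]


@dataclass
class FitResult:
    """Estimates, likelihoods and diagnostics from one model fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    se: dict[str, float] | None
    loglik_model: float
    loglik_saturated: float
    chi_square: float
    chi_square_by_group: dict[str, float]
    df: int
    df_by_group: dict[str, float]
    n_by_group: dict[str, int]
    converged: bool
    n_iter: int
    method: str
    n_free: int
    warnings: list[str] = field(default_factory=list)
    sample_moments: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def total_n(self) -> int:
        return int(sum(self.n_by_group.values()))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_model + 2.0 * self.n_free

    def implied_moments(self, gid: str) -> tuple[np.ndarray, np.ndarray]:
        return implied_moments(self.spec.groups[gid])

    def estimate_table(self) -> pd.DataFrame:
        rows = []
        for lab in self.estimates:
            est = self.estimates[lab]
            se = self.se.get(lab) if self.se else None
            row = {"label": lab, "estimate": est, "se": se}
            if se is not None and se > 0:
                z = est / se
                from scipy.stats import norm
                row["z"] = z
                row["p"] = 2.0 * norm.sf(abs(z))
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------

def ml_discrepancy(sample_mean, sample_cov, implied_mean, implied_cov) -> float:
    """Normal-theory ML discrepancy between sample and implied moments.

    Nonnegative; zero iff the implied moments equal the sample moments.
    Returns ``inf`` when the implied covariance is not positive definite, so
    an optimizer backtracks rather than crashing.
    """
    s_mean = np.asarray(sample_mean, dtype=float)
    s_cov = np.atleast_2d(np.asarray(sample_cov, dtype=float))
    mu = np.asarray(implied_mean, dtype=float)
    sigma = np.atleast_2d(np.asarray(implied_cov, dtype=float))
    p = s_mean.size
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet_sigma):
        return np.inf
    sign_s, logdet_s = np.linalg.slogdet(s_cov)
    if sign_s <= 0:
        raise ValueError("sample covariance matrix is singular")
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return np.inf
    diff = s_mean - mu
    f = (logdet_sigma + np.trace(s_cov @ sigma_inv) - logdet_s - p
         + diff @ sigma_inv @ diff)
    return float(f)


# ---------------------------------------------------------------------------
# compiled spec: fast parameter-vector <-> matrices mapping
# ---------------------------------------------------------------------------

class CompiledSpec:
    """Flattens a ModelSpec's free entries into a parameter vector.

    Each distinct label is one coordinate; writing the vector back into the
    (deep-copied) matrices is a handful of vectorized flat-index assignments,
    which keeps the objective cheap inside optimization loops.
    """

    def __init__(self, spec: ModelSpec) -> None:
        spec.validate()
        self.spec = spec.copy()
        positions = self.spec._label_positions()
        self.labels = list(positions.keys())
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        # per (gid, mat): (flat positions, theta indices)
        assign: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        start = np.zeros(len(self.labels))
        for ti, lab in enumerate(self.labels):
            for gid, mat, idx in positions[lab]:
                pms = self.spec.groups[gid]
                arr = pms.mats[mat]
                flat = int(np.ravel_multi_index(idx, arr.shape)) if arr.ndim > 1 else int(idx[0])
                key = (gid, mat)
                assign.setdefault(key, ([], []))
                assign[key][0].append(flat)
                assign[key][1].append(ti)
                if pms.is_symmetric(mat) and len(idx) == 2 and idx[0] != idx[1]:
                    mflat = int(np.ravel_multi_index((idx[1], idx[0]), arr.shape))
                    assign[key][0].append(mflat)
                    assign[key][1].append(ti)
                start[ti] = arr[idx] if arr.ndim > 1 else arr[idx[0]]
        self.assign = {k: (np.array(v[0]), np.array(v[1])) for k, v in assign.items()}
        self.start = start
        self.variance_labels = self._variance_labels(positions)

    def _variance_labels(self, positions) -> set[str]:
        """Labels whose entries are variances (diagonals of Theta/Psi/Phi)."""
        out = set()
        for lab, pos in positions.items():
            for gid, mat, idx in pos:
                if mat in ("theta_eps", "psi", "phi") and len(idx) == 2 and idx[0] == idx[1]:
                    # regression parameterization: phi[1,1] is a disturbance
                    # variance, phi[1,0] a slope — only diagonals count
                    out.add(lab)
        return out

    def update(self, theta: np.ndarray) -> None:
        for (gid, mat), (flat, tidx) in self.assign.items():
            self.spec.groups[gid].mats[mat].flat[flat] = theta[tidx]

    def implied(self, gid: str) -> tuple[np.ndarray, np.ndarray]:
        pms = self.spec.groups[gid]
        lam = pms.mats["lambda_y"]
        gam = pms.mats["gamma"]
        phi = pms.phi_effective()
        mu = pms.mats["tau_y"] + lam @ (gam @ pms.mats["kappa"])
        sigma_eta = gam @ phi @ gam.T + pms.mats["psi"]
        sigma = lam @ sigma_eta @ lam.T + pms.mats["theta_eps"]
        return mu, 0.5 * (sigma + sigma.T)

    def heywood_labels(self, theta: np.ndarray) -> list[str]:
        return [lab for lab in self.variance_labels
                if theta[self.index[lab]] < 0.0]


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _heuristic_starts(comp: CompiledSpec,
                      stats: Mapping[str, tuple[np.ndarray, np.ndarray, int]]) -> np.ndarray:
    """Observed-moment starting values.

    Intercept mean <- grand pretest mean; change mean <- observed mean change;
    variances <- fractions of the average observed variance; covariances 0.
    """
    any_spec = next(iter(comp.spec.groups.values()))
    p_per_occ = any_spec.p
    means = np.mean([m for m, _, _ in stats.values()], axis=0)
    avg_var = float(np.mean([np.diag(s).mean() for _, s, _ in stats.values()]))
    t1_mean = float(means[:p_per_occ].mean())
    change = float(means[p_per_occ:2 * p_per_occ].mean() - t1_mean) if means.size > p_per_occ else 0.0
    theta = comp.start.copy()
    positions = comp.spec._label_positions()
    for lab, pos in positions.items():
        gid, mat, idx = pos[0]
        pms = comp.spec.groups[gid]
        i = comp.index[lab]
        if mat == "kappa":
            theta[i] = t1_mean if idx[0] == 0 else change
        elif mat == "phi":
            if pms.phi_parameterization == "regression":
                if idx == (0, 0):
                    theta[i] = 0.5 * avg_var
                elif idx == (1, 1):
                    theta[i] = 0.2 * avg_var
                else:
                    theta[i] = 0.0
            elif idx[0] == idx[1]:
                theta[i] = 0.5 * avg_var if idx[0] == 0 else 0.2 * avg_var
            else:
                theta[i] = 0.0
        elif mat == "psi":
            theta[i] = 0.2 * avg_var if idx[0] == idx[1] else 0.0
        elif mat == "theta_eps":
            theta[i] = 0.3 * avg_var if idx[0] == idx[1] else 0.0
        elif mat == "tau_y":
            theta[i] = 0.0
        elif mat in ("lambda_y", "gamma"):
            theta[i] = 1.0
    return theta


# ---------------------------------------------------------------------------
# optimization driver
# ---------------------------------------------------------------------------

def _optimize(objective: Callable[[np.ndarray], float], x0: np.ndarray,
              seed: int, max_restarts: int, maxiter: int = 1000,
              bounds=None) -> tuple[np.ndarray, float, bool, int, list[str]]:
    rng = np.random.default_rng(seed)
    notes: list[str] = []
    best = None
    x_try = x0
    for attempt in range(max_restarts + 1):
        options = {"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7}
        res = minimize(objective, x_try, method="L-BFGS-B", bounds=bounds,
                       options=options)
        # a flat projected gradient at a finite optimum counts as converged
        # even when the line search reports rounding-level "abnormal" exits
        grad_flat = (res.jac is not None
                     and np.max(np.abs(res.jac)) < 1e-4 * (1.0 + abs(res.fun)))
        ok = np.isfinite(res.fun) and (res.success or grad_flat)
        if best is None or (np.isfinite(res.fun) and res.fun < best[1] - 1e-10):
            best = (res.x, res.fun, ok, res.nit)
        elif ok and not best[2] and abs(res.fun - best[1]) < 1e-8:
            best = (res.x, res.fun, ok, res.nit)
        if best[2]:
            break
        notes.append(f"restart {attempt + 1}: optimizer status {res.message!r}")
        x_try = best[0] + rng.normal(scale=0.1 * (1.0 + np.abs(best[0])))
    x, fun, ok, nit = best
    return x, fun, ok, nit, notes


# ---------------------------------------------------------------------------
# summary-statistic ML
# ---------------------------------------------------------------------------

def _check_spec_data(spec: ModelSpec, data: Mapping[str, GroupData]) -> None:
    missing = set(spec.groups) - set(data)
    if missing:
        raise ValueError(f"no data for group(s) {sorted(missing)}")


def fit_ml_summary(spec: ModelSpec, data: Mapping[str, GroupData], *,
                   n_convention: str = "n", compute_se: bool = True,
                   seed: int = DEFAULT_SEED, max_restarts: int = 5,
                   variance_floor: float | None = None,
                   start: np.ndarray | None = None) -> FitResult:
    """Fit by multiple-group MACS maximum likelihood from summary moments.

    ``n_convention`` scales the discrepancy by ``n`` (default, the biased-ML
    covariance denominator) or ``"n-1"``.  ``variance_floor`` (e.g. ``0.0``)
    refits with bounded variances when a Heywood case occurs.
    """
    _check_spec_data(spec, data)
    if n_convention not in ("n", "n-1"):
        raise ValueError("n_convention must be 'n' or 'n-1'")
    comp = CompiledSpec(spec)
    stats: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for gid in spec.groups:
        gd = data[gid]
        m, s, n = gd.moments()
        stats[gid] = (np.asarray(m, float), np.asarray(s, float), int(n))
    eff = {gid: (n if n_convention == "n" else n - 1) for gid, (_, _, n) in stats.items()}
    # constants reused every evaluation
    pre = {}
    for gid, (m, s, n) in stats.items():
        sign, logdet_s = np.linalg.slogdet(s)
        if sign <= 0:
            raise ValueError(f"group {gid}: sample covariance not positive definite")
        pre[gid] = (m, s, logdet_s, m.size)

    def objective(theta: np.ndarray) -> float:
        comp.update(theta)
        total = 0.0
        for gid, (m, s, logdet_s, p) in pre.items():
            mu, sigma = comp.implied(gid)
            min_eig = np.linalg.eigvalsh(sigma)[0]
            if min_eig <= 1e-10 or not np.isfinite(min_eig):
                # graded penalty keeps the line search informative outside
                # the positive-definite region
                return _PENALTY * (1.0 + max(-min_eig, 0.0))
            _, logdet = np.linalg.slogdet(sigma)
            sigma_inv = np.linalg.inv(sigma)
            diff = m - mu
            f = logdet + (s * sigma_inv).sum() - logdet_s - p + diff @ sigma_inv @ diff
            total += eff[gid] * f
        return total

    x0 = start if start is not None else _heuristic_starts(comp, stats)
    bounds = None
    x, fun, ok, nit, notes = _optimize(objective, x0, seed, max_restarts)
    heywood = comp.heywood_labels(x)
    if heywood:
        notes.append("Heywood case: negative variance estimate for "
                     + ", ".join(sorted(heywood)))
        if variance_floor is not None:
            bounds = [(variance_floor, None) if lab in comp.variance_labels
                      else (None, None) for lab in comp.labels]
            x, fun, ok, nit, notes2 = _optimize(objective, x, seed, max_restarts,
                                                bounds=bounds)
            notes += ["refit with variance floor"] + notes2

    comp.update(x)
    chi_by_group = {}
    ll_model = 0.0
    ll_sat = 0.0
    for gid, (m, s, logdet_s, p) in pre.items():
        mu, sigma = comp.implied(gid)
        f = ml_discrepancy(m, s, mu, sigma)
        chi_by_group[gid] = eff[gid] * f
        ll_model += -0.5 * eff[gid] * (p * _LN2PI + f + logdet_s + p)
        ll_sat += -0.5 * eff[gid] * (p * _LN2PI + logdet_s + p)
    chi_square = float(sum(chi_by_group.values()))
    df, identified = degrees_of_freedom(comp.spec)
    if not identified:
        notes.append("model not identified (negative df)")

    se = None
    if compute_se and ok:
        se = standard_errors(lambda t: 0.5 * objective(t), x, comp.labels)
        if se is None:
            notes.append("observed information not invertible; SEs unavailable")

    return FitResult(
        spec=comp.spec,
        estimates={lab: float(x[i]) for i, lab in enumerate(comp.labels)},
        se=se,
        loglik_model=float(ll_model), loglik_saturated=float(ll_sat),
        chi_square=chi_square, chi_square_by_group=chi_by_group,
        df=df, df_by_group=per_group_df(comp.spec),
        n_by_group={gid: n for gid, (_, _, n) in stats.items()},
        converged=bool(ok), n_iter=int(nit), method="ml_summary",
        n_free=len(comp.labels), warnings=notes,
        sample_moments={gid: (m, s) for gid, (m, s, _, _) in pre.items()},
    )


# ---------------------------------------------------------------------------
# FIML
# ---------------------------------------------------------------------------

def _split_patterns(arr: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group rows by missingness pattern -> list of (observed idx, Y block)."""
    obs = ~np.isnan(arr)
    out = []
    uniq, inv = np.unique(obs, axis=0, return_inverse=True)
    for j in range(uniq.shape[0]):
        idx = np.flatnonzero(uniq[j])
        if idx.size == 0:
            continue
        rows = arr[inv == j][:, idx]
        out.append((idx, rows))
    return out


def _pattern_loglik(mu: np.ndarray, sigma: np.ndarray,
                    patterns: list[tuple[np.ndarray, np.ndarray]]) -> float:
    ll = 0.0
    for idx, rows in patterns:
        mu_o = mu[idx]
        sig_o = sigma[np.ix_(idx, idx)]
        sign, logdet = np.linalg.slogdet(sig_o)
        if sign <= 0 or not np.isfinite(logdet):
            return -np.inf
        sinv = np.linalg.inv(sig_o)
        diff = rows - mu_o
        quad = np.einsum("ij,jk,ik->", diff, sinv, diff)
        n_j, p_j = rows.shape
        ll += -0.5 * (n_j * (p_j * _LN2PI + logdet) + quad)
    return float(ll)


def fiml_casewise_loglik(spec: ModelSpec, data: Mapping[str, GroupData],
                         theta: np.ndarray | None = None) -> float:
    """Casewise (full-information) log-likelihood of raw multi-group data.

    With ``theta`` given, the spec's free parameters are set to it first.
    """
    comp = CompiledSpec(spec)
    if theta is not None:
        comp.update(np.asarray(theta, float))
    total = 0.0
    for gid in spec.groups:
        gd = data[gid]
        if not gd.is_raw:
            raise ValueError(f"group {gid}: FIML needs raw data")
        mu, sigma = comp.implied(gid)
        total += _pattern_loglik(mu, sigma, _split_patterns(gd.raw))
    return total


def em_mvn(arr: np.ndarray, *, max_iter: int = 2000, tol: float = 1e-10
           ) -> tuple[np.ndarray, np.ndarray, float, int]:
    """ML mean/covariance of multivariate-normal data with missing values (EM).

    Returns ``(mu, sigma, loglik, n_iter)``; ``sigma`` uses the ``n``
    denominator.  Rows that are entirely missing must be removed beforehand.
    """
    arr = np.asarray(arr, dtype=float)
    n, p = arr.shape
    patterns = _split_patterns(arr)
    mu = np.nanmean(arr, axis=0)
    var = np.nanvar(arr, axis=0)
    var[var <= 0] = 1.0
    sigma = np.diag(var)
    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for idx, rows in patterns:
            n_j = rows.shape[0]
            mis = np.setdiff1d(np.arange(p), idx)
            filled = np.empty((n_j, p))
            filled[:, idx] = rows
            if mis.size:
                sig_oo = sigma[np.ix_(idx, idx)]
                sig_mo = sigma[np.ix_(mis, idx)]
                beta = np.linalg.solve(sig_oo, sig_mo.T).T
                cond_mean = mu[mis] + (rows - mu[idx]) @ beta.T
                filled[:, mis] = cond_mean
                cond_cov = sigma[np.ix_(mis, mis)] - beta @ sig_mo.T
                t2[np.ix_(mis, mis)] += n_j * cond_cov
            t1 += filled.sum(axis=0)
            t2 += filled.T @ filled
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _pattern_loglik(mu, sigma, patterns)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return mu, sigma, float(ll_old), it


def fit_fiml_raw(spec: ModelSpec, data: Mapping[str, GroupData], *,
                 compute_se: bool = True, seed: int = DEFAULT_SEED,
                 max_restarts: int = 5,
                 variance_floor: float | None = None,
                 start: np.ndarray | None = None) -> FitResult:
    """Fit by full-information maximum likelihood from raw data.

    The saturated model (unstructured per-group mean and covariance, fitted by
    EM under the same missingness) provides the reference log-likelihood for
    the likelihood-ratio chi-square and its per-group contributions.
    """
    _check_spec_data(spec, data)
    comp = CompiledSpec(spec)
    group_patterns: dict[str, list] = {}
    sat_ll: dict[str, float] = {}
    sat_moments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_by_group: dict[str, int] = {}
    notes: list[str] = []
    for gid in spec.groups:
        gd = data[gid]
        if not gd.is_raw:
            raise ValueError(f"group {gid}: FIML needs raw data")
        group_patterns[gid] = _split_patterns(gd.raw)
        mu_s, sig_s, ll_s, _ = em_mvn(gd.raw)
        sat_ll[gid] = ll_s
        sat_moments[gid] = (mu_s, sig_s)
        n_by_group[gid] = gd.raw.shape[0]

    def negloglik(theta: np.ndarray) -> float:
        comp.update(theta)
        total = 0.0
        for gid, patterns in group_patterns.items():
            mu, sigma = comp.implied(gid)
            min_eig = np.linalg.eigvalsh(sigma)[0]
            if min_eig <= 1e-10 or not np.isfinite(min_eig):
                return _PENALTY * (1.0 + max(-min_eig, 0.0))
            ll = _pattern_loglik(mu, sigma, patterns)
            if not np.isfinite(ll):
                return _PENALTY
            total -= ll
        return total

    if start is not None:
        x0 = start
    else:
        stats = {gid: (sat_moments[gid][0], sat_moments[gid][1], n_by_group[gid])
                 for gid in spec.groups}
        x0 = _heuristic_starts(comp, stats)
    x, fun, ok, nit, onotes = _optimize(negloglik, x0, seed, max_restarts)
    notes += onotes
    heywood = comp.heywood_labels(x)
    if heywood:
        notes.append("Heywood case: negative variance estimate for "
                     + ", ".join(sorted(heywood)))
        if variance_floor is not None:
            bounds = [(variance_floor, None) if lab in comp.variance_labels
                      else (None, None) for lab in comp.labels]
            x, fun, ok, nit, notes2 = _optimize(negloglik, x, seed, max_restarts,
                                                bounds=bounds)
            notes += ["refit with variance floor"] + notes2

    comp.update(x)
    ll_model_by_group = {}
    for gid, patterns in group_patterns.items():
        mu, sigma = comp.implied(gid)
        ll_model_by_group[gid] = _pattern_loglik(mu, sigma, patterns)
    ll_model = float(sum(ll_model_by_group.values()))
    ll_sat = float(sum(sat_ll.values()))
    chi_by_group = {gid: 2.0 * (sat_ll[gid] - ll_model_by_group[gid])
                    for gid in spec.groups}
    df, identified = degrees_of_freedom(comp.spec)
    if not identified:
        notes.append("model not identified (negative df)")

    se = None
    if compute_se and ok:
        se = standard_errors(negloglik, x, comp.labels)
        if se is None:
            notes.append("observed information not invertible; SEs unavailable")

    return FitResult(
        spec=comp.spec,
        estimates={lab: float(x[i]) for i, lab in enumerate(comp.labels)},
        se=se,
        loglik_model=ll_model, loglik_saturated=ll_sat,
        chi_square=float(sum(chi_by_group.values())),
        chi_square_by_group=chi_by_group,
        df=df, df_by_group=per_group_df(comp.spec),
        n_by_group=n_by_group,
        converged=bool(ok), n_iter=int(nit), method="fiml",
        n_free=len(comp.labels), warnings=notes,
        sample_moments=sat_moments,
    )


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray,
                     rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 0.1)
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                val = (fun(x + ei + ej) - fun(x + ei - ej)
                       - fun(x - ei + ej) + fun(x - ei - ej)) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def standard_errors(negloglik: Callable[[np.ndarray], float],
                    theta_hat: np.ndarray,
                    labels: Sequence[str]) -> dict[str, float] | None:
    """SEs from the inverse numerically differentiated observed information.

    Returns ``None`` when the information matrix is not positive definite.
    """
    hess = _numeric_hessian(negloglik, np.asarray(theta_hat, float))
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        return None
    return {lab: float(np.sqrt(diag[i])) for i, lab in enumerate(labels)}
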