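"""The four-step model sequence for pretest-posttest intervention evaluation.

Two group forms are used throughout, both under the parallel-indicator
identification (unit loadings, zero intercepts, within-occasion-equal
indicator residual variances, free cross-occasion residual covariances for
matching indicators):

``A`` (no-change)
    Second-order intercept only: kappa1 and phi1 free, slope machinery fixed
    at zero, first-order disturbances zeta1/zeta2 free.
``B`` (latent change)
    Intercept plus change factor: kappa2, phi2 and phi12 additionally free,
    zeta1 = zeta2 = 0 (the structural constraint that makes a two-wave latent
    change model identifiable).

The sequence: Model 1 fits A in both groups (no effect anywhere), Model 2
fits B in the intervention group only (the target model), Model 3 fits B in
both (normative change), and Model 4 constrains the intercept mean and
variance to equality across groups on top of the best of M1-M3 (baseline
equivalence).  A sensitivity model regresses the change factor on the
intercept in the intervention group; it is fit-equivalent to the covariance
form and yields the standardized initial-status effect and its R-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import (DEFAULT_SEED, FitResult, GroupData, fit_fiml_raw,
                         fit_ml_summary)
from .fit_stats import (ComparisonResult, FitIndexSet, baseline_chi_square,
                        chi_square_difference, delta_aic, fit_indices,
                        support_label)
from .model_core import ModelSpec, ParameterMatrixSet

__all__ = [
    "build_group_model",
    "build_step_model",
    "single_indicator_latent_change",
    "constrain_intercept",
    "regression_form",
    "sensitivity_regression",
    "run_sequence",
    "SequenceResult",
    "SensitivityResult",
]

STEPS = ("M1", "M2", "M3", "M4")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_group_model(form: str, gid: str, *,
                      share_intercept: bool = False,
                      share_intercept_mean: bool = True,
                      share_intercept_variance: bool = True,
                      phi_parameterization: str = "covariance"
                      ) -> ParameterMatrixSet:
    """One group's matrices for form ``"A"`` (no change) or ``"B"`` (change).

    With ``share_intercept`` the intercept mean/variance labels drop the group
    suffix so that using the same builder for several groups ties them.
    """
    if form not in ("A", "B"):
        raise ValueError(f"unknown group form {form!r}")
    pms = ParameterMatrixSet(m=2, p=2, q=1, r=2,
                             phi_parameterization=phi_parameterization
                             if form == "B" else "covariance")
    # measurement: unit loadings, zero intercepts (parallel indicators)
    lam = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    pms.mats["lambda_y"][:] = lam
    # growth basis: eta1 = intercept, eta2 = intercept + change
    pms.mats["gamma"][:] = np.array([[1.0, 0.0], [1.0, 1.0]])

    k_mean = "kappa1" if (share_intercept and share_intercept_mean) else f"kappa1_{gid}"
    k_var = "phi1" if (share_intercept and share_intercept_variance) else f"phi1_{gid}"
    pms.set_free("kappa", 0, start=3.5, label=k_mean)
    pms.set_free("phi", (0, 0), start=0.4, label=k_var)

    if form == "B":
        pms.set_free("kappa", 1, start=0.1, label=f"kappa2_{gid}")
        if phi_parameterization == "regression":
            pms.set_free("phi", (1, 0), start=0.0, label=f"slope_on_icept_{gid}")
            pms.set_free("phi", (1, 1), start=0.2, label=f"slope_resid_{gid}")
        else:
            pms.set_free("phi", (1, 0), start=0.0, label=f"phi12_{gid}")
            pms.set_free("phi", (1, 1), start=0.2, label=f"phi2_{gid}")
        # zeta fixed to 0: the structural two-wave latent change constraint
    else:
        pms.set_free("psi", (0, 0), start=0.1, label=f"zeta1_{gid}")
        pms.set_free("psi", (1, 1), start=0.1, label=f"zeta2_{gid}")

    # parallel indicators: equal residual variances within occasion,
    # free lag covariances between matching indicators
    pms.set_free("theta_eps", (0, 0), start=0.15, label=f"theta_t1_{gid}")
    pms.set_free("theta_eps", (1, 1), start=0.15, label=f"theta_t1_{gid}")
    pms.set_free("theta_eps", (2, 2), start=0.15, label=f"theta_t2_{gid}")
    pms.set_free("theta_eps", (3, 3), start=0.15, label=f"theta_t2_{gid}")
    pms.set_free("theta_eps", (0, 2), start=0.0, label=f"theta_c1_{gid}")
    pms.set_free("theta_eps", (1, 3), start=0.0, label=f"theta_c2_{gid}")
    return pms


def build_step_model(step: str, group_ids: tuple[str, str] = ("G1", "G2"), *,
                     relax_intercept_mean: bool = False,
                     relax_intercept_variance: bool = False) -> ModelSpec:
    """ModelSpec for one step of the sequence.

    ``group_ids`` is (intervention, control).  Model 4 equates the intercept
    mean and variance across groups on the Model 2 configuration; the two
    ``relax_*`` flags lift either constraint (field-study option when
    randomization failed).
    """
    if step not in STEPS:
        raise ValueError(f"unknown step {step!r}; expected one of {STEPS}")
    g1, g2 = group_ids
    forms = {"M1": ("A", "A"), "M2": ("B", "A"),
             "M3": ("B", "B"), "M4": ("B", "A")}[step]
    share = step == "M4"
    spec = ModelSpec(groups={
        g1: build_group_model(forms[0], g1, share_intercept=share,
                              share_intercept_mean=not relax_intercept_mean,
                              share_intercept_variance=not relax_intercept_variance),
        g2: build_group_model(forms[1], g2, share_intercept=share,
                              share_intercept_mean=not relax_intercept_mean,
                              share_intercept_variance=not relax_intercept_variance),
    }, step_tag=step)
    spec.validate()
    return spec


def single_indicator_latent_change() -> ModelSpec:
    """The single-indicator two-wave latent change model (for counting).

    Seven parameters (two latent means, two variances, one covariance, two
    residual variances) against five identified moments: under-identified,
    which is why parallel indicators (or fixing the residual variances to
    zero) are needed with two waves.
    """
    pms = ParameterMatrixSet(m=2, p=1, q=1, r=2)
    pms.mats["lambda_y"][:] = np.eye(2)
    pms.mats["gamma"][:] = np.array([[1.0, 0.0], [1.0, 1.0]])
    pms.set_free("kappa", 0, label="kappa1")
    pms.set_free("kappa", 1, label="kappa2")
    pms.set_free("phi", (0, 0), label="phi1")
    pms.set_free("phi", (1, 1), label="phi2")
    pms.set_free("phi", (1, 0), label="phi12")
    pms.set_free("theta_eps", (0, 0), label="theta_t1")
    pms.set_free("theta_eps", (1, 1), label="theta_t2")
    return ModelSpec(groups={"G1": pms}, step_tag="CUSTOM")


def constrain_intercept(spec: ModelSpec, *, mean: bool = True,
                        variance: bool = True) -> ModelSpec:
    """Equate the intercept mean and/or variance labels across all groups."""
    out = spec.copy()
    for name, do in (("kappa1", mean), ("phi1", variance)):
        if not do:
            continue
        vals = []
        for pms in out.groups.values():
            for mat, lb in pms.labels.items():
                for idx in zip(*np.nonzero(np.vectorize(
                        lambda v: isinstance(v, str) and v.startswith(f"{name}_"),
                        otypes=[bool])(lb))):
                    lb[idx] = name
                    vals.append((pms, mat, idx))
        if vals:
            # tied entries start from the average of the groups' values
            avg = float(np.mean([p.mats[m][i] for p, m, i in vals]))
            for p, m, i in vals:
                p.mats[m][i] = avg
    out.step_tag = "M4"
    out.validate()
    return out


def regression_form(spec: ModelSpec, gid: str) -> ModelSpec:
    """Rewrite one group's change-factor covariance block as a regression.

    The change factor is expressed as ``slope = g * intercept + disturbance``;
    the implied Phi is identical in span, so the refit has the same likelihood
    while exposing the initial-status effect directly.
    """
    out = spec.copy()
    pms = out.groups[gid]
    if not pms.free["kappa"][1]:
        raise ValueError(f"group {gid} has no free change factor to regress")
    new = build_group_model("B", gid, phi_parameterization="regression")
    # carry over any shared intercept labels
    for mat in ("kappa", "phi"):
        old_labels = pms.labels[mat]
        it = np.ndindex(old_labels.shape)
        for idx in it:
            if old_labels[idx] in ("kappa1", "phi1"):
                new.labels[mat][idx] = old_labels[idx]
    out.groups[gid] = new
    out.step_tag = "SENSITIVITY"
    out.validate()
    return out


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _fit(spec: ModelSpec, data: Mapping[str, GroupData], *, estimator: str,
         seed: int, n_convention: str, compute_se: bool,
         start: np.ndarray | None = None) -> FitResult:
    if estimator == "fiml":
        return fit_fiml_raw(spec, data, seed=seed, compute_se=compute_se,
                            start=start)
    return fit_ml_summary(spec, data, seed=seed, n_convention=n_convention,
                          compute_se=compute_se, start=start)


def _choose_estimator(data: Mapping[str, GroupData]) -> str:
    for gd in data.values():
        if gd.is_raw and np.isnan(gd.raw).any():
            return "fiml"
    # complete raw data can go through the (equivalent, faster) summary route
    return "ml"


def _as_moments(data: Mapping[str, GroupData]) -> Mapping[str, GroupData]:
    out = {}
    for gid, gd in data.items():
        if gd.is_raw and not np.isnan(gd.raw).any():
            m, s, n = gd.moments()
            out[gid] = GroupData.from_moments(gid, m, s, n, names=gd.names)
        else:
            out[gid] = gd
    return out


# ---------------------------------------------------------------------------
# sensitivity model
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Initial-status sensitivity model (change regressed on intercept)."""

    beta: float                 # standardized slope-on-intercept coefficient
    r_squared: float
    gamma: float                # unstandardized regression coefficient
    gamma_se: float | None
    p_value: float | None
    loglik_difference: float    # vs the covariance-form fit (should be ~0)
    fit: FitResult


def sensitivity_regression(best_fit: FitResult,
                           data: Mapping[str, GroupData], *,
                           intervention: str | None = None,
                           seed: int = DEFAULT_SEED,
                           n_convention: str = "n") -> SensitivityResult:
    """Refit the best model with the change factor regressed on the intercept.

    The reparameterization is fit-equivalent (identical log-likelihood); the
    standardized coefficient is ``beta = g * sqrt(phi1 / phi2_implied)`` with
    ``phi2_implied = g**2 * phi1 + v_disturbance``, and ``R^2 = beta**2``.
    """
    spec = best_fit.spec
    gid = intervention if intervention is not None else next(iter(spec.groups))
    pms = spec.groups[gid]
    if not pms.free["kappa"][1]:
        raise ValueError(f"best model has no change factor in group {gid}")
    reg_spec = regression_form(spec, gid)

    # warm start from the covariance-form estimates
    from .estimation import CompiledSpec
    comp = CompiledSpec(reg_spec)
    start = comp.start.copy()
    est = best_fit.estimates
    k1 = est.get("kappa1", est.get(f"kappa1_{gid}"))
    phi1 = est.get("phi1", est.get(f"phi1_{gid}"))
    phi12 = est.get(f"phi12_{gid}", 0.0)
    phi2 = est.get(f"phi2_{gid}", 0.1)
    if phi1 is None or phi1 <= 0:
        raise ValueError("intercept variance must be positive for the "
                         "sensitivity regression")
    gamma0 = phi12 / phi1
    vd0 = max(phi2 - gamma0 ** 2 * phi1, 1e-4)
    seeds = {f"slope_on_icept_{gid}": gamma0, f"slope_resid_{gid}": vd0}
    for lab, val in est.items():
        if lab in comp.index:
            start[comp.index[lab]] = val
    for lab, val in seeds.items():
        start[comp.index[lab]] = val

    estimator = best_fit.method if best_fit.method in ("fiml",) else "ml"
    fit = _fit(reg_spec, data, estimator="fiml" if estimator == "fiml" else "ml",
               seed=seed, n_convention=n_convention, compute_se=True,
               start=start)
    g = fit.estimates[f"slope_on_icept_{gid}"]
    p1 = fit.estimates.get("phi1", fit.estimates.get(f"phi1_{gid}"))
    vd = fit.estimates[f"slope_resid_{gid}"]
    phi2_implied = g * g * p1 + vd
    if phi2_implied <= 0 or p1 <= 0:
        raise ValueError("inadmissible variance estimates in sensitivity model")
    beta = g * np.sqrt(p1 / phi2_implied)
    se = fit.se.get(f"slope_on_icept_{gid}") if fit.se else None
    pval = None
    if se is not None and se > 0:
        from scipy.stats import norm
        pval = float(2.0 * norm.sf(abs(g / se)))
    return SensitivityResult(
        beta=float(beta), r_squared=float(beta ** 2), gamma=float(g),
        gamma_se=se, p_value=pval,
        loglik_difference=float(fit.loglik_model - best_fit.loglik_model),
        fit=fit)


# ---------------------------------------------------------------------------
# the sequence driver
# ---------------------------------------------------------------------------

@dataclass
class SequenceResult:
    """Everything produced by one run of the four-step procedure."""

    fits: dict[str, FitResult]
    indices: dict[str, FitIndexSet]
    comparisons: dict[str, ComparisonResult]
    best_model: str
    sensitivity: SensitivityResult | None
    group_ids: tuple[str, str]
    trajectory: pd.DataFrame = field(default=None)

    def table(self) -> pd.DataFrame:
        """Machine-readable goodness-of-fit table, one row per model."""
        rows = []
        for step, fit in self.fits.items():
            ix = self.indices[step]
            row = {"model": step, "nfp": fit.n_free,
                   "chi_square": fit.chi_square, "df": fit.df,
                   "p_value": ix.p_value}
            for gid in self.group_ids:
                row[f"chi_square_{gid}"] = fit.chi_square_by_group[gid]
                row[f"df_{gid}"] = fit.df_by_group[gid]
            row.update({"cfi": ix.cfi, "tli": ix.tli, "rmsea": ix.rmsea,
                        "rmsea_lo": ix.rmsea_ci90[0], "rmsea_hi": ix.rmsea_ci90[1],
                        "srmr": ix.srmr, "aic": ix.aic,
                        "delta_aic": ix.delta_aic, "support": ix.support,
                        "converged": fit.converged})
            rows.append(row)
        return pd.DataFrame(rows)

    def report_text(self) -> str:
        """Fixed-width goodness-of-fit report mirroring the standard layout."""
        lines = ["Goodness-of-fit indices for the tested models",
                 "=" * 100]
        g1, g2 = self.group_ids
        hdr = (f"{'Model':<8}{'NFP':>4}{'chi2(df)':>16}{'chi2 ' + g1:>14}"
               f"{'chi2 ' + g2:>14}{'CFI':>7}{'TLI':>7}"
               f"{'RMSEA [90% CI]':>22}{'SRMR':>7}{'AIC (dAIC)':>18}")
        lines.append(hdr)
        lines.append("-" * 100)
        for step, fit in self.fits.items():
            ix = self.indices[step]
            mark = " *" if step == self.best_model else "  "
            da = f"({ix.delta_aic:.2f})" if ix.delta_aic is not None else ""
            lines.append(
                f"{step + mark:<8}{fit.n_free:>4}"
                f"{fit.chi_square:>10.3f}({fit.df})"
                f"{fit.chi_square_by_group[g1]:>9.3f}({fit.df_by_group[g1]:.0f})"
                f"{fit.chi_square_by_group[g2]:>9.3f}({fit.df_by_group[g2]:.0f})"
                f"{ix.cfi:>7.3f}{ix.tli:>7.3f}"
                f"{ix.rmsea:>8.3f} [{ix.rmsea_ci90[0]:.3f},{ix.rmsea_ci90[1]:.3f}]"
                f"{ix.srmr:>7.3f}{ix.aic:>12.3f} {da}")
        lines.append("-" * 100)
        lines.append(f"Best model (lowest AIC, ties to fewer parameters): "
                     f"{self.best_model}")
        for name, cmp_ in self.comparisons.items():
            lines.append(f"{name}: delta-chi2({cmp_.delta_df}) = "
                         f"{cmp_.delta_chi_square:.3f}, p = {cmp_.p_value:.3f} "
                         f"-> prefer {cmp_.preferred}")
        if self.sensitivity is not None:
            s = self.sensitivity
            ptxt = f", p = {s.p_value:.3f}" if s.p_value is not None else ""
            lines.append(
                f"Initial-status sensitivity: beta = {s.beta:.2f}"
                f" (unstandardized {s.gamma:.3f}{ptxt}), R^2 = {s.r_squared:.2f}")
        if self.trajectory is not None:
            lines.append("")
            lines.append("Model-implied latent trajectory (best model):")
            lines.append(self.trajectory.to_string(index=False,
                                                   float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def _select_best(aics: dict[str, float], nfps: dict[str, int]) -> str:
    """Lowest AIC; candidates within delta-AIC < 2 are a tie resolved toward
    the model with fewer free parameters."""
    amin = min(aics.values())
    tied = [m for m, a in aics.items() if a - amin < 2.0]
    return sorted(tied, key=lambda m: (nfps[m], aics[m]))[0]


def run_sequence(data: Mapping[str, GroupData], *,
                 group_ids: tuple[str, str] | None = None,
                 estimator: str = "auto", n_convention: str = "n",
                 seed: int = DEFAULT_SEED, compute_se: bool = True,
                 relax_intercept_mean: bool = False,
                 relax_intercept_variance: bool = False,
                 with_sensitivity: bool = True) -> SequenceResult:
    """Run the four-step sequence and the initial-status sensitivity model.

    ``group_ids`` orders (intervention, control); defaults to the data's key
    order.  ``estimator`` is ``"auto"`` (FIML when missing values are present,
    summary ML otherwise), ``"ml"`` or ``"fiml"``.
    """
    if group_ids is None:
        gids = tuple(data.keys())
    else:
        gids = tuple(group_ids)
    if len(gids) != 2:
        raise ValueError("the sequence needs exactly two groups "
                         "(intervention, control)")
    missing = set(gids) - set(data)
    if missing:
        raise ValueError(f"no data for group(s) {sorted(missing)}")
    data = {g: data[g] for g in gids}
    if estimator == "auto":
        estimator = _choose_estimator(data)
    if estimator == "ml":
        data = _as_moments(data)

    fits: dict[str, FitResult] = {}
    for step in ("M1", "M2", "M3"):
        spec = build_step_model(step, gids)
        fits[step] = _fit(spec, data, estimator=estimator, seed=seed,
                          n_convention=n_convention, compute_se=compute_se)

    aics = {s: fits[s].aic for s in fits}
    nfps = {s: fits[s].n_free for s in fits}
    best = _select_best(aics, nfps)

    # Model 4: intercept equated across groups, on top of the best model
    m4_spec = constrain_intercept(
        fits[best].spec,
        mean=not relax_intercept_mean,
        variance=not relax_intercept_variance)
    fits["M4"] = _fit(m4_spec, data, estimator=estimator, seed=seed,
                      n_convention=n_convention, compute_se=compute_se)

    indices: dict[str, FitIndexSet] = {}
    for step, fit in fits.items():
        indices[step] = fit_indices(fit, data, n_convention=n_convention)
    deltas = delta_aic([indices[s].aic for s in ("M1", "M2", "M3")])
    for s, d in zip(("M1", "M2", "M3"), deltas):
        indices[s].delta_aic = float(d)
        indices[s].support = support_label(float(d))

    comparisons = {
        "M1 vs M2": chi_square_difference(fits["M1"], fits["M2"]),
        "M2 vs M3": chi_square_difference(fits["M2"], fits["M3"]),
        f"M4 vs {best}": chi_square_difference(fits["M4"], fits[best]),
    }

    sens = None
    if with_sensitivity and fits[best].spec.groups[gids[0]].free["kappa"][1]:
        sens = sensitivity_regression(fits[best], data, intervention=gids[0],
                                      seed=seed, n_convention=n_convention)

    traj = _trajectory(fits[best], gids)
    return SequenceResult(fits=fits, indices=indices, comparisons=comparisons,
                          best_model=best, sensitivity=sens, group_ids=gids,
                          trajectory=traj)


def _trajectory(fit: FitResult, gids) -> pd.DataFrame:
    rows = []
    for gid in gids:
        mu, _ = fit.implied_moments(gid)
        p = fit.spec.groups[gid].p
        rows.append({"group": gid, "T1": float(mu[:p].mean()),
                     "T2": float(mu[p:2 * p].mean()),
                     "change": float(mu[p:2 * p].mean() - mu[:p].mean())})
    return pd.DataFrame(rows)
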