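"""Matrix representation of second-order multiple-group latent curve models.

A second-order latent curve model (LCM) for ``m`` occasions, ``p`` indicators
per occasion, ``q`` first-order factors per occasion and ``r`` curve factors is
written as a measurement model

.. math::

    y = \\tau_y + \\Lambda_y \\eta + \\varepsilon,
    \\qquad \\eta = \\Gamma \\xi + \\zeta,

with second-order latent means :math:`\\kappa` and covariance :math:`\\Phi`,
first-order disturbance covariance :math:`\\Psi` and indicator residual
covariance :math:`\\Theta_\\varepsilon`.  The model-implied mean vector and
covariance matrix follow by composition:

.. math::

    \\mu = \\tau_y + \\Lambda_y \\Gamma \\kappa, \\qquad
    \\Sigma = \\Lambda_y (\\Gamma \\Phi \\Gamma' + \\Psi) \\Lambda_y'
              + \\Theta_\\varepsilon.

Each group in a multiple-group model owns one :class:`ParameterMatrixSet`;
equality constraints (within or across groups) are expressed by shared
parameter labels, so every distinct label is exactly one free parameter.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParameterMatrixSet",
    "ModelSpec",
    "SpecificationError",
    "implied_moments",
    "count_moments",
    "count_free_parameters",
    "degrees_of_freedom",
    "per_group_df",
    "spec_to_config_text",
    "spec_from_config_text",
]


class SpecificationError(ValueError):
    """Raised when model matrices are dimensionally or structurally invalid."""


# matrix name -> (shape builder, symmetric?)
def _shapes(m: int, p: int, q: int, r: int) -> dict[str, tuple[tuple[int, ...], bool]]:
    mp, mq, qr = m * p, m * q, q * r
    return {
        "lambda_y": ((mp, mq), False),
        "tau_y": ((mp,), False),
        "theta_eps": ((mp, mp), True),
        "gamma": ((mq, qr), False),
        "kappa": ((qr,), False),
        "phi": ((qr, qr), True),
        "psi": ((mq, mq), True),
    }


class ParameterMatrixSet:
    """One group's model matrices with free/fixed masks and equality labels.

    Parameters
    ----------
    m, p, q, r
        Occasions, indicators per occasion, first-order factors per occasion,
        and curve factors per first-order factor.
    phi_parameterization
        ``"covariance"`` (default) stores Phi as a free symmetric covariance
        matrix.  ``"regression"`` (only for two curve factors) stores, in the
        same array, the intercept variance at ``[0, 0]``, the regression of
        the change factor on the intercept at ``[1, 0]`` and the disturbance
        variance of the change factor at ``[1, 1]``; the effective Phi is then
        ``[[phi1, g*phi1], [g*phi1, g**2*phi1 + v]]``.  The two forms span the
        same covariance structures (a one-to-one reparameterization), which is
        what makes the initial-status sensitivity model fit-equivalent.
    """

    def __init__(self, m: int = 2, p: int = 2, q: int = 1, r: int = 2,
                 phi_parameterization: str = "covariance") -> None:
        if min(m, p, q, r) < 1:
            raise SpecificationError("m, p, q, r must all be >= 1")
        if phi_parameterization not in ("covariance", "regression"):
            raise SpecificationError(
                f"unknown phi parameterization {phi_parameterization!r}")
        if phi_parameterization == "regression" and q * r != 2:
            raise SpecificationError(
                "regression parameterization requires exactly 2 curve factors")
        self.m, self.p, self.q, self.r = m, p, q, r
        self.phi_parameterization = phi_parameterization
        self._shapes = _shapes(m, p, q, r)
        self.mats: dict[str, np.ndarray] = {}
        self.free: dict[str, np.ndarray] = {}
        self.labels: dict[str, np.ndarray] = {}
        for name, (shape, _sym) in self._shapes.items():
            self.mats[name] = np.zeros(shape)
            self.free[name] = np.zeros(shape, dtype=bool)
            self.labels[name] = np.full(shape, None, dtype=object)

    # -- structural properties -------------------------------------------------
    @property
    def n_observed(self) -> int:
        return self.m * self.p

    def is_symmetric(self, name: str) -> bool:
        if name == "phi" and self.phi_parameterization == "regression":
            return False
        return self._shapes[name][1]

    # -- mutation helpers ------------------------------------------------------
    def set_fixed(self, name: str, index, value: float) -> None:
        """Fix an entry at ``value`` (and its mirror for symmetric matrices)."""
        self._set(name, index, value=value, free=False, label=None)

    def set_free(self, name: str, index, start: float = 0.0,
                 label: str | None = None) -> None:
        """Free an entry, optionally tying it to other entries via ``label``."""
        self._set(name, index, value=start, free=True, label=label)

    def _set(self, name, index, value, free, label):
        if name not in self.mats:
            raise SpecificationError(f"unknown matrix {name!r}")
        idx = (index,) if np.isscalar(index) else tuple(index)
        self.mats[name][idx] = value
        self.free[name][idx] = free
        self.labels[name][idx] = label
        if self.is_symmetric(name) and len(idx) == 2 and idx[0] != idx[1]:
            mirror = (idx[1], idx[0])
            self.mats[name][mirror] = value
            self.free[name][mirror] = free
            self.labels[name][mirror] = label

    # -- effective matrices ----------------------------------------------------
    def phi_effective(self) -> np.ndarray:
        """Return Phi as a covariance matrix whatever the parameterization."""
        phi = self.mats["phi"]
        if self.phi_parameterization == "covariance":
            return phi
        v1, g, vd = phi[0, 0], phi[1, 0], phi[1, 1]
        return np.array([[v1, g * v1], [g * v1, g * g * v1 + vd]])

    # -- validation ------------------------------------------------------------
    def validate(self) -> None:
        for name, (shape, _) in self._shapes.items():
            if self.mats[name].shape != shape:
                raise SpecificationError(
                    f"matrix {name!r} has shape {self.mats[name].shape}, "
                    f"expected {shape} for (m={self.m}, p={self.p}, "
                    f"q={self.q}, r={self.r})")
            if self.is_symmetric(name):
                a = self.mats[name]
                if not np.allclose(a, a.T):
                    raise SpecificationError(f"matrix {name!r} is not symmetric")

    # -- bookkeeping -----------------------------------------------------------
    def free_entries(self) -> list[tuple[str, tuple[int, ...], str | None]]:
        """Nonredundant free entries as ``(matrix, index, label)`` triples.

        For symmetric matrices only the lower triangle (i >= j) is listed.
        """
        out = []
        for name in self.mats:
            fr = self.free[name]
            it = np.argwhere(fr)
            for idx in it:
                idx = tuple(int(i) for i in idx)
                if self.is_symmetric(name) and len(idx) == 2 and idx[0] < idx[1]:
                    continue
                out.append((name, idx, self.labels[name][idx]))
        return out

    def copy(self) -> "ParameterMatrixSet":
        return copy.deepcopy(self)


@dataclass
class ModelSpec:
    """A multiple-group model: per-group matrix sets plus a step tag.

    Cross-group equality constraints are expressed by using the same parameter
    label in more than one group; :meth:`cross_group_equalities` reports them.
    """

    groups: dict[str, ParameterMatrixSet] = field(default_factory=dict)
    step_tag: str = "CUSTOM"

    def validate(self) -> None:
        if not self.groups:
            raise SpecificationError("model has no groups")
        dims = None
        for gid, pms in self.groups.items():
            pms.validate()
            d = (pms.m, pms.p, pms.q, pms.r)
            if dims is None:
                dims = d
            elif d != dims:
                raise SpecificationError(
                    f"group {gid!r} has dimensions {d}, others have {dims}")
        # every explicit label must have identical current values at its entries
        for lab, positions in self._label_positions().items():
            vals = [self.groups[g].mats[mat][idx] for g, mat, idx in positions]
            if not np.allclose(vals, vals[0]):
                raise SpecificationError(
                    f"label {lab!r} ties entries with differing values {vals}")

    # -- label machinery -------------------------------------------------------
    def _label_positions(self) -> dict[str, list[tuple[str, str, tuple]]]:
        out: dict[str, list[tuple[str, str, tuple]]] = {}
        for gid, pms in self.groups.items():
            for mat, idx, lab in pms.free_entries():
                key = lab if lab is not None else f"{gid}.{mat}{list(idx)}"
                out.setdefault(key, []).append((gid, mat, idx))
        return out

    def free_labels(self) -> list[str]:
        """Distinct free-parameter labels, in order of first appearance."""
        return list(self._label_positions().keys())

    def cross_group_equalities(self) -> set[str]:
        return {lab for lab, pos in self._label_positions().items()
                if len({g for g, _, _ in pos}) > 1}

    @property
    def n_observed(self) -> int:
        return next(iter(self.groups.values())).n_observed

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)

    # -- reporting -------------------------------------------------------------
    def parameter_table(self) -> pd.DataFrame:
        """Human-readable dump: one row per nonredundant matrix entry."""
        rows = []
        for gid, pms in self.groups.items():
            for name in pms.mats:
                a = pms.mats[name]
                fr = pms.free[name]
                lb = pms.labels[name]
                for idx in np.ndindex(a.shape):
                    if pms.is_symmetric(name) and len(idx) == 2 and idx[0] < idx[1]:
                        continue
                    rows.append({
                        "group": gid, "matrix": name,
                        "row": idx[0], "col": idx[1] if len(idx) > 1 else 0,
                        "status": "free" if fr[idx] else "fixed",
                        "label": lb[idx] if lb[idx] is not None else "",
                        "value": float(a[idx]),
                    })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# moment structure and counting
# ---------------------------------------------------------------------------

def implied_moments(pms: ParameterMatrixSet) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix for one group.

    Returns ``mu = tau_y + Lambda_y Gamma kappa`` and
    ``Sigma = Lambda_y (Gamma Phi Gamma' + Psi) Lambda_y' + Theta_eps``,
    with ``Sigma`` exactly symmetrized.
    """
    pms.validate()
    lam = pms.mats["lambda_y"]
    gam = pms.mats["gamma"]
    phi = pms.phi_effective()
    mu = pms.mats["tau_y"] + lam @ (gam @ pms.mats["kappa"])
    sigma_eta = gam @ phi @ gam.T + pms.mats["psi"]
    sigma = lam @ sigma_eta @ lam.T + pms.mats["theta_eps"]
    return mu, 0.5 * (sigma + sigma.T)


def spec_to_config_text(spec: ModelSpec) -> str:
    """Serialize a ModelSpec to a plain-text (YAML) config block."""
    import yaml

    doc: dict = {"step_tag": spec.step_tag, "groups": {}}
    for gid, pms in spec.groups.items():
        block = {"dims": {"m": pms.m, "p": pms.p, "q": pms.q, "r": pms.r},
                 "phi_parameterization": pms.phi_parameterization,
                 "matrices": {}}
        for name, arr in pms.mats.items():
            block["matrices"][name] = {
                "values": np.round(arr, 12).tolist(),
                "free": pms.free[name].tolist(),
                "labels": np.where(pms.labels[name] == None, "",  # noqa: E711
                                   pms.labels[name]).tolist(),
            }
        doc["groups"][gid] = block
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_config_text(text: str) -> ModelSpec:
    """Rebuild a ModelSpec from :func:`spec_to_config_text` output."""
    import yaml

    doc = yaml.safe_load(text)
    groups = {}
    for gid, block in doc["groups"].items():
        d = block["dims"]
        pms = ParameterMatrixSet(m=d["m"], p=d["p"], q=d["q"], r=d["r"],
                                 phi_parameterization=block.get(
                                     "phi_parameterization", "covariance"))
        for name, mat in block["matrices"].items():
            pms.mats[name] = np.asarray(mat["values"], dtype=float)
            pms.free[name] = np.asarray(mat["free"], dtype=bool)
            lab = np.asarray(mat["labels"], dtype=object)
            lab[lab == ""] = None
            pms.labels[name] = lab
        pms.validate()
        groups[gid] = pms
    spec = ModelSpec(groups=groups, step_tag=doc.get("step_tag", "CUSTOM"))
    spec.validate()
    return spec


def count_moments(n_observed: int, n_groups: int) -> int:
    """Number of identified means, variances and covariances.

    Each group contributes ``p(p+1)/2`` variances/covariances plus ``p``
    means; e.g. four observed variables give ``4*5/2 + 4 = 14`` per group.
    """
    if n_observed < 1 or n_groups < 1:
        raise ValueError("n_observed and n_groups must be positive")
    return n_groups * (n_observed * (n_observed + 1) // 2 + n_observed)


def count_free_parameters(spec: ModelSpec) -> int:
    """Distinct free parameters, counting each equality label once."""
    return len(spec.free_labels())


def degrees_of_freedom(spec: ModelSpec, n_observed: int | None = None,
                       n_groups: int | None = None) -> tuple[int, bool]:
    """Moments minus free parameters; negative values signal non-identification.

    Returns ``(df, identified_flag)``.  A negative df means more parameters
    than identified moments — the model cannot be estimated (e.g. the
    single-indicator two-wave latent change model: 7 parameters, 5 moments).
    """
    if n_observed is None:
        n_observed = spec.n_observed
    if n_groups is None:
        n_groups = spec.n_groups
    df = count_moments(n_observed, n_groups) - count_free_parameters(spec)
    return df, df >= 0


def per_group_df(spec: ModelSpec) -> dict[str, float]:
    """Attribute total df across groups: own labels charged to their group,
    shared labels split evenly over the groups that use them."""
    counts = {gid: 0.0 for gid in spec.groups}
    for lab, pos in spec._label_positions().items():
        gids = sorted({g for g, _, _ in pos})
        for g in gids:
            counts[g] += 1.0 / len(gids)
    p = spec.n_observed
    per_group_moments = p * (p + 1) // 2 + p
    return {gid: per_group_moments - c for gid, c in counts.items()}
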