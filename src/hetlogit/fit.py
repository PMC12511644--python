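"""Maximum simulated likelihood estimation.

Fits mixed logit panels (preference or WTP space) and the correlated-error
revealed-preference logit.  Scale parameters are optimized on the log scale
(zero is represented by a boundary floor), the simulated log-likelihood and
its analytic score are evaluated on MLHS draws, and a quasi-Newton optimizer
(L-BFGS-B) is warm-started at plain-logit estimates.  Standard errors come
from the finite-difference Hessian of the score, mapped to the natural
parameter scale by the delta method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, ndtri

from . import mixing
from .data import (
    BinaryPanelDataset,
    ChoiceDataset,
    ConfigurationError,
    ModelSpec,
    spec_from_dict,
    spec_to_dict,
)
from .draws import DrawSet, mlhs, uniform_draws
from .likelihood import (
    P_FLOOR,
    PanelDesign,
    RPDesign,
    build_design,
    build_rp_design,
    build_utilities,
    log_task_probabilities,
    person_likelihoods_from_draws,
    primitive_dims,
)

log = logging.getLogger(__name__)

_LOG_SCALE_LB = np.log(mixing.SCALE_FLOOR)
_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# parameter vector bookkeeping


@dataclass
class ParamIndex:
    """Maps the flat estimation vector to per-coefficient parameter blocks."""

    entries: list  # (coef_name, family, sign, fix_offset, est_names, slice)
    n: int

    @classmethod
    def for_spec(cls, spec: ModelSpec) -> "ParamIndex":
        entries = []
        pos = 0
        for c in spec.coefficients:
            names = mixing.est_param_names(c.dist, c.fix_offset)
            entries.append((c.name, c.dist, c.sign, c.fix_offset, names, slice(pos, pos + len(names))))
            pos += len(names)
        if spec.rp_error_component is not None:
            s = int(spec.rp_error_component.get("sign", 1))
            entries.append(("_rho", "rp_sd", s, True, ("log_sigma",), slice(pos, pos + 1)))
            pos += 1
        return cls(entries, pos)

    def pack(self, natural: Mapping) -> np.ndarray:
        vec = np.empty(self.n)
        for name, fam, sign, fix, names, sl in self.entries:
            if fam == "rp_sd":
                vec[sl] = np.log(max(natural["_rho"]["sigma"], mixing.SCALE_FLOOR))
            else:
                vec[sl] = mixing.natural_to_est(fam, natural[name]["params"], fix)
        return vec

    def unpack(self, vec: np.ndarray) -> dict:
        out = {}
        for name, fam, sign, fix, names, sl in self.entries:
            if fam == "rp_sd":
                out["_rho"] = {"sigma": float(np.exp(vec[sl][0])), "sign": sign}
            else:
                nat = mixing.est_to_natural(fam, vec[sl], fix)
                out[name] = {"dist": fam, "sign": sign, "params": {k: float(v) for k, v in nat.items()}}
        return out

    def bounds(self):
        bounds = [(None, None)] * self.n
        for name, fam, sign, fix, names, sl in self.entries:
            for i, pn in enumerate(names):
                if pn.startswith("log_"):
                    bounds[sl.start + i] = (_LOG_SCALE_LB, 40.0)
                elif pn == "mode_logit":
                    bounds[sl.start + i] = (-7.0, 7.0)
        return bounds

    def est_labels(self) -> list[str]:
        labels = []
        for name, fam, sign, fix, names, sl in self.entries:
            for pn in names:
                labels.append(f"{name}:{pn}")
        return labels

    def natural_labels(self) -> list[str]:
        labels = []
        for name, fam, sign, fix, names, sl in self.entries:
            if fam == "rp_sd":
                labels.append("_rho:sigma")
            else:
                for pn in mixing.natural_param_names(fam, fix):
                    labels.append(f"{name}:{pn}")
        return labels

    def natural_jacobian(self, vec: np.ndarray) -> np.ndarray:
        """Block-diagonal d(natural)/d(estimation-scale) at the estimate."""
        J = np.zeros((self.n, self.n))
        for name, fam, sign, fix, names, sl in self.entries:
            if fam == "rp_sd":
                J[sl, sl] = np.exp(vec[sl][0])
            else:
                J[sl, sl] = mixing.natural_jacobian(fam, vec[sl], fix)
        return J


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedModel:
    """Estimates, covariance and fit statistics of one model."""

    spec: ModelSpec
    params: dict  # name -> {"dist", "sign", "params": natural dict}; "_rho" optional
    estimates: dict  # flat "coef:param" -> value (natural scale)
    std_errors: Optional[dict]
    covariance: Optional[np.ndarray]  # natural scale, ordered as cov_labels
    cov_labels: list
    LL: float
    n_params: int
    n_persons: int
    AIC: float
    BIC: float
    R: int
    seed: int
    draw_scheme: str
    person_likelihoods: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""
    boundary: list = field(default_factory=list)
    name: Optional[str] = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for label in self.cov_labels:
            est = self.estimates[label]
            se = self.std_errors.get(label) if self.std_errors else None
            rows.append({"parameter": label, "estimate": est, "std_error": se})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "name": self.name,
            "spec": spec_to_dict(self.spec),
            "params": self.params,
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "cov_labels": self.cov_labels,
            "LL": self.LL,
            "n_params": self.n_params,
            "n_persons": self.n_persons,
            "AIC": self.AIC,
            "BIC": self.BIC,
            "R": self.R,
            "seed": self.seed,
            "draw_scheme": self.draw_scheme,
            "person_likelihoods": self.person_likelihoods.tolist(),
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "message": self.message,
            "boundary": self.boundary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            spec=spec_from_dict(d["spec"]),
            params=d["params"],
            estimates=d["estimates"],
            std_errors=d["std_errors"],
            covariance=None if d["covariance"] is None else np.asarray(d["covariance"]),
            cov_labels=d["cov_labels"],
            LL=d["LL"],
            n_params=d["n_params"],
            n_persons=d["n_persons"],
            AIC=d["AIC"],
            BIC=d["BIC"],
            R=d["R"],
            seed=d["seed"],
            draw_scheme=d["draw_scheme"],
            person_likelihoods=np.asarray(d["person_likelihoods"]),
            converged=d["converged"],
            grad_norm=d["grad_norm"],
            n_iter=d["n_iter"],
            message=d.get("message", ""),
            boundary=d.get("boundary", []),
            name=d.get("name"),
        )


def information_criteria(fitted: FittedModel) -> tuple[float, float]:
    """AIC = 2k − 2LL; BIC = k·ln(N) − 2LL with N the number of persons."""
    aic = 2.0 * fitted.n_params - 2.0 * fitted.LL
    bic = fitted.n_params * np.log(fitted.n_persons) - 2.0 * fitted.LL
    return aic, bic


# ---------------------------------------------------------------------------
# objective functions (negative simulated LL with analytic score)


def _draws_for(spec: ModelSpec, n_persons: int, R: int, seed: int, scheme: str) -> Optional[DrawSet]:
    D = primitive_dims(spec)[-1][2] if primitive_dims(spec) else 0
    if D == 0:
        return None
    maker = mlhs if scheme == "mlhs" else uniform_draws
    return maker(n_persons, D, R, seed)


def _beta_and_grads(idx: ParamIndex, vec: np.ndarray, U, N: int, R: int):
    """Coefficient draw matrix (C,N,R) plus per-parameter dβ/dθ factors."""
    C = sum(1 for e in idx.entries if e[1] != "rp_sd")
    beta = np.empty((C, N, R))
    grads = []  # list over entries of dict est_name -> array/scalar
    dims_pos = 0
    ci = 0
    for name, fam, sign, fix, names, sl in idx.entries:
        if fam == "rp_sd":
            grads.append(None)
            continue
        if fam == "fixed":
            beta[ci] = vec[sl][0]
            grads.append({"value": 1.0})
        else:
            d = mixing.PRIM_DIMS[fam]
            b, g = mixing.draw_values_and_grads(fam, vec[sl], sign, U[dims_pos : dims_pos + d], fix)
            beta[ci] = b
            grads.append(g)
            dims_pos += d
        ci += 1
    return beta, grads


def _mixed_logit_objective(design: PanelDesign, spec: ModelSpec, idx: ParamIndex, draws):
    N = design.X.shape[0]
    R = draws.R if draws is not None else 1
    U = None if draws is None else np.moveaxis(draws.values, 1, 0)
    wtp = spec.space == "wtp"
    p_idx = design.price_idx

    def negloglik(vec, want_pn=False):
        beta, grads = _beta_and_grads(idx, vec, U, N, R)
        V, inner = build_utilities(design, beta, spec.space)
        lnp, P = log_task_probabilities(design, V)
        P_n, w = person_likelihoods_from_draws(lnp.sum(axis=1))
        LL = float(np.log(P_n).sum())
        resid = (design.chosen[..., None] - P) * design.avail[..., None]
        # score factor per coefficient: dLL/dβ summed over tasks, per (n, r)
        grad = np.zeros(idx.n)
        ci = 0
        for (name, fam, sign, fix, names, sl), g in zip(idx.entries, grads):
            if fam == "rp_sd":
                continue
            if wtp and ci != p_idx:
                s_c = beta[p_idx] * np.einsum("ntj,ntjr->nr", design.X[..., ci], resid)
            elif wtp:
                s_c = np.einsum("ntjr,ntjr->nr", inner, resid)
            else:
                s_c = np.einsum("ntj,ntjr->nr", design.X[..., ci], resid)
            ws = w * s_c
            for i, pn in enumerate(names):
                grad[sl.start + i] = float(np.sum(ws * g[pn]))
            ci += 1
        if want_pn:
            return -LL, -grad, P_n
        return -LL, -grad

    return negloglik


def _rp_objective(design: RPDesign, spec: ModelSpec, idx: ParamIndex, draws):
    N = design.c.shape[0]
    R = draws.R if draws is not None else 1
    U = None if draws is None else np.moveaxis(draws.values, 1, 0)
    s = design.rho_sign
    has_rho = spec.rp_error_component is not None
    eq_is_cig = np.array([e == "cig" for e in design.equations])

    def negloglik(vec, want_pn=False):
        beta, grads = _beta_and_grads(idx, vec, U, N, R)
        Vc = np.zeros((N, R))
        Ve = np.zeros((N, R))
        for ci in range(len(design.coef_names)):
            contrib = beta[ci] * design.x[ci][:, None]
            if eq_is_cig[ci]:
                Vc += contrib
            else:
                Ve += contrib
        if has_rho:
            lam = vec[idx.entries[-1][5]][0]
            sigma = np.exp(lam)
            z = ndtri(U[-1])
            rho = sigma * z
            Vc = Vc + rho
            Ve = Ve + s * rho
        Pc = expit(Vc)
        Pe = expit(Ve)
        c = design.c[:, None]
        e = design.e[:, None]
        # log Bernoulli terms via softplus for stability
        lnL = (
            c * (-np.logaddexp(0.0, -Vc))
            + (1 - c) * (-np.logaddexp(0.0, Vc))
            + e * (-np.logaddexp(0.0, -Ve))
            + (1 - e) * (-np.logaddexp(0.0, Ve))
        )
        P_n, w = person_likelihoods_from_draws(lnL)
        LL = float(np.log(P_n).sum())
        rc = c - Pc
        re = e - Pe
        grad = np.zeros(idx.n)
        ci = 0
        for (name, fam, sign, fix, names, sl), g in zip(idx.entries, grads):
            if fam == "rp_sd":
                gg = (rc + s * re) * sigma * z
                grad[sl.start] = float(np.sum(w * gg))
                continue
            r_eq = rc if eq_is_cig[ci] else re
            base = w * r_eq * design.x[ci][:, None]
            for i, pn in enumerate(names):
                grad[sl.start + i] = float(np.sum(base * g[pn]))
            ci += 1
        if want_pn:
            return -LL, -grad, P_n
        return -LL, -grad

    return negloglik


# ---------------------------------------------------------------------------
# starting values


def _default_start(spec: ModelSpec, mnl_values: Mapping[str, float]) -> dict:
    """Natural-scale starting parameters seeded from plain-logit estimates."""
    out = {}
    for c in spec.coefficients:
        b = float(mnl_values.get(c.name, 0.0))
        mag = max(abs(b), 0.05)
        if c.dist == "fixed":
            out[c.name] = {"value": b}
        elif c.dist == "normal":
            out[c.name] = {"mu": b, "sigma": 0.5 * mag}
        elif c.dist == "uniform":
            width = np.sqrt(12.0) * 0.5 * mag
            out[c.name] = {"a": b - width / 2.0, "b": width}
        elif c.dist == "triangular":
            half = np.sqrt(6.0) * 0.5 * mag / 2.0
            out[c.name] = {"a": b - half, "b": half}
        elif c.dist == "lognormal":
            out[c.name] = {"mu": np.log(mag) - 0.3**2 / 2.0, "sigma": 0.3}
        elif c.dist == "loguniform":
            out[c.name] = {"a": np.log(mag) - 0.25, "b": 0.5}
        elif c.dist == "asym_triangular":
            out[c.name] = {"a": b - mag, "b": b + mag, "c": 0.0}
        elif c.dist == "fm2":
            out[c.name] = {"mu": b - 0.1 - 0.1 / 3.0, "sigma1": 0.2, "sigma2": 0.1}
        elif c.dist == "fm3":
            out[c.name] = {
                "mu": b - 0.1 - 0.1 / 3.0 - 0.05 / 4.0,
                "sigma1": 0.2,
                "sigma2": 0.1,
                "sigma3": 0.05,
            }
    if spec.rp_error_component is not None:
        out["_rho"] = {
            "sigma": float(spec.rp_error_component.get("sd", 0.5)),
            "sign": int(spec.rp_error_component.get("sign", 1)),
        }
    return out


# ---------------------------------------------------------------------------
# the driver


def fit_msl(
    spec: ModelSpec,
    data,
    R: int = 500,
    seed: int = 0,
    start: Optional[Mapping] = None,
    draw_scheme: str = "mlhs",
    maxiter: int = 1000,
    gtol: float = 1e-6,
    compute_covariance: bool = True,
    name: Optional[str] = None,
) -> FittedModel:
    """Fit a model by maximum simulated likelihood.

    Dispatches on the dataset type: a :class:`ChoiceDataset` yields a (mixed)
    logit panel model, a :class:`BinaryPanelDataset` the two-equation
    correlated-error logit.  Deterministic given (spec, data, R, seed, start).

    ``start`` optionally supplies natural-scale parameters per coefficient,
    e.g. ``{"b_price": {"mu": -1.0, "sigma": 0.5}}``; anything missing is
    warm-started from a plain-logit fit.
    """
    is_rp = isinstance(data, BinaryPanelDataset)
    idx = ParamIndex.for_spec(spec)
    N = data.n_persons

    # warm start at plain-logit estimates unless the spec is already all-fixed
    mnl_values: dict[str, float] = {}
    all_fixed = all(c.dist == "fixed" for c in spec.coefficients) and spec.rp_error_component is None
    if not all_fixed:
        base = spec.with_all_fixed()
        fitted0 = fit_msl(
            base, data, R=1, seed=seed, draw_scheme=draw_scheme,
            maxiter=maxiter, compute_covariance=False,
        )
        mnl_values = {c.name: fitted0.params[c.name]["params"]["value"] for c in base.coefficients}

    natural0 = _default_start(spec, mnl_values)
    if start:
        for k, v in start.items():
            if k == "_rho":
                natural0["_rho"].update(v)
            else:
                natural0[k].update(v)
    x0 = idx.pack(
        {k: (v if k == "_rho" else {"params": v}) for k, v in natural0.items()}
    )

    if is_rp:
        design = build_rp_design(data, spec)
    else:
        design = build_design(data, spec)
    draws = _draws_for(spec, N, R, seed, draw_scheme)
    objective = (_rp_objective if is_rp else _mixed_logit_objective)(design, spec, idx, draws)

    opts = {"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol, "maxcor": 25}
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=idx.bounds(), options=opts)
    if not res.success:  # a stalled line search often restarts cleanly
        res2 = minimize(objective, res.x, jac=True, method="L-BFGS-B",
                        bounds=idx.bounds(), options=opts)
        if res2.fun <= res.fun:
            res2.nit += res.nit
            res = res2
    vec = res.x
    nll, ngrad, P_n = objective(vec, want_pn=True)
    LL = -nll
    grad_norm = float(np.max(np.abs(ngrad)))
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        log.warning("fit did not converge: %s (grad norm %.2e)", res.message, grad_norm)

    params = idx.unpack(vec)
    boundary = [
        f"{name_}:{pn}"
        for name_, fam, sign, fix, names, sl in idx.entries
        for i, pn in enumerate(names)
        if pn.startswith("log_") and vec[sl.start + i] < _LOG_SCALE_LB + 1.0
    ]

    # natural-scale estimates, flat
    labels = idx.natural_labels()
    flat = {}
    for name_, fam, sign, fix, names, sl in idx.entries:
        if fam == "rp_sd":
            flat["_rho:sigma"] = params["_rho"]["sigma"]
        else:
            for pn in mixing.natural_param_names(fam, fix):
                flat[f"{name_}:{pn}"] = params[name_]["params"][pn]

    cov_nat = None
    ses = None
    if compute_covariance:
        H = _fd_hessian(objective, vec)
        # parameters pinned at a bound, and scale parameters that collapsed to
        # (effectively) zero, leave flat likelihood directions: they are
        # excluded from the inversion and their uncertainty reported as
        # unavailable
        est_names = idx.est_labels()
        free = np.ones(idx.n, dtype=bool)
        for i, (lb, ub) in enumerate(idx.bounds()):
            if (lb is not None and vec[i] <= lb + 1e-6) or (
                ub is not None and vec[i] >= ub - 1e-6
            ):
                free[i] = False
            if est_names[i].split(":")[1].startswith("log_") and vec[i] < np.log(1e-2):
                free[i] = False
        try:
            cov_est = np.zeros((idx.n, idx.n))
            sub = np.linalg.inv(H[np.ix_(free, free)])
            if not np.all(np.isfinite(sub)) or np.any(np.diag(sub) < 0):
                raise np.linalg.LinAlgError
            cov_est[np.ix_(free, free)] = sub
            J = idx.natural_jacobian(vec)
            cov_nat = J @ cov_est @ J.T
            ses = {
                lab: (float(np.sqrt(max(cov_nat[i, i], 0.0))) if free[i] else None)
                for i, lab in enumerate(labels)
            }
        except np.linalg.LinAlgError:
            log.warning("Hessian singular or indefinite; covariance unavailable")
            cov_nat, ses = None, None

    n_params = spec.n_params
    aic = 2.0 * n_params - 2.0 * LL
    bic = n_params * np.log(N) - 2.0 * LL
    return FittedModel(
        spec=spec,
        params=params,
        estimates=flat,
        std_errors=ses,
        covariance=cov_nat,
        cov_labels=labels,
        LL=LL,
        n_params=n_params,
        n_persons=N,
        AIC=aic,
        BIC=bic,
        R=R if draws is not None else 1,
        seed=seed,
        draw_scheme=draw_scheme,
        person_likelihoods=P_n,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        message=str(res.message),
        boundary=boundary,
        name=name,
    )


def _fd_hessian(objective, vec: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    n = len(vec)
    H = np.empty((n, n))
    for i in range(n):
        h = step * (1.0 + abs(vec[i]))
        xp = vec.copy()
        xp[i] += h
        xm = vec.copy()
        xm[i] -= h
        _, gp = objective(xp)
        _, gm = objective(xm)
        H[i] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0
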