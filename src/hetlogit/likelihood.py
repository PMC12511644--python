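"""Choice probabilities and simulated likelihoods.

Utilities are linear in attributes (preference space) or scaled money-metric
(WTP space).  Under type-I extreme-value errors the task-level choice
probability is the softmax over available alternatives; a person's panel
probability is the product over their tasks; random tastes are integrated out
by averaging the panel product over draws (maximum simulated likelihood).

The revealed-preference model is a pair of binary logits sharing an
individual-level normal error component ρ_n that induces correlation between
the two outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import mixing
from .data import (
    BinaryPanelDataset,
    ChoiceDataset,
    ConfigurationError,
    ModelSpec,
    ValidationError,
    validate_spec,
)

P_FLOOR = 1e-300
_NEG_INF = -1e30


# ---------------------------------------------------------------------------
# elementary probability operations


def mnl_probabilities(V: np.ndarray, available: Optional[np.ndarray] = None) -> np.ndarray:
    """Softmax choice probabilities over available alternatives (last axis).

    Unavailable alternatives get probability zero; the remainder renormalize.
    """
    V = np.asarray(V, dtype=float)
    if available is None:
        available = np.ones(V.shape, dtype=bool)
    available = np.asarray(available, dtype=bool)
    if not available.any(axis=-1).all():
        raise ValidationError("a task has no available alternatives")
    if not np.isfinite(V[available]).all():
        raise ValidationError("utilities must be finite")
    Vm = np.where(available, V, _NEG_INF)
    Vm = Vm - Vm.max(axis=-1, keepdims=True)
    e = np.where(available, np.exp(Vm), 0.0)
    return e / e.sum(axis=-1, keepdims=True)


def panel_probability(task_probs) -> float:
    """Probability of a person's observed sequence of choices (product over tasks)."""
    p = np.asarray(task_probs, dtype=float)
    if p.size == 0:
        raise ValidationError("empty panel")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("task probabilities must lie in (0, 1]")
    return float(np.prod(p))


def rp_probabilities(V_cig, V_ecig, rho, sign: int = 1):
    """Use probabilities for the two-equation correlated-error logit.

    P_cig = logistic(V_cig + ρ), P_ecig = logistic(V_ecig + s·ρ); a shared ρ
    with s = +1 makes the outcomes positively associated, s = −1 negatively.
    """
    return expit(np.asarray(V_cig) + np.asarray(rho)), expit(
        np.asarray(V_ecig) + sign * np.asarray(rho)
    )


def rp_person_likelihood(c, e, V_cig, V_ecig, rho_draws, sign: int = 1) -> float:
    """Average over ρ draws of the joint Bernoulli likelihood of (c, e)."""
    rho = np.asarray(rho_draws, dtype=float)
    pc, pe = rp_probabilities(V_cig, V_ecig, rho, sign)
    lik = pc**c * (1 - pc) ** (1 - c) * pe**e * (1 - pe) ** (1 - e)
    return float(max(lik.mean(), P_FLOOR))


# ---------------------------------------------------------------------------
# panel design: dense padded arrays for vectorized likelihoods


@dataclass
class PanelDesign:
    """Dense (person, task, alternative) layout of a long-format choice panel."""

    person_ids: np.ndarray  # (N,) original labels, first-appearance order
    X: np.ndarray  # (N, T, J, C) attribute value per coefficient
    avail: np.ndarray  # (N, T, J) bool
    chosen: np.ndarray  # (N, T, J) float 0/1
    task_mask: np.ndarray  # (N, T) bool
    alt_codes: np.ndarray  # (N, T, J) int, -1 for padding
    alt_labels: list
    coef_names: list
    price_idx: Optional[int] = None

    @property
    def shape(self):
        return self.X.shape


def build_design(data: ChoiceDataset, spec: ModelSpec) -> PanelDesign:
    validate_spec(spec, data)
    t = data.table
    pid, persons = pd.factorize(t["person_id"], sort=False)
    tid = (
        t.groupby("person_id", sort=False)["task_id"]
        .transform(lambda s: pd.factorize(s)[0])
        .to_numpy()
    )
    pos = t.groupby(["person_id", "task_id"], sort=False).cumcount().to_numpy()
    aid, alts = pd.factorize(t["alt_id"], sort=False)

    N = len(persons)
    T = int(tid.max()) + 1
    J = int(pos.max()) + 1
    C = len(spec.coefficients)

    X = np.zeros((N, T, J, C))
    avail = np.zeros((N, T, J), dtype=bool)
    chosen = np.zeros((N, T, J))
    task_mask = np.zeros((N, T), dtype=bool)
    alt_codes = np.full((N, T, J), -1, dtype=int)

    avail[pid, tid, pos] = t["available"].to_numpy(dtype=bool)
    chosen[pid, tid, pos] = t["chosen"].to_numpy(dtype=float)
    task_mask[pid, tid] = True
    alt_codes[pid, tid, pos] = aid

    for ci, coef in enumerate(spec.coefficients):
        if coef.asc_group is not None:
            members = set(data.alt_groups[coef.asc_group])
            x = t["alt_id"].isin(members).to_numpy(dtype=float)
        else:
            x = np.zeros(len(t))
            for a in coef.attributes:
                x = x + t[a].to_numpy(dtype=float)
        X[pid, tid, pos, ci] = x

    # chosen only counts where available
    chosen *= avail

    price_idx = None
    if spec.space == "wtp":
        price_idx = [c.name for c in spec.coefficients].index(spec.price_coefficient)
    return PanelDesign(
        person_ids=np.asarray(persons),
        X=X,
        avail=avail,
        chosen=chosen,
        task_mask=task_mask,
        alt_codes=alt_codes,
        alt_labels=list(alts),
        coef_names=[c.name for c in spec.coefficients],
        price_idx=price_idx,
    )


# ---------------------------------------------------------------------------
# vectorized utilities / probabilities over draws


def build_utilities(design: PanelDesign, beta: np.ndarray, space: str = "preference"):
    """Deterministic utilities V for every (person, task, alternative, draw).

    ``beta`` has shape (C, N, R).  In WTP space V = β_price · (price + Σ_k
    w_k·x_k + ASCs): the designated price coefficient scales the bracket of
    money-metric terms, so non-price coefficients are read directly as WTP.
    Returns (V, inner) where inner is the WTP-space bracket (None otherwise).
    """
    X = design.X
    if space == "preference":
        V = np.einsum("ntjc,cnr->ntjr", X, beta)
        return V, None
    p = design.price_idx
    keep = [k for k in range(X.shape[-1]) if k != p]
    inner = X[..., p][..., None] + np.einsum("ntjc,cnr->ntjr", X[..., keep], beta[keep])
    V = beta[p][:, None, None, :] * inner
    return V, inner


def log_task_probabilities(design: PanelDesign, V: np.ndarray):
    """(ln P of chosen alternative per task, full probability array P)."""
    avail = design.avail[..., None]
    Vm = np.where(avail, V, _NEG_INF)
    M = Vm.max(axis=2, keepdims=True)
    e = np.where(avail, np.exp(Vm - M), 0.0)
    denom = e.sum(axis=2, keepdims=True)
    P = e / np.where(denom > 0, denom, 1.0)
    lse = M[:, :, 0, :] + np.log(np.where(denom[:, :, 0, :] > 0, denom[:, :, 0, :], 1.0))
    V_chosen = np.einsum("ntj,ntjr->ntr", design.chosen, V)
    lnp = np.where(design.task_mask[..., None], V_chosen - lse, 0.0)
    return lnp, P


def person_likelihoods_from_draws(lnL_nr: np.ndarray):
    """Simulated P_n = (1/R)·Σ_r Π_t P_ntj*(β_r), with posterior draw weights.

    Returns (P_n, w_nr) where w_nr are the normalized per-draw contributions
    used by the analytic score.
    """
    m = lnL_nr.max(axis=1)
    A = np.exp(lnL_nr - m[:, None])
    S = A.sum(axis=1)
    P_n = np.maximum(np.exp(m) * S / lnL_nr.shape[1], P_FLOOR)
    w = A / S[:, None]
    return P_n, w


def simulated_person_probability(
    spec: ModelSpec, params: Mapping, data: ChoiceDataset, draws
) -> np.ndarray:
    """Simulated panel probability P_n per person at given natural parameters.

    ``params`` maps coefficient name to its natural parameter dict; ``draws``
    is a uniform DrawSet with the primitive dimensions the spec requires (in
    coefficient order).  With no random coefficients this reduces exactly to
    the plain MNL panel likelihood.
    """
    design = build_design(data, spec)
    beta = coefficient_draws_matrix(spec, params, draws, design.person_ids.shape[0])
    V, _ = build_utilities(design, beta, spec.space)
    lnp, _ = log_task_probabilities(design, V)
    P_n, _ = person_likelihoods_from_draws(lnp.sum(axis=1))
    return P_n


def primitive_dims(spec: ModelSpec) -> list[tuple[str, int, int]]:
    """Allocate primitive draw dimensions: (coef name, start, stop) per coefficient."""
    out = []
    start = 0
    for c in spec.coefficients:
        d = mixing.PRIM_DIMS[c.dist]
        out.append((c.name, start, start + d))
        start += d
    if spec.rp_error_component is not None:
        out.append(("_rho", start, start + 1))
    return out


def coefficient_draws_matrix(
    spec: ModelSpec, params: Mapping, draws, n_persons: int
) -> np.ndarray:
    """(C, N, R) matrix of person-level coefficient values at natural parameters."""
    R = draws.R if draws is not None else 1
    C = len(spec.coefficients)
    beta = np.empty((C, n_persons, R))
    dims = primitive_dims(spec)
    U = None if draws is None else np.moveaxis(draws.values, 1, 0)
    for ci, coef in enumerate(spec.coefficients):
        p = params[coef.name]
        p = p.get("params", p)  # accept FittedModel.params entries or bare dicts
        if coef.dist == "fixed":
            beta[ci] = p["value"]
            continue
        _, lo, hi = dims[ci]
        if U is None or hi > U.shape[0]:
            raise ConfigurationError(
                f"draws do not cover coefficient {coef.name!r} (family {coef.dist})"
            )
        beta[ci] = mixing.draw_coefficients(coef.dist, p, coef.sign, U[lo:hi])
    return beta


# ---------------------------------------------------------------------------
# revealed-preference design


@dataclass
class RPDesign:
    person_ids: np.ndarray
    c: np.ndarray  # (N,) 0/1 cigarette use
    e: np.ndarray  # (N,) 0/1 e-cigarette use
    x: np.ndarray  # (C, N) covariate value per coefficient (1.0 for intercepts)
    equations: list  # "cig" / "ecig" per coefficient
    coef_names: list
    rho_sign: int


def build_rp_design(data: BinaryPanelDataset, spec: ModelSpec) -> RPDesign:
    validate_spec(spec, data)
    t = data.table
    N = len(t)
    C = len(spec.coefficients)
    x = np.ones((C, N))
    for ci, coef in enumerate(spec.coefficients):
        if coef.attributes:
            x[ci] = np.sum([t[a].to_numpy(dtype=float) for a in coef.attributes], axis=0)
    sign = 1
    if spec.rp_error_component is not None:
        sign = int(spec.rp_error_component.get("sign", 1))
    return RPDesign(
        person_ids=t["person_id"].to_numpy(),
        c=t["cig"].to_numpy(dtype=float),
        e=t["ecig"].to_numpy(dtype=float),
        x=x,
        equations=[c.equation for c in spec.coefficients],
        coef_names=[c.name for c in spec.coefficients],
        rho_sign=sign,
    )
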