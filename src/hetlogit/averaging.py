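"""Sequential latent-class model averaging.

Already-fitted constituent models are treated as latent classes whose
parameters are frozen; the only free parameters are the class-membership
weights.  With person-level likelihoods P_nk from constituent k, the averaged
log-likelihood is

    LL_MA = Σ_n ln( Σ_k π_k · P_nk ),   π_k = exp(θ_k) / Σ_j exp(θ_j),

with θ_1 ≡ 0 for identification.  The mixture log-likelihood is concave in π,
so any interior stationary point of θ is the global optimum; degenerate
(vertex) solutions are represented by capping |θ| at 30.  The conservative
information criterion counts every parameter of every constituent plus the
K−1 estimated weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import softmax

from .data import ValidationError

THETA_CAP = 30.0


@dataclass
class ModelAverage:
    """Fitted model average over K frozen constituent models."""

    theta: np.ndarray  # (K,) weight parameters, theta[0] == 0
    pi: np.ndarray  # (K,) weights on the simplex
    LL: float
    P: np.ndarray  # (N, K) constituent person-likelihood columns
    constituent_n_params: tuple[int, ...]
    constituent_names: tuple[str, ...]
    n_params_conservative: int
    AIC: float

    @property
    def K(self) -> int:
        return len(self.pi)

    def person_probability(self, n: int) -> float:
        """Averaged person likelihood Σ_k π_k·P_nk for person index n."""
        return float(self.P[n] @ self.pi)

    def person_probabilities(self) -> np.ndarray:
        return self.P @ self.pi

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "theta": self.theta.tolist(),
                    "pi": self.pi.tolist(),
                    "LL": self.LL,
                    "constituent_n_params": list(self.constituent_n_params),
                    "constituent_names": list(self.constituent_names),
                    "n_params_conservative": self.n_params_conservative,
                    "AIC": self.AIC,
                    "P": self.P.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ModelAverage":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            theta=np.asarray(d["theta"]),
            pi=np.asarray(d["pi"]),
            LL=d["LL"],
            P=np.asarray(d["P"]),
            constituent_n_params=tuple(d["constituent_n_params"]),
            constituent_names=tuple(d["constituent_names"]),
            n_params_conservative=d["n_params_conservative"],
            AIC=d["AIC"],
        )


def _ll_and_grad(free_theta: np.ndarray, P: np.ndarray):
    theta = np.concatenate([[0.0], free_theta])
    pi = softmax(theta)
    mix = P @ pi
    LL = float(np.log(mix).sum())
    # dLL/dtheta_k = Σ_n π_k (P_nk − mix_n) / mix_n
    g = pi * ((P / mix[:, None]).sum(axis=0) - P.shape[0])
    return LL, g[1:], pi


def fit_model_average(
    P: np.ndarray,
    n_params: Optional[Sequence[int]] = None,
    names: Optional[Sequence[str]] = None,
) -> ModelAverage:
    """Estimate averaging weights from a persons × K matrix of P_n columns.

    Constituent parameters stay frozen — only the weights are estimated, so
    nothing beyond the model outputs P_nk is needed.  θ components are capped
    at ±30 so degenerate (single-model) averages are representable.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need a persons x K matrix with K >= 2")
    if not np.isfinite(P).all():
        raise ValidationError("non-finite person likelihoods")
    if np.any(P <= 0) or np.any(P > 1):
        raise ValidationError("person likelihoods must lie in (0, 1]")
    K = P.shape[1]

    def nll(ft):
        LL, g, _ = _ll_and_grad(ft, P)
        return -LL, -g

    bounds = [(-THETA_CAP, THETA_CAP)] * (K - 1)
    best = None
    ll_cols = np.log(P).sum(axis=0)
    starts = [np.zeros(K - 1)]
    k_star = int(np.argmax(ll_cols))
    if k_star > 0:  # also try starting near the best constituent's vertex
        s = np.zeros(K - 1)
        s[k_star - 1] = THETA_CAP
        starts.append(s)
    for x0 in starts:
        res = minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    LL, _, pi = _ll_and_grad(best.x, P)
    # a vertex optimum can sit just outside the capped region: never report
    # an average worse than its best constituent
    if LL < ll_cols[k_star]:
        vert = np.full(K - 1, -THETA_CAP)
        if k_star > 0:
            vert[k_star - 1] = THETA_CAP
        ll_v, _, pi_v = _ll_and_grad(vert, P)
        if ll_v > LL:
            LL, pi = ll_v, pi_v
            best.x = vert
    theta = np.concatenate([[0.0], best.x])
    if n_params is None:
        n_params = [0] * K
    if names is None:
        names = [f"model_{k + 1}" for k in range(K)]
    k_cons = int(sum(n_params) + (K - 1))
    return ModelAverage(
        theta=theta,
        pi=pi,
        LL=LL,
        P=P,
        constituent_n_params=tuple(int(v) for v in n_params),
        constituent_names=tuple(names),
        n_params_conservative=k_cons,
        AIC=2.0 * k_cons - 2.0 * LL,
    )


def average_models(models, names: Optional[Sequence[str]] = None) -> ModelAverage:
    """Model-average a list of FittedModel objects sharing one dataset."""
    if len(models) < 2:
        raise ValueError("model averaging needs at least 2 constituent models")
    n0 = len(models[0].person_likelihoods)
    if any(len(m.person_likelihoods) != n0 for m in models):
        raise ValidationError("constituent models were fitted on different persons")
    P = np.column_stack([m.person_likelihoods for m in models])
    if names is None:
        names = [m.name or f"model_{i + 1}" for i, m in enumerate(models)]
    return fit_model_average(P, [m.n_params for m in models], names)


def ma_person_probability(ma: ModelAverage, person: int) -> float:
    return ma.person_probability(person)


def ma_information_criterion(ma: ModelAverage) -> float:
    """Conservative AIC: all constituent parameters plus the K−1 weights."""
    return ma.AIC
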