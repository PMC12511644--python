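"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own simulation machinery: quadrature
replaces draw-averaging, explicit loops replace vectorized scores.
"""

import numpy as np
from scipy.special import expit


def gauss_hermite_normal(n_nodes=101):
    """Nodes/weights for E[f(Z)] with Z ~ N(0,1) (probabilists' Hermite)."""
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return z, w / w.sum()


def logit_choice_prob_quadrature(x_alt, chosen_idx, mu, sigma, n_nodes=201):
    """P(chosen) for a one-task logit with a single N(mu, sigma^2) coefficient."""
    z, w = gauss_hermite_normal(n_nodes)
    beta = mu + sigma * z  # (Q,)
    V = np.outer(np.asarray(x_alt), beta)  # (J, Q)
    V -= V.max(axis=0, keepdims=True)
    P = np.exp(V) / np.exp(V).sum(axis=0, keepdims=True)
    return float(np.sum(w * P[chosen_idx]))


def rp_joint_prob_quadrature(c, e, V_cig, V_ecig, sigma_rho, sign=1, n_nodes=201):
    """E_rho of the joint Bernoulli probability of (c, e)."""
    z, w = gauss_hermite_normal(n_nodes)
    rho = sigma_rho * z
    pc = expit(V_cig + rho)
    pe = expit(V_ecig + sign * rho)
    lik = pc**c * (1 - pc) ** (1 - c) * pe**e * (1 - pe) ** (1 - e)
    return float(np.sum(w * lik))


def mixture_normal_mean_quadrature(components, f, n_nodes=101):
    """E[f(beta)] under a finite normal mixture, by quadrature."""
    z, w = gauss_hermite_normal(n_nodes)
    total = 0.0
    for weight, mu, sd in components:
        total += weight * float(np.sum(w * f(mu + sd * z)))
    return total


def expected_group_share(table, attributes, tastes_fixed, random_name, components, group_mask_col):
    """Analytic expected share of a group of alternatives under mixture tastes.

    One taste is mixture-normal; all others fixed.  Integrates the MNL
    probability task by task with Gauss–Hermite quadrature.
    """
    z, w = gauss_hermite_normal(61)
    share = 0.0
    n_tasks = 0
    for (_, _), g in table.groupby(["person_id", "task_id"], sort=False):
        X = {a: g[a].to_numpy(dtype=float) for a in attributes}
        V_fixed = np.zeros(len(g))
        for name, val in tastes_fixed.items():
            V_fixed += val * X[name]
        mask = g[group_mask_col].to_numpy(dtype=float)
        task_share = 0.0
        for weight, mu, sd in components:
            beta = mu + sd * z  # (Q,)
            V = V_fixed[:, None] + beta[None, :] * X[random_name][:, None]
            V -= V.max(axis=0, keepdims=True)
            P = np.exp(V) / np.exp(V).sum(axis=0, keepdims=True)
            task_share += weight * float(np.sum(w * (mask @ P)))
        share += task_share
        n_tasks += 1
    return share / n_tasks
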