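"""Post-estimation: enumerated choice shares, unconditional preference and
WTP distributions, WTP means with confidence intervals, model comparison.

Sample enumeration averages each alternative's predicted probability over
persons, tasks and draws; with a full set of alternative-specific constants
the logit score equations force these shares to equal the observed choice
shares.  Unconditionals are draws from the fitted population-level mixing
distribution (not conditioned on any person's choices); for a model average
they are sampled by first picking a constituent with the estimated weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from . import mixing
from .averaging import ModelAverage
from .data import BinaryPanelDataset, ChoiceDataset, ValidationError
from .draws import mlhs
from .fit import FittedModel
from .likelihood import (
    build_design,
    build_rp_design,
    build_utilities,
    coefficient_draws_matrix,
    log_task_probabilities,
    primitive_dims,
)
from scipy.special import expit, ndtri


# ---------------------------------------------------------------------------
# sample enumeration


@dataclass
class EnumeratedShares:
    shares: dict  # group label -> average predicted probability
    grouping: dict  # group label -> tuple of alternative labels

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares)


def _choice_probability_matrix(fitted: FittedModel, data: ChoiceDataset):
    """Average over draws of predicted P (N, T, J), plus the design."""
    spec = fitted.spec
    design = build_design(data, spec)
    N = design.X.shape[0]
    D = primitive_dims(spec)[-1][2] if spec.coefficients else 0
    draws = mlhs(N, D, fitted.R, fitted.seed) if D > 0 else None
    beta = coefficient_draws_matrix(spec, fitted.params, draws, N)
    V, _ = build_utilities(design, beta, spec.space)
    _, P = log_task_probabilities(design, V)
    return P.mean(axis=3), design


def sample_enumeration(
    model: Union[FittedModel, ModelAverage],
    data,
    grouping: Optional[Mapping[str, Sequence]] = None,
    constituents: Optional[Sequence[FittedModel]] = None,
) -> EnumeratedShares:
    """Average predicted choice probabilities, aggregated by alternative group.

    For a model average, shares are the π-weighted mix of each constituent's
    enumeration (pass the constituent FittedModels in estimation order).
    """
    if isinstance(model, ModelAverage):
        if constituents is None:
            raise ValueError("pass constituent FittedModels to enumerate a model average")
        parts = [sample_enumeration(m, data, grouping) for m in constituents]
        shares = {
            g: float(sum(w * p.shares[g] for w, p in zip(model.pi, parts)))
            for g in parts[0].shares
        }
        return EnumeratedShares(shares, parts[0].grouping)

    if isinstance(data, BinaryPanelDataset):
        return _rp_enumeration(model, data)

    P_bar, design = _choice_probability_matrix(model, data)
    labels = design.alt_labels
    if grouping is None:
        grouping = {str(a): (a,) for a in labels}
    seen = [a for g in grouping.values() for a in g]
    if len(seen) != len(set(seen)) or set(seen) != set(labels):
        raise ValidationError(
            f"grouping must partition the alternatives {labels}, got {grouping}"
        )
    code_of = {a: i for i, a in enumerate(labels)}
    n_tasks = design.task_mask.sum()
    shares = {}
    for g, alts in grouping.items():
        codes = {code_of[a] for a in alts}
        mask = np.isin(design.alt_codes, list(codes)) & design.avail
        shares[g] = float(np.sum(P_bar * mask) / n_tasks)
    return EnumeratedShares(shares, {g: tuple(a) for g, a in grouping.items()})


def _rp_enumeration(fitted: FittedModel, data: BinaryPanelDataset) -> EnumeratedShares:
    spec = fitted.spec
    design = build_rp_design(data, spec)
    N = len(design.c)
    D = primitive_dims(spec)[-1][2]
    draws = mlhs(N, D, fitted.R, fitted.seed) if D > 0 else None
    beta = coefficient_draws_matrix(spec, fitted.params, draws, N)
    R = beta.shape[2]
    Vc = np.zeros((N, R))
    Ve = np.zeros((N, R))
    for ci, eq in enumerate(design.equations):
        contrib = beta[ci] * design.x[ci][:, None]
        if eq == "cig":
            Vc += contrib
        else:
            Ve += contrib
    if spec.rp_error_component is not None:
        sigma = fitted.params["_rho"]["sigma"]
        z = ndtri(np.moveaxis(draws.values, 1, 0)[-1])
        Vc = Vc + sigma * z
        Ve = Ve + design.rho_sign * sigma * z
    pc = float(expit(Vc).mean())
    pe = float(expit(Ve).mean())
    return EnumeratedShares(
        {"smoker": pc, "nonsmoker": 1 - pc, "vaper": pe, "nonvaper": 1 - pe},
        {"smoker": ("cig",), "vaper": ("ecig",)},
    )


# ---------------------------------------------------------------------------
# unconditional preference / WTP distributions


@dataclass
class PreferenceSample:
    coefficient: str
    values: np.ndarray
    source: str  # "model" or "model_average"
    seed: int


def sample_unconditionals(
    model: Union[FittedModel, ModelAverage],
    S: int,
    seed: int = 0,
    constituents: Optional[Sequence[FittedModel]] = None,
    coefficients: Optional[Sequence[str]] = None,
) -> dict[str, PreferenceSample]:
    """S draws per coefficient from the fitted mixing distributions.

    For a model average this is mixture sampling: each draw first selects a
    constituent with probabilities π, then draws from that constituent's
    fitted distribution.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(model, ModelAverage):
        if constituents is None:
            raise ValueError("pass constituent FittedModels for a model average")
        ks = rng.choice(model.K, size=S, p=model.pi)
        per = [
            sample_unconditionals(m, S, seed=int(rng.integers(2**31)), coefficients=coefficients)
            for m in constituents
        ]
        out = {}
        for name in per[0]:
            vals = np.empty(S)
            for k in range(model.K):
                sel = ks == k
                vals[sel] = per[k][name].values[: int(sel.sum())]
            out[name] = PreferenceSample(name, vals, "model_average", seed)
        return out

    out = {}
    for c in model.spec.coefficients:
        if coefficients is not None and c.name not in coefficients:
            continue
        p = model.params[c.name]["params"]
        vals = mixing.sample(c.dist, p, c.sign, S, rng)
        out[c.name] = PreferenceSample(c.name, vals, "model", seed)
    return out


# ---------------------------------------------------------------------------
# WTP means with confidence intervals


def wtp_means(fitted: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Mean WTP per non-price coefficient of a WTP-space model, with CIs.

    The mean is the analytic mean of each coefficient's fitted mixing
    distribution; the CI is delta-method from the natural-scale covariance
    (normal-theory, default 95%).
    """
    if fitted.spec.space != "wtp":
        raise ValueError("wtp_means requires a model estimated in WTP space")
    from scipy.stats import norm as _norm

    zc = _norm.ppf(0.5 + level / 2.0)
    rows = []
    for c in fitted.spec.coefficients:
        if c.name == fitted.spec.price_coefficient:
            continue
        p = fitted.params[c.name]["params"]
        mean = mixing.analytic_mean(c.dist, p, c.sign)
        lo = hi = se = None
        if fitted.covariance is not None:
            names = mixing.natural_param_names(c.dist, c.fix_offset)
            labs = [f"{c.name}:{pn}" for pn in names]
            pos = [fitted.cov_labels.index(l) for l in labs]
            sub = fitted.covariance[np.ix_(pos, pos)]
            g = mixing.mean_gradient(c.dist, p, c.sign)[: len(pos)]
            se = float(np.sqrt(max(g @ sub @ g, 0.0)))
            lo, hi = mean - zc * se, mean + zc * se
        rows.append(
            {"coefficient": c.name, "mean_wtp": mean, "se": se, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densities and model comparison


@dataclass
class DensitySummary:
    grid: np.ndarray
    density: np.ndarray
    quantiles: dict
    share_positive: float
    modes: np.ndarray
    point_mass: Optional[float] = None


def density_summary(
    sample: PreferenceSample,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 512,
) -> DensitySummary:
    """Kernel density (Silverman bandwidth), quantiles and share above zero."""
    x = np.asarray(sample.values, dtype=float)
    qs = {q: float(np.quantile(x, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)}
    share_pos = float(np.mean(x > 0))
    if np.std(x) < 1e-12:
        g = np.array([x[0]]) if grid is None else np.asarray(grid)
        d = np.zeros_like(g, dtype=float)
        return DensitySummary(g, d, qs, share_pos, np.array([x[0]]), point_mass=float(x[0]))
    if grid is None:
        lo, hi = x.min(), x.max()
        pad = 0.05 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, n_grid)
    kde = gaussian_kde(x, bw_method="silverman")
    dens = kde(grid)
    mode_idx = argrelmax(dens, order=3)[0]
    if len(mode_idx) == 0:
        mode_idx = np.array([int(np.argmax(dens))])
    # keep modes that are non-negligible relative to the highest peak
    mode_idx = mode_idx[dens[mode_idx] > 0.05 * dens.max()]
    return DensitySummary(np.asarray(grid), dens, qs, share_pos, np.asarray(grid)[mode_idx])


def compare_models(
    models: Sequence[Union[FittedModel, ModelAverage]],
    names: Optional[Sequence[str]] = None,
    shares: Optional[Sequence[Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Comparison table (LL, k, AIC, BIC, optional enumerated shares), AIC-ascending."""
    if len(models) == 0:
        raise ValueError("no models to compare")
    n0 = None
    rows = []
    for i, m in enumerate(models):
        if isinstance(m, ModelAverage):
            n = m.P.shape[0]
            row = {
                "model": (names[i] if names else None) or "MA",
                "LL": m.LL,
                "n_params": m.n_params_conservative,
                "AIC": m.AIC,
                "BIC": np.nan,
            }
        else:
            n = m.n_persons
            row = {
                "model": (names[i] if names else None) or m.name or f"model_{i + 1}",
                "LL": m.LL,
                "n_params": m.n_params,
                "AIC": m.AIC,
                "BIC": m.BIC,
            }
        if n0 is None:
            n0 = n
        elif n != n0:
            raise ValidationError("models were fitted on different datasets")
        if shares is not None:
            row.update({f"share_{g}": v for g, v in shares[i].items()})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
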