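"""The parametric mixing families: transforms from primitive draws to tastes.

Each taste coefficient β_m varies over persons according to one of the
families below.  Person-level values are built from standard uniform
primitives (MLHS or pseudo-random); normal primitives are obtained through the
inverse normal CDF.

Families and implementations (s is the fixed sign of the log families):

========  =============================  ===========================
tag       parameters (natural scale)     β from primitives
========  =============================  ===========================
fixed     value                          value
normal    μ, σ                           μ + σ·z
uniform   a, b                           a + b·u            support [a, a+b]
triangular a, b                          a + b·(u1 + u2)    support [a, a+2b]
lognormal μ, σ                           s·exp(μ + σ·z)
loguniform a, b                          s·exp(a + b·u)
asym_triangular a, b, c                  two-piece triangle on [a, b],
                                         mode m = (a+b)/2 + c
fm2/fm3   μ, σ_1..σ_P                    μ + Σ_p σ_p·u^p  (one u per draw)
========  =============================  ===========================

The asymmetric triangular draws a piece (below / above the mode) with
probability proportional to each piece's triangle area and then inverts the
piece CDF, β_lower = a + (m−a)·√u1, β_upper = b − (b−m)·√u2, which yields a
proper triangular density and collapses to the symmetric triangular at c = 0.

For estimation, scale parameters (σ, the range b, the span b−a of the
asymmetric triangular) are optimized on the log scale and the asymmetric
triangular's mode as a logistic fraction of its support, which keeps every
family's parameter space unconstrained.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit, ndtri
from scipy.stats import norm

from .data import ConfigurationError

# number of primitive uniform dimensions each family consumes
PRIM_DIMS = {
    "fixed": 0,
    "normal": 1,
    "uniform": 1,
    "triangular": 2,
    "lognormal": 1,
    "loguniform": 1,
    "asym_triangular": 3,  # piece selector + one per piece
    "fm2": 1,
    "fm3": 1,
}

SCALE_FLOOR = 1e-8  # exact-zero scales represented by this boundary
_EXP_CAP = 100.0  # cap on log-family exponents; keeps wandering optimizers finite

_NATURAL = {
    "fixed": ("value",),
    "normal": ("mu", "sigma"),
    "uniform": ("a", "b"),
    "triangular": ("a", "b"),
    "lognormal": ("mu", "sigma"),
    "loguniform": ("a", "b"),
    "asym_triangular": ("a", "b", "c"),
    "fm2": ("mu", "sigma1", "sigma2"),
    "fm3": ("mu", "sigma1", "sigma2", "sigma3"),
}

_LOG_SCALED = {
    "normal": ("mu", "log_sigma"),
    "uniform": ("a", "log_b"),
    "triangular": ("a", "log_b"),
    "lognormal": ("mu", "log_sigma"),
    "loguniform": ("a", "log_b"),
}


def natural_param_names(family: str, fix_offset: bool = True) -> tuple[str, ...]:
    names = _NATURAL[family]
    if family == "asym_triangular" and fix_offset:
        return names[:2]
    return names


def est_param_names(family: str, fix_offset: bool = True) -> tuple[str, ...]:
    if family in _LOG_SCALED:
        return _LOG_SCALED[family]
    if family == "asym_triangular":
        return ("a", "log_range") if fix_offset else ("a", "log_range", "mode_logit")
    return _NATURAL[family]  # fixed, fm2, fm3: unconstrained


def _fm_order(family: str) -> int:
    return {"fm2": 2, "fm3": 3}[family]


# ---------------------------------------------------------------------------
# estimation-scale <-> natural-scale parameter maps


def natural_to_est(family: str, params: dict, fix_offset: bool = True) -> np.ndarray:
    p = params
    if family in ("normal", "lognormal"):
        return np.array([p["mu"], np.log(max(p["sigma"], SCALE_FLOOR))])
    if family in ("uniform", "triangular", "loguniform"):
        return np.array([p["a"], np.log(max(p["b"], SCALE_FLOOR))])
    if family == "asym_triangular":
        a, b = p["a"], p["b"]
        if not b > a:
            raise ConfigurationError("asym_triangular requires b > a")
        g = np.log(b - a)
        if fix_offset:
            return np.array([a, g])
        m = (a + b) / 2.0 + p.get("c", 0.0)
        f = (m - a) / (b - a)
        if not 0.0 < f < 1.0:
            raise ConfigurationError("asym_triangular mode must lie inside (a, b)")
        return np.array([a, g, _logit(f)])
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        return np.array([p["mu"]] + [p[f"sigma{i}"] for i in range(1, P + 1)])
    if family == "fixed":
        return np.array([p["value"]])
    raise ConfigurationError(f"unknown family {family!r}")


def est_to_natural(family: str, est: np.ndarray, fix_offset: bool = True) -> dict:
    if family in ("normal", "lognormal"):
        return {"mu": est[0], "sigma": np.exp(est[1])}
    if family in ("uniform", "triangular", "loguniform"):
        return {"a": est[0], "b": np.exp(est[1])}
    if family == "asym_triangular":
        a = est[0]
        b = a + np.exp(est[1])
        f = 0.5 if fix_offset else expit(est[2])
        m = a + f * (b - a)
        return {"a": a, "b": b, "c": m - (a + b) / 2.0}
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        out = {"mu": est[0]}
        out.update({f"sigma{i}": est[i] for i in range(1, P + 1)})
        return out
    if family == "fixed":
        return {"value": est[0]}
    raise ConfigurationError(f"unknown family {family!r}")


def natural_jacobian(family: str, est: np.ndarray, fix_offset: bool = True) -> np.ndarray:
    """d(natural params)/d(estimation params), for delta-method covariances."""
    if family in ("normal", "lognormal", "uniform", "triangular", "loguniform"):
        return np.diag([1.0, np.exp(est[1])])
    if family == "asym_triangular":
        span = np.exp(est[1])
        if fix_offset:
            # natural (a, b) vs est (a, log_range)
            return np.array([[1.0, 0.0], [1.0, span]])
        f = expit(est[2])
        # natural (a, b, c) vs est (a, log_range, mode_logit)
        return np.array(
            [
                [1.0, 0.0, 0.0],
                [1.0, span, 0.0],
                [0.0, span * (f - 0.5), span * f * (1 - f)],
            ]
        )
    n = len(est)
    return np.eye(n)


# ---------------------------------------------------------------------------
# primitive -> coefficient transforms and their estimation-scale gradients


def draw_coefficients(family: str, params: dict, sign: int, U: np.ndarray) -> np.ndarray:
    """Person×draw coefficient values from uniform primitives U of shape (d, ..., R)."""
    if U.shape[0] != PRIM_DIMS[family]:
        raise ConfigurationError(
            f"{family} needs {PRIM_DIMS[family]} primitive dims, got {U.shape[0]}"
        )
    if family == "fixed":
        raise ConfigurationError("fixed coefficients have no draws")
    if family == "normal":
        return params["mu"] + params["sigma"] * ndtri(U[0])
    if family == "uniform":
        return params["a"] + params["b"] * U[0]
    if family == "triangular":
        return params["a"] + params["b"] * (U[0] + U[1])
    if family == "lognormal":
        return sign * np.exp(np.clip(params["mu"] + params["sigma"] * ndtri(U[0]), -_EXP_CAP, _EXP_CAP))
    if family == "loguniform":
        return sign * np.exp(np.clip(params["a"] + params["b"] * U[0], -_EXP_CAP, _EXP_CAP))
    if family == "asym_triangular":
        a, b = params["a"], params["b"]
        m = (a + b) / 2.0 + params.get("c", 0.0)
        f = (m - a) / (b - a)
        lower = a + (m - a) * np.sqrt(U[1])
        upper = b - (b - m) * np.sqrt(U[2])
        return np.where(U[0] < f, lower, upper)
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        u = U[0]
        out = np.full_like(u, float(params["mu"]))
        up = np.ones_like(u)
        for p in range(1, P + 1):
            up = up * u
            out = out + params[f"sigma{p}"] * up
        return out
    raise ConfigurationError(f"unknown family {family!r}")


def transform_coefficients(spec, params: dict, draws) -> np.ndarray:
    """Spec-level wrapper: apply a CoefficientSpec's family to a DrawSet."""
    U = np.moveaxis(draws.values, 1, 0)  # (dims, persons, R)
    return draw_coefficients(spec.dist, params, spec.sign, U)


def draw_values_and_grads(
    family: str, est: np.ndarray, sign: int, U: np.ndarray, fix_offset: bool = True
):
    """β draws plus dβ/d(estimation params); used by the analytic score.

    Returns ``(beta, grads)`` where grads maps estimation-parameter name to an
    array broadcastable against beta.  For the asymmetric triangular the piece
    indicator is held fixed when differentiating (the simulated likelihood is
    piecewise smooth in the mode parameter).
    """
    nat = est_to_natural(family, est, fix_offset)
    if family == "normal":
        z = ndtri(U[0])
        sz = nat["sigma"] * z
        return nat["mu"] + sz, {"mu": 1.0, "log_sigma": sz}
    if family == "uniform":
        bu = nat["b"] * U[0]
        return nat["a"] + bu, {"a": 1.0, "log_b": bu}
    if family == "triangular":
        bu = nat["b"] * (U[0] + U[1])
        return nat["a"] + bu, {"a": 1.0, "log_b": bu}
    if family == "lognormal":
        z = ndtri(U[0])
        beta = sign * np.exp(np.clip(nat["mu"] + nat["sigma"] * z, -_EXP_CAP, _EXP_CAP))
        return beta, {"mu": beta, "log_sigma": beta * nat["sigma"] * z}
    if family == "loguniform":
        beta = sign * np.exp(np.clip(nat["a"] + nat["b"] * U[0], -_EXP_CAP, _EXP_CAP))
        return beta, {"a": beta, "log_b": beta * nat["b"] * U[0]}
    if family == "asym_triangular":
        a, b = nat["a"], nat["b"]
        span = b - a
        m = (a + b) / 2.0 + nat["c"]
        f = (m - a) / span
        s1, s2 = np.sqrt(U[1]), np.sqrt(U[2])
        low = U[0] < f
        beta = np.where(low, a + (m - a) * s1, b - (b - m) * s2)
        d_g = np.where(low, f * span * s1, span * (1.0 - (1.0 - f) * s2))
        grads = {"a": 1.0, "log_range": d_g}
        if not fix_offset:
            dm = span * f * (1.0 - f)
            grads["mode_logit"] = np.where(low, s1 * dm, s2 * dm)
        return beta, grads
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        u = U[0]
        beta = np.full_like(u, float(nat["mu"]))
        grads = {"mu": 1.0}
        up = np.ones_like(u)
        for p in range(1, P + 1):
            up = up * u
            beta = beta + nat[f"sigma{p}"] * up
            grads[f"sigma{p}"] = up.copy()
        return beta, grads
    raise ConfigurationError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# moments, supports, densities


def analytic_mean(family: str, params: dict, sign: int = -1) -> float:
    """Closed-form mean of the mixing distribution (used for WTP means)."""
    p = params
    if family == "fixed":
        return float(p["value"])
    if family == "normal":
        return float(p["mu"])
    if family == "uniform":
        return float(p["a"] + p["b"] / 2.0)
    if family == "triangular":
        return float(p["a"] + p["b"])
    if family == "lognormal":
        return float(sign * np.exp(p["mu"] + p["sigma"] ** 2 / 2.0))
    if family == "loguniform":
        a, b = float(p["a"]), float(p["b"])
        if b < 1e-12:
            return float(sign * np.exp(a))
        return float(sign * np.exp(a) * (np.exp(b) - 1.0) / b)
    if family == "asym_triangular":
        a, b = float(p["a"]), float(p["b"])
        m = (a + b) / 2.0 + float(p.get("c", 0.0))
        return (a + b + m) / 3.0
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        return float(p["mu"] + sum(p[f"sigma{i}"] / (i + 1.0) for i in range(1, P + 1)))
    raise ConfigurationError(f"no analytic mean for family {family!r}")


def mean_gradient(family: str, params: dict, sign: int = -1) -> np.ndarray:
    """d(mean)/d(natural params), ordered as natural_param_names (c included)."""
    p = params
    if family == "fixed":
        return np.array([1.0])
    if family == "normal":
        return np.array([1.0, 0.0])
    if family == "uniform":
        return np.array([1.0, 0.5])
    if family == "triangular":
        return np.array([1.0, 1.0])
    if family == "lognormal":
        mean = analytic_mean(family, p, sign)
        return np.array([mean, mean * p["sigma"]])
    if family == "loguniform":
        a, b = float(p["a"]), float(p["b"])
        mean = analytic_mean(family, p, sign)
        if b < 1e-8:
            return np.array([mean, mean / 2.0])
        d_b = sign * np.exp(a) * (np.exp(b) * (b - 1.0) + 1.0) / b**2
        return np.array([mean, d_b])
    if family == "asym_triangular":
        # mean = (a + b + m)/3 with m = (a+b)/2 + c
        return np.array([0.5, 0.5, 1.0 / 3.0])
    if family in ("fm2", "fm3"):
        P = _fm_order(family)
        return np.array([1.0] + [1.0 / (i + 1.0) for i in range(1, P + 1)])
    raise ConfigurationError(f"no mean gradient for family {family!r}")


def support(family: str, params: dict, sign: int = -1) -> tuple[float, float]:
    p = params
    if family == "fixed":
        return (p["value"], p["value"])
    if family == "normal" or family in ("fm2", "fm3"):
        return (-np.inf, np.inf)
    if family == "uniform":
        return (p["a"], p["a"] + p["b"])
    if family == "triangular":
        return (p["a"], p["a"] + 2.0 * p["b"])
    if family == "lognormal":
        return (0.0, np.inf) if sign > 0 else (-np.inf, 0.0)
    if family == "loguniform":
        lo, hi = np.exp(p["a"]), np.exp(p["a"] + p["b"])
        return (lo, hi) if sign > 0 else (-hi, -lo)
    if family == "asym_triangular":
        return (p["a"], p["b"])
    raise ConfigurationError(f"unknown family {family!r}")


def density(family: str, params: dict, sign: int, grid: np.ndarray) -> np.ndarray:
    """Closed-form density of the mixing distribution on a grid."""
    x = np.asarray(grid, dtype=float)
    p = params
    if family == "normal":
        return norm.pdf(x, loc=p["mu"], scale=max(p["sigma"], SCALE_FLOOR))
    if family == "uniform":
        a, b = p["a"], p["b"]
        return np.where((x >= a) & (x <= a + b), 1.0 / b, 0.0)
    if family == "triangular":
        a, b = p["a"], p["b"]
        out = np.zeros_like(x)
        up = (x >= a) & (x <= a + b)
        dn = (x > a + b) & (x <= a + 2 * b)
        out[up] = (x[up] - a) / b**2
        out[dn] = (a + 2 * b - x[dn]) / b**2
        return out
    if family == "lognormal":
        y = sign * x
        out = np.zeros_like(x)
        pos = y > 0
        out[pos] = norm.pdf(np.log(y[pos]), loc=p["mu"], scale=p["sigma"]) / y[pos]
        return out
    if family == "loguniform":
        y = sign * x
        lo, hi = np.exp(p["a"]), np.exp(p["a"] + p["b"])
        out = np.zeros_like(x)
        inside = (y >= lo) & (y <= hi)
        out[inside] = 1.0 / (p["b"] * y[inside])
        return out
    if family == "asym_triangular":
        a, b = p["a"], p["b"]
        m = (a + b) / 2.0 + p.get("c", 0.0)
        out = np.zeros_like(x)
        lo = (x >= a) & (x <= m)
        hi = (x > m) & (x <= b)
        out[lo] = 2.0 * (x[lo] - a) / ((b - a) * (m - a))
        out[hi] = 2.0 * (b - x[hi]) / ((b - a) * (b - m))
        return out
    raise ConfigurationError(f"no closed-form density for family {family!r}")


def sample(family: str, params: dict, sign: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Independent pseudo-random draws from a mixing distribution."""
    if family == "fixed":
        return np.full(size, float(params["value"]))
    d = PRIM_DIMS[family]
    U = rng.random((d, size)).clip(1e-12, 1 - 1e-12)
    return draw_coefficients(family, params, sign, U)
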