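"""Synthetic choice data with known (recorded) preference heterogeneity.

Three generators mirror the structures the estimators assume:

* a drug-choice discrete choice experiment — 1,000 persons × 10 tasks by
  default, four alternatives per task (two branded, two unbranded) described
  by country of production, drug characteristic (standard / fast acting /
  double strength), side-effect risk and price, with person-level tastes
  drawn from a different distribution per attribute (including a bimodal
  branded taste);
* a generic DCE over an arbitrary attribute layout and any mixing family;
* the revealed-preference structure: two binary outcomes per person sharing
  a normal individual error component.

Choices are generated by comparing a single U[0,1] draw per task to the
cumulative MNL probabilities implied by the person's tastes, so generated
choice frequencies converge to the analytic mixed-logit shares.  All
randomness flows from one master seed through named substreams (tastes,
attribute levels, choices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import mixing
from .data import BinaryPanelDataset, ChoiceDataset, ConfigurationError


@dataclass(frozen=True)
class TrueTasteConfig:
    """Generating taste distribution per coefficient.

    Each entry maps a coefficient name to a dict with a ``dist`` tag — any
    mixing family, or ``"mixture"`` for a finite normal mixture with
    ``components`` [(weight, mean, sd), ...] — plus that family's parameters.
    """

    tastes: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self):
        for name, t in self.tastes.items():
            if t.get("dist") == "mixture":
                w = np.array([c[0] for c in t["components"]], dtype=float)
                if abs(w.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(f"mixture weights for {name!r} must sum to 1")
            for v in t.values():
                if isinstance(v, (int, float)) and not np.isfinite(v):
                    raise ConfigurationError(f"non-finite parameter in taste {name!r}")

    def names(self):
        return list(self.tastes)


def default_drug_config() -> TrueTasteConfig:
    """Frozen generating tastes for the simulated drug-choice study.

    A deliberately heterogeneous set: the branded taste is bimodal (half the
    population dislikes brands, half pays a premium), country-of-production
    and drug-characteristic tastes follow normal / uniform / triangular laws,
    the side-effect-risk taste is strictly negative (lognormal), and the
    price taste is a fixed −0.8 per unit.
    """
    return TrueTasteConfig(
        {
            "branded": {
                "dist": "mixture",
                "components": [(0.5, -2.0, 0.5), (0.5, 2.0, 0.5)],
            },
            "country_CH": {"dist": "normal", "mu": 0.5, "sigma": 0.5},
            "char_fast": {"dist": "uniform", "a": 0.0, "b": 1.0},
            "char_double": {"dist": "triangular", "a": 0.2, "b": 0.5},
            "risk": {"dist": "lognormal", "mu": 0.0, "sigma": 0.5, "sign": -1},
            "price": {"dist": "fixed", "value": -0.8},
        }
    )


# attribute level grids of the drug design (documented, frozen)
DRUG_ALTERNATIVES = ("branded_1", "branded_2", "generic_1", "generic_2")
DRUG_LEVELS = {
    "country_CH": (0.0, 1.0),
    "characteristic": ("standard", "fast", "double"),
    "risk": (0.1, 0.2, 0.5, 1.0),  # side-effect risk, 10-percentage-point units
    "price": (2.0, 3.0, 4.0, 5.0, 6.0),
}


def _substream(seed: int, label: str) -> np.random.Generator:
    tag = int.from_bytes(label.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


def sample_tastes(config: TrueTasteConfig, n: int, rng: np.random.Generator) -> dict:
    """One taste vector of length n per configured coefficient."""
    out = {}
    for name, t in config.tastes.items():
        t = dict(t)
        dist = t.pop("dist")
        if dist == "mixture":
            comps = t["components"]
            w = np.array([c[0] for c in comps])
            ks = rng.choice(len(comps), size=n, p=w)
            mus = np.array([c[1] for c in comps])[ks]
            sds = np.array([c[2] for c in comps])[ks]
            out[name] = rng.normal(mus, sds)
        else:
            sign = int(t.pop("sign", -1))
            out[name] = mixing.sample(dist, t, sign, n, rng)
    return out


def true_density(config: TrueTasteConfig, coefficient: str, grid) -> np.ndarray:
    """Exact generating density on a grid (closed-form families and mixtures)."""
    t = dict(config.tastes[coefficient])
    dist = t.pop("dist")
    x = np.asarray(grid, dtype=float)
    if dist == "mixture":
        out = np.zeros_like(x)
        for w, mu, sd in t["components"]:
            out += w * norm.pdf(x, mu, sd)
        return out
    if dist == "fixed":
        raise ConfigurationError("point-mass taste has no density")
    sign = int(t.pop("sign", -1))
    return mixing.density(dist, t, sign, x)


def true_mean(config: TrueTasteConfig, coefficient: str) -> float:
    t = dict(config.tastes[coefficient])
    dist = t.pop("dist")
    if dist == "mixture":
        return float(sum(w * mu for w, mu, _ in t["components"]))
    sign = int(t.pop("sign", -1))
    return mixing.analytic_mean(dist, t, sign)


def _choices_from_utilities(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick alternatives by comparing U[0,1] draws to cumulative MNL probabilities."""
    V = V - V.max(axis=-1, keepdims=True)
    P = np.exp(V)
    P /= P.sum(axis=-1, keepdims=True)
    u = rng.random(P.shape[:-1] + (1,))
    return (P.cumsum(axis=-1) < u).sum(axis=-1)


def simulate_drug_dce(
    n_persons: int = 1000,
    n_tasks: int = 10,
    config: Optional[TrueTasteConfig] = None,
    seed: int = 0,
    store_tastes: bool = False,
):
    """The simulated drug-choice DCE: (ChoiceDataset, truth record).

    Per person, tastes are drawn once from ``config``; per task, attribute
    levels are assigned independently from the level grids; per task, the
    choice compares one U[0,1] draw to the cumulative MNL probabilities.
    """
    config = config or default_drug_config()
    needed = {"branded", "country_CH", "char_fast", "char_double", "risk", "price"}
    missing = needed - set(config.names())
    if missing:
        raise ConfigurationError(f"drug config missing coefficients: {sorted(missing)}")

    rng_t = _substream(seed, "tastes")
    rng_l = _substream(seed, "levels")
    rng_c = _substream(seed, "choices")
    tastes = sample_tastes(config, n_persons, rng_t)

    J = len(DRUG_ALTERNATIVES)
    shape = (n_persons, n_tasks, J)
    branded = np.zeros(shape)
    branded[:, :, 0:2] = 1.0
    country = np.array(DRUG_LEVELS["country_CH"])[rng_l.integers(0, 2, size=shape)]
    char = rng_l.integers(0, 3, size=shape)  # 0 standard, 1 fast, 2 double
    char_fast = (char == 1).astype(float)
    char_double = (char == 2).astype(float)
    risk = np.array(DRUG_LEVELS["risk"])[rng_l.integers(0, 4, size=shape)]
    price = np.array(DRUG_LEVELS["price"])[rng_l.integers(0, 5, size=shape)]

    attrs = {
        "branded": branded,
        "country_CH": country,
        "char_fast": char_fast,
        "char_double": char_double,
        "risk": risk,
        "price": price,
    }
    V = np.zeros(shape)
    for name, x in attrs.items():
        V += tastes[name][:, None, None] * x
    choice = _choices_from_utilities(V, rng_c)

    pid = np.repeat(np.arange(n_persons), n_tasks * J)
    tid = np.tile(np.repeat(np.arange(n_tasks), J), n_persons)
    aid = np.tile(np.array(DRUG_ALTERNATIVES), n_persons * n_tasks)
    chosen = (np.tile(np.arange(J), n_persons * n_tasks)
              == np.repeat(choice.reshape(-1), J))
    table = pd.DataFrame(
        {
            "person_id": pid,
            "task_id": tid,
            "alt_id": aid,
            "available": True,
            "chosen": chosen,
            **{k: v.reshape(-1) for k, v in attrs.items()},
        }
    )
    dataset = ChoiceDataset(
        table,
        tuple(attrs),
        {
            "branded": ("branded_1", "branded_2"),
            "unbranded": ("generic_1", "generic_2"),
        },
    )
    truth = {
        "generator": "drug_dce",
        "seed": seed,
        "n_persons": n_persons,
        "n_tasks": n_tasks,
        "config": {k: dict(v) for k, v in config.tastes.items()},
        "levels": {k: list(v) for k, v in DRUG_LEVELS.items()},
    }
    if store_tastes:
        truth["tastes"] = {k: v.tolist() for k, v in tastes.items()}
    return dataset, truth


def simulate_generic_dce(
    alternatives: Sequence[str],
    attribute_levels: Mapping[str, Sequence[float]],
    config: TrueTasteConfig,
    n_persons: int,
    n_tasks: int,
    seed: int = 0,
    opt_out: bool = False,
    store_tastes: bool = False,
):
    """Generic DCE: uniform level assignment per alternative, arbitrary tastes.

    With ``opt_out`` an extra alternative with all-zero attributes is
    appended (the reference alternative).
    """
    missing = set(attribute_levels) - set(config.names())
    if missing:
        raise ConfigurationError(f"config missing coefficients: {sorted(missing)}")
    alts = list(alternatives) + (["optout"] if opt_out else [])
    J = len(alts)
    Jx = len(alternatives)
    attrs = list(attribute_levels)

    rng_t = _substream(seed, "tastes")
    rng_l = _substream(seed, "levels")
    rng_c = _substream(seed, "choices")
    tastes = sample_tastes(config, n_persons, rng_t)

    shape = (n_persons, n_tasks, J)
    X = {}
    for a in attrs:
        lv = np.asarray(attribute_levels[a], dtype=float)
        x = np.zeros(shape)
        x[:, :, :Jx] = lv[rng_l.integers(0, len(lv), size=(n_persons, n_tasks, Jx))]
        X[a] = x
    V = np.zeros(shape)
    for a in attrs:
        V += tastes[a][:, None, None] * X[a]
    choice = _choices_from_utilities(V, rng_c)

    pid = np.repeat(np.arange(n_persons), n_tasks * J)
    tid = np.tile(np.repeat(np.arange(n_tasks), J), n_persons)
    aid = np.tile(np.array(alts), n_persons * n_tasks)
    chosen = (np.tile(np.arange(J), n_persons * n_tasks)
              == np.repeat(choice.reshape(-1), J))
    table = pd.DataFrame(
        {
            "person_id": pid,
            "task_id": tid,
            "alt_id": aid,
            "available": True,
            "chosen": chosen,
            **{a: X[a].reshape(-1) for a in attrs},
        }
    )
    groups = {"product": tuple(alternatives)}
    if opt_out:
        groups["optout"] = ("optout",)
    dataset = ChoiceDataset(table, tuple(attrs), groups)
    truth = {
        "generator": "generic_dce",
        "seed": seed,
        "n_persons": n_persons,
        "n_tasks": n_tasks,
        "config": {k: dict(v) for k, v in config.tastes.items()},
        "levels": {k: list(map(float, v)) for k, v in attribute_levels.items()},
    }
    if store_tastes:
        truth["tastes"] = {k: v.tolist() for k, v in tastes.items()}
    return dataset, truth


# ---------------------------------------------------------------------------
# revealed-preference structure


def rp_intercepts_for_shares(p_cig: float, p_ecig: float, sigma_rho: float = 0.0,
                             sign: int = 1) -> tuple[float, float]:
    """Intercepts hitting target marginal use shares given the error component.

    For σ_ρ > 0 the marginal P = E_ρ logistic(ASC + ρ) is inverted by
    Gauss–Hermite quadrature and bisection.
    """
    from scipy.optimize import brentq

    def marginal(a, s):
        if sigma_rho == 0.0:
            return expit(a)
        nodes, w = np.polynomial.hermite_e.hermegauss(63)
        return float(np.sum(w * expit(a + s * sigma_rho * nodes)) / w.sum())

    a_c = brentq(lambda a: marginal(a, 1) - p_cig, -30, 30)
    a_e = brentq(lambda a: marginal(a, sign) - p_ecig, -30, 30)
    return a_c, a_e


def simulate_rp_binary(
    n: int,
    intercepts: tuple[float, float],
    gammas: Optional[Mapping[str, tuple[float, float]]] = None,
    sigma_rho: float = 0.0,
    sign: int = 1,
    seed: int = 0,
) -> BinaryPanelDataset:
    """Two correlated binary outcomes per person.

    ``gammas`` maps covariate name to its (cigarette, e-cigarette) effect;
    covariates are standard-normal draws.  Each person draws ρ ~ N(0, σ_ρ²);
    outcomes are Bernoulli with logistic(V_cig + ρ) and logistic(V_ecig + s·ρ).
    """
    if sigma_rho < 0:
        raise ConfigurationError("sigma_rho must be >= 0")
    rng = _substream(seed, "rp")
    a_c, a_e = intercepts
    Vc = np.full(n, float(a_c))
    Ve = np.full(n, float(a_e))
    cols = {}
    for name, (g_c, g_e) in (gammas or {}).items():
        z = rng.standard_normal(n)
        cols[name] = z
        Vc = Vc + g_c * z
        Ve = Ve + g_e * z
    rho = sigma_rho * rng.standard_normal(n)
    c = (rng.random(n) < expit(Vc + rho)).astype(int)
    e = (rng.random(n) < expit(Ve + sign * rho)).astype(int)
    table = pd.DataFrame({"person_id": np.arange(n), "cig": c, "ecig": e, **cols})
    return BinaryPanelDataset(table, tuple(cols))


def rp_composition_dataset(
    n_cig_only: int = 1038, n_ecig_only: int = 148, n_dual: int = 619, n_neither: int = 226
) -> BinaryPanelDataset:
    """Deterministic dataset with an exact product-use composition.

    Defaults reproduce the motivating sample: 1,038 cigarette-only users,
    148 e-cigarette-only users, 619 dual users and 226 recent quitters
    (N = 2,031), i.e. cigarette-use share 0.8158 and e-cigarette 0.3776.
    """
    c = [1] * n_cig_only + [0] * n_ecig_only + [1] * n_dual + [0] * n_neither
    e = [0] * n_cig_only + [1] * n_ecig_only + [1] * n_dual + [0] * n_neither
    table = pd.DataFrame({"person_id": np.arange(len(c)), "cig": c, "ecig": e})
    return BinaryPanelDataset(table, ())
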