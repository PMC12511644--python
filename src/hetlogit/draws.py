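"""Quasi-random primitive draws for simulating the mixing integral.

Modified Latin hypercube sampling (MLHS): for each (person, dimension) the R
draws are an equidistant grid i/R shifted by a single U(0,1)/R offset and then
randomly permuted, so after sorting the R values occupy the R strata
[i/R, (i+1)/R) exactly once.  Substreams are derived deterministically from a
master seed per (person, dimension), so person i's draws do not depend on how
many other persons are in the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class DrawSet:
    """Primitive draws indexed (person, dimension, r)."""

    values: np.ndarray  # (n_persons, n_dims, R)
    families: tuple[str, ...]  # "std_uniform" or "std_normal" per dimension
    R: int
    seed: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be (persons, dims, R)")
        if self.values.shape[1] != len(self.families):
            raise ValueError("one family tag per dimension required")
        if self.R < 1:
            raise ValueError("R must be >= 1")


def mlhs(n_persons: int, n_dims: int, R: int, seed: int) -> DrawSet:
    """Modified Latin hypercube draws on (0,1).

    One uniform shift and one random permutation per (person, dimension).
    """
    if n_persons < 1 or n_dims < 1:
        raise ValueError("n_persons and n_dims must be >= 1")
    if R < 1:
        raise ValueError("R must be >= 1")
    grid = np.arange(R, dtype=float)
    out = np.empty((n_persons, n_dims, R))
    for i in range(n_persons):
        for d in range(n_dims):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, d))
            )
            shift = rng.random()
            vals = (grid + shift) / R
            rng.shuffle(vals)
            out[i, d] = vals
    np.clip(out, _EPS, 1.0 - _EPS, out=out)
    return DrawSet(out, ("std_uniform",) * n_dims, R, seed)


def uniform_draws(n_persons: int, n_dims: int, R: int, seed: int) -> DrawSet:
    """Plain pseudo-random U(0,1) draws with the same substream layout as MLHS."""
    out = np.empty((n_persons, n_dims, R))
    for i in range(n_persons):
        for d in range(n_dims):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i, d))
            )
            out[i, d] = rng.random(R)
    np.clip(out, _EPS, 1.0 - _EPS, out=out)
    return DrawSet(out, ("std_uniform",) * n_dims, R, seed)


def to_normal(draws: DrawSet) -> DrawSet:
    """Map uniform primitives through the inverse standard-normal CDF."""
    if any(f != "std_uniform" for f in draws.families):
        raise ValueError("to_normal expects uniform primitives")
    u = draws.values
    n_clipped = int(np.sum((u <= 0) | (u >= 1)))
    if n_clipped:
        log.warning("clipped %d uniform values away from {0,1}", n_clipped)
        u = np.clip(u, _EPS, 1.0 - _EPS)
    z = ndtri(u)
    return DrawSet(z, ("std_normal",) * u.shape[1], draws.R, draws.seed)
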