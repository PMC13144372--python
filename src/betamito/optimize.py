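"""Minimal global-best particle swarm optimizer for parameter fitting.

Provides the generic fitting hook used to tune model parameters against a
user-supplied loss (e.g. a target knockdown/wild-type secretion ratio).
Deterministic given the seed; particles whose loss is non-finite are
resampled uniformly inside the bounds and the incident logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    trace: list = field(default_factory=list)  # best loss after each iteration
    n_evaluations: int = 0
    resampled: int = 0


def particle_swarm(loss: Callable[[np.ndarray], float],
                   bounds: Sequence[Sequence[float]],
                   budget: int,
                   seed: int = 0,
                   n_particles: int = 12,
                   inertia: float = 0.72,
                   c_personal: float = 1.49,
                   c_global: float = 1.49) -> PSOResult:
    """Minimize ``loss`` over a box with ``budget`` total evaluations.

    ``budget`` must be at least ``n_particles`` (one full population); with
    ``budget == n_particles`` the result is the best of the initial
    population.  Velocities reflect at the bounds.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    if budget < n_particles:
        raise ValueError(
            f"budget={budget} is below the population size {n_particles}")
    rng = np.random.default_rng(seed)
    span = hi - lo
    X = lo + rng.random((n_particles, d)) * span
    V = (rng.random((n_particles, d)) - 0.5) * span * 0.1
    res = PSOResult(best_x=X[0].copy(), best_f=np.inf)

    def safe_loss(x, i):
        for _ in range(20):
            f = float(loss(x))
            if np.isfinite(f):
                return x, f
            res.resampled += 1
            log.warning("non-finite loss at particle %d; resampling", i)
            x = lo + rng.random(d) * span
        raise RuntimeError("loss repeatedly non-finite")

    F = np.empty(n_particles)
    for i in range(n_particles):
        X[i], F[i] = safe_loss(X[i], i)
    res.n_evaluations = n_particles
    P, Pf = X.copy(), F.copy()
    g = int(np.argmin(F))
    res.best_x, res.best_f = X[g].copy(), float(F[g])
    res.trace.append(res.best_f)

    while res.n_evaluations + n_particles <= budget:
        r1 = rng.random((n_particles, d))
        r2 = rng.random((n_particles, d))
        V = (inertia * V + c_personal * r1 * (P - X)
             + c_global * r2 * (res.best_x - X))
        X = X + V
        # reflect at the box boundary
        for k in range(2):
            over = X > hi
            X[over] = (2 * hi - X)[over] if k == 0 else np.minimum(X, hi)[over]
            under = X < lo
            X[under] = (2 * lo - X)[under] if k == 0 else np.maximum(X, lo)[under]
        np.clip(X, lo, hi, out=X)
        for i in range(n_particles):
            X[i], f = safe_loss(X[i], i)
            res.n_evaluations += 1
            if f < Pf[i]:
                P[i], Pf[i] = X[i].copy(), f
            if f < res.best_f:
                res.best_x, res.best_f = X[i].copy(), float(f)
        res.trace.append(res.best_f)
    return res
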