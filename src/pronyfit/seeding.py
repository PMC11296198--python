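"""Multi-start log-barrier (interior-point) seeding of the genetic algorithm.

The constrained data-misfit problem

    min_x f(x)   s.t.  g(x) <= 0          (the Prony simplex + ordering set)

is solved through the barrier sequence

    min_x f(x) - mu * sum_i ln(s_i),   s_i = -g_i(x) > 0,

driving the barrier weight mu to a floor through a geometric schedule.  The
inner minimizations use a derivative-free simplex search; the contract the
rest of the pipeline relies on is descent (returned objective <= start
objective) and strict interiority, not the brand of inner solver.  Each
restart begins from an independent random viable point; the deduplicated,
objective-sorted solution set seeds generation zero of the GA.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .prony import (TRAIN, DMADataset, PronySeries, equation_objective,
                    viability_check)

__all__ = ["SeedConfig", "BarrierProblem", "random_start", "solve_barrier",
           "seed_population"]

TAU_LOG_RANGE = (1e-4, 1e2)  # seconds; spans the sub-ms to ~minute window


@dataclass(frozen=True)
class SeedConfig:
    """Barrier schedule and restart policy.

    ``rng_seed`` None falls back to a clock-derived seed (reproducible runs
    should always pass one explicitly).
    """

    n_restarts: int = 100
    rng_seed: int | None = None
    mu0: float = 1.0
    mu_reduction: float = 0.2
    mu_floor: float = 1e-8
    inner_tolerance: float = 1e-10
    inner_maxiter: int = 300

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if not (0 < self.mu_reduction < 1) or self.mu0 <= 0 or self.mu_floor <= 0:
            raise ValueError("barrier schedule must be positive and decreasing")


class BarrierProblem:
    """Barrier-augmented data misfit in the free vector x = [g, log tau].

    Slacks (one per inequality): g_k, 1 - g_k, 1 - sum g, and the ordering
    gaps tau_{k+1} - tau_k; tau > 0 holds by the log parametrization.
    """

    def __init__(self, data: DMADataset, order: int, subset: str = TRAIN):
        self.data = data
        self.order = order
        self.subset = subset

    def unpack(self, x: np.ndarray) -> PronySeries:
        n = self.order
        g = np.asarray(x[:n], dtype=float)
        # clamp against under/overflow of the log parametrization
        tau = np.clip(np.exp(np.asarray(x[n:], dtype=float)), 1e-12, 1e12)
        return PronySeries(g=g, tau=tau, g_inf=1.0 - g.sum())

    def pack(self, p: PronySeries) -> np.ndarray:
        return np.concatenate([p.g, np.log(p.tau)])

    def slacks(self, x: np.ndarray) -> np.ndarray:
        n = self.order
        g = x[:n]
        tau = np.exp(x[n:])
        return np.concatenate([g, 1.0 - g, [1.0 - g.sum()], np.diff(tau)])

    def objective(self, x: np.ndarray) -> float:
        return equation_objective(self.unpack(x), self.data, self.subset)

    def value(self, x: np.ndarray, mu: float) -> float:
        s = self.slacks(x)
        if np.any(s <= 0.0):
            return np.inf
        return self.objective(x) - mu * float(np.sum(np.log(s)))


def random_start(order: int, rng: np.random.Generator) -> PronySeries:
    """Viable random series: g = flat simplex draw * U(0,1), tau log-uniform sorted."""
    if order < 1:
        raise ValueError("order must be >= 1")
    w = rng.dirichlet(np.ones(order))
    total = rng.uniform(0.0, 1.0)
    g = np.clip(w * total, 1e-12, None)
    lo, hi = np.log(TAU_LOG_RANGE[0]), np.log(TAU_LOG_RANGE[1])
    tau = np.sort(np.exp(rng.uniform(lo, hi, size=order)))
    return PronySeries(g=g, tau=tau, g_inf=1.0 - g.sum())


def solve_barrier(start: PronySeries, data: DMADataset,
                  cfg: SeedConfig = SeedConfig(), subset: str = TRAIN) -> PronySeries:
    """Barrier minimization from one viable start; never worse than the start."""
    prob = BarrierProblem(data, start.order, subset)
    x = prob.pack(start)
    f0 = prob.objective(x)
    if not np.isfinite(f0):
        raise ValueError("objective non-finite at start; check normalization scale")
    best_x, best_f = x.copy(), f0

    mu = cfg.mu0
    while True:
        with np.errstate(invalid="ignore"):  # simplex may probe the barrier's inf
            res = minimize(prob.value, x, args=(mu,), method="Nelder-Mead",
                           options={"fatol": cfg.inner_tolerance,
                                    "xatol": 1e-10,
                                    "maxiter": cfg.inner_maxiter,
                                    "maxfev": 2 * cfg.inner_maxiter})
        if np.all(prob.slacks(res.x) > 0.0):
            x = res.x
            f = prob.objective(x)
            if f < best_f:
                best_f, best_x = f, x.copy()
        if mu <= cfg.mu_floor:
            break
        mu = max(mu * cfg.mu_reduction, cfg.mu_floor)

    out = prob.unpack(best_x)
    # keep the iterate strictly interior and ordered on output
    g = np.clip(out.g, 1e-12, 1.0 - 1e-12)
    tau = np.sort(np.clip(out.tau, 1e-12, 1e12))
    return PronySeries(g=g, tau=tau, g_inf=1.0 - g.sum())


def seed_population(data: DMADataset, order: int,
                    cfg: SeedConfig = SeedConfig()) -> list[PronySeries]:
    """Independent barrier solutions, deduplicated and sorted by objective."""
    seed = cfg.rng_seed if cfg.rng_seed is not None else int(_time.time_ns() % 2**31)
    rng = np.random.default_rng(seed)
    solutions: list[tuple[float, PronySeries]] = []
    for _ in range(cfg.n_restarts):
        start = random_start(order, rng)
        sol = solve_barrier(start, data, cfg)
        solutions.append((equation_objective(sol, data, TRAIN), sol))
    solutions.sort(key=lambda t: t[0])

    kept: list[PronySeries] = []
    vecs: list[np.ndarray] = []
    for _, sol in solutions:
        v = np.concatenate([[sol.g_inf], sol.g, sol.tau])
        if all(np.max(np.abs(v - u)) > 1e-9 for u in vecs):
            kept.append(sol)
            vecs.append(v)
    assert all(viability_check(p) for p in kept)
    return kept
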