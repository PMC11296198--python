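"""Genetic evolution of Prony parameter sets under viability constraints.

A chromosome is the ordered vector [g_inf, g_1..g_N, tau_1..tau_N] of length
2N + 1.  Each generation is built from elitism plus three equal operator
shares: crossover offspring (50:50 single-point / K-point), Gaussian mutants
of top-ranked members, and fresh random individuals.  Every child passes
through a repair step (simplex renormalization, tau sorted ascending) so the
population stays closed over the constraint set; repaired children are
re-checked and redrawn on the (theoretical) failure path, falling back to a
parent copy after bounded retries.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fitness import (FitnessReport, SimulationSettings, ValidationCurves,
                      evaluate_population)
from .prony import DMADataset, PronySeries, viability_check
from .seeding import SeedConfig, random_start, seed_population

__all__ = ["GAConfig", "GenerationRecord", "encode", "decode", "repair",
           "single_point_crossover", "k_point_crossover", "gaussian_mutation",
           "next_generation", "run", "load_records"]

G_EPS = 1e-6       # floor projected onto near-zero strengths during repair
MAX_RETRIES = 50   # bounded redraws for invalid children before parent fallback
TAU_BOUNDS = (1e-8, 1e6)


# -- chromosome codec ------------------------------------------------------

def encode(p: PronySeries) -> np.ndarray:
    return np.concatenate([[p.g_inf], p.g, p.tau])


def decode(values: np.ndarray) -> PronySeries:
    n = (values.size - 1) // 2
    return PronySeries(g=values[1:n + 1], tau=values[n + 1:], g_inf=float(values[0]))


def repair(values: np.ndarray) -> np.ndarray:
    """Project a chromosome back onto the constraint set.

    Strengths are clipped into (0, 1), rescaled so their sum stays below 1,
    g_inf reset to 1 - sum(g); relaxation times are clipped positive and
    sorted ascending.
    """
    v = np.asarray(values, dtype=float).copy()
    n = (v.size - 1) // 2
    g = np.clip(v[1:n + 1], G_EPS, 1.0 - G_EPS)
    total = g.sum()
    if total > 1.0 - G_EPS:
        g *= (1.0 - G_EPS) / total
    tau = np.sort(np.clip(v[n + 1:], *TAU_BOUNDS))
    v[0] = 1.0 - g.sum()
    v[1:n + 1] = g
    v[n + 1:] = tau
    return v


def _is_viable(values: np.ndarray) -> bool:
    return viability_check(decode(values))


# -- genetic operators -----------------------------------------------------

def _splice(p1: np.ndarray, p2: np.ndarray, cuts) -> tuple[np.ndarray, np.ndarray]:
    """Alternate parent segments at the given sorted cut indices."""
    c1, c2 = p1.copy(), p2.copy()
    take_second = False
    prev = 0
    for cut in list(cuts) + [p1.size]:
        if take_second:
            c1[prev:cut] = p2[prev:cut]
            c2[prev:cut] = p1[prev:cut]
        take_second = not take_second
        prev = cut
    return c1, c2


def single_point_crossover(p1: np.ndarray, p2: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Cut index uniform on {1..2N+1}; prefix of one parent + suffix of the other.

    A cut at 2N+1 returns parent copies (the printed upper bound is the full
    chromosome length).
    """
    if p1.size != p2.size:
        raise ValueError("parents must have equal length")
    for _ in range(MAX_RETRIES):
        cut = int(rng.integers(1, p1.size + 1))
        c1, c2 = _splice(p1, p2, [cut])
        c1, c2 = repair(c1), repair(c2)
        if _is_viable(c1) and _is_viable(c2):
            return c1, c2
    return p1.copy(), p2.copy()


def k_point_crossover(p1: np.ndarray, p2: np.ndarray, k: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """k distinct sorted interior cuts; alternating parent segments."""
    if p1.size != p2.size:
        raise ValueError("parents must have equal length")
    if not (1 <= k < p1.size):
        raise ValueError("need 1 <= k < chromosome length")
    for _ in range(MAX_RETRIES):
        cuts = np.sort(rng.choice(np.arange(1, p1.size), size=k, replace=False))
        c1, c2 = _splice(p1, p2, cuts.tolist())
        c1, c2 = repair(c1), repair(c2)
        if _is_viable(c1) and _is_viable(c2):
            return c1, c2
    return p1.copy(), p2.copy()


def gaussian_mutation(p: np.ndarray, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian perturbation: additive for g/g_inf, multiplicative
    (lognormal, spread ~ sigma * tau) for the relaxation times."""
    n = (p.size - 1) // 2
    for _ in range(MAX_RETRIES):
        c = p.copy()
        c[:n + 1] += sigma * rng.standard_normal(n + 1)
        c[n + 1:] *= np.exp(sigma * rng.standard_normal(n))
        c = repair(c)
        if _is_viable(c):
            return c
    return p.copy()


# -- generation construction ----------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Run-level knobs.

    ``num_in_gen`` is the number of candidates forward-simulated per
    generation (the shell enforces the protocol floor of 100; the engine only
    requires it to fit in the population).  ``population_size`` must be a
    multiple of 3 so the operator thirds are exact.
    """

    order: int
    num_iteration: int = 20
    num_in_gen: int = 100
    population_size: int = 999
    k_points: int = 2
    mutation_sigma: float = 0.05
    elite_count: int = 3
    rng_seed: int | None = None
    seed_restarts: int = 100
    min_error: float = 0.0
    no_change_window: int = 0
    no_change_tol: float = 1e-12
    seed_config: SeedConfig | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.population_size % 3 != 0:
            raise ValueError("population_size must be divisible by 3")
        if not (1 <= self.num_in_gen <= self.population_size):
            raise ValueError("need 1 <= num_in_gen <= population_size")
        if not (0 <= self.elite_count < self.population_size):
            raise ValueError("elite_count must be < population_size")
        if not (1 <= self.k_points < 2 * self.order + 1):
            raise ValueError("k_points must be in [1, 2N]")


def _rank_weights(n: int) -> np.ndarray:
    w = np.arange(n, 0, -1, dtype=float)
    return w / w.sum()


def next_generation(pop: list[np.ndarray], reports: list[FitnessReport],
                    cfg: GAConfig, rng: np.random.Generator,
                    return_tags: bool = False):
    """Elite copies + exact thirds of crossover / mutation / random children."""
    order = sorted(range(len(pop)), key=lambda i: reports[i].rank_key)
    ranked = [pop[i] for i in order]
    new: list[np.ndarray] = [ranked[i].copy() for i in range(cfg.elite_count)]
    tags = ["elite"] * cfg.elite_count

    remainder = cfg.population_size - cfg.elite_count
    n_third = remainder // 3
    weights = _rank_weights(len(ranked))

    # crossover third: 50:50 single-point / K-point, rank-biased parents
    while sum(t == "crossover" for t in tags) < n_third:
        i, j = rng.choice(len(ranked), size=2, replace=False, p=weights)
        if rng.random() < 0.5:
            c1, c2 = single_point_crossover(ranked[i], ranked[j], rng)
        else:
            c1, c2 = k_point_crossover(ranked[i], ranked[j], cfg.k_points, rng)
        for c in (c1, c2):
            if sum(t == "crossover" for t in tags) < n_third:
                new.append(c)
                tags.append("crossover")

    # mutation third: Gaussian mutants of rank-biased members
    for _ in range(n_third):
        i = rng.choice(len(ranked), p=weights)
        new.append(gaussian_mutation(ranked[i], cfg.mutation_sigma, rng))
        tags.append("mutation")

    # random third (plus any slot left by integer division)
    while len(new) < cfg.population_size:
        new.append(encode(random_start(cfg.order, rng)))
        tags.append("random")

    return (new, tags) if return_tags else new


# -- provenance ------------------------------------------------------------

@dataclass
class GenerationRecord:
    """Backup/provenance unit: one fully evaluated generation."""

    generation_index: int
    population: list
    reports: list
    best_so_far: dict
    rng_state: dict
    timestamp: float

    def to_json(self) -> str:
        return json.dumps({
            "generation_index": self.generation_index,
            "population": [list(map(float, c)) for c in self.population],
            "reports": [r.to_dict() for r in self.reports],
            "best_so_far": self.best_so_far,
            "rng_state": self.rng_state,
            "timestamp": self.timestamp,
        })

    @classmethod
    def from_json(cls, line: str) -> "GenerationRecord":
        d = json.loads(line)
        reports = [FitnessReport(equation_error=r["equation_error"],
                                 ramp_error_pct=r["ramp_error_pct"],
                                 upper_error_pct=r["upper_error_pct"],
                                 lower_error_pct=r["lower_error_pct"])
                   for r in d["reports"]]
        return cls(generation_index=d["generation_index"],
                   population=[np.asarray(c, dtype=float) for c in d["population"]],
                   reports=reports,
                   best_so_far=d["best_so_far"],
                   rng_state=d["rng_state"],
                   timestamp=d["timestamp"])


def load_records(path) -> list[GenerationRecord]:
    lines = Path(path).read_text().strip().splitlines()
    return [GenerationRecord.from_json(ln) for ln in lines if ln.strip()]


def _best_entry(pop, reports) -> dict:
    i = min(range(len(pop)), key=lambda j: reports[j].rank_key)
    r = reports[i]
    return {"chromosome": list(map(float, pop[i])),
            "equation_error": r.equation_error,
            "mean_error_pct": r.mean_error_pct}


def _better(a: dict, b: dict) -> dict:
    def key(e):
        m = e["mean_error_pct"]
        return (0, m) if m is not None else (1, e["equation_error"])
    return a if key(a) <= key(b) else b


def run(data: DMADataset, curves: ValidationCurves, cfg: GAConfig,
        sim: SimulationSettings, backup_path=None) -> list[GenerationRecord]:
    """Seed, then evolve until an ending condition; one record per generation.

    Ending conditions: ``num_iteration`` generations completed, best
    cumulative mean error <= ``min_error``, or no change of the best mean
    error within ``no_change_tol`` over ``no_change_window`` generations.
    Each record is appended to the backup file before the loop proceeds.
    """
    seed = cfg.rng_seed if cfg.rng_seed is not None else int(_time.time_ns() % 2**31)
    rng = np.random.default_rng(seed)

    scfg = cfg.seed_config or SeedConfig(n_restarts=cfg.seed_restarts)
    scfg = SeedConfig(n_restarts=scfg.n_restarts,
                      rng_seed=int(rng.integers(2**31)),
                      mu0=scfg.mu0, mu_reduction=scfg.mu_reduction,
                      mu_floor=scfg.mu_floor,
                      inner_tolerance=scfg.inner_tolerance,
                      inner_maxiter=scfg.inner_maxiter)
    seeds = seed_population(data, cfg.order, scfg)
    pop = [encode(s) for s in seeds[:cfg.population_size]]
    while len(pop) < cfg.population_size:
        pop.append(encode(random_start(cfg.order, rng)))

    fh = open(backup_path, "a") if backup_path is not None else None
    records: list[GenerationRecord] = []
    best = None
    best_mean_history: list[float | None] = []
    try:
        for gen in range(cfg.num_iteration + 1):
            if gen > 0:
                pop = next_generation(pop, records[-1].reports, cfg, rng)
            reports = evaluate_population([decode(c) for c in pop], data,
                                          curves, sim, cfg.num_in_gen)
            entry = _best_entry(pop, reports)
            best = entry if best is None else _better(best, entry)
            rec = GenerationRecord(generation_index=gen,
                                   population=[c.copy() for c in pop],
                                   reports=reports,
                                   best_so_far=dict(best),
                                   rng_state=rng.bit_generator.state,
                                   timestamp=_time.time())
            records.append(rec)
            if fh is not None:
                fh.write(rec.to_json() + "\n")
                fh.flush()

            m = best["mean_error_pct"]
            best_mean_history.append(m)
            if m is not None and m <= cfg.min_error:
                break
            w = cfg.no_change_window
            if (w > 0 and len(best_mean_history) > w
                    and best_mean_history[-1] is not None
                    and best_mean_history[-1 - w] is not None
                    and abs(best_mean_history[-1] - best_mean_history[-1 - w])
                    <= cfg.no_change_tol):
                break
    finally:
        if fh is not None:
            fh.close()
    return records


def resume(data: DMADataset, curves: ValidationCurves, cfg: GAConfig,
           sim: SimulationSettings, backup_path) -> list[GenerationRecord]:
    """Continue an interrupted run from the backup's last RNG state.

    Returns the full record list (previous + newly evolved generations up to
    ``cfg.num_iteration``).
    """
    records = load_records(backup_path)
    if not records:
        return run(data, curves, cfg, sim, backup_path=backup_path)
    last = records[-1]
    rng = np.random.default_rng()
    rng.bit_generator.state = last.rng_state
    pop = [np.asarray(c, dtype=float) for c in last.population]
    best = dict(last.best_so_far)
    with open(backup_path, "a") as fh:
        for gen in range(last.generation_index + 1, cfg.num_iteration + 1):
            pop = next_generation(pop, records[-1].reports, cfg, rng)
            reports = evaluate_population([decode(c) for c in pop], data,
                                          curves, sim, cfg.num_in_gen)
            best = _better(best, _best_entry(pop, reports))
            rec = GenerationRecord(generation_index=gen,
                                   population=[c.copy() for c in pop],
                                   reports=reports,
                                   best_so_far=dict(best),
                                   rng_state=rng.bit_generator.state,
                                   timestamp=_time.time())
            records.append(rec)
            fh.write(rec.to_json() + "\n")
            fh.flush()
            m = best["mean_error_pct"]
            if m is not None and m <= cfg.min_error:
                break
    return records
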