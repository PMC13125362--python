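"""Hybrid Bayesian-genetic hyperparameter optimization (PD-BayGA).

The optimizer minimizes J(lambda) = -M(lambda) + beta * C(lambda) / C_max,
where M = alpha * Sens + (1 - alpha) * Spec is the sensitivity-weighted
validation score (alpha = 0.7 by default, reflecting the clinical cost of a
missed PD case) and C is the training cost per epoch. A genetic algorithm
(tournament selection, uniform crossover, per-gene mutation, elitism)
explores the mixed discrete-continuous space while a Gaussian-process
surrogate injects one expected-improvement proposal per generation.

Continuous genes are handled in transformed space (log10 for rates);
categorical genes are resampled from their choice lists. C_max is tracked as
the running maximum of observed costs and all stored J values are
re-normalized against the final C_max so records are mutually comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = [
    "Dimension",
    "SearchSpace",
    "EvalRecord",
    "default_space",
    "score_M",
    "objective_J",
    "sample_candidate",
    "ga_generation",
    "bo_propose",
    "optimize",
]


@dataclass(frozen=True)
class Dimension:
    """One search dimension: continuous (linear or log10 scale) or categorical."""

    name: str
    kind: str                      # 'continuous-log' | 'continuous-linear' | 'categorical'
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind in ("continuous-log", "continuous-linear"):
            if not (math.isfinite(self.low) and math.isfinite(self.high)
                    and self.low < self.high):
                raise ValueError(f"{self.name}: invalid bounds")
            if self.kind == "continuous-log" and self.low <= 0:
                raise ValueError(f"{self.name}: log dimension needs positive bounds")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: choices must be non-empty")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    # transformed coordinates (continuous genes live here)
    def to_t(self, v: float) -> float:
        return math.log10(v) if self.kind == "continuous-log" else float(v)

    def from_t(self, t: float) -> float:
        lo, hi = self.t_bounds()
        t = min(max(t, lo), hi)
        return 10.0 ** t if self.kind == "continuous-log" else t

    def t_bounds(self):
        if self.kind == "continuous-log":
            return math.log10(self.low), math.log10(self.high)
        return self.low, self.high

    def contains(self, v) -> bool:
        if self.kind == "categorical":
            return v in self.choices
        return self.low - 1e-12 <= v <= self.high + 1e-12


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple

    def __iter__(self):
        return iter(self.dimensions)

    def validate(self, candidate: dict) -> None:
        for dim in self.dimensions:
            if dim.name not in candidate or not dim.contains(candidate[dim.name]):
                raise ValueError(f"candidate out of bounds on {dim.name!r}")


def default_space() -> SearchSpace:
    """The tuned hyperparameters and their search ranges."""
    return SearchSpace((
        Dimension("eta0", "continuous-log", 1e-4, 5e-3),
        Dimension("batch_size", "categorical", choices=(16, 32, 64)),
        Dimension("dropout", "continuous-linear", 0.0, 0.5),
        Dimension("weight_decay", "continuous-log", 1e-6, 1e-3),
        Dimension("attn_heads", "categorical", choices=(2, 4, 6, 8)),
        Dimension("attn_dim", "categorical", choices=(96, 192)),
    ))


@dataclass
class EvalRecord:
    """One evaluated configuration."""

    candidate: dict
    sens: float
    spec: float
    M: float
    cost: float
    J: float
    failed: bool = False


def score_M(sens: float, spec: float, alpha: float = 0.7) -> float:
    """PD-aware validation score M = alpha * Sens + (1 - alpha) * Spec."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha * sens + (1.0 - alpha) * spec


def objective_J(M: float, cost: float, c_max: float, beta: float) -> float:
    """Scalar objective J = -M + beta * C / C_max (lower is better)."""
    if cost <= 0 or c_max <= 0:
        raise ValueError("costs must be positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return -M + beta * cost / c_max


def sample_candidate(space: SearchSpace, seed) -> dict:
    """Seeded uniform draw: log-uniform on log dimensions, uniform on linear
    and categorical ones."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    cand = {}
    for dim in space:
        if dim.kind == "categorical":
            cand[dim.name] = dim.choices[int(rng.integers(len(dim.choices)))]
        else:
            lo, hi = dim.t_bounds()
            cand[dim.name] = dim.from_t(float(rng.uniform(lo, hi)))
    return cand


# --------------------------------------------------------------------------
# genetic half
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaRates:
    crossover: float = 0.9
    mutation: float = 0.2          # per-gene probability
    mutation_sigma: float = 0.1    # fraction of the transformed range
    tournament: int = 2


def _tournament(pop, fitness, rng, size):
    idx = rng.integers(len(pop), size=size)
    best = min(idx, key=lambda i: fitness[i])
    return pop[best]


def _mutate(cand: dict, space: SearchSpace, rates: GaRates,
            rng: np.random.Generator) -> dict:
    out = dict(cand)
    for dim in space:
        if rng.random() >= rates.mutation:
            continue
        if dim.kind == "categorical":
            out[dim.name] = dim.choices[int(rng.integers(len(dim.choices)))]
        else:
            lo, hi = dim.t_bounds()
            t = dim.to_t(out[dim.name]) + rng.normal(0, rates.mutation_sigma * (hi - lo))
            out[dim.name] = dim.from_t(t)
    return out


def ga_generation(population, fitness, space: SearchSpace,
                  rates: GaRates = GaRates(), seed=0,
                  n_offspring: int | None = None):
    """One GA step: tournament selection, uniform crossover, per-gene mutation
    (Gaussian in transformed space; resampling for categoricals), with the
    best individual preserved unchanged (elitism). Returns a population of
    ``n_offspring`` (default: input size) in-bounds candidates."""
    if not population:
        raise ValueError("population must be non-empty")
    if len(fitness) != len(population):
        raise ValueError("fitness must align with the population")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_out = n_offspring if n_offspring is not None else len(population)
    elite = dict(population[int(np.argmin(fitness))])
    offspring = [elite]
    while len(offspring) < n_out:
        pa = _tournament(population, fitness, rng, rates.tournament)
        pb = _tournament(population, fitness, rng, rates.tournament)
        if rng.random() < rates.crossover:
            child = {d.name: (pa if rng.random() < 0.5 else pb)[d.name]
                     for d in space}
        else:
            child = dict(pa)
        offspring.append(_mutate(child, space, rates, rng))
    for cand in offspring:
        space.validate(cand)
    return offspring[:n_out]


# --------------------------------------------------------------------------
# Bayesian half
# --------------------------------------------------------------------------

def _encode(cand: dict, space: SearchSpace) -> np.ndarray:
    """Map a candidate to [0, 1]^D for the surrogate: continuous genes by
    their transformed coordinate, categoricals by normalized choice index."""
    v = []
    for dim in space:
        if dim.kind == "categorical":
            v.append(dim.choices.index(cand[dim.name]) / max(len(dim.choices) - 1, 1))
        else:
            lo, hi = dim.t_bounds()
            v.append((dim.to_t(cand[dim.name]) - lo) / (hi - lo))
    return np.array(v)


def bo_propose(history, space: SearchSpace, seed=0, pool_size: int = 256) -> dict:
    """Expected-improvement proposal from a Gaussian-process surrogate over
    the observed (candidate, J) history; with fewer than 3 observations it
    falls back to a seeded random draw. The acquisition is maximized over a
    seeded random candidate pool, so proposals are always in-bounds."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    usable = [(c, j) for c, j in history if np.isfinite(j)]
    if len(usable) < 3:
        return sample_candidate(space, rng)

    X = np.array([_encode(c, space) for c, _ in usable])
    y = np.array([j for _, j in usable])
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), alpha=1e-6,
                                  normalize_y=True, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)

    pool = [sample_candidate(space, rng) for _ in range(pool_size)]
    P = np.array([_encode(c, space) for c in pool])
    mu, sd = gp.predict(P, return_std=True)
    best = y.min()
    sd = np.maximum(sd, 1e-12)
    imp = best - mu                     # minimizing J
    zscore = imp / sd
    ei = imp * norm.cdf(zscore) + sd * norm.pdf(zscore)
    return pool[int(np.argmax(ei))]


# --------------------------------------------------------------------------
# the optimization loop
# --------------------------------------------------------------------------

def optimize(evaluator, space: SearchSpace, budget: int, beta: float = 0.1,
             alpha: float = 0.7, seed: int = 0, population_size: int = 10,
             rates: GaRates = GaRates()):
    """Run PD-BayGA: alternate GA generations with one BO proposal injected
    per generation until ``budget`` evaluations are spent.

    ``evaluator`` maps a candidate dict to ``(sens, spec, cost)``. A raised
    exception is recorded as a failed trial (worst J) and the search
    continues. Returns ``(best_candidate, history)`` with every stored J
    re-normalized against the final C_max.
    """
    if budget < population_size:
        raise ValueError("budget must cover at least one population")
    rng = np.random.default_rng(seed)
    history: list = []
    c_max = 0.0

    def run_trial(cand: dict) -> EvalRecord:
        nonlocal c_max
        try:
            sens, spec, cost = evaluator(cand)
            m = score_M(sens, spec, alpha)
            c_max = max(c_max, cost)
            rec = EvalRecord(dict(cand), sens, spec, m, cost,
                             objective_J(m, cost, c_max, beta))
        except Exception:
            rec = EvalRecord(dict(cand), 0.0, 0.0, 0.0, float("nan"),
                             float("inf"), failed=True)
        history.append(rec)
        return rec

    population = [sample_candidate(space, rng)
                  for _ in range(min(population_size, budget))]
    records = [run_trial(c) for c in population]

    while len(history) < budget:
        fitness = [r.J for r in records]
        n_next = min(population_size, budget - len(history))
        n_ga = max(n_next - 1, 1)
        next_pop = ga_generation(population, fitness, space, rates, rng,
                                 n_offspring=n_ga)
        if len(next_pop) < n_next:
            pairs = [(r.candidate, r.J) for r in history]
            next_pop.append(bo_propose(pairs, space, rng))
        population = next_pop
        records = [run_trial(c) for c in population]

    # re-normalize all J values against the final C_max
    for rec in history:
        if not rec.failed:
            rec.J = objective_J(rec.M, rec.cost, c_max, beta)
    ok = [r for r in history if not r.failed]
    if not ok:
        raise RuntimeError("every evaluation failed")
    best = min(ok, key=lambda r: r.J)
    return dict(best.candidate), history
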