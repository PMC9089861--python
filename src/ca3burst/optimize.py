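"""Indicator-based evolutionary multi-objective fitting of model parameters.

Each candidate parameter set ("individual") is simulated under three DC-step
protocols; the 12 features per protocol are compared to experimental (or
ground-truth-derived) target means, each error measured in units of the
target SD.  IBEA with the additive-epsilon indicator evolves the population;
every feature×protocol pair is one objective (36 total), while the scalar
fitness used for reporting and elitism is the sum of all errors.  After a
run, individuals whose worst per-feature error is below 6 SD are accepted.

Variation operators are the standard real-coded pair: simulated binary
crossover (SBX, η=10) and bounded polynomial mutation (η=20, rate 1/n);
offspring are clipped to the bounds.  All randomness flows from one seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .biophysics import PARAMETER_NAMES, ParameterBounds, ParameterSet
from .features import FeatureTargets, extract_features, feature_errors, MISSING_PENALTY
from .simulator import CompartmentalModel, SimulationError, simulate
from .stimuli import DCStep

__all__ = [
    "Individual",
    "OptimizationRun",
    "evaluate",
    "ibea_run",
    "select_individuals",
    "dc_protocols",
]

SELECTION_SD_THRESHOLD = 6.0


@dataclass
class Individual:
    """One candidate solution with its per-objective errors."""

    params: ParameterSet
    errors: dict[str, float] = field(default_factory=dict)  # "protocol/feature" -> SD units

    @property
    def fitness(self) -> float:
        return float(sum(self.errors.values()))

    @property
    def max_error(self) -> float:
        return float(max(self.errors.values())) if self.errors else math.inf

    def objective_vector(self, keys: Sequence[str]) -> np.ndarray:
        return np.array([self.errors[k] for k in keys])

    def to_record(self) -> dict:
        return {"params": self.params.to_dict(), "errors": self.errors,
                "fitness": self.fitness}


@dataclass
class OptimizationRun:
    """Final population plus per-generation fitness statistics."""

    population: list[Individual]
    history: list[dict]  # per generation: best/median/q25/q75 fitness
    seed: int
    n_gen: int
    pop_size: int

    @property
    def best(self) -> Individual:
        return min(self.population, key=lambda ind: ind.fitness)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"seed": self.seed, "n_gen": self.n_gen,
                                 "pop_size": self.pop_size}) + "\n")
            for h in self.history:
                fh.write(json.dumps({"generation": h}) + "\n")
            for ind in self.population:
                fh.write(json.dumps({"individual": ind.to_record()}) + "\n")


def dc_protocols(amplitudes: Sequence[float], delay: float = 250.0,
                 duration: float = 500.0) -> list[DCStep]:
    """The three-step DC protocol family spanning the f-I range."""
    protos = []
    for a in amplitudes:
        stim = DCStep(amplitude=a, delay=delay, duration=duration)
        stim.protocol = f"dc_{a:g}nA"
        protos.append(stim)
    return protos


def evaluate(params: ParameterSet, model: CompartmentalModel,
             protocols: Sequence[DCStep], targets: FeatureTargets,
             dt: float = 0.025, tail: float = 50.0) -> Individual:
    """Simulate every protocol, extract features and score against targets.

    A numerical failure in any protocol yields worst-case (penalty) errors
    for that protocol rather than an exception, so the optimizer can keep
    ranking individuals.
    """
    errors: dict[str, float] = {}
    for stim in protocols:
        proto = stim.protocol
        try:
            res = simulate(model, params, stimuli=[stim], recordings=(0,),
                           duration=stim.delay + stim.duration + tail, dt=dt)
            fv = extract_features(res.voltage, stim)
            fv.protocol = proto
            errs = feature_errors(fv, targets, protocol=proto)
        except SimulationError:
            errs = {f: MISSING_PENALTY for f in targets.mean[proto]}
        for fname, e in errs.items():
            errors[f"{proto}/{fname}"] = float(e)
    return Individual(params=params, errors=errors)


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _sbx_crossover(p1, p2, lo, hi, rng, eta: float = 10.0, p_cross: float = 0.9):
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > p_cross:
        return c1, c2
    for i in range(p1.size):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        x1, x2 = min(p1[i], p2[i]), max(p1[i], p2[i])
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[i] = 0.5 * ((x1 + x2) - beta * (x2 - x1))
        c2[i] = 0.5 * ((x1 + x2) + beta * (x2 - x1))
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _polynomial_mutation(x, lo, hi, rng, eta: float = 20.0,
                         rate: Optional[float] = None):
    y = x.copy()
    n = x.size
    rate = 1.0 / n if rate is None else rate
    for i in range(n):
        if rng.random() > rate:
            continue
        span = hi[i] - lo[i]
        if span <= 0:
            continue
        u = rng.random()
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[i] = x[i] + delta * span
    return np.clip(y, lo, hi)


# ---------------------------------------------------------------------------
# IBEA
# ---------------------------------------------------------------------------

def _ibea_fitness(obj: np.ndarray, kappa: float = 0.05) -> np.ndarray:
    """Additive-epsilon indicator fitness (larger is better)."""
    n = obj.shape[0]
    # normalize objectives to [0, 1]
    lo = obj.min(axis=0)
    span = obj.max(axis=0) - lo
    span[span <= 0] = 1.0
    z = (obj - lo) / span
    # I(i, j): smallest epsilon by which i must be shifted to dominate j
    eps = np.max(z[:, None, :] - z[None, :, :], axis=2)  # eps[i, j] = I(i -> j)
    c = np.abs(eps).max() or 1.0
    fit = np.zeros(n)
    for i in range(n):
        # sum over j != i of -exp(-I(j, i) / (kappa c))
        contrib = -np.exp(-eps[:, i] / (kappa * c))
        fit[i] = contrib.sum() + np.exp(-eps[i, i] / (kappa * c))
    return fit


def _environmental_selection(pop: list[Individual], keys, size: int,
                             kappa: float = 0.05) -> list[Individual]:
    alive = list(range(len(pop)))
    obj = np.vstack([pop[i].objective_vector(keys) for i in alive])
    while len(alive) > size:
        fit = _ibea_fitness(obj, kappa)
        worst = int(np.argmin(fit))
        alive.pop(worst)
        obj = np.delete(obj, worst, axis=0)
    return [pop[i] for i in alive]


def ibea_run(targets: FeatureTargets, bounds: ParameterBounds,
             model: CompartmentalModel, protocols: Sequence[DCStep],
             pop_size: int = 24, n_gen: int = 20, seed: int = 0,
             kappa: float = 0.05, eta_cross: float = 10.0,
             eta_mut: float = 20.0, dt: float = 0.025,
             evaluator: Optional[Callable] = None,
             initial: Optional[Sequence[ParameterSet]] = None) -> OptimizationRun:
    """Run IBEA over the free-parameter space.

    The initial population is sampled uniformly within the bounds (optionally
    seeded with ``initial`` parameter sets); each generation applies binary-
    tournament mating selection, SBX crossover and polynomial mutation, then
    indicator-based environmental selection over parents+offspring.  The best
    scalar fitness is non-increasing across generations because the best
    individual always survives selection into the reported elite.
    """
    if pop_size % 2:
        raise ValueError("pop_size must be even")
    rng = np.random.default_rng(seed)
    lo, hi = bounds.as_arrays()
    evaluate_fn = evaluator or (
        lambda ps: evaluate(ps, model, protocols, targets, dt=dt)
    )

    def sample() -> ParameterSet:
        return ParameterSet.from_vector(lo + rng.random(lo.size) * (hi - lo))

    population = []
    if initial:
        population.extend(Individual(p.copy()) for p in initial)
    while len(population) < pop_size:
        population.append(Individual(sample()))
    population = [evaluate_fn(ind.params) for ind in population[:pop_size]]
    keys = sorted(population[0].errors)

    history = []
    best_ever = min(population, key=lambda i: i.fitness)

    def log_gen():
        fits = np.array([i.fitness for i in population])
        history.append({
            "best": float(min(best_ever.fitness, fits.min())),
            "median": float(np.median(fits)),
            "q25": float(np.percentile(fits, 25)),
            "q75": float(np.percentile(fits, 75)),
        })

    log_gen()
    for gen in range(n_gen):
        # binary tournament on scalar fitness (lower is better)
        def tournament() -> Individual:
            a, b = rng.integers(len(population)), rng.integers(len(population))
            return population[a] if population[a].fitness <= population[b].fitness else population[b]

        offspring = []
        while len(offspring) < pop_size:
            v1 = tournament().params.to_vector()
            v2 = tournament().params.to_vector()
            c1, c2 = _sbx_crossover(v1, v2, lo, hi, rng, eta=eta_cross)
            c1 = _polynomial_mutation(c1, lo, hi, rng, eta=eta_mut)
            c2 = _polynomial_mutation(c2, lo, hi, rng, eta=eta_mut)
            offspring.append(Individual(ParameterSet.from_vector(c1)))
            if len(offspring) < pop_size:
                offspring.append(Individual(ParameterSet.from_vector(c2)))
        offspring = [evaluate_fn(ind.params) for ind in offspring]
        combined = population + offspring
        population = _environmental_selection(combined, keys, pop_size, kappa)
        cand = min(population, key=lambda i: i.fitness)
        if cand.fitness < best_ever.fitness:
            best_ever = cand
        if best_ever not in population:
            worst = max(range(len(population)), key=lambda k: population[k].fitness)
            population[worst] = best_ever  # elitism: keep the best ever seen
        log_gen()

    return OptimizationRun(population=population, history=history, seed=seed,
                           n_gen=n_gen, pop_size=pop_size)


def select_individuals(population: Sequence[Individual],
                       threshold: float = SELECTION_SD_THRESHOLD) -> list[Individual]:
    """Keep individuals whose error on every feature is below ``threshold`` SD."""
    return [ind for ind in population if ind.max_error < threshold]
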