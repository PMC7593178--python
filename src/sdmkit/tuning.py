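"""Hyperparameter tuning: exhaustive grid, random sample, genetic algorithm.

All three tuners share the fitness convention: models are ranked by the
validation metric, but any combination whose validation score exceeds
its training score is flagged as underfitting and ranked last (for
AICc the ranking is simply ascending AICc — no validation partition
exists). The genetic algorithm seeds its population with the random
search, then per generation keeps the fittest fraction plus a random
fraction of the rest and breeds children by uniform crossover with
optional mutation, defaults: population 20, 5 generations, keep-best
0.4, keep-random 0.2, mutation chance 0.4 — 60 trainings in total.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import fit_and_score
from .models import HYPER_SCHEMAS, HyperCombo
from .swd import FoldSpec, SWDTable

__all__ = [
    "HyperGrid",
    "TuneResult",
    "GAConfig",
    "grid_search",
    "random_search",
    "rank_fitness",
    "crossover",
    "optimize_model",
    "expected_trainings",
]

log = logging.getLogger("sdmkit.tuning")


def _round_half_even(x: float) -> int:
    """Banker's rounding; keeps GA retention counts reproducible."""
    return int(np.rint(x))


@dataclass
class HyperGrid:
    """Candidate-value domains for one method's hyperparameters."""

    method: str
    domains: dict[str, list]

    def __post_init__(self) -> None:
        schema = HYPER_SCHEMAS.get(self.method)
        if schema is None:
            raise ValueError(f"unknown method {self.method!r}")
        unknown = set(self.domains) - set(schema)
        if unknown:
            raise ValueError(f"hyperparameters {sorted(unknown)} not in {self.method} schema")
        for name, values in self.domains.items():
            if len(values) == 0:
                raise ValueError(f"domain for {name!r} is empty")
        self.names = sorted(self.domains)

    @property
    def n_combinations(self) -> int:
        out = 1
        for name in self.names:
            out *= len(self.domains[name])
        return out

    def combo_at(self, flat_index: int, seed: int = 0) -> HyperCombo:
        """The flat_index-th combination in row-major (sorted-name) order."""
        values = {}
        rem = flat_index
        for name in reversed(self.names):
            dom = self.domains[name]
            rem, j = divmod(rem, len(dom))
            values[name] = dom[j]
        return HyperCombo(self.method, values, seed)

    def all_combos(self, seed: int = 0) -> list[HyperCombo]:
        return [self.combo_at(i, seed) for i in range(self.n_combinations)]


@dataclass
class Evaluated:
    combo: HyperCombo
    train: float
    validation: float | None
    order: int  # insertion order, the last tie-break


@dataclass
class TuneResult:
    """Evaluated combinations, ranked, with the training-effort ledger."""

    metric: str
    evaluated: list[Evaluated]
    trainings_performed: int
    cache_hits: int = 0
    generations_log: list[dict] = field(default_factory=list)

    @property
    def best(self) -> Evaluated:
        return self.evaluated[0]

    @property
    def best_combo(self) -> HyperCombo:
        return self.best.combo

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.evaluated:
            row = {"method": e.combo.method, **e.combo.values,
                   "train": e.train, "validation": e.validation}
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metric": self.metric,
                "trainings_performed": self.trainings_performed,
                "cache_hits": self.cache_hits,
                "generations": self.generations_log,
                "evaluated": [
                    {
                        "combo": e.combo.to_dict(),
                        "train": e.train,
                        "validation": e.validation,
                    }
                    for e in self.evaluated
                ],
            },
            indent=1,
        )


def rank_fitness(evaluated: list[Evaluated], metric: str) -> list[Evaluated]:
    """Order combinations by fitness.

    AUC/TSS: non-underfit first (underfit = validation > train), then
    validation descending, train descending, insertion order. AICc:
    ascending value, no underfit rule.
    """
    if metric.lower() == "aicc":
        return sorted(
            evaluated,
            key=lambda e: (np.isnan(e.train), e.train, e.order),
        )

    def key(e: Evaluated):
        underfit = e.validation is not None and e.validation > e.train
        val = e.validation if e.validation is not None else e.train
        return (underfit, -val, -e.train, e.order)

    return sorted(evaluated, key=key)


class _Evaluator:
    """Trains and scores combos, memoised by combo identity."""

    def __init__(self, table, metric, fold, validation, seed):
        self.table, self.metric = table, metric
        self.fold, self.validation = fold, validation
        self.seed = seed
        self.cache: dict[tuple, Evaluated] = {}
        self.trainings = 0
        self.cache_hits = 0
        self._order = 0

    def __call__(self, combo: HyperCombo) -> Evaluated:
        self.trainings += 1  # training *requests*; cache hits logged apart
        key = combo.key()
        if key in self.cache:
            self.cache_hits += 1
            return self.cache[key]
        result, _ = fit_and_score(
            self.table,
            combo.with_seed(self.seed),
            self.metric,
            fold=self.fold,
            validation=self.validation,
        )
        if self.metric.lower() == "aicc":
            ev = Evaluated(combo, result.train_value, None, self._order)
        else:
            ev = Evaluated(combo, result.train_value, result.validation_value, self._order)
        self._order += 1
        self.cache[key] = ev
        return ev


def grid_search(
    table: SWDTable,
    fold: FoldSpec | None,
    grid: HyperGrid,
    metric: str = "auc",
    validation: SWDTable | None = None,
    seed: int = 0,
) -> TuneResult:
    """Evaluate every combination of the grid exactly once."""
    ev = _Evaluator(table, metric, fold, validation, seed)
    evaluated = [ev(c) for c in grid.all_combos(seed)]
    return TuneResult(metric, rank_fitness(evaluated, metric), ev.trainings, ev.cache_hits)


def random_search(
    table: SWDTable,
    fold: FoldSpec | None,
    grid: HyperGrid,
    metric: str = "auc",
    population_size: int = 20,
    seed: int = 0,
    validation: SWDTable | None = None,
    _evaluator: "_Evaluator | None" = None,
) -> TuneResult:
    """Evaluate a uniform without-replacement sample of the grid."""
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    total = grid.n_combinations
    n = min(population_size, total)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    picks = rng.choice(total, size=n, replace=False)
    ev = _evaluator or _Evaluator(table, metric, fold, validation, seed)
    evaluated = [ev(grid.combo_at(int(i), seed)) for i in picks]
    return TuneResult(metric, rank_fitness(evaluated, metric), ev.trainings, ev.cache_hits)


@dataclass
class GAConfig:
    """Genetic-algorithm settings (defaults are the shipped defaults)."""

    population_size: int = 20
    generations: int = 5
    keep_best: float = 0.4
    keep_random: float = 0.2
    mutation_chance: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("keep_best", "keep_random", "mutation_chance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.keep_best + self.keep_random > 1:
            raise ValueError("keep_best + keep_random must be <= 1")
        if self.population_size < 1 or self.generations < 0:
            raise ValueError("population_size >= 1 and generations >= 0 required")


def crossover(
    parent1: HyperCombo,
    parent2: HyperCombo,
    grid: HyperGrid,
    mutation_chance: float,
    rng: np.random.Generator,
) -> HyperCombo:
    """Breed one child: uniform inheritance per hyperparameter, then with
    probability ``mutation_chance`` one hyperparameter is resampled from
    its domain excluding both parents' values (skipped when no third
    value exists). ``rng`` may be a Generator or an integer seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if parent1.method != parent2.method or parent1.method != grid.method:
        raise ValueError("parents must share the grid's method")
    values = {}
    for name in grid.names:
        pick = parent1 if rng.uniform() < 0.5 else parent2
        values[name] = pick[name]
    if rng.uniform() < mutation_chance:
        name = grid.names[rng.integers(len(grid.names))]
        excluded = {parent1[name], parent2[name]}
        candidates = [v for v in grid.domains[name] if v not in excluded]
        if candidates:
            values[name] = candidates[rng.integers(len(candidates))]
    return HyperCombo(grid.method, values, parent1.seed)


def expected_trainings(ga: GAConfig) -> int:
    """Closed-form training-request count of the genetic algorithm."""
    size = ga.population_size
    kept = _round_half_even(size * ga.keep_best) + _round_half_even(size * ga.keep_random)
    return size + ga.generations * (size - kept)


def optimize_model(
    table: SWDTable,
    fold: FoldSpec | None,
    grid: HyperGrid,
    metric: str = "auc",
    ga: GAConfig | None = None,
    validation: SWDTable | None = None,
) -> TuneResult:
    """Genetic-algorithm hyperparameter optimisation.

    Starts from a random-search population, then per generation: rank
    by fitness, retain round(size*keep_best) elites plus
    round(size*keep_random) uniformly from the remainder, and refill
    the population with crossover children (evaluating only new
    children; previously seen combinations are served from cache).
    With ``generations=0`` this *is* the random search.
    """
    ga = ga or GAConfig()
    rng = np.random.default_rng(np.random.SeedSequence([ga.seed, 23]))
    ev = _Evaluator(table, metric, fold, validation, ga.seed)
    init = random_search(
        table, fold, grid, metric,
        population_size=ga.population_size, seed=ga.seed,
        validation=validation, _evaluator=ev,
    )
    population = list(init.evaluated)
    size = len(population)  # may be < requested on tiny grids
    n_best = _round_half_even(size * ga.keep_best)
    n_rand = _round_half_even(size * ga.keep_random)
    gen_log: list[dict] = []

    def log_generation(gen: int, pop: list[Evaluated]) -> None:
        vals = [e.validation if e.validation is not None else e.train for e in pop]
        gen_log.append(
            {
                "generation": gen,
                "best": float(np.nanmax(vals)) if metric.lower() != "aicc" else float(np.nanmin(vals)),
                "mean": float(np.nanmean(vals)),
                "trainings": ev.trainings,
                "cache_hits": ev.cache_hits,
            }
        )

    population = rank_fitness(population, metric)
    log_generation(0, population)
    for gen in range(1, ga.generations + 1):
        elites = population[:n_best]
        remainder = population[n_best:]
        lucky_idx = rng.choice(len(remainder), size=min(n_rand, len(remainder)), replace=False) if remainder else []
        lucky = [remainder[i] for i in sorted(lucky_idx)]
        retained = elites + lucky
        if len(retained) < 2:
            retained = population[: max(2, len(retained))]
        children: list[Evaluated] = []
        while len(retained) + len(children) < size:
            i, j = rng.choice(len(retained), size=2, replace=False)
            child = crossover(
                retained[i].combo, retained[j].combo, grid, ga.mutation_chance, rng
            )
            children.append(ev(child))
        population = rank_fitness(retained + children, metric)
        log_generation(gen, population)
        log.info(
            "GA generation %d/%d: best=%.4f trainings=%d",
            gen, ga.generations, gen_log[-1]["best"], ev.trainings,
        )
    return TuneResult(
        metric,
        population,
        trainings_performed=ev.trainings,
        cache_hits=ev.cache_hits,
        generations_log=gen_log,
    )
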