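"""Evolutionary search over register-machine classifiers.

A (mu+lambda) generational scheme: tournament parent selection,
segment recombination, point mutation restricted to effective
instructions, and truncation survival over the pooled parents and
offspring (which makes the best fitness trajectory monotone).
Fitness is mean classification error (MCE) on the training fold —
lower is better.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .lgp_core import (
    ARITHMETIC_OPERATORS,
    COMPARATORS,
    Instruction,
    Operand,
    Program,
    effective_instructions,
    effective_subprogram,
    execute_matrix,
    random_operand,
    random_program,
)

__all__ = [
    "EvolutionConfig",
    "Individual",
    "mce_fitness",
    "tournament_select",
    "mutate",
    "recombine",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the evolutionary run.

    Defaults are the published full-scale settings; reduced settings
    (smaller population / fewer generations) only change search effort,
    never the semantics of the evolved programs.
    """

    population_size: int = 500
    n_parents: int = 500
    n_generations: int = 500
    tournament_size: int = 16
    max_program_length: int = 500
    constant_set: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    n_calc_registers: int = 150
    mutation_rate: float = 0.9
    recombination_rate: float = 0.7
    p_branch: float = 0.25
    operand_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # feat / calc / const
    admit_both_offspring: bool = True
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.n_parents < 1 or self.n_generations < 0:
            raise ValueError("counts must be positive")
        if not (1 <= self.tournament_size <= self.population_size):
            raise ValueError("tournament_size must be in [1, population_size]")
        if self.max_program_length < 1 or self.n_calc_registers < 1:
            raise ValueError("invalid program shape bounds")

    @classmethod
    def from_file(cls, path) -> "EvolutionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("constant_set", "operand_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kw) -> "EvolutionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Individual:
    program: Program
    fitness: float
    n_effective: int


def mce_fitness(program: Program, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of training samples misclassified (threshold 0.5 on the
    sigmoid score, i.e. sign of the final r[0])."""
    if len(y) == 0:
        raise ValueError("empty training set")
    # executing the effective subset is exact (semantics-preserving) and faster
    out = execute_matrix(effective_subprogram(program), X)
    pred = (out >= 0.0).astype(int)
    return float(np.mean(pred != y))


def _evaluate(program: Program, X: np.ndarray, y: np.ndarray) -> Individual:
    eff = effective_subprogram(program)
    out = execute_matrix(eff, X)
    fitness = float(np.mean((out >= 0.0).astype(int) != y))
    return Individual(program, fitness, len(eff))


def tournament_select(pop: Sequence[Individual], k: int, rng: np.random.Generator) -> Individual:
    """Sample k individuals with replacement; return the lowest-MCE one
    (ties go to the first sampled)."""
    if not pop:
        raise ValueError("empty population")
    idx = rng.integers(len(pop), size=k)
    best = pop[idx[0]]
    for i in idx[1:]:
        if pop[i].fitness < best.fitness:
            best = pop[i]
    return best


def _mutate_operand(old: Operand, config: EvolutionConfig, n_features: int,
                    rng: np.random.Generator) -> Operand:
    for _ in range(50):
        new = random_operand(config, n_features, rng)
        if new != old:
            return new
    return old  # degenerate operand space


def mutate(program: Program, config: EvolutionConfig, rng: np.random.Generator) -> Program:
    """Change exactly one element of one effective instruction.

    The element is the destination register, the operator/comparator, or
    one operand; destinations remain calculation registers.  Programs
    with no effective instruction fall back to mutating any instruction.
    """
    mask = effective_instructions(program)
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        candidates = np.arange(len(program))
    pos = int(rng.choice(candidates))
    ins = program.instructions[pos]
    n_features = program.n_features

    if ins.kind == "assign":
        element = rng.integers(4)  # dest / op / lhs / rhs
        if element == 0 and config.n_calc_registers > 1:
            new_dest = ins.dest
            while new_dest == ins.dest:
                new_dest = int(rng.integers(config.n_calc_registers))
            new_ins = dataclasses.replace(ins, dest=new_dest)
        elif element == 1:
            others = [o for o in ARITHMETIC_OPERATORS if o != ins.op]
            new_ins = dataclasses.replace(ins, op=str(rng.choice(others)))
        elif element == 2:
            new_ins = dataclasses.replace(ins, lhs=_mutate_operand(ins.lhs, config, n_features, rng))
        else:
            new_ins = dataclasses.replace(ins, rhs=_mutate_operand(ins.rhs, config, n_features, rng))
    else:
        element = rng.integers(3)  # comparator / lhs / rhs
        if element == 0:
            new_ins = dataclasses.replace(ins, op="<" if ins.op == ">" else ">")
        elif element == 1:
            new_ins = dataclasses.replace(ins, lhs=_mutate_operand(ins.lhs, config, n_features, rng))
        else:
            new_ins = dataclasses.replace(ins, rhs=_mutate_operand(ins.rhs, config, n_features, rng))

    new_instructions = list(program.instructions)
    new_instructions[pos] = new_ins
    return Program(tuple(new_instructions), n_features, program.n_calc_registers)


def recombine(p1: Program, p2: Program, rng: np.random.Generator,
              max_length: int = 500) -> tuple[Program, Program]:
    """Exchange one contiguous instruction segment between two parents.

    Segment endpoints are uniform; segment pairs whose exchange would
    leave an offspring empty or beyond *max_length* are resampled.
    """
    n1, n2 = len(p1), len(p2)
    for _ in range(200):
        i1 = int(rng.integers(0, n1 + 1)); j1 = int(rng.integers(i1, n1 + 1))
        i2 = int(rng.integers(0, n2 + 1)); j2 = int(rng.integers(i2, n2 + 1))
        len1 = n1 - (j1 - i1) + (j2 - i2)
        len2 = n2 - (j2 - i2) + (j1 - i1)
        if 1 <= len1 <= max_length and 1 <= len2 <= max_length:
            c1 = p1.instructions[:i1] + p2.instructions[i2:j2] + p1.instructions[j1:]
            c2 = p2.instructions[:i2] + p1.instructions[i1:j1] + p2.instructions[j2:]
            return (Program(c1, p1.n_features, p1.n_calc_registers),
                    Program(c2, p2.n_features, p2.n_calc_registers))
    return p1, p2  # no valid exchange found


def evolve(X: np.ndarray, y: np.ndarray, config: EvolutionConfig,
           rng: np.random.Generator, history: list | None = None) -> Individual:
    """Run one evolutionary search and return the lowest-MCE individual.

    Each generation draws ``n_parents`` offspring via tournament
    selection with optional recombination then mutation; survivors are
    the ``population_size`` best of the pooled parents+offspring, sorted
    stably by (MCE, number of effective instructions, insertion order).

    If *history* is a list, the best fitness after each generation
    (including the initial population) is appended to it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]

    pop = [_evaluate(random_program(config, n_features, rng), X, y)
           for _ in range(config.population_size)]
    pop.sort(key=lambda ind: (ind.fitness, ind.n_effective))
    if history is not None:
        history.append(pop[0].fitness)

    for _ in range(config.n_generations):
        offspring_programs: list[Program] = []
        while len(offspring_programs) < config.n_parents:
            parent = tournament_select(pop, config.tournament_size, rng)
            if rng.random() < config.recombination_rate:
                mate = tournament_select(pop, config.tournament_size, rng)
                c1, c2 = recombine(parent.program, mate.program, rng,
                                   config.max_program_length)
                children = [c1, c2] if config.admit_both_offspring else [c1]
            else:
                children = [parent.program]
            for child in children:
                if rng.random() < config.mutation_rate:
                    child = mutate(child, config, rng)
                offspring_programs.append(child)
        offspring = [_evaluate(p, X, y) for p in offspring_programs[: config.n_parents]]
        pool = pop + offspring
        pool.sort(key=lambda ind: (ind.fitness, ind.n_effective))  # stable: insertion order last
        pop = pool[: config.population_size]
        if history is not None:
            history.append(pop[0].fitness)

    return pop[0]
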