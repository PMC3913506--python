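"""Genetic-algorithm optimisation (GAO) benchmark.

A textbook simple GA over the same two-reagent space, *without* the
surrogate model: the foil against which the model-guided design is judged.
Selection uses the same squared-response law as EDO for comparability;
crossover swaps whole reagents between two parents; mutation is the shared
single-level change operator.  The default sizing — a 40-compound random
initial population plus 10 generations of 10 offspring — spends exactly
the same 140-evaluation budget as the model-guided design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design import EvaluatedDesign, RunResult
from .edo import _build_result, _uniform_untested, mutate, select_parents
from .landscape import CombinatorialLandscape, CompoundKey

__all__ = ["GAOConfig", "GAO", "gao_crossover", "run_gao"]


@dataclass(frozen=True)
class GAOConfig:
    """Simple-GA settings; construction enforces that the schedule fits the
    budget (initial + offspring x generations <= budget)."""

    initial_population: int = 40
    offspring_per_generation: int = 10
    n_generations: int = 10
    mutation_prob: float = 0.05
    selection_exponent: int = 2  # squared-response law, as in EDO
    budget: int = 140
    stop_at_known_optimum: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_population < 2:
            raise ValueError("initial_population must be >= 2")
        if self.offspring_per_generation < 1 or self.n_generations < 0:
            raise ValueError("offspring and generation counts must be positive")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.selection_exponent != 2:
            raise ValueError("only the squared-response selection law is supported")
        total = self.initial_population + self.offspring_per_generation * self.n_generations
        if total > self.budget:
            raise ValueError(
                f"schedule of {total} evaluations exceeds the budget {self.budget}"
            )


def gao_crossover(
    parent_1: CompoundKey, parent_2: CompoundKey, rng: np.random.Generator
) -> CompoundKey:
    """One-point reagent swap: reagent A from one parent, B from the other,
    the side chosen uniformly."""
    if rng.random() < 0.5:
        return CompoundKey(parent_1.reagent_a, parent_2.reagent_b)
    return CompoundKey(parent_2.reagent_a, parent_1.reagent_b)


def run_gao(landscape: CombinatorialLandscape, config: GAOConfig | None = None) -> RunResult:
    """Run the simple-GA benchmark; same results contract as the EDO run."""
    config = config or GAOConfig()
    l_a, l_b = landscape.l_a, landscape.l_b
    if landscape.n_available == 0:
        raise ValueError("landscape has no available responses")
    n_init = min(config.initial_population, landscape.n_cells)
    rng = np.random.default_rng(config.seed)
    _, known_max = landscape.global_optimum()

    design = EvaluatedDesign(budget=config.budget)
    taken: set[CompoundKey] = set()
    while len(taken) < n_init:
        taken.add(_uniform_untested(taken, l_a, l_b, rng))
    for key in sorted(taken):  # deterministic insertion order
        design.add(key, landscape.evaluate(key), 1)

    def found_optimum() -> bool:
        return config.stop_at_known_optimum and any(
            r.activity == known_max for r in design.scored_records()
        )

    truncated = False
    for _ in range(config.n_generations):
        if found_optimum():
            break
        remaining = min(
            config.budget - design.n_unique, landscape.n_cells - design.n_unique
        )
        target = min(config.offspring_per_generation, remaining)
        if target <= 0:
            truncated = True
            break
        truncated = (target < config.offspring_per_generation) or truncated
        pending: list[CompoundKey] = []
        pending_set: set[CompoundKey] = set()
        pool_size = len(design.scored_records())
        for _ in range(target):
            if pool_size >= 2:
                p1, p2 = select_parents(design, 2, rng)
                child = gao_crossover(p1, p2, rng)
            else:
                child = _uniform_untested(design.keys | pending_set, l_a, l_b, rng)
            child = mutate(child, config.mutation_prob, l_a, l_b, rng)
            if child in design.keys or child in pending_set:
                child = _uniform_untested(design.keys | pending_set, l_a, l_b, rng)
            pending.append(child)
            pending_set.add(child)
        generation = design.last_generation + 1
        for key in pending:
            design.add(key, landscape.evaluate(key), generation)

    return _build_result("GAO", design, landscape, config, truncated, known_max)


class GAO:
    """Model-style front end: ``GAO(landscape, config).fit() -> RunResult``."""

    def __init__(
        self,
        landscape: CombinatorialLandscape,
        config: GAOConfig | None = None,
        **overrides,
    ) -> None:
        self.landscape = landscape
        base = config or GAOConfig()
        self.config = replace(base, **overrides) if overrides else base

    def fit(self, seed: int | None = None) -> RunResult:
        config = self.config if seed is None else replace(self.config, seed=seed)
        return run_gao(self.landscape, config)
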