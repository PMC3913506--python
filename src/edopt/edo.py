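"""Evolutionary model-based design for optimisation (EDO).

EDO searches a two-reagent combinatorial space for the maximum-activity
compound with a very small number of experiments by evolving a design
across generations:

1. an initial design of ``l_A + l_B`` distinct compounds covering every
   level of both reagents (each A level paired with a random B level and
   vice versa; 100 compounds on a 50x50 grid);
2. each subsequent generation fits a random-forest surrogate to all tested
   compounds, selects parents with probability proportional to the
   *square* of their response (pi_i = y_i^2 / sum_j y_j^2, over the whole
   tested pool), recombines each parent by fixing one reagent (chosen at
   random) and taking the surrogate-predicted best untested level of the
   other, and mutates each offspring with a small probability;
3. the run stops at the known optimum (benchmark mode), at the generation
   cap, or at the unique-evaluation budget (140 by default, matching the
   classic 100 + 4 x 10 accounting).

No compound is ever evaluated twice; every stochastic choice flows from a
single seeded generator, so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .design import EvaluatedDesign, RunResult
from .landscape import CombinatorialLandscape, CompoundKey
from .surrogate import Surrogate, SurrogateConfig, fit_surrogate

logger = logging.getLogger(__name__)

__all__ = [
    "EDOConfig",
    "EDO",
    "initial_design",
    "selection_probabilities",
    "select_parents",
    "model_guided_crossover",
    "mutate",
    "edo_generation",
    "run_edo",
]


@dataclass(frozen=True)
class EDOConfig:
    """EDO run settings.

    The initial design size is not free: the two-way coverage construction
    fixes it at ``l_A + l_B`` (100 on the 50x50 grid).  ``max_generations``
    counts the evolution steps after the initial design; with the default
    budget of 140 unique evaluations, at most four 10-point generations fit
    after the 100-point start.
    """

    parents_per_generation: int = 10
    mutation_prob: float = 0.05
    max_generations: int = 5
    budget: int = 140
    stop_at_known_optimum: bool = True
    seed: int = 0
    surrogate_config: SurrogateConfig = field(default_factory=SurrogateConfig)

    def __post_init__(self) -> None:
        if self.parents_per_generation < 1:
            raise ValueError("parents_per_generation must be >= 1")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        if self.budget < 2:
            raise ValueError("budget must be >= 2")


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------


def initial_design(l_a: int, l_b: int, rng: np.random.Generator) -> list[CompoundKey]:
    """Two-way-coverage random initial design of ``l_a + l_b`` compounds.

    Each level of reagent A is paired with a random level of B, then each
    level of B with a random level of A; a second-set draw colliding with
    an existing compound is redrawn among the remaining partner levels (or,
    if the whole column is taken, replaced by a random untested cell so the
    design size stays ``l_a + l_b``).
    """
    if l_a < 1 or l_b < 1:
        raise ValueError("level counts must be >= 1")
    if l_a + l_b > l_a * l_b:
        raise ValueError(
            f"a {l_a}x{l_b} grid cannot host {l_a + l_b} distinct compounds"
        )
    chosen: list[CompoundKey] = []
    taken: set[CompoundKey] = set()
    for a in range(1, l_a + 1):
        key = CompoundKey(a, int(rng.integers(1, l_b + 1)))
        chosen.append(key)
        taken.add(key)
    for b in range(1, l_b + 1):
        available = [a for a in range(1, l_a + 1) if CompoundKey(a, b) not in taken]
        if available:
            key = CompoundKey(available[int(rng.integers(len(available)))], b)
        else:  # whole column already covered by the first set
            pool = [
                CompoundKey(a, bb)
                for a in range(1, l_a + 1)
                for bb in range(1, l_b + 1)
                if CompoundKey(a, bb) not in taken
            ]
            key = pool[int(rng.integers(len(pool)))]
        chosen.append(key)
        taken.add(key)
    return chosen


def selection_probabilities(responses: Sequence[float]) -> np.ndarray:
    """Fitness-proportional selection law: pi_i = y_i^2 / sum_j y_j^2.

    Squaring sharpens the pull toward high-activity compounds; it also
    silently assumes non-negative responses, so negatives are rejected.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise ValueError("no responses to select from")
    if np.any(y < 0):
        raise ValueError("selection law is undefined for negative responses")
    w = y**2
    total = w.sum()
    if total == 0:
        raise ValueError("all responses are zero; selection probabilities undefined")
    return w / total


def select_parents(
    design: EvaluatedDesign, count: int, rng: np.random.Generator
) -> list[CompoundKey]:
    """Draw ``count`` distinct parents from the whole tested pool.

    Sequential weighted draws without replacement, with weights y_i^2
    renormalised after each removal; the pool is every scored compound
    tested so far, not only the latest generation.
    """
    scored = design.scored_records()
    if count > len(scored):
        raise ValueError(f"cannot select {count} parents from a pool of {len(scored)}")
    keys = [r.key for r in scored]
    weights = np.asarray([r.activity for r in scored], dtype=float) ** 2
    if np.any(weights < 0) or weights.sum() == 0:
        selection_probabilities([r.activity for r in scored])  # raise with the right message
    parents: list[CompoundKey] = []
    alive = list(range(len(keys)))
    for _ in range(count):
        w = weights[alive]
        idx = int(rng.choice(len(alive), p=w / w.sum()))
        parents.append(keys[alive[idx]])
        del alive[idx]
    return parents


def mutate(
    compound: CompoundKey,
    p: float,
    l_a: int,
    l_b: int,
    rng: np.random.Generator,
) -> CompoundKey:
    """With probability ``p``, change one reagent level.

    The reagent is chosen uniformly and its level replaced by a uniformly
    drawn *different* level (a mutation must change the compound); with a
    single-level reagent the other side is mutated instead.
    """
    if rng.random() >= p:
        return compound
    sides = [s for s, l in (("A", l_a), ("B", l_b)) if l >= 2]
    if not sides:
        return compound
    side = sides[int(rng.integers(len(sides)))] if len(sides) == 1 else (
        "A" if rng.random() < 0.5 else "B"
    )
    if side == "A":
        draw = int(rng.integers(1, l_a))  # 1 .. l_a - 1
        level = draw if draw < compound.reagent_a else draw + 1
        return CompoundKey(level, compound.reagent_b)
    draw = int(rng.integers(1, l_b))
    level = draw if draw < compound.reagent_b else draw + 1
    return CompoundKey(compound.reagent_a, level)


def model_guided_crossover(
    parent: CompoundKey,
    model: Surrogate,
    tested: set[CompoundKey],
    already_chosen: set[CompoundKey],
    rng: np.random.Generator,
    l_a: int,
    l_b: int,
    trace: dict | None = None,
) -> CompoundKey:
    """Surrogate-guided recombination of one parent.

    Fixes one reagent (chosen with probability 1/2 each) at the parent's
    level, enumerates every candidate varying the other reagent, discards
    candidates already tested or already chosen this generation, and
    returns the candidate with the highest predicted activity (prediction
    ties broken by the lowest level index).  If the chosen side is
    exhausted the other side is tried; if both are exhausted a uniformly
    random untested compound is returned.

    ``trace``, when given, receives the fixed side, surviving candidates
    and their predictions — used by oracle-equivalence instrumentation.
    """
    first = "A" if rng.random() < 0.5 else "B"
    order = [first, "B" if first == "A" else "A"]
    excluded = tested | already_chosen
    for side in order:
        if side == "A":  # fix reagent A, vary the B levels
            candidates = [CompoundKey(parent.reagent_a, b) for b in range(1, l_b + 1)]
        else:
            candidates = [CompoundKey(a, parent.reagent_b) for a in range(1, l_a + 1)]
        survivors = [c for c in candidates if c not in excluded]
        if not survivors:
            continue
        preds = np.asarray(model.predict(survivors), dtype=float)
        winner = survivors[int(np.argmax(preds))]  # first max = lowest level index
        if trace is not None:
            trace.update(
                side=side, candidates=survivors, predictions=preds, winner=winner,
                fallback=False,
            )
        return winner
    pool = [
        CompoundKey(a, b)
        for a in range(1, l_a + 1)
        for b in range(1, l_b + 1)
        if CompoundKey(a, b) not in excluded
    ]
    if not pool:
        raise ValueError("entire grid already tested; no candidate left")
    winner = pool[int(rng.integers(len(pool)))]
    if trace is not None:
        trace.update(side=None, candidates=pool, predictions=None, winner=winner,
                     fallback=True)
    return winner


# ---------------------------------------------------------------------------
# generation step and full run
# ---------------------------------------------------------------------------


def _uniform_untested(
    excluded: set[CompoundKey], l_a: int, l_b: int, rng: np.random.Generator
) -> CompoundKey:
    pool = [
        CompoundKey(a, b)
        for a in range(1, l_a + 1)
        for b in range(1, l_b + 1)
        if CompoundKey(a, b) not in excluded
    ]
    if not pool:
        raise ValueError("entire grid already tested")
    return pool[int(rng.integers(len(pool)))]


def edo_generation(
    design: EvaluatedDesign,
    landscape: CombinatorialLandscape,
    config: EDOConfig,
    rng: np.random.Generator,
    model: Surrogate | None = None,
) -> bool:
    """Advance the design by one generation, in place.

    Fits the surrogate on all scored data (unless an explicit ``model`` is
    injected), selects parents, recombines, mutates, resolves collisions,
    and evaluates the new candidates on the landscape.  Missing cells
    consume budget and are recorded with a missing response.  Returns
    ``True`` when the generation had to be truncated (budget or grid
    exhaustion left fewer than ``parents_per_generation`` slots).
    """
    l_a, l_b = landscape.l_a, landscape.l_b
    scored = design.scored_records()
    remaining_budget = (
        config.budget - design.n_unique if config.budget is not None else np.inf
    )
    untested = landscape.n_cells - design.n_unique
    target = int(min(config.parents_per_generation, remaining_budget, untested))
    if target <= 0:
        return True
    if model is None:
        model = fit_surrogate(
            [r.key for r in scored],
            [r.activity for r in scored],
            config.surrogate_config,
            l_a,
            l_b,
        )
    n_parents = min(target, len(scored))
    parents = select_parents(design, n_parents, rng)

    pending: list[CompoundKey] = []
    pending_set: set[CompoundKey] = set()
    i = 0
    while len(pending) < target:
        parent = parents[i % len(parents)]
        i += 1
        child = model_guided_crossover(
            parent, model, design.keys, pending_set, rng, l_a, l_b
        )
        pending.append(child)
        pending_set.add(child)

    # mutation, with collisions against tested or pending points resolved
    # by a uniform untested redraw
    final: list[CompoundKey] = []
    taken = design.keys | pending_set
    for child in pending:
        taken.discard(child)
        mutant = mutate(child, config.mutation_prob, l_a, l_b, rng)
        if mutant in taken:
            mutant = _uniform_untested(taken, l_a, l_b, rng)
        taken.add(mutant)
        final.append(mutant)

    generation = design.last_generation + 1
    for key in final:
        design.add(key, landscape.evaluate(key), generation)
    truncated = target < config.parents_per_generation
    logger.debug(
        "generation %d: %d new compounds (truncated=%s)", generation, len(final), truncated
    )
    return truncated


def run_edo(
    landscape: CombinatorialLandscape,
    config: EDOConfig | None = None,
    model: Surrogate | None = None,
) -> RunResult:
    """Run the full EDO procedure and return its results object.

    ``model``, when given, replaces the per-generation random-forest fit
    (used with the oracle surrogate in benchmark equivalence studies).
    """
    config = config or EDOConfig()
    l_a, l_b = landscape.l_a, landscape.l_b
    if landscape.n_available == 0:
        raise ValueError("landscape has no available responses")
    if config.budget < l_a + l_b:
        raise ValueError(
            f"budget {config.budget} cannot host the {l_a + l_b}-point initial design"
        )
    rng = np.random.default_rng(config.seed)
    _, known_max = landscape.global_optimum()

    design = EvaluatedDesign(budget=config.budget)
    for key in initial_design(l_a, l_b, rng):
        design.add(key, landscape.evaluate(key), 1)

    truncated = False

    def done() -> bool:
        if config.stop_at_known_optimum and any(
            r.activity == known_max for r in design.scored_records()
        ):
            return True
        return False

    for _ in range(config.max_generations):
        if done() or design.n_unique >= min(config.budget, landscape.n_cells):
            break
        truncated = edo_generation(design, landscape, config, rng, model=model) or truncated

    return _build_result("EDO", design, landscape, config, truncated, known_max)


def _build_result(
    method: str,
    design: EvaluatedDesign,
    landscape: CombinatorialLandscape,
    config,
    truncated: bool,
    known_max: float,
) -> RunResult:
    best_key, best_value = design.best()
    generation_found = next(
        r.generation for r in design.records if r.activity == best_value
    )
    return RunResult(
        method=method,
        design=design,
        landscape=landscape,
        best_key=best_key,
        best_value=best_value,
        generation_found=generation_found,
        per_generation_best=design.best_by_generation(),
        n_generations=design.last_generation,
        truncated=truncated,
        reached_known_optimum=best_value == known_max,
        seed=config.seed,
        config=config,
    )


class EDO:
    """Model-style front end: ``EDO(landscape, config).fit() -> RunResult``.

    Mirrors the fitted-model idiom: the object binds the data (the
    landscape standing in for the laboratory) and the run settings; ``fit``
    executes the sequential design and returns the results object.
    """

    def __init__(
        self,
        landscape: CombinatorialLandscape,
        config: EDOConfig | None = None,
        model: Surrogate | None = None,
        **overrides,
    ) -> None:
        self.landscape = landscape
        base = config or EDOConfig()
        self.config = replace(base, **overrides) if overrides else base
        self.model = model

    def fit(self, seed: int | None = None) -> RunResult:
        config = self.config if seed is None else replace(self.config, seed=seed)
        return run_edo(self.landscape, config, model=self.model)
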