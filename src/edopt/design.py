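"""Experimental-design bookkeeping shared by the EDO and GAO runners.

An :class:`EvaluatedDesign` is the growing record ``(X_k; y_k)`` of the
compounds tested generation by generation, with the two invariants every
sequential design here must respect: no compound is ever evaluated twice,
and the number of unique evaluations never exceeds the budget.  A
:class:`RunResult` is the results object a completed run returns, in the
spirit of a fitted-model results class: it carries the full design, the
best compound found, per-generation progress, and convenience accessors
for the goodness metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import CombinatorialLandscape, CompoundKey

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import GoodnessReport

__all__ = ["EvalRecord", "EvaluatedDesign", "RunResult"]


@dataclass(frozen=True)
class EvalRecord:
    """One evaluation: compound, measured activity (``None`` when the cell
    turned out to be missing), and the generation it belongs to."""

    key: CompoundKey
    activity: float | None
    generation: int


class EvaluatedDesign:
    """Ordered, duplicate-free record of evaluations across generations."""

    def __init__(self, budget: int | None = None) -> None:
        self.budget = budget
        self._records: list[EvalRecord] = []
        self._keys: set[CompoundKey] = set()

    # -- mutation ---------------------------------------------------------

    def add(self, key: CompoundKey, activity: float | None, generation: int) -> None:
        key = CompoundKey(*key)
        if key in self._keys:
            raise ValueError(f"compound {key} already evaluated")
        if self.budget is not None and len(self._records) >= self.budget:
            raise ValueError("evaluation budget exhausted")
        last = self._records[-1].generation if self._records else 0
        if generation not in (last, last + 1) or generation < 1:
            raise ValueError(
                f"generation indices must be contiguous from 1; got {generation} after {last}"
            )
        self._records.append(EvalRecord(key, activity, generation))
        self._keys.add(key)

    # -- queries ----------------------------------------------------------

    @property
    def records(self) -> list[EvalRecord]:
        return list(self._records)

    @property
    def keys(self) -> set[CompoundKey]:
        return set(self._keys)

    @property
    def n_unique(self) -> int:
        return len(self._records)

    @property
    def last_generation(self) -> int:
        return self._records[-1].generation if self._records else 0

    def scored_records(self) -> list[EvalRecord]:
        """Records with a non-missing response (the model-fit / selection pool)."""
        return [r for r in self._records if r.activity is not None]

    def generation_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for r in self._records:
            sizes[r.generation] = sizes.get(r.generation, 0) + 1
        return sizes

    def best(self) -> tuple[CompoundKey, float]:
        scored = self.scored_records()
        if not scored:
            raise ValueError("no scored evaluations yet")
        best = max(scored, key=lambda r: r.activity)
        return best.key, best.activity

    def best_by_generation(self) -> list[float]:
        """Cumulative best response after each generation (non-decreasing)."""
        out: list[float] = []
        best = -np.inf
        for k in range(1, self.last_generation + 1):
            for r in self._records:
                if r.generation == k and r.activity is not None:
                    best = max(best, r.activity)
            out.append(best)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.generation, r.key.reagent_a, r.key.reagent_b, r.activity)
                for r in self._records
            ],
            columns=["generation", "reagent_a", "reagent_b", "activity"],
        )


@dataclass
class RunResult:
    """Outcome of a completed optimisation run.

    ``best_value`` is the maximum response over all recorded evaluations
    (the run's y-hat-max); ``generation_found`` is the generation at which
    that value was first evaluated.  ``truncated`` flags a final generation
    cut short by the budget or by grid exhaustion;
    ``reached_known_optimum`` is meaningful only in benchmark mode, where
    the landscape's global maximum is known.
    """

    method: str
    design: EvaluatedDesign
    landscape: CombinatorialLandscape
    best_key: CompoundKey
    best_value: float
    generation_found: int
    per_generation_best: list[float]
    n_generations: int
    truncated: bool
    reached_known_optimum: bool
    seed: int
    config: object

    def __post_init__(self) -> None:
        _, best = self.design.best()
        if best != self.best_value:
            raise ValueError("best_value inconsistent with the recorded design")

    @property
    def n_evaluations(self) -> int:
        return self.design.n_unique

    # -- metrics glue ------------------------------------------------------

    def dgo(self) -> float:
        """Design goodness DGO against the landscape's known extremes."""
        from .metrics import dgo

        stats = self.landscape.describe()
        return dgo(self.best_value, stats.y_max, stats.y_min)

    def dgo_alpha(self, alpha: float) -> float:
        from .metrics import dgo_alpha

        return dgo_alpha(self.design, self.landscape, alpha)

    def enrichment_curve(self, alpha: float) -> list[float]:
        from .metrics import enrichment_curve

        return enrichment_curve(self, self.landscape, alpha)

    def goodness_report(self, alphas: Sequence[float] = (0.01, 0.05)) -> "GoodnessReport":
        from .metrics import build_goodness_report

        return build_goodness_report(self, self.landscape, alphas)

    def to_frame(self) -> pd.DataFrame:
        return self.design.to_frame()

    def summary(self) -> str:
        """Plain-text summary table of the run."""
        stats = self.landscape.describe()
        sizes = self.design.generation_sizes()
        lines = [
            f"{self.method} run summary",
            "=" * 44,
            f"landscape            {self.landscape.name or '<unnamed>'}",
            f"space size N         {self.landscape.n_cells}",
            f"unique evaluations   {self.n_evaluations}",
            f"generations          {self.n_generations}"
            + ("  (truncated)" if self.truncated else ""),
            f"best compound        {self.best_key}",
            f"best response        {self.best_value:.4f}  (found at generation {self.generation_found})",
            f"known space maximum  {stats.y_max:.4f}",
            f"DGO                  {self.dgo():.4f}",
            "-" * 44,
            "generation sizes     "
            + ", ".join(f"m{k}={sizes[k]}" for k in sorted(sizes)),
            "per-generation best  "
            + ", ".join(f"{v:.3f}" for v in self.per_generation_best),
        ]
        return "\n".join(lines)
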