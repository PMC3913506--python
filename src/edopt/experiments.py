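"""Replication studies: head-to-head comparison and robustness sweeps.

`run_comparison` pits the model-guided design (EDO) against the simple-GA
benchmark (GAO) on the *same* landscape at the *same* unique-evaluation
budget and reports both designs' goodness criteria, the one-tailed
two-proportion tests on their optimal-region coverage, and frequency
tables of the high responses.  `robustness_study` reruns EDO with many
different initial populations (seeds) and reports the fraction of
replicates whose best found response clears a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .design import RunResult
from .edo import EDOConfig, run_edo
from .gao import GAOConfig, run_gao
from .landscape import CombinatorialLandscape
from .metrics import (
    GoodnessReport,
    build_goodness_report,
    one_tailed_two_proportion_test,
    response_frequency_table,
)

__all__ = ["ComparisonReport", "RobustnessResult", "run_comparison", "robustness_study"]


@dataclass
class ComparisonReport:
    """Everything needed to compare two designs run on one landscape."""

    edo_result: RunResult
    gao_result: RunResult
    edo_goodness: GoodnessReport
    gao_goodness: GoodnessReport
    p_values: dict[float, float]
    edo_frequency_table: dict[tuple[float, float], int]
    gao_frequency_table: dict[tuple[float, float], int]
    frequency_threshold: float

    def to_dict(self) -> dict:
        def freq(table):
            return [
                {"lo": lo, "hi": hi, "count": c} for (lo, hi), c in sorted(table.items())
            ]

        return {
            "edo": self.edo_goodness.to_dict(),
            "gao": self.gao_goodness.to_dict(),
            "p_values": {str(a): p for a, p in self.p_values.items()},
            "frequency_threshold": self.frequency_threshold,
            "edo_frequency_table": freq(self.edo_frequency_table),
            "gao_frequency_table": freq(self.gao_frequency_table),
            "edo_seed": self.edo_result.seed,
            "gao_seed": self.gao_result.seed,
        }

    def to_json(self, path_or_buf=None) -> str | None:
        text = json.dumps(self.to_dict(), indent=2)
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        return None

    def summary(self) -> str:
        lines = [
            "EDO vs GAO comparison",
            "=" * 50,
            f"{'criterion':<22}{'EDO':>12}{'GAO':>12}",
            f"{'DGO':<22}{self.edo_goodness.dgo:>12.4f}{self.gao_goodness.dgo:>12.4f}",
        ]
        for a in sorted(self.edo_goodness.dgo_alpha):
            lines.append(
                f"{f'DGO_{a}':<22}"
                f"{self.edo_goodness.dgo_alpha[a]:>12.4f}"
                f"{self.gao_goodness.dgo_alpha[a]:>12.4f}"
            )
        for a in sorted(self.p_values):
            lines.append(f"one-tailed p (alpha={a}): {self.p_values[a]:.4f}")
        return "\n".join(lines)


def run_comparison(
    landscape: CombinatorialLandscape,
    edo_config: EDOConfig | None = None,
    gao_config: GAOConfig | None = None,
    alphas: Sequence[float] = (0.01, 0.05),
    frequency_threshold: float = 6.0,
    frequency_bin_width: float = 0.25,
    allow_unequal_budgets: bool = False,
) -> ComparisonReport:
    """Run both methods on the same landscape and compile the comparison.

    The two budgets must match (like-for-like comparison) unless
    ``allow_unequal_budgets`` is set.
    """
    edo_config = edo_config or EDOConfig()
    gao_config = gao_config or GAOConfig()
    if edo_config.budget != gao_config.budget and not allow_unequal_budgets:
        raise ValueError(
            f"unequal budgets ({edo_config.budget} vs {gao_config.budget}); "
            "set allow_unequal_budgets to override"
        )
    edo_result = run_edo(landscape, edo_config)
    gao_result = run_gao(landscape, gao_config)
    edo_goodness = build_goodness_report(edo_result, landscape, alphas)
    gao_goodness = build_goodness_report(gao_result, landscape, alphas)
    p_values: dict[float, float] = {}
    for a in alphas:
        region_size = len(landscape.optimal_region(a))
        x1 = round(edo_goodness.dgo_alpha[a] * region_size)
        x2 = round(gao_goodness.dgo_alpha[a] * region_size)
        p_values[a] = one_tailed_two_proportion_test(x1, region_size, x2, region_size)
    return ComparisonReport(
        edo_result=edo_result,
        gao_result=gao_result,
        edo_goodness=edo_goodness,
        gao_goodness=gao_goodness,
        p_values=p_values,
        edo_frequency_table=response_frequency_table(
            edo_result, frequency_threshold, frequency_bin_width
        ),
        gao_frequency_table=response_frequency_table(
            gao_result, frequency_threshold, frequency_bin_width
        ),
        frequency_threshold=frequency_threshold,
    )


@dataclass
class RobustnessResult:
    """Outcome of an initial-population robustness sweep."""

    proportion: float
    threshold: float
    n_replicates: int
    best_values: list[float]
    seeds: list[int]
    n_success: int

    def to_dict(self) -> dict:
        return {
            "proportion": self.proportion,
            "threshold": self.threshold,
            "n_replicates": self.n_replicates,
            "n_success": self.n_success,
            "best_values": self.best_values,
            "seeds": self.seeds,
        }


def robustness_study(
    landscape: CombinatorialLandscape,
    config: EDOConfig | None = None,
    n_replicates: int = 100,
    success_threshold: float = 7.60,
    base_seed: int | None = None,
) -> RobustnessResult:
    """Rerun EDO with ``n_replicates`` different initial populations.

    Replicate ``i`` uses seed ``base_seed + i`` (``base_seed`` defaults to
    the config seed); success means the replicate's best found response is
    >= ``success_threshold``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or EDOConfig()
    if base_seed is None:
        base_seed = config.seed
    seeds = [int(base_seed) + i for i in range(n_replicates)]
    best_values = [
        run_edo(landscape, replace(config, seed=s)).best_value for s in seeds
    ]
    n_success = int(sum(v >= success_threshold for v in best_values))
    return RobustnessResult(
        proportion=n_success / n_replicates,
        threshold=success_threshold,
        n_replicates=n_replicates,
        best_values=best_values,
        seeds=seeds,
        n_success=n_success,
    )
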